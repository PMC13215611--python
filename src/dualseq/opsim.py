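"""Cross-condition similarity of operation embeddings.

Tests the core hypothesis that the operations decoded in the Short
(interfering) condition are the *same* operations the model learned in the
Long condition: for each trial and operation the latent embedding is
averaged over a 13-sample (52 ms) window centred on the operation's peak
predicted probability, and a resampling procedure compares, in cosine
distance, Short-condition operation embeddings against (a) the same
operation and (b) the other operations of the same task in the Long
condition — each relative to the within-Long same-operation baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

EMBED_WINDOW_SAMPLES = 13
PEAK_PROB_MIN = 0.1


@dataclass
class EmbeddingRecord:
    trial: int
    participant: int
    task: int
    operation: str       # "E" | "C" | "R"
    condition: str       # "Short" | "Long"
    peak_sample: int
    vector: np.ndarray


def extract_operation_embeddings(traces: np.ndarray, embeddings: np.ndarray,
                                 valid: np.ndarray, metadata: pd.DataFrame,
                                 task: int, operations=("E", "C", "R"),
                                 window_samples: int = EMBED_WINDOW_SAMPLES,
                                 min_peak_prob: float = PEAK_PROB_MIN):
    """One record per (trial, operation): window-averaged latent vector.

    traces: (n, T, K+1) probabilities for this task's head; embeddings:
    (n, T, F); valid: (n, T) mask.  The peak is the argmax of the
    operation's probability inside the valid window; operations whose peak
    probability stays below ``min_peak_prob`` are skipped (returned in the
    second element for logging).
    """
    if traces.shape[0] == 0:
        raise ValueError("empty traces")
    half = window_samples // 2
    records, skipped = [], []
    for i in range(traces.shape[0]):
        v = valid[i]
        for k, op in enumerate(operations):
            p = np.where(v, traces[i, :, k], -np.inf)
            peak = int(p.argmax())
            if p[peak] < min_peak_prob:
                skipped.append((i, op))
                continue
            lo = max(peak - half, 0)
            hi = min(peak + half + 1, int(v.sum()))
            vec = embeddings[i, lo:hi].mean(axis=0)
            records.append(EmbeddingRecord(
                trial=int(metadata["trial"].iloc[i]),
                participant=int(metadata["participant"].iloc[i]),
                task=task, operation=op,
                condition=str(metadata["condition"].iloc[i]),
                peak_sample=peak, vector=vec))
    return records, skipped


def records_to_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"trial": r.trial, "participant": r.participant, "task": r.task,
               "operation": r.operation, "condition": r.condition,
               "peak_sample": r.peak_sample}
        row.update({f"f{j}": x for j, x in enumerate(r.vector)})
        rows.append(row)
    return pd.DataFrame(rows)


def _mean_pairwise_cosine_distance(a: np.ndarray, b: np.ndarray | None = None
                                   ) -> float:
    """Mean 1 - cos(x, y) over pairs, in closed form.

    The mean pairwise cosine similarity between two sets is exactly the dot
    product of their mean unit vectors, so no pair enumeration (or pair
    subsampling) is needed.  With ``b=None`` the within-set mean over the
    n(n-1) ordered pairs with distinct indices is returned (self-pairs
    excluded analytically).
    """
    an = a / np.linalg.norm(a, axis=1, keepdims=True)
    if b is None:
        n = len(an)
        if n < 2:
            raise ValueError("within-set distance needs >= 2 vectors")
        s = an.sum(axis=0)
        return float(1.0 - (s @ s - n) / (n * (n - 1)))
    bn = b / np.linalg.norm(b, axis=1, keepdims=True)
    return float(1.0 - an.mean(axis=0) @ bn.mean(axis=0))


@dataclass
class SimilaritySummary:
    """Per (task, operation): resampling medians and percentile CIs of the
    same-operation and other-operation statistics."""

    table: pd.DataFrame  # columns: task, operation, stat, median, ci_low, ci_high

    def separation_holds(self) -> bool:
        """Same-operation upper CI below other-operation lower CI everywhere."""
        t = self.table.pivot_table(index=["task", "operation"], columns="stat",
                                   values=["median", "ci_low", "ci_high"])
        same_hi = t[("ci_high", "same")]
        other_lo = t[("ci_low", "other")]
        return bool((same_hi < other_lo).all())


def similarity_resampling(frame: pd.DataFrame, n_iter: int = 1000,
                          n_samp: int = 1000, seed: int = 0,
                          operations=("E", "C", "R")) -> SimilaritySummary:
    """Resampled cross-condition embedding-similarity statistics.

    Per iteration and (task, operation): resample with replacement
    ``n_samp`` vectors from each of Short/same-op, Long/same-op and
    Long/other-ops; compute |D_cross_same - D_within| and
    |D_cross_other - D_within| where D_within is the mean pairwise cosine
    distance within the Long/same-op resample.  Pairwise means are exact
    (closed form over all pairs).  Summaries are medians and [2.5, 97.5]
    percentile CIs over iterations.
    """
    rng = np.random.default_rng(seed)
    fcols = [c for c in frame.columns if c.startswith("f")]
    rows = []
    for task in sorted(frame["task"].unique()):
        ft = frame[frame["task"] == task]
        for op in operations:
            sets = {
                "short_same": ft[(ft.condition == "Short") & (ft.operation == op)],
                "long_same": ft[(ft.condition == "Long") & (ft.operation == op)],
                "long_other": ft[(ft.condition == "Long") & (ft.operation != op)],
            }
            for name, s in sets.items():
                if len(s) == 0:
                    raise ValueError(f"empty embedding set {name} "
                                     f"(task {task}, operation {op})")
            vecs = {k: s[fcols].to_numpy(float) for k, s in sets.items()}
            same_stat = np.empty(n_iter)
            other_stat = np.empty(n_iter)
            for it in range(n_iter):
                r = {k: v[rng.integers(0, len(v), size=n_samp)]
                     for k, v in vecs.items()}
                d_within = _mean_pairwise_cosine_distance(r["long_same"])
                d_same = _mean_pairwise_cosine_distance(
                    r["short_same"], r["long_same"])
                d_other = _mean_pairwise_cosine_distance(
                    r["short_same"], r["long_other"])
                same_stat[it] = abs(d_same - d_within)
                other_stat[it] = abs(d_other - d_within)
            for stat_name, stat in (("same", same_stat), ("other", other_stat)):
                lo, med, hi = np.percentile(stat, [2.5, 50, 97.5])
                rows.append({"task": task, "operation": op, "stat": stat_name,
                             "median": med, "ci_low": lo, "ci_high": hi})
    return SimilaritySummary(table=pd.DataFrame(rows))
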