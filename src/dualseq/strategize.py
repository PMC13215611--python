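"""Per-trial posteriors over cross-task operation sequences.

The sequence model outputs, per task, a probability trace for each
operation's onset.  Shifting the Task 2 traces by the trial's SOA puts all
six operations on a common (Task 1) clock; sampling an onset for each
operation from its normalized trace, discarding draws that violate the
within-task order E→C→R, and classifying each retained draw against the
six-label taxonomy yields a posterior over sequence labels {A..F, INVALID}
that carries the decoding uncertainty forward into behavioural analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sequences import SEQUENCE_LABELS, SEQUENCE_ORDERS

N_DRAWS = 1000
MIN_TOTAL_PROB = 1e-6

_ORDER_TO_LABEL = {order: lab for lab, order in SEQUENCE_ORDERS.items()}
_OPS = ("E1", "C1", "R1", "E2", "C2", "R2")


class UndecodableTrial(Exception):
    """An operation's trace carries (near) zero total probability."""


def sample_onsets(trace_task1: np.ndarray, trace_task2: np.ndarray,
                  soa_samples: int, n: int = N_DRAWS,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """Joint onset draws on the common clock; only order-valid draws kept.

    trace_task1 / trace_task2: (T, >=3) per-timestep operation
    probabilities (columns E, C, R; extra columns such as Negative are
    ignored).  Task 2 onsets are shifted by +soa_samples.  Returns an
    (n_retained, 6) integer array of onsets ordered as E1,C1,R1,E2,C2,R2.
    """
    rng = np.random.default_rng() if rng is None else rng
    draws = np.empty((n, 6), dtype=np.float64)
    for j, (trace, shift) in enumerate(
            ((trace_task1, 0), (trace_task2, soa_samples))):
        for k in range(3):
            p = np.asarray(trace[:, k], dtype=np.float64).clip(min=0)
            tot = p.sum()
            if tot < MIN_TOTAL_PROB:
                raise UndecodableTrial(
                    f"operation {_OPS[3 * j + k]} has total probability {tot:.2e}")
            cdf = np.cumsum(p / tot)
            bins = np.searchsorted(cdf, rng.random(n))
            # onsets are continuous; a uniform draw within the sample bin
            # keeps cross-task comparisons free of discretization ties
            draws[:, 3 * j + k] = bins + rng.random(n) + shift
    ok = ((draws[:, 0] < draws[:, 1]) & (draws[:, 1] < draws[:, 2])
          & (draws[:, 3] < draws[:, 4]) & (draws[:, 4] < draws[:, 5]))
    return draws[ok]


def classify_sequence(onsets) -> str:
    """Map six onsets (E1,C1,R1,E2,C2,R2 on a common clock) to a label.

    Exact ties between onsets are conservatively INVALID — with ties the
    interleaving is not identifiable.  Any ordering outside the six-label
    taxonomy (e.g. E2 before E1, or R1 after R2) is INVALID too.
    """
    onsets = np.asarray(onsets)
    if len(np.unique(onsets)) < 6:
        return "INVALID"
    order = tuple(np.array(_OPS)[np.argsort(onsets)])
    return _ORDER_TO_LABEL.get(order, "INVALID")


@dataclass
class SequencePosterior:
    trial: int
    counts: dict          # label -> retained-draw count (incl. INVALID)
    n_drawn: int
    n_retained: int

    @property
    def probabilities(self) -> dict:
        if self.n_retained == 0:
            return {}
        return {k: v / self.n_retained for k, v in self.counts.items() if v}

    @property
    def mode(self) -> str | None:
        probs = self.probabilities
        return max(probs, key=probs.get) if probs else None


def sequence_posterior(retained: np.ndarray, trial: int = -1,
                       n_drawn: int = N_DRAWS) -> SequencePosterior:
    """Label relative frequencies among retained draws."""
    if len(retained) == 0:
        raise UndecodableTrial("no retained draws")
    counts = {}
    for row in retained:
        lab = classify_sequence(row)
        counts[lab] = counts.get(lab, 0) + 1
    return SequencePosterior(trial=trial, counts=counts, n_drawn=n_drawn,
                             n_retained=int(len(retained)))


def decode_trials(traces1: np.ndarray, traces2: np.ndarray,
                  valid1: np.ndarray, valid2: np.ndarray,
                  stim1: np.ndarray, stim2: np.ndarray,
                  soa_ms: np.ndarray, fs: float, n: int = N_DRAWS,
                  seed: int = 0) -> pd.DataFrame:
    """Decode every trial; returns the posterior table.

    traces*: (n_trials, T, 4) per-task probability traces on padded
    windows; onsets are measured from each task's stimulus sample and the
    Task 2 clock is shifted by the SOA.  Columns: trial, n_retained,
    p_A..p_F, p_INVALID, mode, decodable.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(traces1.shape[0]):
        t1 = traces1[i][valid1[i]][int(stim1[i]):]
        t2 = traces2[i][valid2[i]][int(stim2[i]):]
        soa_samples = int(round(soa_ms[i] / 1000.0 * fs))
        row = {"trial": i, "n_retained": 0, "decodable": False, "mode": None}
        row.update({f"p_{lab}": 0.0 for lab in SEQUENCE_LABELS})
        row["p_INVALID"] = 0.0
        try:
            retained = sample_onsets(t1, t2, soa_samples, n=n, rng=rng)
            post = sequence_posterior(retained, trial=i, n_drawn=n)
        except UndecodableTrial:
            rows.append(row)
            continue
        row["n_retained"] = post.n_retained
        row["decodable"] = True
        row["mode"] = post.mode
        for lab, p in post.probabilities.items():
            row[f"p_{lab}"] = p
        rows.append(row)
    return pd.DataFrame(rows)
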