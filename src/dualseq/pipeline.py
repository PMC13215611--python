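"""End-to-end orchestration of the trial-level sequence analysis.

Stages, mirroring the analysis design:

1. Long-condition epochs of each task (training participants only) are
   band-passed, average-referenced and cropped, a 10-component spatial
   basis is fitted, and the gamma-constrained EM decomposition estimates
   per-trial onset distributions for the three operations — optionally
   after tuning the event width for stability.
2. The onset distributions become per-timestep soft labels (with a
   Negative class) for all Long trials, and the sequence labeler is
   trained on MAD-z-scored raw epochs of both tasks jointly, with jitter,
   KL loss and early stopping, validated on held-out participants.
3. The trained model is applied to every trial of both conditions,
   yielding probability traces and latent embeddings.
4. Operation embeddings are compared across conditions (resampled cosine
   distances), and per-trial sequence posteriors are decoded from the
   SOA-aligned traces.
5. Sequence posteriors drive multiply-imputed mixed-model analyses of
   Task 1 behaviour, pooled by Rubin's rules with Holm-adjusted contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import eventdecomp as ed
from .behavior import impute_and_fit, pool_all
from .opsim import (extract_operation_embeddings, records_to_frame,
                    similarity_resampling, SimilaritySummary)
from .preprocess import (compute_norm_stats, mad_zscore,
                         prepare_for_decomposition, split_participants)
from .seqmodel import ModelConfig, SequenceModel, build_model, infer, train_model
from .strategize import decode_trials
from .synthdata import EpochSet

MIN_RT_S = 0.2


@dataclass
class PipelineResult:
    event_models: dict            # task -> EventModel
    chosen_widths: dict           # task -> float (ms)
    width_profiles: dict          # task -> {width: K}
    em_onset_errors: dict         # (task, op) -> median |err| ms (Long train)
    model: SequenceModel
    history: dict
    model_onset_errors: dict      # (task, op) -> median |err| ms (Long held-out)
    similarity: SimilaritySummary
    embedding_frame: pd.DataFrame
    posteriors: pd.DataFrame      # per-trial sequence posteriors (+ metadata)
    pooled: pd.DataFrame
    decode_stats: dict

    def summary(self) -> dict:
        out = {
            "chosen_width_ms": self.chosen_widths,
            "n_events": {t: m.n_events for t, m in self.event_models.items()},
            "em_onset_median_err_ms": {f"{t}:{op}": v for (t, op), v
                                       in self.em_onset_errors.items()},
            "model_onset_median_err_ms": {f"{t}:{op}": v for (t, op), v
                                          in self.model_onset_errors.items()},
            "embedding_separation": self.similarity.separation_holds(),
        }
        out.update(self.decode_stats)
        return out


OPS_BY_TASK = {1: ("E1", "C1", "R1"), 2: ("E2", "C2", "R2")}


def _true_onsets_ms(truth: pd.DataFrame, meta: pd.DataFrame, task: int):
    """(n, 3) planted onsets in ms from this task's own stimulus."""
    tt = truth.set_index("trial").loc[meta["trial"].to_numpy()]
    ops = OPS_BY_TASK[task]
    ons = np.stack([tt[f"onset_{op}"].to_numpy() for op in ops], axis=1)
    if task == 2:
        ons = ons - tt["soa_ms"].to_numpy()[:, None]
    return ons


def fit_decomposition(epochs: EpochSet, train_ids, widths=None,
                      fixed_width_ms: float = 50.0, n_components: int = 10,
                      K_max: int = 6, scan_max_iter: int = 60,
                      scan_subsample: int = 300):
    """Stage 1 for one task.  Returns a dict of fitted pieces.

    The width scan decides only the event count per width and the stable
    width, both insensitive to fit precision, so it runs EM with a capped
    iteration budget on an evenly-spaced subsample of at most
    ``scan_subsample`` training trials; the chosen width's model is then
    refitted on all training trials with the full budget before labelling.
    """
    fs = epochs.fs
    rt_ok = (epochs.rt_sample - epochs.stim_sample) / fs >= MIN_RT_S
    long_mask = (epochs.metadata["condition"] == "Long").to_numpy() & rt_ok
    elong = epochs.subset(long_mask)
    tr_mask = elong.metadata["participant"].isin(train_ids).to_numpy()
    prep_tr = prepare_for_decomposition(elong.subset(tr_mask))
    basis = ed.fit_spatial_basis(prep_tr, n_components)

    if widths is not None:
        step = max(1, prep_tr.n_trials // scan_subsample)
        prep_scan = prep_tr.subset(np.arange(0, prep_tr.n_trials, step))

        def factory(w):
            return ed.compute_matches(prep_scan, basis,
                                      ed.half_sine_template(w, fs))[0]

        width, model, _, profile = ed.tune_event_width(
            factory, list(widths), K_max=K_max, fs=fs,
            max_iter=scan_max_iter)
        template = ed.half_sine_template(width, fs)
        if model.n_events == 0:
            raise RuntimeError("decomposition found no events")
        # refit the chosen order on all training trials, full budget
        m_tr, mstats = ed.compute_matches(prep_tr, basis, template)
        model, _ = ed.em_fit(m_tr, model.n_events, init=model,
                             width_ms=width, fs=fs)
    else:
        width = fixed_width_ms
        template = ed.half_sine_template(width, fs)
        m_tr, mstats = ed.compute_matches(prep_tr, basis, template)
        model, _ = ed.cumulative_fit(m_tr, K_max, width_ms=width, fs=fs)
        profile = {width: model.n_events}
    if model.n_events == 0:
        raise RuntimeError("decomposition found no events")

    # soft labels for all Long trials (fixed parameters, E-step only)
    prep_all = prepare_for_decomposition(elong)
    m_all, _ = ed.compute_matches(prep_all, basis, template, stats=mstats)
    onsets_all = ed.estimate_onsets(m_all, model)
    labels = ed.build_label_tensors(onsets_all, elong.stim_sample,
                                    elong.data.shape[2], elong.valid_samples)
    return {"long": elong, "train_mask": tr_mask, "basis": basis,
            "template": template, "match_stats": mstats, "model": model,
            "onsets": onsets_all, "labels": labels, "width": width,
            "profile": profile}


def run_pipeline(epochs: dict, truth: pd.DataFrame, seed: int = 0,
                 widths=None, fixed_width_ms: float = 50.0,
                 train_fraction: float = 0.85, lr: float = 1e-3,
                 max_epochs: int = 40, model_config: ModelConfig | None = None,
                 n_decode_draws: int = 1000, m_imputations: int = 100,
                 n_similarity_iter: int = 1000, verbose: bool = False,
                 ) -> PipelineResult:
    """Run stages 1-5 on a task-keyed dict of EpochSets plus ground truth.

    ``widths=None`` skips the width scan and fits at ``fixed_width_ms``;
    pass e.g. ``range(20, 61, 5)`` for the stability scan.
    """
    rng = np.random.default_rng(seed)
    fs = epochs[1].fs
    train_ids, val_ids = split_participants(
        epochs[1].metadata["participant"].to_numpy(), train_fraction,
        seed=int(rng.integers(2**31)))

    # --- stage 1: decomposition
    dec = {}
    em_errors = {}
    for task in (1, 2):
        dec[task] = fit_decomposition(epochs[task], train_ids, widths=widths,
                                      fixed_width_ms=fixed_width_ms)
        est_ms = dec[task]["onsets"].expected_onsets() / fs * 1000.0
        true_ms = _true_onsets_ms(truth, dec[task]["long"].metadata, task)
        for k, op in enumerate(OPS_BY_TASK[task][:dec[task]["model"].n_events]):
            em_errors[(task, op)] = float(np.median(
                np.abs(est_ms[:, k] - true_ms[:, k])))

    # --- stage 2: sequence model training on Long trials
    train_sets, val_sets, tr_labels, va_labels, norm_stats = {}, {}, {}, {}, {}
    for task in (1, 2):
        elong = dec[task]["long"]
        tr_mask = dec[task]["train_mask"]
        etr, eva = elong.subset(tr_mask), elong.subset(~tr_mask)
        ns = compute_norm_stats(etr)
        norm_stats[task] = ns
        train_sets[task] = mad_zscore(etr, ns)
        val_sets[task] = mad_zscore(eva, ns)
        tr_labels[task] = dec[task]["labels"][tr_mask]
        va_labels[task] = dec[task]["labels"][~tr_mask]

    mcfg = model_config or ModelConfig(n_channels=epochs[1].n_channels, fs=fs,
                                       seed=int(rng.integers(2**31)))
    model = build_model(mcfg)
    model, history = train_model(model, train_sets, val_sets, tr_labels,
                                 va_labels, lr=lr, max_epochs=max_epochs,
                                 seed=int(rng.integers(2**31)),
                                 verbose=verbose)

    # --- stage 3: inference everywhere
    traces, embs, valids, zsets = {}, {}, {}, {}
    for task in (1, 2):
        z = mad_zscore(epochs[task], norm_stats[task])
        zsets[task] = z
        tr, emb, valid = infer(model, z)
        traces[task] = tr[task - 1]
        embs[task] = emb
        valids[task] = valid

    # model onset recovery on held-out Long trials
    model_errors = {}
    for task in (1, 2):
        meta = epochs[task].metadata
        hold = ((meta["condition"] == "Long")
                & meta["participant"].isin(val_ids)).to_numpy()
        idx = np.flatnonzero(hold)
        true_ms = _true_onsets_ms(truth, meta.iloc[idx], task)
        for k, op in enumerate(OPS_BY_TASK[task]):
            errs = []
            for j, i in enumerate(idx):
                p = np.where(valids[task][i], traces[task][i, :, k], -np.inf)
                est = (p.argmax() - epochs[task].stim_sample[i]) / fs * 1000.0
                errs.append(abs(est - true_ms[j, k]))
            model_errors[(task, op)] = float(np.median(errs))

    # --- stage 4a: embedding similarity (Long held-out + all Short)
    frames = []
    for task in (1, 2):
        meta = epochs[task].metadata
        use = ((meta["condition"] == "Short")
               | meta["participant"].isin(val_ids)).to_numpy()
        idx = np.flatnonzero(use)
        recs, _ = extract_operation_embeddings(
            traces[task][idx], embs[task][idx], valids[task][idx],
            meta.iloc[idx].reset_index(drop=True), task)
        frames.append(records_to_frame(recs))
    embedding_frame = pd.concat(frames, ignore_index=True)
    similarity = similarity_resampling(embedding_frame,
                                       n_iter=n_similarity_iter,
                                       seed=int(rng.integers(2**31)))

    # --- stage 4b: sequence decoding (all trials; Long as validation)
    meta1 = epochs[1].metadata
    posteriors = decode_trials(
        traces[1], traces[2], valids[1], valids[2],
        epochs[1].stim_sample, epochs[2].stim_sample,
        meta1["soa_ms"].to_numpy(), fs, n=n_decode_draws,
        seed=int(rng.integers(2**31)))
    posteriors["condition"] = meta1["condition"].to_numpy()
    posteriors["participant"] = meta1["participant"].to_numpy()
    truth_lab = truth.set_index("trial")["sequence_label"]
    posteriors["true_label"] = truth_lab.loc[meta1["trial"]].to_numpy()

    dd = posteriors[posteriors["decodable"]]
    short = dd[dd["condition"] == "Short"]
    long_ = dd[dd["condition"] == "Long"]
    decode_stats = {
        "n_decodable": int(len(dd)),
        "short_mode_accuracy": float((short["mode"] == short["true_label"]).mean()),
        "long_mode_A_rate": float((long_["mode"] == "A").mean()),
        "invalid_draw_fraction": float(
            (dd["p_INVALID"] * dd["n_retained"]).sum() / dd["n_retained"].sum()),
    }

    # --- stage 5: behaviour (Short condition, Task 1 RT and accuracy)
    usable = short[short[[f"p_{l}" for l in "ABCDEF"]].sum(axis=1) > 0]
    behavior = pd.DataFrame({
        "trial": meta1["trial"].to_numpy(),
        "participant": meta1["participant"].to_numpy(),
        "rt": meta1["rt_ms"].to_numpy(),
        "correct": meta1["correct"].to_numpy().astype(int),
    })
    imputed = impute_and_fit(usable[["trial"] + [f"p_{l}" for l in "ABCDEF"]],
                             behavior, m=m_imputations,
                             seed=int(rng.integers(2**31)))
    pooled = pool_all(imputed)

    return PipelineResult(
        event_models={t: dec[t]["model"] for t in (1, 2)},
        chosen_widths={t: dec[t]["width"] for t in (1, 2)},
        width_profiles={t: dec[t]["profile"] for t in (1, 2)},
        em_onset_errors=em_errors, model=model, history=history,
        model_onset_errors=model_errors, similarity=similarity,
        embedding_frame=embedding_frame, posteriors=posteriors,
        pooled=pooled, decode_stats=decode_stats)
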