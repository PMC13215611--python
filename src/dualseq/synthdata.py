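"""Synthetic dual-task EEG generator with known ground truth.

Emulates the psychological-refractory-period (PRP) design: on every trial a
visual Task 1 is followed, after a stimulus-onset asynchrony (SOA) of 300 ms
(Short condition) or 1200 ms (Long condition), by an auditory Task 2.  Each
task passes through three latent cognitive operations — Encoding (E),
Central (C) and Response (R) — whose onsets are marked in the EEG by a brief
topographic half-sine event.  Inter-onset stage durations are gamma
distributed (shape 2), matching the prior used by the event decomposition.

In the Long condition the two tasks never overlap, so the cross-task
operation ordering is always the serial sequence A (E1→C1→R1→E2→C2→R2).  In
the Short condition each participant mixes the six valid cross-task
interleavings A–F; the planted sequence label drives both the onset ordering
and (configurably) reaction time and accuracy, so the full pipeline —
decomposition, sequence labelling, decoding and behavioural modelling — can
be validated against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sequences import SEQUENCE_ORDERS, SEQUENCE_LABELS

OPERATIONS = ("E1", "C1", "R1", "E2", "C2", "R2")

#: gamma shape for stage durations; scale is mean/GAMMA_SHAPE
GAMMA_SHAPE = 2.0


@dataclass
class SimConfig:
    """Generator settings. Defaults define the package's study conditions."""

    n_participants: int = 6
    trials_per_condition: int = 120
    fs: float = 250.0
    n_channels: int = 32
    event_width_ms: float = 50.0
    #: per-task (stimulus→E, E→C, C→R) mean stage durations in ms
    stage_mean_ms: tuple = ((100.0, 180.0, 180.0), (80.0, 160.0, 160.0))
    soa_short_ms: float = 300.0
    soa_long_ms: float = 1200.0
    #: Short-condition probability over sequence labels A..F
    strategy_mixture: tuple = (0.25, 0.15, 0.15, 0.15, 0.15, 0.15)
    #: mean inter-onset gap (ms) used when building Short-condition orderings
    short_gap_mean_ms: float = 110.0
    amplitude: float = 1.0
    noise_sd: float = 0.5
    ar_coef: float = 0.0  # optional AR(1) noise colouring
    motor_delay_ms: float = 100.0
    #: per-label Task 1 RT shift (ms) and accuracy logit shift
    rt_shift_ms: dict = field(default_factory=lambda: {
        "A": 0.0, "B": 20.0, "C": 35.0, "D": 50.0, "E": 65.0, "F": 80.0})
    acc_logit_shift: dict = field(default_factory=lambda: {
        "A": 0.0, "B": 0.5, "C": 0.5, "D": 0.8, "E": 0.8, "F": 1.0})
    base_acc_logit: float = 1.5
    pre_pad_ms: float = 250.0
    post_pad_ms: float = 300.0
    seed: int = 0

    def validate(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")
        for means in self.stage_mean_ms:
            if any(m <= 0 for m in means):
                raise ValueError("stage means must be positive")
        if self.soa_short_ms <= 0 or self.soa_long_ms <= 0:
            raise ValueError("SOAs must be positive")
        mix = np.asarray(self.strategy_mixture, float)
        if mix.shape != (6,) or not np.isclose(mix.sum(), 1.0) or (mix < 0).any():
            raise ValueError("strategy_mixture must be 6 probabilities summing to 1")


@dataclass
class TrialTruth:
    """Ground truth for one dual-task trial (times in ms from Task 1 stimulus)."""

    participant: int
    condition: str          # "Short" | "Long"
    sequence_label: str     # A..F
    onsets: dict            # operation -> onset ms on the Task 1 clock
    soa_ms: float
    rt1_ms: float
    rt2_ms: float           # measured from the Task 2 stimulus
    correct1: bool
    correct2: bool


@dataclass
class EpochSet:
    """Trials × channels × samples with per-trial alignment bookkeeping.

    ``data`` is padded to the longest trial; ``valid_samples[i]`` gives each
    trial's true length.  Sample 0 is the start of the pre-stimulus pad,
    ``stim_sample`` the task's own stimulus onset and ``rt_sample`` the
    response; the window always extends ``pre_pad_ms`` before the stimulus
    and ``post_pad_ms`` beyond the response.
    """

    data: np.ndarray          # (n_trials, n_channels, n_samples)
    fs: float
    stim_sample: np.ndarray   # (n_trials,)
    rt_sample: np.ndarray     # (n_trials,)
    valid_samples: np.ndarray  # (n_trials,)
    metadata: pd.DataFrame
    pre_pad_ms: float = 250.0
    post_pad_ms: float = 300.0

    def __post_init__(self):
        n = self.data.shape[0]
        for arr in (self.stim_sample, self.rt_sample, self.valid_samples):
            if len(arr) != n:
                raise ValueError("per-trial arrays must match n_trials")
        if np.any(self.stim_sample < 0) or np.any(self.rt_sample <= self.stim_sample):
            raise ValueError("need 0 <= stim_sample < rt_sample")
        if np.any(self.rt_sample >= self.valid_samples):
            raise ValueError("rt_sample must precede the end of the valid window")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def subset(self, idx) -> "EpochSet":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return EpochSet(
            data=self.data[idx],
            fs=self.fs,
            stim_sample=self.stim_sample[idx],
            rt_sample=self.rt_sample[idx],
            valid_samples=self.valid_samples[idx],
            metadata=self.metadata.iloc[idx].reset_index(drop=True),
            pre_pad_ms=self.pre_pad_ms,
            post_pad_ms=self.post_pad_ms,
        )


def make_topographies(n_operations: int, n_channels: int, seed: int) -> np.ndarray:
    """Distinct unit-norm channel patterns, one per cognitive operation.

    Patterns are mutually orthogonal (pairwise cosine similarity 0), the
    strongest form of the distinctness the downstream analysis assumes.
    """
    if n_operations > n_channels:
        raise ValueError(
            f"cannot place {n_operations} separable patterns in {n_channels} channels")
    rng = np.random.default_rng(seed)
    g = rng.standard_normal((n_channels, n_operations))
    q, r = np.linalg.qr(g)
    q = q * np.sign(np.diag(r))  # deterministic sign convention
    return q.T.copy()  # (n_operations, n_channels), rows unit norm


def _gamma_ms(rng: np.random.Generator, mean_ms: float, size=None) -> np.ndarray:
    return rng.gamma(GAMMA_SHAPE, mean_ms / GAMMA_SHAPE, size=size)


def sample_trial_onsets(config: SimConfig, participant: int, condition: str,
                        rng: np.random.Generator) -> TrialTruth:
    """Draw one trial's latent operation onsets, label and behaviour.

    Long condition: each task's three onsets accumulate gamma stage
    durations from its own stimulus; Task 2 starts at the long SOA, so the
    label is A by construction (trials whose Task 1 response would spill
    past the SOA are redrawn).  Short condition: a label is drawn from the
    participant's strategy mixture and the six onsets are built as
    cumulative gamma gaps in the label's order, with Task 2's first onset
    floored at the SOA plus a Task 2 encoding latency so that every onset
    is causal with respect to its own stimulus.
    """
    config.validate()
    m1, m2 = config.stage_mean_ms
    if condition == "Long":
        soa = config.soa_long_ms
        while True:
            t1 = np.cumsum(_gamma_ms(rng, np.asarray(m1)))
            if t1[-1] < soa:
                break
        t2 = soa + np.cumsum(_gamma_ms(rng, np.asarray(m2)))
        onsets = dict(zip(OPERATIONS, np.concatenate([t1, t2])))
        label = "A"
    elif condition == "Short":
        soa = config.soa_short_ms
        mix = np.asarray(config.strategy_mixture, float)
        label = SEQUENCE_LABELS[rng.choice(6, p=mix)]
        order = SEQUENCE_ORDERS[label]
        times = np.empty(6)
        times[0] = _gamma_ms(rng, m1[0])  # order always starts with E1
        gaps = _gamma_ms(rng, config.short_gap_mean_ms, size=5)
        for i in range(1, 6):
            times[i] = times[i - 1] + gaps[i - 1]
        # Task 2 cannot start before its own stimulus: floor E2 at
        # soa + encoding latency and shift everything after it in the order.
        e2_pos = order.index("E2")
        floor = soa + _gamma_ms(rng, m2[0])
        deficit = floor - times[e2_pos]
        if deficit > 0:
            times[e2_pos:] += deficit
        onsets = {op: times[i] for i, op in enumerate(order)}
    else:
        raise ValueError(f"unknown condition {condition!r}")

    motor1 = _gamma_ms(rng, config.motor_delay_ms)
    motor2 = _gamma_ms(rng, config.motor_delay_ms)
    rt1 = onsets["R1"] + motor1 + config.rt_shift_ms.get(label, 0.0)
    rt2 = onsets["R2"] - soa + motor2
    logit = config.base_acc_logit + config.acc_logit_shift.get(label, 0.0)
    p_correct = 1.0 / (1.0 + np.exp(-logit))
    return TrialTruth(
        participant=participant, condition=condition, sequence_label=label,
        onsets=onsets, soa_ms=soa, rt1_ms=float(rt1), rt2_ms=float(rt2),
        correct1=bool(rng.random() < p_correct),
        correct2=bool(rng.random() < 1.0 / (1.0 + np.exp(-config.base_acc_logit))),
    )


def half_sine(width_samples: int) -> np.ndarray:
    """Positive half-sine event waveform, peak amplitude 1."""
    i = np.arange(width_samples)
    return np.sin(np.pi * (i + 0.5) / width_samples)


def render_epochs(truths: list, topographies: np.ndarray, config: SimConfig,
                  rng: np.random.Generator, task: int = 1):
    """Render one task's epochs (time-locked to that task's stimulus).

    Every operation of *both* tasks that falls inside a window is drawn into
    it, so Short-condition epochs contain cross-task activity exactly as
    real recordings would.  signal = Σ_ops amplitude · topography ⊗
    half-sine(event_width) centred at the onset, plus Gaussian noise
    (optionally AR(1)-coloured).

    Returns (EpochSet, truth DataFrame aligned to trials).
    """
    if task not in (1, 2):
        raise ValueError("task must be 1 or 2")
    fs = config.fs
    pre = int(round(config.pre_pad_ms / 1000.0 * fs))
    post = int(round(config.post_pad_ms / 1000.0 * fs))
    w = int(round(config.event_width_ms / 1000.0 * fs))
    wave = half_sine(w) * config.amplitude
    half_w = w // 2

    rts = []
    offsets = []
    for tr in truths:
        offset = 0.0 if task == 1 else tr.soa_ms  # task clock origin on T1 clock
        rt = tr.rt1_ms if task == 1 else tr.rt2_ms
        rts.append(rt)
        offsets.append(offset)
    rt_samples = np.array([int(round(r / 1000.0 * fs)) for r in rts])
    valid = pre + rt_samples + post + 1
    n_samples = int(valid.max())
    n = len(truths)
    data = np.zeros((n, config.n_channels, n_samples), dtype=np.float64)

    for i, tr in enumerate(truths):
        T = valid[i]
        noise = rng.standard_normal((config.n_channels, T)) * config.noise_sd
        if config.ar_coef:
            a = config.ar_coef
            for t in range(1, T):
                noise[:, t] += a * noise[:, t - 1]
            noise *= np.sqrt(1 - a * a)
        data[i, :, :T] = noise
        for k, op in enumerate(OPERATIONS):
            onset_ms = tr.onsets[op] - offsets[i]
            center = pre + int(round(onset_ms / 1000.0 * fs))
            start = center - half_w
            if start + w <= 0 or start >= T:
                continue  # outside this task's window: not rendered here
            lo = max(start, 0)
            hi = min(start + w, T)
            data[i, :, lo:hi] += np.outer(topographies[k], wave[lo - start:hi - start])
        # onsets for this task's own operations must fit inside the window
        own = OPERATIONS[:3] if task == 1 else OPERATIONS[3:]
        for op in own:
            c = pre + int(round((tr.onsets[op] - offsets[i]) / 1000.0 * fs))
            if not (0 <= c < T):
                raise ValueError(
                    f"trial {i}: onset {op} at sample {c} outside window of {T}")

    meta = pd.DataFrame({
        "trial": np.arange(n),
        "participant": [tr.participant for tr in truths],
        "condition": [tr.condition for tr in truths],
        "task": task,
        "soa_ms": [tr.soa_ms for tr in truths],
        "rt_ms": rts,
        "correct": [tr.correct1 if task == 1 else tr.correct2 for tr in truths],
    })
    truth = truth_table(truths)
    truth["trial"] = np.arange(n)
    epochs = EpochSet(
        data=data.astype(np.float32), fs=fs,
        stim_sample=np.full(n, pre, dtype=int),
        rt_sample=pre + rt_samples,
        valid_samples=valid.astype(int),
        metadata=meta,
        pre_pad_ms=config.pre_pad_ms, post_pad_ms=config.post_pad_ms,
    )
    return epochs, truth


def truth_table(truths: list) -> pd.DataFrame:
    rows = []
    for tr in truths:
        row = {
            "participant": tr.participant, "condition": tr.condition,
            "sequence_label": tr.sequence_label, "soa_ms": tr.soa_ms,
            "rt1_ms": tr.rt1_ms, "rt2_ms": tr.rt2_ms,
            "correct1": tr.correct1, "correct2": tr.correct2,
        }
        for op in OPERATIONS:
            row[f"onset_{op}"] = tr.onsets[op]
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_behavior_posteriors(n_trials: int = 600, n_participants: int = 6,
                                 mixture=(0.3, 0.14, 0.14, 0.14, 0.14, 0.14),
                                 concentration: float = 0.01,
                                 rt_shift_ms: dict | None = None,
                                 base_rt_ms: float = 560.0,
                                 participant_sd_ms: float = 15.0,
                                 resid_sd_ms: float = 60.0,
                                 seed: int = 0):
    """Behaviour-level draw for testing the imputation machinery in isolation.

    Per trial a sequence posterior p_i ~ Dirichlet(6 * concentration *
    mixture) is drawn, the true label from Categorical(p_i), and RT from
    the label's shift plus a participant random intercept and residual
    noise — so p_i is by construction the correct posterior of the label
    and multiple imputation from it is proper.  Small ``concentration``
    gives sparse, informative posteriors (most mass on one label, as the
    decoder produces on well-decoded trials); large values approach
    uninformative posteriors equal to the mixture.  Returns (posteriors,
    behavior, truth labels) with the column layout the behavior module
    consumes.
    """
    rng = np.random.default_rng(seed)
    shift = {"A": 0.0, "B": 20.0, "C": 35.0, "D": 50.0, "E": 65.0, "F": 80.0} \
        if rt_shift_ms is None else rt_shift_ms
    alpha = np.asarray(mixture, float) * 6.0 * concentration
    probs = rng.dirichlet(alpha, size=n_trials)
    lab_idx = (rng.random(n_trials)[:, None] >
               np.cumsum(probs, axis=1)).sum(axis=1)
    labels = np.array(SEQUENCE_LABELS)[lab_idx]
    pid = rng.integers(0, n_participants, n_trials)
    p_eff = rng.standard_normal(n_participants) * participant_sd_ms
    rt = (base_rt_ms + np.array([shift[l] for l in labels])
          + p_eff[pid] + rng.standard_normal(n_trials) * resid_sd_ms)
    correct = (rng.random(n_trials) < 0.85).astype(int)
    posteriors = pd.DataFrame({"trial": np.arange(n_trials)})
    for j, lab in enumerate(SEQUENCE_LABELS):
        posteriors[f"p_{lab}"] = probs[:, j]
    behavior = pd.DataFrame({"trial": np.arange(n_trials), "participant": pid,
                             "rt": rt, "correct": correct})
    return posteriors, behavior, labels


def generate_dataset(config: SimConfig):
    """Full study draw: returns ({1: EpochSet, 2: EpochSet}, truth DataFrame).

    Both epoch sets cover the same trials in the same order; Task 1 epochs
    are time-locked to the Task 1 stimulus, Task 2 epochs to the Task 2
    stimulus.  The truth table (one row per trial, shared across tasks)
    keeps onsets on the Task 1 clock.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    truths = []
    for p in range(config.n_participants):
        for condition in ("Long", "Short"):
            for _ in range(config.trials_per_condition):
                truths.append(sample_trial_onsets(config, p, condition, rng))
    epochs = {}
    truth = None
    for task in (1, 2):
        task_rng = np.random.default_rng(rng.integers(2**31))
        epochs[task], truth = render_epochs(truths, make_topographies(
            6, config.n_channels, config.seed), config, task_rng, task=task)
    return epochs, truth
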