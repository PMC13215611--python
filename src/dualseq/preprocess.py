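"""Epoch conditioning for the two analysis branches.

The event decomposition consumes average-referenced, 1–50 Hz band-passed
epochs cropped from stimulus onset to 50 ms past the response, with
fast-guess trials (RT < 0.2 s) removed.  The sequence model consumes the
full padded windows, robustly standardized by median/MAD statistics
estimated on the training split only, and — during training — randomly
jittered within the pre-stimulus and post-response pads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.stats import median_abs_deviation

from .synthdata import EpochSet

#: consistency constant making MAD comparable to the SD under normality
MAD_SCALE = 1.4826


@dataclass
class NormStats:
    """Per-channel robust location/scale, estimated on training trials only."""

    median: np.ndarray  # (n_channels,)
    mad: np.ndarray     # (n_channels,)

    def __post_init__(self):
        if np.any(self.mad <= 0):
            raise ValueError("degenerate channel: MAD must be positive")


def _valid_concat(epochs: EpochSet) -> np.ndarray:
    """Stack every trial's valid samples into one (n_channels, total) array."""
    parts = [epochs.data[i, :, :epochs.valid_samples[i]]
             for i in range(epochs.n_trials)]
    return np.concatenate(parts, axis=1)


def compute_norm_stats(train: EpochSet) -> NormStats:
    x = _valid_concat(train)
    return NormStats(median=np.median(x, axis=1),
                     mad=median_abs_deviation(x, axis=1, scale=1.0))


def mad_zscore(epochs: EpochSet, stats: NormStats) -> EpochSet:
    """z = (x - median) / (1.4826 * MAD), per channel."""
    med = stats.median[None, :, None]
    scale = (MAD_SCALE * stats.mad)[None, :, None]
    data = (epochs.data - med) / scale
    # zero out padding beyond each trial's valid window
    for i in range(epochs.n_trials):
        data[i, :, epochs.valid_samples[i]:] = 0.0
    return EpochSet(data=data.astype(np.float32), fs=epochs.fs,
                    stim_sample=epochs.stim_sample.copy(),
                    rt_sample=epochs.rt_sample.copy(),
                    valid_samples=epochs.valid_samples.copy(),
                    metadata=epochs.metadata.copy(),
                    pre_pad_ms=epochs.pre_pad_ms, post_pad_ms=epochs.post_pad_ms)


def post_rt_samples(fs: float, extra_ms: float = 50.0) -> int:
    """Samples of post-response signal kept for the decomposition.

    Rounded *up* (50 ms at 250 Hz = 12.5 → 13) so at least the stated
    duration is retained.
    """
    return int(np.ceil(extra_ms / 1000.0 * fs))


def prepare_for_decomposition(epochs: EpochSet, low: float = 1.0,
                              high: float = 50.0, min_rt_s: float = 0.2) -> EpochSet:
    """Average-reference, band-pass, drop fast guesses, crop to [stim, RT+50 ms].

    Filtering is zero-phase (forward-backward butterworth) so onsets are not
    latency shifted.  Returned epochs are re-aligned: sample 0 is stimulus
    onset and the pads are gone.
    """
    fs = epochs.fs
    if not (0 < low < high):
        raise ValueError("need 0 < low < high")
    if high >= fs / 2:
        raise ValueError(f"high cutoff {high} Hz at or above Nyquist ({fs / 2} Hz)")
    keep = (epochs.rt_sample - epochs.stim_sample) / fs >= min_rt_s
    if not keep.any():
        raise ValueError("no trials remain after the minimum-RT filter")
    sub = epochs.subset(keep)

    sos = signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    extra = post_rt_samples(fs)
    lengths = (sub.rt_sample - sub.stim_sample) + extra
    n_samples = int(lengths.max())
    out = np.zeros((sub.n_trials, sub.n_channels, n_samples), dtype=np.float32)
    for i in range(sub.n_trials):
        x = sub.data[i, :, :sub.valid_samples[i]].astype(np.float64)
        x = x - x.mean(axis=0, keepdims=True)        # average reference
        x = signal.sosfiltfilt(sos, x, axis=1)       # zero-phase band-pass
        s, e = sub.stim_sample[i], sub.stim_sample[i] + lengths[i]
        out[i, :, :lengths[i]] = x[:, s:e]

    meta = sub.metadata.copy()
    return EpochSet(data=out, fs=fs,
                    stim_sample=np.zeros(sub.n_trials, dtype=int),
                    rt_sample=(sub.rt_sample - sub.stim_sample).astype(int),
                    valid_samples=lengths.astype(int),
                    metadata=meta, pre_pad_ms=0.0,
                    post_pad_ms=extra / fs * 1000.0)


def split_participants(participants, train_fraction: float = 0.85, seed: int = 0):
    """Deterministic participant-level partition into (train, validation) ids."""
    unique = np.unique(np.asarray(participants))
    if len(unique) < 2:
        raise ValueError("cannot split a single participant")
    rng = np.random.default_rng(seed)
    order = rng.permutation(unique)
    n_train = int(round(train_fraction * len(unique)))
    n_train = min(max(n_train, 1), len(unique) - 1)
    return np.sort(order[:n_train]), np.sort(order[n_train:])


def split_by_participant(epochs: EpochSet, train_fraction: float = 0.85,
                         seed: int = 0):
    """Partition an EpochSet by participant; no participant straddles the split."""
    train_ids, val_ids = split_participants(
        epochs.metadata["participant"].to_numpy(), train_fraction, seed)
    part = epochs.metadata["participant"].to_numpy()
    return (epochs.subset(np.isin(part, train_ids)),
            epochs.subset(np.isin(part, val_ids)))


def jitter_crop(stim_sample: int, rt_sample: int, valid_samples: int,
                rng: np.random.Generator):
    """Draw a training window (start, end] inside the trial's pads.

    Start is uniform in the pre-stimulus pad [0, stim], end uniform in the
    post-response pad [rt+1, valid].  With zero-width pads the window is
    exactly [stim, rt+1] and deterministic.
    """
    if not (0 <= stim_sample < rt_sample < valid_samples):
        raise ValueError("invalid trial bookkeeping")
    start = int(rng.integers(0, stim_sample + 1))
    end = int(rng.integers(rt_sample + 1, valid_samples + 1))
    return start, end
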