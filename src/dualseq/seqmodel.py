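"""Causal spatiotemporal sequence labeler for operation onsets.

Maps raw-channel epochs to per-timestep probabilities over
{Encoding, Central, Response, Negative} for each task, trained on the soft
labels produced by the event decomposition with a KL-divergence loss.  The
architecture follows the contract: per-timestep spatial mixing (pointwise
convolution) → temporal dropout → two parallel causal temporal convolutions
at 12 ms and 36 ms scales, concatenated → a relative positional-encoding
feature → a stack of five causal sequence-mixing layers → one linear head
per task with a softmax.

The sequence-mixing layers are gated causal dilated convolutions with
residual connections (dilations 1, 2, 4, 8, 16), a minimal causal layer
honouring the same in/out contract as a selective state-space layer at desk
scale.  The whole model, including NAdam optimization, is implemented on
numpy arrays with hand-written backpropagation, so inference and training
are exactly reproducible from a seed on any machine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import jitter_crop
from .synthdata import EpochSet


@dataclass
class ModelConfig:
    n_channels: int = 32
    spatial_features: int = 32
    temporal_kernel_ms: tuple = (12.0, 36.0)
    temporal_features: int = 32      # per temporal scale
    n_sequence_layers: int = 5
    feature_dim: int = 64
    dropout_rate: float = 0.1
    n_classes: int = 4               # K operations + Negative
    fs: float = 250.0
    n_tasks: int = 2
    seed: int = 0
    sequence_layer: str = "gated-causal-dilated-conv"
    dtype: str = "float32"    # float64 available for gradient checking

    def kernel_samples(self) -> tuple:
        ks = tuple(max(1, int(round(ms / 1000.0 * self.fs)))
                   for ms in self.temporal_kernel_ms)
        if any(k < 1 for k in ks):
            raise ValueError("kernel under one sample")
        return ks


def positional_encoding(stim_sample: int, rt_sample: int,
                        n_samples: int) -> np.ndarray:
    """Relative trial position: 0 before the stimulus, linear 0→1 from
    stimulus to response, 1 thereafter."""
    if rt_sample <= stim_sample:
        raise ValueError("rt must come after the stimulus")
    t = np.arange(n_samples, dtype=np.float64)
    pos = (t - stim_sample) / (rt_sample - stim_sample)
    return np.clip(pos, 0.0, 1.0)


def kl_loss(label: np.ndarray, pred: np.ndarray,
            mask: np.ndarray | None = None) -> float:
    """Mean over timesteps of KL(label || pred), with 0·log 0 = 0 and the
    prediction floored at 1e-9.  ``mask`` selects the timesteps that count."""
    if label.shape != pred.shape:
        raise ValueError("shape mismatch between labels and predictions")
    p = np.maximum(pred, 1e-9)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(label > 0, label * (np.log(np.maximum(label, 1e-300))
                                             - np.log(p)), 0.0)
    per_t = terms.sum(axis=-1)
    if mask is not None:
        return float(per_t[mask].mean()) if mask.any() else 0.0
    return float(per_t.mean())


# ---------------------------------------------------------------------------
# layers (forward + manual backward)


def _mm(a2: np.ndarray, b: np.ndarray, out_shape) -> np.ndarray:
    """(..., Fin) @ (Fin, Fout) through one BLAS call."""
    return (a2.reshape(-1, a2.shape[-1]) @ b).reshape(out_shape)


def _causal_conv(x: np.ndarray, w: np.ndarray, dilation: int = 1) -> np.ndarray:
    """y[t] = sum_i x[t - i*dilation] @ w[i];  x: (B,T,Fin), w: (k,Fin,Fout)."""
    k, B, T = w.shape[0], x.shape[0], x.shape[1]
    y = _mm(x, w[0], (B, T, w.shape[2]))
    for i in range(1, k):
        s = i * dilation
        y[:, s:, :] += _mm(x[:, :-s, :], w[i], (B, T - s, w.shape[2]))
    return y


def _causal_conv_grads(x: np.ndarray, w: np.ndarray, gy: np.ndarray,
                       dilation: int = 1):
    k, B, T = w.shape[0], x.shape[0], x.shape[1]
    Fin = x.shape[2]
    gw = np.empty_like(w)
    gx = _mm(gy, w[0].T, x.shape)
    x2 = x.reshape(-1, Fin)
    gy2 = gy.reshape(-1, gy.shape[-1])
    gw[0] = x2.T @ gy2
    for i in range(1, k):
        s = i * dilation
        gw[i] = x[:, :-s, :].reshape(-1, Fin).T @ gy[:, s:, :].reshape(-1, gy.shape[-1])
        gx[:, :-s, :] += _mm(gy[:, s:, :], w[i].T, (B, T - s, Fin))
    return gx, gw


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class SequenceModel:
    """The network.  Parameters live in ``self.params`` (name -> array)."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config
        k1, k2 = c.kernel_samples()
        self.k1, self.k2 = k1, k2
        self.dilations = [2**i for i in range(c.n_sequence_layers)]
        p = {}

        dt = np.dtype(config.dtype)

        def init(shape, fan_in):
            return (rng.standard_normal(shape) / np.sqrt(fan_in)).astype(dt)

        p["Ws"] = init((c.n_channels, c.spatial_features), c.n_channels)
        p["bs"] = np.zeros(c.spatial_features, dt)
        p["Wt1"] = init((k1, c.spatial_features, c.temporal_features),
                        k1 * c.spatial_features)
        p["bt1"] = np.zeros(c.temporal_features, dt)
        p["Wt2"] = init((k2, c.spatial_features, c.temporal_features),
                        k2 * c.spatial_features)
        p["bt2"] = np.zeros(c.temporal_features, dt)
        d_in = 2 * c.temporal_features + 1
        p["Win"] = init((d_in, c.feature_dim), d_in)
        p["bin"] = np.zeros(c.feature_dim, dt)
        for i in range(c.n_sequence_layers):
            p[f"Wd{i}"] = init((3, c.feature_dim, c.feature_dim),
                               3 * c.feature_dim)
            p[f"bd{i}"] = np.zeros(c.feature_dim, dt)
            p[f"Wg{i}"] = init((3, c.feature_dim, c.feature_dim),
                               3 * c.feature_dim)
            p[f"bg{i}"] = np.zeros(c.feature_dim, dt)
            p[f"Wp{i}"] = init((c.feature_dim, c.feature_dim), c.feature_dim)
            p[f"bp{i}"] = np.zeros(c.feature_dim, dt)
        for task in range(c.n_tasks):
            p[f"Wh{task}"] = init((c.feature_dim, c.n_classes), c.feature_dim)
            p[f"bh{task}"] = np.zeros(c.n_classes, dt)
        self.params = p

    # -- forward -----------------------------------------------------------

    def encode(self, x: np.ndarray, pos: np.ndarray,
               dropout_rng: np.random.Generator | None = None):
        """Shared encoder: x (B,T,C), pos (B,T) -> (embeddings, cache)."""
        p = self.params
        c = self.config
        cache = {"x": x}

        h0 = _mm(x, p["Ws"], (*x.shape[:2], p["Ws"].shape[1])) + p["bs"]
        if dropout_rng is not None and c.dropout_rate > 0:
            keep = (dropout_rng.random(h0.shape[:2]) >= c.dropout_rate)
            dmask = (keep[:, :, None] / (1.0 - c.dropout_rate)).astype(h0.dtype)
            h0 = h0 * dmask
            cache["dmask"] = dmask
        cache["h0"] = h0

        a1 = _causal_conv(h0, p["Wt1"]) + p["bt1"]
        a2 = _causal_conv(h0, p["Wt2"]) + p["bt2"]
        t1, t2 = np.tanh(a1), np.tanh(a2)
        cache["t1"], cache["t2"] = t1, t2
        feat = np.concatenate([t1, t2, pos[:, :, None].astype(t1.dtype)], axis=2)
        cache["feat"] = feat

        h = _mm(feat, p["Win"], (*feat.shape[:2], p["Win"].shape[1])) + p["bin"]
        cache["h_in"] = h
        for i, dil in enumerate(self.dilations):
            z = _causal_conv(h, p[f"Wd{i}"], dil) + p[f"bd{i}"]
            g = _causal_conv(h, p[f"Wg{i}"], dil) + p[f"bg{i}"]
            zt = np.tanh(z)
            gs = 1.0 / (1.0 + np.exp(-g))
            u = zt * gs
            v = _mm(u, p[f"Wp{i}"], u.shape) + p[f"bp{i}"]
            cache[f"blk{i}"] = (h, zt, gs, u)
            h = h + v
        cache["emb"] = h
        return h, cache

    def head(self, emb: np.ndarray, task: int) -> np.ndarray:
        """Task-specific classification head with per-timestep softmax."""
        p = self.params
        logits = _mm(emb, p[f"Wh{task}"],
                     (*emb.shape[:2], p[f"Wh{task}"].shape[1])) + p[f"bh{task}"]
        return _softmax(logits)

    def forward(self, x: np.ndarray, pos: np.ndarray, task: int,
                dropout_rng: np.random.Generator | None = None,
                want_cache: bool = False):
        """x: (B,T,C); pos: (B,T).  Returns (probs, embeddings[, cache])."""
        emb, cache = self.encode(x, pos, dropout_rng)
        cache["task"] = task
        probs = self.head(emb, task)
        cache["probs"] = probs
        if want_cache:
            return probs, emb, cache
        return probs, emb

    # -- backward ----------------------------------------------------------

    def backward(self, cache: dict, dlogits: np.ndarray, grads: dict):
        """Accumulate parameter gradients given d(loss)/d(logits)."""
        p = self.params
        task = cache["task"]
        emb = cache["emb"]

        def acc(name, g):
            grads[name] = grads.get(name, 0.0) + g

        acc(f"Wh{task}", emb.reshape(-1, emb.shape[-1]).T
            @ dlogits.reshape(-1, dlogits.shape[-1]))
        acc(f"bh{task}", dlogits.sum(axis=(0, 1)))
        dh = _mm(dlogits, p[f"Wh{task}"].T, (*dlogits.shape[:2], emb.shape[-1]))

        for i in reversed(range(len(self.dilations))):
            dil = self.dilations[i]
            h_in, zt, gs, u = cache[f"blk{i}"]
            dv = dh  # residual: dh flows both into v and straight through
            acc(f"Wp{i}", u.reshape(-1, u.shape[-1]).T
                @ dv.reshape(-1, dv.shape[-1]))
            acc(f"bp{i}", dv.sum(axis=(0, 1)))
            du = _mm(dv, p[f"Wp{i}"].T, dv.shape)
            dz = du * gs * (1.0 - zt**2)
            dg = du * zt * gs * (1.0 - gs)
            dx1, gWd = _causal_conv_grads(h_in, p[f"Wd{i}"], dz, dil)
            dx2, gWg = _causal_conv_grads(h_in, p[f"Wg{i}"], dg, dil)
            acc(f"Wd{i}", gWd)
            acc(f"bd{i}", dz.sum(axis=(0, 1)))
            acc(f"Wg{i}", gWg)
            acc(f"bg{i}", dg.sum(axis=(0, 1)))
            dh = dh + dx1 + dx2

        feat = cache["feat"]
        acc("Win", feat.reshape(-1, feat.shape[-1]).T
            @ dh.reshape(-1, dh.shape[-1]))
        acc("bin", dh.sum(axis=(0, 1)))
        dfeat = _mm(dh, p["Win"].T, (*dh.shape[:2], p["Win"].shape[0]))
        F = self.config.temporal_features
        dt1 = dfeat[:, :, :F] * (1.0 - cache["t1"]**2)
        dt2 = dfeat[:, :, F:2 * F] * (1.0 - cache["t2"]**2)
        h0 = cache["h0"]
        dh0a, gWt1 = _causal_conv_grads(h0, p["Wt1"], dt1)
        dh0b, gWt2 = _causal_conv_grads(h0, p["Wt2"], dt2)
        acc("Wt1", gWt1)
        acc("bt1", dt1.sum(axis=(0, 1)))
        acc("Wt2", gWt2)
        acc("bt2", dt2.sum(axis=(0, 1)))
        dh0 = dh0a + dh0b
        if "dmask" in cache:
            dh0 = dh0 * cache["dmask"]
        x_ = cache["x"]
        acc("Ws", x_.reshape(-1, x_.shape[-1]).T
            @ dh0.reshape(-1, dh0.shape[-1]))
        acc("bs", dh0.sum(axis=(0, 1)))


def build_model(config: ModelConfig) -> SequenceModel:
    config.kernel_samples()
    if config.n_sequence_layers < 1:
        raise ValueError("need at least one sequence layer")
    return SequenceModel(config)


# ---------------------------------------------------------------------------
# optimizer


class NAdam:
    """Nesterov-momentum Adam (Dozat 2016 formulation)."""

    def __init__(self, params: dict, lr: float = 5e-5, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict):
        self.t += 1
        b1, b2, t = self.b1, self.b2, self.t
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = (b1 * self.m[k] / (1 - b1**(t + 1))
                     + (1 - b1) * g / (1 - b1**t))
            v_hat = self.v[k] / (1 - b2**t)
            params[k] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


# ---------------------------------------------------------------------------
# batching helpers


def _gather_windows(epochs: EpochSet, labels: np.ndarray | None, idx,
                    rng: np.random.Generator | None):
    """Assemble a left-aligned batch, optionally jittered inside the pads.

    Returns (x (B,T,C), pos (B,T), lab (B,T,nc) or None, mask (B,T)).
    """
    xs, poss, labs, lens = [], [], [], []
    for i in idx:
        stim, rt, valid = (int(epochs.stim_sample[i]), int(epochs.rt_sample[i]),
                           int(epochs.valid_samples[i]))
        if rng is not None:
            s, e = jitter_crop(stim, rt, valid, rng)
        else:
            s, e = 0, valid
        xs.append(epochs.data[i, :, s:e].T)
        poss.append(positional_encoding(stim - s, rt - s, e - s))
        if labels is not None:
            labs.append(labels[i, s:e, :])
        lens.append(e - s)
    T = max(lens)
    B = len(idx)
    C = epochs.n_channels
    x = np.zeros((B, T, C), dtype=np.float32)
    pos = np.zeros((B, T), dtype=np.float32)
    mask = np.zeros((B, T), dtype=bool)
    lab = None
    if labels is not None:
        nc = labels.shape[2]
        lab = np.zeros((B, T, nc), dtype=np.float32)
        lab[:, :, nc - 1] = 1.0  # padding is Negative (loss-masked anyway)
    for b, L in enumerate(lens):
        x[b, :L] = xs[b]
        pos[b, :L] = poss[b]
        mask[b, :L] = True
        if labels is not None:
            lab[b, :L] = labs[b]
    return x, pos, lab, mask


def _epoch_pass(model, opt, epochs_by_task, labels_by_task, idx_by_task,
                batch_size, rng, train: bool):
    """One pass over the data; returns mean KL per timestep (both tasks)."""
    total, count = 0.0, 0
    heads = {t: i for i, t in enumerate(sorted(idx_by_task))}
    order = {t: (rng.permutation(len(ix)) if train else np.arange(len(ix)))
             for t, ix in idx_by_task.items()}
    n_batches = max(int(np.ceil(len(ix) / batch_size))
                    for ix in idx_by_task.values())
    for b in range(n_batches):
        grads = {}
        batch_loss, batch_n = 0.0, 0
        for task, ix in idx_by_task.items():
            sel = order[task][b * batch_size:(b + 1) * batch_size]
            if len(sel) == 0:
                continue
            sub = ix[sel]
            x, pos, lab, mask = _gather_windows(
                epochs_by_task[task], labels_by_task[task], sub,
                rng if train else None)
            probs, _, cache = model.forward(
                x, pos, heads[task], dropout_rng=rng if train else None,
                want_cache=True)
            n_valid = int(mask.sum())
            batch_loss += kl_loss(lab, probs, mask) * n_valid
            batch_n += n_valid
            if train:
                dlogits = (probs - lab) * mask[:, :, None] / n_valid
                model.backward(cache, dlogits, grads)
        if train and grads:
            opt.step(model.params, grads)
        total += batch_loss
        count += batch_n
    return total / max(count, 1)


def train_model(model: SequenceModel, train_by_task: dict, val_by_task: dict,
                train_labels: dict, val_labels: dict, lr: float = 5e-5,
                max_epochs: int = 100, patience: int = 3, batch_size: int = 64,
                seed: int = 0, verbose: bool = False):
    """Joint two-task training with KL loss, jitter and early stopping.

    Stops when validation loss has not decreased for ``patience`` epochs and
    restores the weights of the best validation epoch.  Returns a history
    dict with per-epoch train/validation losses.
    """
    rng = np.random.default_rng(seed)
    opt = NAdam(model.params, lr=lr)
    tr_idx = {t: np.arange(e.n_trials) for t, e in train_by_task.items()}
    va_idx = {t: np.arange(e.n_trials) for t, e in val_by_task.items()}
    history = {"train_loss": [], "val_loss": []}
    best_loss, best_params, best_epoch = np.inf, None, -1
    for epoch in range(max_epochs):
        tr_loss = _epoch_pass(model, opt, train_by_task, train_labels, tr_idx,
                              batch_size, rng, train=True)
        va_loss = _epoch_pass(model, opt, val_by_task, val_labels, va_idx,
                              batch_size, rng, train=False)
        if not np.isfinite(tr_loss) or not np.isfinite(va_loss):
            raise FloatingPointError(
                f"divergent loss at epoch {epoch}: train={tr_loss} val={va_loss}")
        history["train_loss"].append(tr_loss)
        history["val_loss"].append(va_loss)
        if verbose:
            print(f"epoch {epoch}: train {tr_loss:.4f} val {va_loss:.4f}")
        if va_loss < best_loss:
            best_loss, best_epoch = va_loss, epoch
            best_params = {k: v.copy() for k, v in model.params.items()}
        elif epoch - best_epoch >= patience:
            break
    if best_params is not None:
        model.params = best_params
    history["best_epoch"] = best_epoch
    return model, history


def infer(model: SequenceModel, epochs: EpochSet, batch_size: int = 64):
    """Deterministic inference on full padded windows.

    Returns (traces, embeddings, valid): per-task lists are not needed —
    the caller picks the head via ``task`` — so this returns, for the given
    EpochSet, a dict {task: (n,T,nc) probabilities}, the shared (n,T,F)
    embeddings and the (n,T) validity mask.
    """
    n = epochs.n_trials
    idx = np.arange(n)
    traces = {t: [] for t in range(model.config.n_tasks)}
    embs = []
    masks = []
    for b in range(int(np.ceil(n / batch_size))):
        sub = idx[b * batch_size:(b + 1) * batch_size]
        x, pos, _, mask = _gather_windows(epochs, None, sub, None)
        emb, _ = model.encode(x, pos)
        for task in range(model.config.n_tasks):
            traces[task].append(model.head(emb, task))
        embs.append(emb)
        masks.append(mask)
    T = max(a.shape[1] for a in embs)

    def pad(chunks, fill=0.0):
        out = []
        for a in chunks:
            if a.shape[1] < T:
                pad_w = [(0, 0), (0, T - a.shape[1])] + \
                        ([(0, 0)] if a.ndim == 3 else [])
                a = np.pad(a, pad_w, constant_values=fill)
            out.append(a)
        return np.concatenate(out, axis=0)

    return ({t: pad(v) for t, v in traces.items()}, pad(embs),
            pad(masks, fill=False).astype(bool))
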