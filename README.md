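# dualseq

Trial-level decomposition and sequence decoding of dual-task EEG.

## The problem

In the psychological-refractory-period (PRP) paradigm two choice tasks are
presented in close succession (stimulus-onset asynchrony 300 ms in the
Short condition, 1200 ms in the Long condition) and responding to the
second task slows when the tasks overlap.  Classical analyses average
reaction times over trials and therefore assume every trial interleaves
the two tasks' processing the same way.  `dualseq` implements the opposite
approach: estimate, for every single trial, *when* each latent cognitive
operation — Encoding (E), Central (C), Response (R), for each task —
occurred, decode the cross-task operation sequence with its uncertainty,
and ask whether the sequence a trial used predicts its behaviour.

The pipeline, for analysts of multichannel epoched time series:

1. **synthdata** — dual-task EEG generator with known operation onsets,
   sequence strategies and behaviour (the package ships no recordings;
   everything is validated on ground truth).
2. **preprocess** — average reference, zero-phase 1–50 Hz band-pass,
   RT cropping; robust median/MAD z-scoring; participant-level 85/15
   splits; training-window jitter.
3. **eventdecomp** — gamma-constrained EM decomposition: each task's Long
   (non-overlapping) epochs are modelled as K ordered half-sine
   topographic events separated by Gamma(shape 2) stage durations, fitted
   by an exact forward–backward EM in a 10-component PCA space, with
   cumulative (one-event-at-a-time) model-order selection and an
   event-width stability scan (20–60 ms).  Output: per-trial onset
   probability distributions — soft labels.
4. **seqmodel** — a causal spatiotemporal sequence labeler (pointwise
   spatial mixing, temporal dropout, 12/36 ms causal convolutions,
   relative positional encoding, five gated causal dilated residual
   layers, task-specific softmax heads) trained on the soft labels with a
   KL loss; pure numpy with hand-written backpropagation.
5. **opsim** — do Short-condition operations live where their
   Long-condition counterparts live in embedding space?  Resampled mean
   pairwise cosine distances with percentile CIs.
6. **strategize** — per-trial posteriors over the six valid cross-task
   sequences A–F (A = E1→C1→R1→E2→C2→R2 is fully serial; in B–F Task 2
   processing starts before Task 1 ends) by sampling onsets from the
   traces under within-task ordering constraints.
7. **behavior** — multiple imputation from the sequence posteriors into
   mixed-effects RT and accuracy models, pooled by Rubin's rules with
   Holm-adjusted pairwise contrasts.

## The model in brief

For one task's epoch, match series `y_d(t)` (PCA components
cross-correlated with a unit-energy half-sine template, standardized) are
modelled with K ordered latent onsets:

    log p(y, t_1..t_K) = Σ_k [ m_k·y(t_k) − ‖m_k‖²/2 ]         (emission, LR form)
                       + Σ_j log Gamma_d(d_j; shape 2, θ_j)     (stage durations)

with stage durations shifted by one event width between consecutive
onsets.  Exact E-step marginals `γ_k(t)` (verified against brute-force
enumeration) are both the M-step weights and, with a Negative class
absorbing the remainder, the per-timestep training targets for the
sequence labeler.  Decoded traces are sampled (1000 draws/trial),
order-filtered, classified into A–F, and the label uncertainty is pooled
through m = 100 imputations by Rubin's rules:
`T = Ū + (1 + 1/m)B`, `df = (m−1)(1 + Ū/((1+1/m)B))²`.

## Worked example

```python
from dualseq.synthdata import SimConfig, generate_dataset
from dualseq.pipeline import run_pipeline

cfg = SimConfig(n_participants=6, trials_per_condition=40, seed=3)
epochs, truth = generate_dataset(cfg)          # two task-locked EpochSets
res = run_pipeline(epochs, truth, seed=1, fixed_width_ms=50.0,
                   lr=1e-3, max_epochs=80, m_imputations=20)
print(res.summary())
```

prints (abridged):

```
'n_events': {1: 3, 2: 3}
'em_onset_median_err_ms':    {'1:E1': 3.9, '1:C1': 3.5, '1:R1': 3.0,
                              '2:E2': 3.5, '2:C2': 5.0, '2:R2': 3.2}
'model_onset_median_err_ms': {'1:E1': 7.0, '1:C1': 8.6, '1:R1': 7.6,
                              '2:E2': 7.7, '2:C2': 6.4, '2:R2': 7.7}
'embedding_separation': True
'short_mode_accuracy': 0.6125
'long_mode_A_rate': 1.0
```

Reading: the decomposition finds exactly the three planted events per task
and localizes their onsets to within a few milliseconds (the planted event
width is 50 ms); the sequence labeler, trained only on Long trials,
recovers onsets on held-out participants almost as well; Short-condition
operations embed with their Long counterparts (same-operation distance
statistics ≈ 0, other-operation ≈ 0.2, non-overlapping CIs); the decoded
posterior mode matches the planted strategy on 61% of Short trials at this
reduced size (87% at the default 120 trials per condition — decoding
quality grows with training data) and is the serial sequence A on 100% of
Long trials.  `res.pooled` then lists the Rubin-pooled sequence effects on
Task 1 RT and accuracy with Holm-adjusted p-values — on these conditions
every RT contrast against the serial sequence A is positive, as planted:

```
response   term  estimate    se  ci_low  ci_high  p_holm
      rt B vs A    185.69 58.91   68.36   303.03     0.0
      rt C vs A    283.52 65.09  154.40   412.65     0.0
      rt D vs A    281.61 61.03  159.22   404.00     0.0
      rt E vs A    382.81 62.87  257.64   507.98     0.0
      rt F vs A    428.65 65.67  298.38   558.93     0.0
```

(The estimates combine the planted 20–80 ms shifts with the construction
effect that later sequences place the Task 1 response onset later.)

A shell interface wraps the same stages:

```
dualseq simulate --out data/ --seed 9
dualseq fit-events --epochs data/task1.h5 --widths 20:60:5 --out model1.json
dualseq analyze --data data/ --out results/
```

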