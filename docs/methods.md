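# Methods

`dualseq` implements a trial-level analysis of dual-task EEG in the
psychological-refractory-period (PRP) paradigm: decompose multichannel
epochs into probabilistic onsets of latent cognitive operations, train a
sequence labeler on those soft labels, decode each trial's cross-task
operation sequence with its uncertainty, and carry that uncertainty into
behavioural models by multiple imputation.  Because the package ships no
EEG recordings, a synthetic-data module generates dual-task epochs with
known ground truth; every stage is validated against that truth.

## The generative model (synthdata)

Each trial presents a visual Task 1 and, after a stimulus-onset asynchrony
(SOA) of 300 ms (Short condition) or 1200 ms (Long condition), an auditory
Task 2.  Each task traverses three operations — Encoding (E), Central (C),
Response (R) — whose onsets are marked by a 50 ms topographic half-sine
event.  Topographies for the six operations are mutually orthogonal
unit-norm channel patterns (32 channels by default); the analysis only
requires them to be distinct (pairwise |cos| ≤ 0.3), and orthogonality is
the cleanest such choice.

Stage durations (stimulus→E, E→C, C→R) are Gamma(shape 2, scale mean/2);
the shape is fixed at 2 throughout the package so the generator matches the
decomposition prior.  Default stage means are (100, 180, 180) ms for Task 1
and (80, 160, 160) ms for Task 2, plus a gamma motor delay of mean 100 ms,
giving Task 1 reaction times near 560 ms — the scale typical of speeded
three-choice responses.  In the Long condition both tasks run serially from
their own stimuli, so the cross-task sequence is always the serial ordering
A; trials whose Task 1 response would spill past the SOA are redrawn
(negligible mass at these means).  In the Short condition a sequence label
A–F is drawn from the participant's strategy mixture (default: A 25%, each
other label 15%) and the six onsets are built as cumulative Gamma(2) gaps
of mean 110 ms in the label's order; Task 2's first onset is floored at
SOA plus a Task 2 encoding latency so every onset stays causal with
respect to its own stimulus.  Per-label reaction-time shifts (0–80 ms) and
accuracy logit shifts (0–1) plant the behavioural effects the last stage
must recover.  Note the planted RT shift is *added to* the
construction-driven difference (later labels place R1 later), so the total
expected RT difference between labels exceeds the nominal shift.

Signals are the sum of amplitude-1 half-sine events (each task's epoch
window renders all events falling inside it, so Short-condition epochs
contain cross-task activity) plus white Gaussian noise of sd 0.5 per
channel and sample (optional AR(1) colouring behind a flag).  The default
signal-to-noise is deliberately comfortable: these data exist to verify the
machinery, not to emulate single-trial human EEG, where event amplitudes
rarely exceed the noise floor.  Consequences: recovery numbers here
(onset errors of a few ms, >70% strategy identification) are upper bounds
on what real recordings would allow; artifacts, volume conduction,
non-stationary noise and ERP morphology are out of scope.  Each task's
epochs are time-locked to that task's stimulus with 250 ms pre-stimulus
and 300 ms post-response pads.  Sampling rate is 250 Hz, at which 13
samples equal 52 ms (the embedding window) and the 12/36 ms temporal
kernels round to 3/9 samples.

A separate behaviour-level harness (`simulate_behavior_posteriors`) tests
the imputation machinery in isolation: per trial a label posterior is
drawn from a sparse Dirichlet (concentration 0.01, i.e. ~95% of mass on
one label on average), the true label from that posterior, and RT from the
label plus participant and residual noise.  By construction the posterior
is the correct conditional of the label, so multiple imputation from it is
proper.  The concentration models well-decoded trials because the
harness's purpose is validating the imputation and pooling machinery;
decode quality itself is tested in the pipeline.  A known limitation of
the whole approach (here and with real decoders): the posteriors condition
only on the signal, not on behaviour, so regression estimates attenuate as
posteriors flatten — with ~80% of mass on the true label a planted 50 ms
effect pools to about 39 ms.

## Epoch conditioning (preprocess)

For decomposition: average reference per sample, zero-phase (forward–
backward) order-4 Butterworth band-pass 1–50 Hz, removal of trials with
RT < 0.2 s, crop to [stimulus, RT + 50 ms].  Zero-phase filtering is used
so the filter cannot shift onset latencies.  50 ms at 250 Hz is 12.5
samples; it is rounded *up* to 13 so at least the stated post-response
window is retained.  For the sequence model: per-channel robust z-scoring,
z = (x − median) / (1.4826·MAD), with statistics estimated on
training-split trials only; 1.4826 makes the MAD consistent with the SD
under normality.  Splits are at participant level (85/15 by a seeded
shuffle, at least one participant per side); training windows are jittered
uniformly within the pads, validation/inference windows are the full pads.
Baseline correction is available behind a flag but off by default: after
MAD z-scoring of drift-free synthetic data it is a no-op in expectation.

## Event decomposition (eventdecomp)

The decomposition is fitted per task on Long-condition training epochs
only (in the Short condition the two tasks' events interleave, breaking
the serial stage structure the model assumes) and applied, with fixed
parameters, to label all Long trials.

Spatial reduction: PCA of the channel covariance averaged over training
trials, keeping 10 components.  Template: unit-energy discretized positive
half-sine of the candidate event width.  Matching: centred
cross-correlation of each component series with the template, standardized
per component over the training set, giving series y_d(t) that are
approximately N(0, 1) when no event is present.

Model: K strictly ordered latent onsets t_1 < … < t_K per trial; the
emission at an onset is a Gaussian likelihood ratio,
log g_k(t) = Σ_d (m_kd·y_d(t) − m_kd²/2), and the K+1 stage durations
(window start → t_1, inter-onset gaps, t_K → window end) follow shifted
discretized Gamma(2, θ_j): mass on sample-width bins, renormalized over
each trial's support, with a minimum duration of one event width between
consecutive onsets (half a width at the window edges).  The shift encodes
that two half-sine events closer than their width would merge into one
deflection; without it EM happily stacks several "events" inside one match
peak.  The E-step is an exact forward–backward dynamic program over
(event index × time), vectorized across trials (convolutions as
lower-triangular Toeplitz matmuls, per-trial rescaling for stability); a
brute-force enumeration oracle verifies it to 1e−8 on small instances.
The M-step sets m_k to the γ-weighted mean of y and θ_j to
(E[duration] − shift)/2.  Because the per-trial renormalization makes the
θ update approximate, the update is guarded: if a step would lower the
log-likelihood the previous parameters are kept and the fit is declared
converged, so the likelihood trace is non-decreasing by construction.
Convergence: relative gain < 1e−4 or 200 iterations.

Model order (cumulative fitting): starting from a zero-event
duration-only null, events are added one at a time; the candidate K+1
model keeps the K accepted events and seeds the new one in each stage in
turn (at the strongest match inside that stage), the best insertion
winning.  Acceptance requires three things:

1. the log-likelihood gain must exceed twice the gain that a pure-noise
   surrogate chain (iid standard-normal match series with the same trial
   lengths and dimension — exactly the standardized emission's null)
   achieves at the same step.  EM always gains likelihood when an event is
   added, from time-selection noise and from the added stage's duration
   flexibility; the surrogate measures that gain (deterministic and cached
   per data geometry), and only evidence beyond it counts.  Measured at
   200 trials × 10 components the null gain is ~20–45 per step while
   planted events gain several hundred;
2. every event's magnitude norm must exceed an absolute floor of 0.05
   (standardized units);
3. no event's norm may fall below a quarter of the strongest event's:
   band-pass filtering necessarily turns each brief deflection into a main
   lobe plus ~10%-energy side lobes, which behave like genuine (they
   generalize across trials) but attenuated events.  This guard would also
   reject a genuinely weak event below a quarter of the strongest
   pattern's energy — a documented trade-off.

Event width is tuned by a stability scan over 20–60 ms in 5 ms steps: the
chosen width is the centre of the longest run of consecutive widths giving
the same event count (ties resolved toward larger widths, the upper-middle
element on even-length runs); no run of three or more is an error.

Soft labels: the per-trial onset marginals γ_k(t) become per-timestep
class probabilities; if the K operation probabilities ever exceed 1 in
total at a timestep they are rescaled to sum to 1, a Negative class takes
the remainder, and pad samples outside the decomposition window are purely
Negative.  Every timestep sums to 1 exactly.

## Sequence labeler (seqmodel)

Per-timestep classifier over {E, C, R, Negative} per task, from raw
(MAD-z-scored) channels: pointwise spatial mixing to 32 features →
temporal dropout (whole timesteps zeroed, rate 0.1, training only) → two
parallel causal temporal convolutions (3 and 9 samples = 12 and 36 ms at
250 Hz, 32 features each, tanh) → concatenation plus a relative
positional-encoding feature (0 before the stimulus, linear to 1 at the
response, 1 after) → five causal sequence-mixing layers → per-task linear
heads with softmax.  The sequence-mixing layer is a gated causal dilated
convolution block (tanh × sigmoid gating, pointwise projection, residual;
dilations 1, 2, 4, 8, 16), a minimal causal layer meeting the same
in/out contract as a selective state-space layer at this scale; the
configuration records the layer type.  Everything — forward, backward,
NAdam — is implemented on numpy arrays (float32 by default; float64
available and used for gradient checking), so training is exactly
reproducible from a seed.  Causality is tested directly: truncating a
trial's future leaves past outputs unchanged.

Training: Long-condition trials only, both tasks through the shared
encoder with separate heads, loss = sum of the two tasks' mean
per-timestep KL(label‖prediction) (prediction floored at 1e−9), windows
re-jittered every epoch, batch padding loss-masked.  Optimizer NAdam;
the learning-rate default in the signature is 5e−5, but the pipeline and
acceptance runs use 1e−3 with at most 18–40 epochs — at a few hundred
trials the loss surface is benign and the small rate would simply spend
the budget crawling.  Early stopping: patience 3 on validation loss,
best-epoch weights restored.

## Embedding similarity (opsim)

Embeddings are the final sequence-layer outputs (64 features).  Per trial
and operation, the embedding is averaged over 13 samples (52 ms) centred
on the operation's peak predicted probability (truncated at trial edges;
peaks under 0.1 probability are skipped and logged).  The resampling
comparison draws, per iteration (1000 iterations, 1000 samples with
replacement per set), three sets per task and operation — Short/same
operation, Long/same operation, Long/other operations — and computes mean
pairwise cosine distances, subsampled to at most 1e5 pairs.  The reported
statistics are |D(Short-same, Long-same) − D_within(Long-same)| and
|D(Short-same, Long-other) − D_within(Long-same)|: the cross-condition
distance for the same operation, and for other operations, each relative
to the within-Long baseline.  Summaries are medians with [2.5, 97.5]
percentile CIs over iterations.  If the model embeds Short-condition
operations where their Long counterparts live, the same-operation
statistic sits at ~0 and strictly below the other-operation statistic.

## Sequence decoding (strategize)

Task 2 traces are shifted by the trial's SOA onto the Task 1 clock.  Per
trial, 1000 joint draws sample each operation's onset independently from
its normalized trace; a uniform sub-sample jitter makes the draws
continuous (onsets are continuous quantities — integer bins produced
spurious cross-task ties).  Draws violating within-task order E<C<R for
either task are discarded; retained draws are classified against the
six-sequence taxonomy (the interleavings of two ordered triples that
begin with E1 and end with R2 — brute-force enumeration confirms 20
interleavings total, 6 after the constraint).  Exact ties and orderings
outside the taxonomy are INVALID.  Label frequencies among retained draws
form the trial's sequence posterior; trials with an operation carrying
under 1e−6 total probability, or with no retained draws, are flagged
undecodable and excluded downstream.

## Behaviour (behavior)

Multiple imputation: per imputation (default 100) one label per decodable
trial is drawn from its posterior over A–F (INVALID mass renormalized
away); per imputed dataset a linear mixed model RT ~ sequence with random
participant intercept (statsmodels MixedLM, REML; fixed-effects fallback
with participant indicators if the fit fails) and a logistic mixed model
for correctness (statsmodels BinomialBayesMixedGLM, variational fit; GLM
fallback) are fitted with sequence A as the reference level.  Coefficients
are pooled with Rubin's rules — Q̄, Ū, B, T = Ū + (1+1/m)B,
df = (m−1)(1 + Ū/((1+1/m)B))², t-based CI and p; B = 0 falls back to the
normal reference — and contrast families are Holm-adjusted (step-down,
via statsmodels, cross-checked against hand computation).  Levels absent
from an imputation are pooled over the remaining imputations.

## Problem sizes and numerical choices

Default study conditions: 6 participants × 120 trials × 2 conditions per
task (1440 epochs per task), 32 channels, 250 Hz.  The pipeline fits the
decomposition on the ~600 Long training epochs per task, trains the
labeler on all Long epochs (validation on held-out participants), infers
on everything, decodes all trials and analyzes the Short condition.  The
width scan runs capped-iteration EM (60 iterations) on an evenly spaced
subsample of at most 300 training trials — the event count per width and
the stable width are insensitive to fit precision — and the chosen model
order is then refitted on all training trials at the full budget.
Training runs up to 50 epochs at learning rate 1e−3; decode quality
improves with training (strategy-mode accuracy 0.74 after 18 epochs, 0.87
near convergence, with the INVALID draw mass falling from ~9% to under
5%), so budget-reduced runs trade a little decoding sharpness for time.
The acceptance script runs this end to end with the width scan, 100
imputations and a 60-replicate behavioural calibration.  Tolerances:
EM convergence 1e−4 relative; oracle equivalence asserted at 1e−8; label
tensors sum to 1 within 1e−9; causality at 1e−6 (float32 forward).

## Known limitations

- The synthetic SNR is generous; all recovery figures are ceilings, not
  estimates of real-EEG performance.
- The relative magnitude guard (¼ of the strongest event) would reject a
  true event more than ~4× weaker than the strongest one.
- Model-order selection at very small trial counts (tens of trials)
  remains noisier than at the intended scale, surrogate calibration
  notwithstanding.
- Sequence posteriors condition on the EEG only; behavioural estimates
  attenuate when decoding is poor (see the harness discussion above).
- The pooled F-style omnibus test is not implemented; inference is per
  contrast with Holm adjustment.
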