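# Methods

This note documents the models, numerical conventions and design choices
behind `gcfn`, in the spirit of a methods appendix: what is computed, under
which assumptions, and where the genuinely open decisions were made.

## Trial representation and data ingestion

The pipeline's universal container is the `TrialSet`: trials × channels ×
samples in microvolts, one class label per trial (0 = left hand, 1 = right
hand, 2 = foot, 3 = tongue), a sampling rate, and ordered electrode labels.
Epochs are cut from continuous recordings on half-open, cue-relative
windows; the default window is [0.5, 4.0) s after the cue, which yields
875 samples at 250 Hz. The phrase "0.5–4 s after the task starts" is
ambiguous between cue-relative and imagination-period-relative timing; the
cue-relative reading is used because the window length (3.5 s) — the only
quantity that affects the tensor geometry — is identical either way.

GDF sessions are parsed with `mne`; epoching is then done directly on the
signal array (cue sample + `round(0.5·fs)`, exactly 875 samples) rather
than through `mne.Epochs`, so the half-open sample-count contract is exact.
Trials carrying the expert artifact marker (event 1023) are **kept** by
default: the benchmark's advertised 288 trials/session and the 576 → 6336
augmentation arithmetic are only consistent with no exclusion. An
`exclude_artifacts` switch drops them for users who want the conservative
protocol. The internal container is a NumPy `.npz` archive; its round-trip
is bit-exact on every field.

## Synthetic ERD/ERS generator

The simulator exists so the full pipeline is testable without external
data. Each trial is the sum of

* background noise with a 1/f amplitude spectrum above 1 Hz (flat below),
  scaled to `noise_sigma` (default 10 µV) — the canonical EEG spectral
  shape without committing to a biophysical model;
* band-limited Gaussian oscillations in the mu (8–13 Hz) and beta
  (17–30 Hz) bands, each scaled to `rhythm_amp` (default 5 µV), independent
  across channels and trials.

Class structure enters only through amplitude gains on designated
channels: left hand scales mu+beta at C4 by `1 − erd_depth` (contralateral
ERD) and at C3 by `1 + erd_depth` (ipsilateral ERS); right hand mirrors
this; foot attenuates beta at Cz and tongue attenuates mu at Cz. These four
spatial–spectral signatures are linearly separable by construction.
`erd_depth = 0` removes all class dependence, giving an exchangeable null.

Deliberate simplifications: oscillations are stationary over the epoch (no
ERD onset ramp), there is no volume conduction, no eye-blink/EMG artifacts,
and no inter-trial non-stationarity. Passing the learnability tests
therefore shows that the pipeline can extract lateralized band-power
structure end to end — not that it reaches any particular accuracy on real
recordings, where SNR, artifacts and session drift dominate.

The generator can also emit a minimal GDF 1.25 file (float32 samples, unit
gain, mode-1 event table with cue codes 769–772) purely as a reader
fixture; it is written by hand because no installed library writes GDF.

## Augmentation

The slide-and-recombine rule produces, for step `S` and trial length `T`,
the circular shifts by `kS` samples for `k = 1 … ⌈T/S⌉ − 1`. The stopping
rule `kS ≥ T` is read as *do not emit* the overlapping copy (rather than
clipping it); this is the only reading that reproduces the 576 → 6336
expansion at `S = 80`, `T = 875`. When `S` divides `T`, the copy `k = T/S`
would equal the original and is likewise excluded by the same rule. Shifts
are sample-value permutations per channel, so all marginal moments are
preserved; the splice discontinuity is left unsmoothed. Augmentation is
applied to raw epochs, before filtering.

## Preprocessing

The 5th-order Butterworth bandpass (8–30 Hz) is applied forward–backward
(zero phase) by default — standard for offline analysis, as it leaves ERD
timing undistorted; since the original recipe does not state causality, a
causal single-pass mode is exposed (`zero_phase=False`). Per-trial
standardization pools mean and **population** standard deviation over all
channels and samples of the trial; a zero-variance trial raises an error
naming the trial. The recurrent branch consumes the transpose
(time × channels), time steps along samples.

## Time-frequency images

The Morlet CWT uses the mother wavelet `ψ(t) = e^{iωt}e^{−t²/2}` with
ω = 6 (the conventional admissibility-respecting value; the source recipe
leaves it unstated). Scales are `α_f = ω/(2πf)` so that each analysis row's
center frequency is exactly `f` Hz; the default grid is 32 linear
frequencies in [8, 30]. The transform is the discretized correlation
integral `(1/√α) Σ_n x(t_n) ψ*((t_n − τ)/α) Δt`, evaluated by FFT
convolution with the Gaussian envelope truncated at 8 standard deviations
(amplitude ~1e−14 of peak — far below every stated tolerance); edges are
implicitly zero-padded. A brute-force double-sum evaluation of the same
integral serves as the oracle in the tests (agreement ≲ 1e−15 relative).

The published input geometry (224 × 93) does not follow arithmetically
from 22 channels, so the image construction is a documented convention:
22 channels × 32 frequencies are stacked in electrode order (704 rows ×
T columns) and bilinearly resized to 224 × 93 — this preserves the stated
stacking layout while matching the network's input exactly. Min–max
scaling is **per image** (among per-image/per-channel/global, the per-image
choice makes each sample self-normalized and the rendering invariant to
trial gain), then values are rounded to the 256-level 8-bit grid and
divided by 255.

## The fusion network

No deep-learning framework is used: layers, backpropagation and Adam are
implemented in numpy (the model is small enough that CPU matrix products
dominate). The published parameter counts pin several conventions down
uniquely, and the implementation adopts them:

* **Convolution** — 'valid' padding is forced (93 → 93 needs a width-1
  kernel; 224 → 1 needs the full-height kernel). A full-height H × 1
  kernel makes the convolution a per-column matrix product, implemented as
  such. Count: 64·(224+1) = 14,400.
* **Pooling** — 1 × 3, stride 1 × 3, floor semantics (93 → 31), no
  partial windows.
* **GRU** — the counts 3,675 (25 units on 22 inputs) and 11,550 (50 on
  25) equal `3(u(i+u) + 2u)`, i.e. the two-bias *reset-after* convention
  (separate input-side and recurrent-side biases; the reset gate
  multiplies the recurrent term inside tanh). The state update follows
  `h_t = (1 − z_t)h_{t−1} + z_t h̃_t`. Layer 1 returns the full sequence,
  layer 2 only the final state. The "Tanh" rows of the published table are
  read as the cells' internal activation, not extra layers.
* **Classifier** — concatenation (1984 + 50 = 2034) → FC-128 + ReLU →
  dropout 0.3 (after FC-128 only) → FC-4 + softmax; counts 260,480 and
  516.

Initialization (unstated in the recipe): Glorot-uniform for convolution,
dense and GRU input kernels; per-gate orthogonal recurrent kernels; zero
biases; all seeded. Loss is mean cross-entropy with probabilities clipped
at 1e−12 (result-invariant at reported precision). The single-branch
ablations (GRU-only, CNN-only) reuse the identical classifier head.

A finite-difference gradient check across every layer type guards the
manual backpropagation; an independent scalar-loop recurrence oracle
guards the GRU cell.

## Cross-validation and metrics

Folds can be drawn in two modes. `"paper"` partitions the augmented trials
uniformly at random — the original protocol, in which shifted copies of
one source trial can appear on both sides of a fold; the package
reproduces it for fidelity and emits a leakage warning. `"group_safe"`
assigns each source trial with all its copies to one fold and is the
honest-generalization alternative. Both are deterministic given the seed.

Metrics: accuracy, 4 × 4 confusion matrix (rows true), per-class precision
and recall (NaN — not 0 — where a denominator is empty), and kappa
`(p0 − pe)/(1 − pe)` with `pe` fixed at 0.25 for the balanced four-class
task. Fold aggregation is the arithmetic mean of fold accuracies, with the
aggregate kappa computed from that mean; under fixed `pe` this equals the
mean of per-fold kappas, so the ambiguity between the two readings is
immaterial. Training hyperparameters are unstated in the source recipe;
the defaults (Adam 1e−3, batch 64, ≤100 epochs, early stopping with
patience 10 on validation loss) are ordinary values for networks of this
size and are fully exposed in `TrainConfig`.

## CSP-LDA baseline

For each class, one-versus-rest CSP solves the generalized eigenproblem of
the class-average trial covariance against the composite covariance.
Per-trial covariances are normalized by their trace before averaging
(amplitude invariance); the composite is the **sum** of the four class
averages, placing every generalized eigenvalue in (0, 1); it receives a
diagonal loading of 1e−8 × mean diagonal for conditioning. Per class the
`m = 2` largest- and smallest-eigenvalue filters are kept (16 features
total; the source recipe does not state its count). Features are
block-normalized log variances, `log(var_j / Σ_block var)`. Classification
is scikit-learn's LDA (least-squares solver, small shrinkage as the
diagonal loading); argmax prediction resolves exact ties to the lower
class index.

## Problem sizes and test design

The bundled checks run the full pipeline at synthetic scale: 50 trials per
class, ERD depth 0.6, 3 folds, ≤30 epochs, and a width-reduced network
(8 conv filters, 8/16 GRU units, FC-32) whose input geometry (875 × 22 and
224 × 93) is unchanged. These sizes were chosen as the smallest
configuration at which both decoders separate the simulated classes
decisively (the fusion network reaches ~0.96, CSP-LDA ~0.75 against 0.25
chance at the fixed seeds) while a null run with `erd_depth = 0` stays
within binomial noise of chance. The full published geometry is built and
verified shape-by-shape and count-by-count, but only trained at reduced
width.

## Known limitations

* The 224-row image convention is a documented choice, not derivable from
  the source recipe; other resize conventions would change pixel values
  (though not the contracts tested).
* The paper-mode protocol's augmentation-before-splitting inflates
  validation accuracy through temporal overlap between folds; use
  `group_safe` for honest generalization estimates.
* The numpy training loop is single-threaded BLAS-bound and intended for
  research-scale experiments, not full-benchmark GPU training.
* The simulator's stationary, artifact-free trials are easier than real
  EEG; synthetic accuracies say nothing quantitative about real subjects.
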