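# Methods

This note records the models, conventions and numerical choices behind
`eegxai`, in the spirit of a methods appendix: what is simulated, what is
computed, which knobs matter, and where the design was genuinely open.

## Synthetic EEG generator

Each recording is `n_channels × (duration · fs)` of unit-variance
background noise (pink 1/f by default; white and AR(1) with configurable
coefficient are available), scaled by `background_sd`.  During each
annotated seizure interval, every *informative* channel additionally
receives an independent unit-variance ictal component scaled by
`ictal_amplitude · background_sd`.  The component is a 70/30 mix of
band-limited filtered noise (4th-order Butterworth bandpass over
`ictal_band`, default 3–20 Hz) and a carrier at the band's centre
frequency amplitude-modulated at 3 Hz — a crude spike-wave morphology that
puts energy in both the low and beta ranges, where amplitude-type features
discriminate ictal activity.  Onsets are rectangular.

Because background and component are unit variance, an informative
channel's in-seizure RMS is ~`sqrt(1 + amplitude²)` times its baseline —
an analytically known effect size that the tests verify by direct RMS
computation on the generated arrays.  Channel labels follow the standard
longitudinal bipolar montage (Fp1-F7, F7-T7, …), cycled or truncated.

Seeding: all randomness for recording *r* flows from
`default_rng([seed, r])`, so recordings are independent streams yet the
whole cohort is reproducible bit for bit from one master seed.

What the generator does *not* emulate: physiological artifacts (EMG, eye
blinks, electrode pops), inter-patient variability, seizure evolution or
propagation, and spatial correlation between channels.  Passing tests on
this data therefore demonstrate correctness of the pipeline's statistics
and the explainers' ability to recover a planted channel effect — not
clinical seizure-detection performance.

## Pre-processing

* Power-line notch: IIR notch, quality factor 30, at a configurable line
  frequency (60 Hz default).  High-pass: second-order Butterworth at
  0.5 Hz.  Both are applied zero-phase (forward–backward) per channel, so
  filtering commutes with channel permutation and adds no phase
  distortion before feature computation.  Filters run on whole recordings
  before windowing.
* Windows are 2 s.  A window is labelled ictal iff it lies entirely inside
  a seizure annotation and non-ictal iff entirely outside all of them;
  boundary-straddling windows are discarded, so labels are unambiguous.
* Oversampling stride is `round(L·(1−overlap))` samples, minimum 1 (80 %
  of a 512-sample window is not an integer, hence the rounding rule); the
  window count per interval is `floor((D−L)/stride)+1`.  Overlap applies
  to the ictal class of training sets only.  Test sets are always cut
  without overlap and balanced by seeded uniform subsampling of the
  majority class (the minority class is fully retained).
* Band separation uses second-order Butterworth filters: low = lowpass at
  12 Hz, beta = bandpass 12–25 Hz, gamma = highpass at 25 Hz (the upper
  edge is Nyquist), plus the unfiltered full band.

## Feature battery

Fourteen features per channel per band (56 values per window–channel):
Mean, STD, RMS, Range, IR, MAD, Skewness, Kurtosis, Hjorth Mobility and
Complexity, MedFreq, PkFreq, zero crossings, SampEn.  Fixed conventions:

* population (n-denominator) variance; linear-interpolation quantiles;
  Fisher (excess) kurtosis;
* Hjorth mobility `sqrt(var(Δx)/var(x))`, complexity
  `Mobility(Δx)/Mobility(x)`; both scale-invariant;
* Welch PSD with Hann window, segment `min(256, L)`, 50 % overlap; MedFreq
  is the frequency below which half the PSD mass lies, PkFreq the argmax;
* zero crossings count strict sign changes with zero samples skipped;
* SampEn with m = 2, r = 0.2·STD and Chebyshev distance, self-matches
  excluded, both template counts over the same N−m start indices — the
  customary defaults; `A = 0` or `B = 0` is reported as a configurable cap
  (10 in the feature table) with a QC flag.

Degenerate inputs (constant signal, all-zero band) yield defined values
(0) plus a QC flag propagated into the table's `qc` column rather than
NaNs.

## Classifier

The reference network is a 1-D CNN over the raw `channels × L` window:
two convolution blocks (16 then 32 filters, kernel 5, stride 2, ReLU), a
64-unit dense layer, dropout 0.25 between the fully connected layers, and
a 2-unit softmax.  Training is Adam (α = 0.001, β₁ = 0.9, β₂ = 0.999,
ε = 1e-7) on cross-entropy, 100 epochs, batch 100, no early stopping; the
validation split (stratified 20 % of the training set) is monitored only
and never drives model selection.  Inputs are standardised by the training
set's global mean and SD (a scalar affine map, so per-channel amplitude
relations — the discriminative signal — are preserved).  The layer
hyperparameters are config-driven because the downstream analysis is
model-agnostic: every component consumes only the classifier contract
(`fit` / `predict_proba`).  An optional weight-shared twin branch over two
channel halves is available.  The network, including backpropagation and
Adam, is implemented directly on numpy arrays; parameter init, batch
shuffling and dropout masks are all seeded, so training is deterministic.

The *linear oracle* scores a window as
`sigmoid(gain · (Σ_c w_c · meanpower(x_c) − threshold))`.  It needs no
training; `oracle_for_config` sets unit weights on the planted channels
and the threshold halfway between the analytic in/out-seizure expected
powers.  Because only weighted channels influence it, it provides exact
ground truth for attribution experiments (dummy channels must get zero).

## Attribution

* Value function: `v(S) = f(x with channels outside S masked)`, target =
  ictal-class probability (what the softmax exposes), not the logit.
* Masking default is zeros — high-passed EEG is zero-mean, so zeros ≈
  channel mean; channel-mean and reference-window replacements are
  provided.
* Exact Shapley: full 2^M enumeration with the standard weights
  `|S|!(M−|S|−1)!/M!`; refused for M > 16.  An independent
  permutation-form implementation (average marginal contribution over all
  M! orders) serves as the test oracle.
* Owen/partition values: binary coalition tree over channels paired in
  montage order, padded to the next power of two with empty groups.  At
  each node the two children are attributed by averaging their marginal
  contributions over both join orders, recursively down to single
  channels; contributions telescope, so efficiency holds exactly by
  construction.  For additive value functions this equals the exact
  Shapley value (asserted to 1e-8); for non-additive models on M ≤ 8 the
  two routes agree within 0.1 on probability-scale attributions in our
  tests.  The coalition-pair convention — both members of a deepest
  sibling pair receive the mean of their two values — is available as
  `pair_mean=True`; it preserves the total and is off by default because
  it intentionally coarsens per-channel resolution.
* LIME: Bernoulli(½) binary channel masks (the first sample keeps all
  channels), proximity weight `exp(−d²/width²)` with d the Euclidean
  distance between mask and all-ones, default width `0.75·sqrt(M)`, ridge
  penalty 1.0, 1000 samples; all configurable and seeded.  The surrogate's
  coefficients are the importances.  The sampling estimator converges to
  the weighted-least-squares closed form on the full mask set (checked by
  brute force at M = 6).
* Attributions are signed and computed only for windows labelled ictal
  and predicted ictal.  Signed values are kept (no absolute value) since
  the correlation analysis is rank-based; an analysis on |φ| can be done
  downstream on the tidy importance table.

## Correlation analysis

Each (window, channel) pair of the correctly classified ictal windows
contributes one observation (feature value, importance value); pairs are
pooled per subject.  Pooling is the default because it yields the large
pair counts that drive small p-values in this design; a
`per_channel_mean` mode (average over windows first, one observation per
channel) is provided.  Spearman's ρ is the Pearson correlation of average
ranks; p-values are exact (full permutation enumeration) for n < 10 and
use `t = ρ·sqrt((n−2)/(1−ρ²))` with n−2 df otherwise; |ρ| = 1 is reported
with p = 0.  No multiple-testing correction is applied — results carry raw
p-values plus the interpretation band.  Band boundaries (0.30 / 0.50 /
0.70 / 0.90 on |ρ|) assign boundary values to the higher band.

The Friedman test on the subjects × overlap-rates accuracy matrix uses
the chi-square approximation with average ranks for ties (scipy); the
degenerate all-tied matrix is reported as statistic 0, p = 1.  At least 3
conditions are required — the study design always compares 3 overlap
rates.

## Problem sizes

The synthetic cohort study runs 3 subjects × 3 recordings of 120 s at
256 Hz with 8 bipolar channels, one 20 s seizure per recording, 2
informative channels at 5× background amplitude.  Eight channels keep the
exact-enumeration cross-checks cheap and keep the pooled correlation
informative: with 2 planted channels among 8, the planted (window,
channel) pairs are a quarter of the pool, which puts the expected
feature/importance ρ in the moderate-to-high range under the planted
effect while an independent permutation stays negligible.  Unit tests use
further reduced sizes (128 Hz, 4–8 channels, 40–60 s recordings).

## Limitations

* The generator's simplifications (above) mean results transfer to real
  EEG only as a validation of the machinery, not of clinical performance.
* Exact Shapley enumeration is exponential; beyond 16 channels only the
  Owen route is available, and its agreement with exact values is exact
  only for additive models.
* Spearman captures monotone association only; non-monotone dependence
  between features and importances is invisible to this analysis.
* EDF export depends on mne's optional export backend; the native
  interchange format is NPZ plus plain-text annotations.
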