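# eegxai

Do channel-importance values produced by SHAP- and LIME-style explanations
of an EEG seizure classifier actually track the electrophysiology?  This
package implements, as a tested pipeline, the evaluation needed to answer
that question: train a patient-specific seizure-window classifier, explain
its decisions at the *channel* level, compute a standard battery of
per-channel EEG features, and measure the Spearman rank correlation between
the two — end to end on synthetic multichannel EEG with known ground-truth
informative channels.

It is aimed at researchers working on explainable ML for neurophysiological
signals who want a transparent, fully seeded reference implementation of
channel-coalition attribution methods and of the correlation analysis
around them.

## What it computes

**Classification.** 2 s windows of a bipolar-montage EEG recording are
labelled ictal / non-ictal, after a power-line notch and a 0.5 Hz
second-order high-pass Butterworth filter.  Class balance is restored in
two steps: ictal windows are oversampled with 50 / 70 / 80 % overlap and
the majority class is subsampled.  Models are evaluated with
leave-one-recording-out cross-validation (sensitivity, specificity,
accuracy, F1, AUC-ROC), and a Friedman rank test compares accuracies across
overlap rates.  A config-driven 1-D CNN (ReLU convolutions, dropout 0.25,
2-unit softmax, Adam with α=0.001, β₁=0.9, β₂=0.999, ε=1e-7) is provided,
along with a closed-form linear oracle classifier for controlled
experiments.

**Attribution.** For a window x and model f, a channel's Shapley value is

φ_i = Σ_{S ⊆ N∖{i}} |S|! (M−|S|−1)! / M! · [v(S∪{i}) − v(S)],

with v(S) = f(x with the channels outside S masked).  The package computes
this exactly by enumeration (M ≤ 16), via Owen values on a binary coalition
tree (channels paired in montage order, padded to a power of two) for any
M, and via channel-group LIME: a ridge surrogate fitted to f on random
binary channel masks weighted by exp(−d²/width²), d the Euclidean distance
of the mask from the unperturbed instance.  Attributions are computed for
windows that are both labelled and predicted ictal.

**Correlation.** Fourteen features (amplitude statistics, Hjorth mobility
and complexity, Welch median/peak frequency, zero crossings, sample
entropy) are computed per channel in four bands (low < 12 Hz, beta
12–25 Hz, gamma > 25 Hz, and the unfiltered full band) — 56 values per
(window, channel).  For every (feature, band, method), Spearman's ρ between
feature values and importance values is computed with tie-aware average
ranks, an exact permutation p-value for n < 10 and the t approximation
otherwise, and banded as negligible (< 0.30), low, moderate, high or very
high (≥ 0.90).

**Synthetic ground truth.** The generator plants a band-limited ictal
oscillation (filtered noise plus a 3 Hz amplitude-modulated carrier) on a
known subset of channels during annotated seizure intervals, over pink /
white / AR(1) background noise — so the channels an explainer *should*
rank highest are known exactly.

## Worked example

```python
from eegxai import (SynthConfig, generate_subject, oracle_for_config,
                    loro_evaluate, explain_correct_ictal,
                    compute_feature_table, correlate_all,
                    balance_two_step, segment_windows, LimeConfig)
from eegxai.preprocess import preprocess_recording

cfg = SynthConfig(n_channels=8, fs=256.0, n_recordings=3,
                  recording_duration=120.0, seizure_intervals=[(50.0, 70.0)],
                  informative_channels=frozenset({0, 1}),
                  ictal_amplitude=5.0, seed=11)
recordings, truth = generate_subject(cfg, subject_id="S0")
oracle = oracle_for_config(cfg)

metrics = loro_evaluate(recordings, overlap=0.8,
                        classifier_factory=lambda c, L: oracle, seed=0)
print("per-fold accuracy:", [round(m.accuracy, 2) for m in metrics])

rec0 = preprocess_recording(recordings[0])
test = balance_two_step(
    segment_windows(rec0, overlap=0.0, which="ictal"),
    segment_windows(rec0, overlap=0.0, which="nonictal"), seed=0)
importances = explain_correct_ictal(
    oracle, test, lime_config=LimeConfig(n_samples=1000, seed=0))
mean_shap = (importances.query("method == 'shap'")
             .groupby("channel")["value"].mean())
print("top channels by mean SHAP:", list(mean_shap.nlargest(2).index))

features = compute_feature_table(test)
results = correlate_all(features, importances, subject="S0")
for _, r in results.sort_values("rho", ascending=False).head(3).iterrows():
    print(f"{r.band}/{r.feature} ({r.method}): rho={r.rho:.2f}, "
          f"p={r.p:.2e}, {r.label}")
```

prints

```
per-fold accuracy: [1.0, 1.0, 1.0]
top channels by mean SHAP: [0, 1]
low/MedFreq (shap): rho=0.76, p=4.13e-16, high positive
full/IR (shap): rho=0.76, p=4.70e-16, high positive
full/STD (shap): rho=0.76, p=4.70e-16, high positive
```

Every fold separates the classes (the oracle matches the planted effect),
the two planted channels carry the largest mean SHAP values, and
amplitude-type features correlate highly with importance — exactly the
behaviour the planted-effect configuration should produce.  Replacing the
importances with an independent permutation drops all correlations into
the negligible band.

The same experiment is available from the shell:

```
eegxai all --outdir out/ --seed 1          # or: eegxai synth / preprocess /
                                           # train / evaluate / explain /
                                           # correlate / report
```

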