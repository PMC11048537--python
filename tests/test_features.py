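"""Feature battery: analytic sine checks, brute-force oracles and
scale-equivariance classes."""

import numpy as np
import pytest

from eegxai.containers import WindowSet
from eegxai.features import (FEATURES, amplitude_stats, compute_feature_table,
                             feature_table_wide, hjorth, sample_entropy,
                             spectral_features, zero_crossings)

FS = 256.0


def sine(freq, fs=FS, duration=2.0, amplitude=1.0, phase=0.0):
    t = np.arange(int(duration * fs)) / fs
    return amplitude * np.sin(2 * np.pi * freq * t + phase)


class TestAmplitudeStats:
    def test_analytic_sine(self):
        x = sine(10.0, amplitude=2.0)  # integer number of cycles
        s = amplitude_stats(x)
        assert s["RMS"] == pytest.approx(2.0 / np.sqrt(2), rel=1e-3)
        assert s["Mean"] == pytest.approx(0.0, abs=1e-12)
        assert s["Range"] == pytest.approx(4.0, rel=1e-3)

    def test_quantile_oracle_small_vector(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        s = amplitude_stats(x)
        assert s["IR"] == pytest.approx(2.0, abs=1e-12)
        assert s["MAD"] == pytest.approx(1.0, abs=1e-12)
        assert s["STD"] == pytest.approx(np.sqrt(2.0), abs=1e-12)  # population

    def test_gaussian_kurtosis_near_zero(self, rng):
        x = rng.standard_normal(100_000)
        assert abs(amplitude_stats(x)["Kurtosis"]) < 0.1

    def test_constant_signal_flagged(self):
        flags = []
        s = amplitude_stats(np.ones(100), flags)
        assert s["Skewness"] == 0.0 and s["Kurtosis"] == 0.0
        assert "constant" in flags


class TestHjorth:
    def test_sine_mobility_closed_form(self):
        # first difference of a sinusoid has amplitude 2 sin(pi f / fs)
        for f in (5.0, 20.0, 40.0):
            m = hjorth(sine(f, duration=4.0))["Mobility"]
            assert m == pytest.approx(2 * np.sin(np.pi * f / FS), rel=0.01)

    def test_white_noise_more_complex_than_sine(self, rng):
        noise = hjorth(rng.standard_normal(512))["Complexity"]
        tone = hjorth(sine(10.0))["Complexity"]
        assert noise > tone

    def test_scale_invariance(self, rng):
        x = rng.standard_normal(512)
        a, b = hjorth(x), hjorth(10.0 * x)
        assert a["Mobility"] == pytest.approx(b["Mobility"], abs=1e-12)
        assert a["Complexity"] == pytest.approx(b["Complexity"], abs=1e-12)

    def test_zero_variance_flagged(self):
        flags = []
        out = hjorth(np.ones(10), flags)
        assert out == {"Mobility": 0.0, "Complexity": 0.0}
        assert "zero_variance" in flags


class TestSpectral:
    BIN = FS / 256  # Welch segment 256 samples -> 1 Hz bins

    def test_single_tone(self):
        s = spectral_features(sine(10.0), FS)
        assert abs(s["MedFreq"] - 10.0) <= self.BIN
        assert abs(s["PkFreq"] - 10.0) <= self.BIN

    def test_two_equal_tones(self):
        x = sine(8.0) + sine(24.0)
        s = spectral_features(x, FS)
        assert 8.0 < s["MedFreq"] < 24.0
        assert min(abs(s["PkFreq"] - 8.0), abs(s["PkFreq"] - 24.0)) <= self.BIN

    def test_white_noise_median_near_quarter_fs(self, rng):
        x = rng.standard_normal(65536)
        s = spectral_features(x, FS)
        assert s["MedFreq"] == pytest.approx(FS / 4, rel=0.1)

    def test_all_zero_flagged(self):
        flags = []
        s = spectral_features(np.zeros(256), FS, flags)
        assert s == {"MedFreq": 0.0, "PkFreq": 0.0}
        assert "all_zero" in flags


class TestZeroCrossings:
    def test_sine_against_brute_force(self):
        x = sine(10.0)  # 2 s, phase 0
        brute = 0
        signs = [v for v in np.sign(x) if v != 0]
        for a, b in zip(signs, signs[1:]):
            brute += a != b
        assert zero_crossings(x) == brute
        assert brute in (39, 40)

    def test_positive_signal_zero(self):
        assert zero_crossings(np.abs(np.random.default_rng(0).standard_normal(50)) + 1) == 0

    def test_alternating_definition(self):
        assert zero_crossings(np.array([1.0, -1.0, 1.0, -1.0])) == 3
        assert zero_crossings(np.array([1.0, 0.0, -1.0])) == 1  # zeros skipped


def sampen_bruteforce(x, m=2, r=None):
    """Independent O(n^2) double-loop reference implementation."""
    x = np.asarray(x, float)
    n = len(x)
    if r is None:
        r = 0.2 * np.std(x)
    B = A = 0
    for i in range(n - m):
        for j in range(i + 1, n - m):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                B += 1
            if max(abs(x[i + k] - x[j + k]) for k in range(m + 1)) <= r:
                A += 1
    if A == 0 or B == 0:
        return np.inf
    return -np.log(A / B)


class TestSampleEntropy:
    def test_constant_signal_zero(self):
        assert sample_entropy(np.ones(100)) == 0.0

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            x = rng.uniform(-1, 1, size=200)
            assert sample_entropy(x) == pytest.approx(
                sampen_bruteforce(x), abs=1e-12)

    def test_periodic_below_shuffled(self, rng):
        saw = np.tile(np.linspace(-1, 1, 25), 8)
        shuffled = rng.permutation(saw)
        assert sample_entropy(saw) < sample_entropy(shuffled)

    def test_no_matches_capped_and_flagged(self):
        flags = []
        # strictly monotone with huge steps and tiny r: no length-3 matches
        x = np.arange(60.0) ** 2
        val = sample_entropy(x, r=1e-12, cap=10.0, flags=flags)
        assert val == 10.0
        assert "sampen_capped" in flags


class TestFeatureTable:
    def make_windows(self, data):
        return WindowSet(
            data=data,
            labels=np.ones(len(data), dtype=int),
            provenance=[("r", i) for i in range(len(data))],
            fs=FS,
        )

    def test_shape_56_per_window_channel(self, rng):
        ws = self.make_windows(rng.standard_normal((1, 4, 512)))
        table = compute_feature_table(ws)
        assert len(table) == 4 * 56
        assert set(table["feature"]) == set(FEATURES)
        assert set(table["band"]) == {"low", "beta", "gamma", "full"}
        wide = feature_table_wide(table)
        assert wide.shape == (4, 2 + 56)

    def test_identical_channels_identical_rows(self, rng):
        one = rng.standard_normal((1, 1, 512))
        ws = self.make_windows(np.repeat(one, 3, axis=1))
        table = compute_feature_table(ws)
        pivot = table.pivot_table(index=["band", "feature"], columns="channel",
                                  values="value")
        assert np.allclose(pivot[0], pivot[1])
        assert np.allclose(pivot[0], pivot[2])

    def test_scale_classes_for_all_features(self, rng):
        x = rng.standard_normal((1, 1, 512))
        base = compute_feature_table(self.make_windows(x))
        scaled = compute_feature_table(self.make_windows(2.0 * x))
        merged = base.merge(scaled, on=["band", "feature", "channel"],
                            suffixes=("", "_x2"))
        equivariant = {"Mean", "STD", "RMS", "Range", "IR", "MAD"}
        invariant = {"Skewness", "Kurtosis", "Mobility", "Complexity",
                     "MedFreq", "PkFreq", "ZC", "SampEn"}
        assert equivariant | invariant == set(FEATURES)
        for _, row in merged.iterrows():
            if row["feature"] in equivariant:
                assert row["value_x2"] == pytest.approx(2 * row["value"],
                                                        abs=1e-9)
            else:
                assert row["value_x2"] == pytest.approx(row["value"],
                                                        abs=1e-9, rel=1e-9)

    def test_window_order_irrelevant(self, rng):
        data = rng.standard_normal((3, 2, 512))
        t_fwd = compute_feature_table(self.make_windows(data))
        t_rev = compute_feature_table(self.make_windows(data[::-1]))
        fwd0 = t_fwd[t_fwd["window"] == 0].reset_index(drop=True)
        rev2 = t_rev[t_rev["window"] == 2].reset_index(drop=True)
        assert np.allclose(fwd0["value"], rev2["value"])
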