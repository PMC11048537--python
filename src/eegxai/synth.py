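"""Synthetic multichannel EEG with annotated seizures and known ground truth.

The generator emulates scalp EEG as used in patient-specific seizure
detection studies: a bipolar-montage channel set (18-21 channels), 256 Hz
sampling, several recordings per subject (so leave-one-recording-out
evaluation can be exercised) and per-recording seizure intervals.  During a
seizure, a configurable subset of *informative* channels additionally
carries a band-limited ictal oscillation — filtered noise mixed with a 3 Hz
amplitude-modulated carrier, a crude spike-wave morphology — scaled
relative to the background standard deviation.  All other channels, and all
channels outside seizures, contain only background noise, so the
ground-truth channel importance is known exactly.

The module also provides a closed-form *linear oracle* classifier whose
ictal score is a fixed monotone function of a weighted sum of per-channel
mean power.  It needs no training and serves as a transparent test double
for the CNN when validating attribution methods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

from .containers import EEGRecording

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "generate_recording",
    "generate_subject",
    "make_linear_oracle",
    "oracle_for_config",
    "LinearOracle",
    "BIPOLAR_LABELS",
]

#: Standard longitudinal-bipolar montage labels (10/20 system); cycled or
#: truncated to the requested channel count.
BIPOLAR_LABELS = [
    "Fp1-F7", "F7-T7", "T7-P7", "P7-O1", "Fp1-F3", "F3-C3", "C3-P3",
    "P3-O1", "Fp2-F4", "F4-C4", "C4-P4", "P4-O2", "Fp2-F8", "F8-T8",
    "T8-P8", "P8-O2", "Fz-Cz", "Cz-Pz", "T7-FT9", "FT9-FT10", "FT10-T8",
]


def default_channel_labels(n_channels: int) -> list[str]:
    reps = -(-n_channels // len(BIPOLAR_LABELS))
    labels = (BIPOLAR_LABELS * reps)[:n_channels]
    # disambiguate cycled duplicates
    seen: dict[str, int] = {}
    out = []
    for lab in labels:
        k = seen.get(lab, 0)
        out.append(lab if k == 0 else f"{lab}.{k}")
        seen[lab] = k + 1
    return out


@dataclass
class SynthConfig:
    """Study conditions for the synthetic cohort.

    ``ictal_amplitude`` is the standard deviation of the added ictal
    component in units of the background standard deviation; 0 disables the
    effect (null configuration).  ``seizure_intervals`` is either one list
    of ``(start_s, stop_s)`` applied to every recording, or a list of such
    lists indexed by recording.
    """

    n_channels: int = 18
    fs: float = 256.0
    n_recordings: int = 3
    recording_duration: float = 120.0
    seizure_intervals: list = field(default_factory=lambda: [(50.0, 70.0)])
    informative_channels: frozenset = frozenset({0, 1})
    ictal_band: tuple[float, float] = (3.0, 20.0)
    ictal_amplitude: float = 3.0
    noise_model: str = "pink"  # {"white", "pink", "ar1"}
    ar_coeff: float = 0.95
    background_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.informative_channels = frozenset(int(c) for c in self.informative_channels)
        if self.n_channels < 1 or self.fs <= 0:
            raise ValueError("n_channels and fs must be positive")
        if not self.informative_channels <= set(range(self.n_channels)):
            raise ValueError("informative_channels outside 0..n_channels-1")
        if self.ictal_amplitude < 0:
            raise ValueError("ictal_amplitude must be non-negative")
        if self.fs <= 2 * self.ictal_band[1]:
            raise ValueError("fs must exceed twice the ictal band upper edge")
        if self.noise_model not in ("white", "pink", "ar1"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        for iv in self._intervals_for(0):
            pass  # validates

    def _intervals_for(self, recording_index: int) -> list[tuple[float, float]]:
        ivs = self.seizure_intervals
        if ivs and isinstance(ivs[0], (list, tuple)) and ivs[0] and isinstance(
            ivs[0][0], (list, tuple)
        ):
            raise ValueError("seizure_intervals nested too deeply")
        if ivs and isinstance(ivs[0], (list, tuple)) and len(ivs[0]) == 2 and not isinstance(
            ivs[0][0], (list, tuple)
        ):
            per_rec = [ivs] * self.n_recordings
        else:
            per_rec = list(ivs)
            if len(per_rec) != self.n_recordings:
                raise ValueError("per-recording interval list length mismatch")
        out = sorted((float(s), float(e)) for s, e in per_rec[recording_index])
        for s, e in out:
            if not (0 <= s < e <= self.recording_duration):
                raise ValueError(f"seizure interval ({s}, {e}) outside recording")
        for (s0, e0), (s1, _) in zip(out, out[1:]):
            if s1 < e0:
                raise ValueError("seizure intervals overlap")
        return out


@dataclass
class GroundTruth:
    """What the generator planted: which channels carry the effect."""

    informative_channels: frozenset
    channel_weights: np.ndarray  # zero exactly on non-informative channels
    seizure_intervals: list[tuple[float, float]]


def _background(rng: np.random.Generator, model: str, n_ch: int, n: int,
                ar_coeff: float) -> np.ndarray:
    if model == "white":
        x = rng.standard_normal((n_ch, n))
    elif model == "pink":
        white = rng.standard_normal((n_ch, n))
        spec = np.fft.rfft(white, axis=1)
        f = np.fft.rfftfreq(n)
        scale = np.ones_like(f)
        scale[1:] = 1.0 / np.sqrt(f[1:])
        scale[0] = 0.0
        x = np.fft.irfft(spec * scale, n=n, axis=1)
    else:  # AR(1)
        eps = rng.standard_normal((n_ch, n))
        x = np.empty_like(eps)
        x[:, 0] = eps[:, 0]
        a = ar_coeff
        for t in range(1, n):
            x[:, t] = a * x[:, t - 1] + eps[:, t]
    x -= x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _ictal_waveform(rng: np.random.Generator, n: int, fs: float,
                    band: tuple[float, float]) -> np.ndarray:
    """Unit-variance ictal component: band-limited noise + 3 Hz AM carrier."""
    lo, hi = band
    sos = sp_signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    noise = sp_signal.sosfiltfilt(sos, rng.standard_normal(n))
    noise /= max(noise.std(), 1e-12)
    t = np.arange(n) / fs
    fc = 0.5 * (lo + hi)
    phase = rng.uniform(0, 2 * math.pi)
    am = 0.5 * (1.0 + np.sin(2 * math.pi * 3.0 * t + phase))
    carrier = np.sin(2 * math.pi * fc * t + rng.uniform(0, 2 * math.pi))
    sw = am * carrier
    sw /= max(sw.std(), 1e-12)
    x = 0.7 * noise + 0.3 * sw
    return x / max(x.std(), 1e-12)


def generate_recording(config: SynthConfig, recording_index: int,
                       subject_id: str = "S0") -> tuple[EEGRecording, GroundTruth]:
    """Generate one recording; fully determined by ``(config.seed, recording_index)``."""
    intervals = config._intervals_for(recording_index)
    n = int(round(config.recording_duration * config.fs))
    rng = np.random.default_rng([config.seed, recording_index])
    data = config.background_sd * _background(
        rng, config.noise_model, config.n_channels, n, config.ar_coeff
    )
    weights = np.zeros(config.n_channels)
    for s, e in intervals:
        i0, i1 = int(round(s * config.fs)), int(round(e * config.fs))
        for ch in sorted(config.informative_channels):
            wave = _ictal_waveform(rng, i1 - i0, config.fs, config.ictal_band)
            data[ch, i0:i1] += config.ictal_amplitude * config.background_sd * wave
    for ch in config.informative_channels:
        weights[ch] = config.ictal_amplitude
    rec = EEGRecording(
        data=data,
        fs=config.fs,
        channel_labels=default_channel_labels(config.n_channels),
        annotations=[(s, e, "ictal") for s, e in intervals],
        subject_id=subject_id,
        recording_id=f"{subject_id}_rec{recording_index}",
    )
    gt = GroundTruth(
        informative_channels=config.informative_channels,
        channel_weights=weights,
        seizure_intervals=intervals,
    )
    return rec, gt


def generate_subject(config: SynthConfig, subject_id: str = "S0"
                     ) -> tuple[list[EEGRecording], GroundTruth]:
    """All recordings of one subject (shared ground truth)."""
    recs = []
    gt = None
    for i in range(config.n_recordings):
        rec, gt = generate_recording(config, i, subject_id=subject_id)
        recs.append(rec)
    return recs, gt


class LinearOracle:
    """Training-free classifier: sigmoid of weighted per-channel mean power.

    ``score(x) = sigmoid(gain * (sum_c w_c * mean(x_c^2) - threshold))``.
    Deterministic, differentiably monotone in each channel's power, and
    therefore an exact reference for attribution methods.
    """

    def __init__(self, weights, threshold: float = 0.0, gain: float = 1.0):
        self.weights = np.asarray(weights, dtype=np.float64)
        if self.weights.ndim != 1:
            raise ValueError("weights must be 1-D")
        self.threshold = float(threshold)
        self.gain = float(gain)

    def fit(self, windows) -> "LinearOracle":  # Classifier contract; no training
        if windows.n_channels != len(self.weights):
            raise ValueError("channel count mismatch")
        return self

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        single = x.ndim == 2
        if single:
            x = x[None]
        if x.shape[1] != len(self.weights):
            raise ValueError(
                f"window has {x.shape[1]} channels, oracle has {len(self.weights)} weights"
            )
        meanpower = np.mean(x * x, axis=2)
        score = meanpower @ self.weights
        p = 1.0 / (1.0 + np.exp(-self.gain * (score - self.threshold)))
        return p[0] if single else p

    def predict(self, x: np.ndarray) -> np.ndarray:
        return (np.atleast_1d(self.predict_proba(x)) >= 0.5).astype(int)


def make_linear_oracle(weights, threshold: float = 0.0, gain: float = 1.0) -> LinearOracle:
    """Build the closed-form per-channel-power classifier."""
    return LinearOracle(weights, threshold=threshold, gain=gain)


def oracle_for_config(config: SynthConfig) -> LinearOracle:
    """Oracle matched to the generator's ground truth.

    Unit weights on informative channels.  With unit-variance background and
    a unit-variance ictal component scaled by amplitude ``a``, in-seizure
    mean power on an informative channel is ~``sd^2*(1 + a^2)`` versus
    ``sd^2`` outside, so the threshold sits halfway between.
    """
    w = np.zeros(config.n_channels)
    inf = sorted(config.informative_channels)
    w[inf] = 1.0
    n_inf = max(len(inf), 1)
    sd2 = config.background_sd ** 2
    a2 = config.ictal_amplitude ** 2
    threshold = n_inf * sd2 * (1.0 + a2 / 2.0)
    gap = n_inf * sd2 * max(a2, 1.0)
    gain = 10.0 / gap
    return LinearOracle(w, threshold=threshold, gain=gain)
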