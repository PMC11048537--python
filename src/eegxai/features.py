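"""Per-channel, per-band EEG feature battery (14 features x 4 bands = 56).

Amplitude statistics (Mean, STD, RMS, Range, interquartile range IR, median
absolute deviation MAD, Skewness, Kurtosis), Hjorth Mobility/Complexity,
Welch-PSD spectral summaries (median and peak frequency), zero-crossing
count and sample entropy, computed per channel on each of four versions of
a window: low (<12 Hz), beta (12-25 Hz), gamma (>25 Hz) and the unfiltered
full band.

Conventions (configurable nowhere on purpose — one definition per feature):
population (n-denominator) variance, linear-interpolation quantiles, Fisher
(excess) kurtosis, SampEn with m=2 and r=0.2*STD and Chebyshev distance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from .containers import WindowSet
from .preprocess import band_split

__all__ = [
    "FEATURES",
    "amplitude_stats",
    "hjorth",
    "spectral_features",
    "zero_crossings",
    "sample_entropy",
    "compute_channel_features",
    "compute_feature_table",
    "feature_table_wide",
]

FEATURES = [
    "Mean", "STD", "RMS", "Range", "IR", "MAD", "Skewness", "Kurtosis",
    "Mobility", "Complexity", "MedFreq", "PkFreq", "ZC", "SampEn",
]


def amplitude_stats(x: np.ndarray, flags: list | None = None) -> dict[str, float]:
    """Moment and order statistics of one signal.

    A constant signal has undefined skewness/kurtosis; both are reported as
    0 and ``"constant"`` is appended to ``flags``.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 4:
        raise ValueError("need at least 4 samples")
    q1, q3 = np.percentile(x, [25, 75])
    med = np.median(x)
    out = {
        "Mean": float(np.mean(x)),
        "STD": float(np.std(x)),  # population
        "RMS": float(np.sqrt(np.mean(x * x))),
        "Range": float(np.max(x) - np.min(x)),
        "IR": float(q3 - q1),
        "MAD": float(np.median(np.abs(x - med))),
    }
    if out["STD"] == 0.0:
        out["Skewness"] = 0.0
        out["Kurtosis"] = 0.0
        if flags is not None:
            flags.append("constant")
    else:
        out["Skewness"] = float(sp_stats.skew(x))
        out["Kurtosis"] = float(sp_stats.kurtosis(x))  # Fisher / excess
    return out


def hjorth(x: np.ndarray, flags: list | None = None) -> dict[str, float]:
    """Hjorth Mobility and Complexity via first-difference variance ratios.

    Mobility = sqrt(var(dx)/var(x)); Complexity = Mobility(dx)/Mobility(x).
    Both are scale-invariant.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    v0 = np.var(x)
    if v0 == 0:
        if flags is not None:
            flags.append("zero_variance")
        return {"Mobility": 0.0, "Complexity": 0.0}
    d1 = np.diff(x)
    d2 = np.diff(d1)
    v1, v2 = np.var(d1), np.var(d2)
    mobility = np.sqrt(v1 / v0)
    if v1 == 0:
        if flags is not None:
            flags.append("zero_variance")
        return {"Mobility": float(mobility), "Complexity": 0.0}
    complexity = np.sqrt(v2 / v1) / mobility
    return {"Mobility": float(mobility), "Complexity": float(complexity)}


def spectral_features(x: np.ndarray, fs: float,
                      flags: list | None = None) -> dict[str, float]:
    """Median and peak frequency of the Welch PSD.

    Welch with a Hann window, segment length min(256, len(x)), 50 % overlap.
    MedFreq is the frequency below which half the total PSD mass lies;
    PkFreq is the argmax of the PSD.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < 64:
        raise ValueError("need at least 64 samples")
    if not np.any(x):
        if flags is not None:
            flags.append("all_zero")
        return {"MedFreq": 0.0, "PkFreq": 0.0}
    nperseg = min(256, x.size)
    f, psd = sp_signal.welch(x, fs=fs, window="hann", nperseg=nperseg,
                             noverlap=nperseg // 2)
    total = np.sum(psd)
    if total == 0:
        if flags is not None:
            flags.append("all_zero")
        return {"MedFreq": 0.0, "PkFreq": 0.0}
    cum = np.cumsum(psd)
    med = f[int(np.searchsorted(cum, 0.5 * total))]
    return {"MedFreq": float(med), "PkFreq": float(f[int(np.argmax(psd))])}


def zero_crossings(x: np.ndarray) -> int:
    """Strict sign changes between consecutive samples; zeros are skipped."""
    x = np.asarray(x, dtype=np.float64)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    s = np.sign(x)
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.sum(s[:-1] != s[1:]))


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None,
                   cap: float = np.inf, flags: list | None = None) -> float:
    """Sample entropy: -ln(A/B) with Chebyshev distance, self-matches excluded.

    B counts template-vector pairs of length ``m`` within tolerance ``r``
    (default 0.2 * population STD), A the same for length ``m + 1``; both
    counts run over the same N - m template start indices.  ``A == 0`` or
    ``B == 0`` gives +inf, reported as ``cap`` with a flag.
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    if n < 50:
        raise ValueError("need at least 50 samples")
    if r is None:
        r = 0.2 * np.std(x)
    n_templates = n - m
    xm = sliding_window_view(x, m)[:n_templates]
    xm1 = sliding_window_view(x, m + 1)

    def pair_count(templates: np.ndarray) -> int:
        # Chebyshev distances over all i < j pairs
        d = np.abs(templates[:, None, :] - templates[None, :, :]).max(axis=2)
        iu = np.triu_indices(len(templates), k=1)
        return int(np.sum(d[iu] <= r))

    B = pair_count(xm)
    A = pair_count(xm1)
    if B == 0 or A == 0:
        if flags is not None:
            flags.append("sampen_capped")
        return float(cap)
    return float(-np.log(A / B))


def compute_channel_features(x: np.ndarray, fs: float,
                             sampen_cap: float = np.inf
                             ) -> tuple[dict[str, float], list[str]]:
    """All 14 features for one single-channel signal; returns (values, QC flags)."""
    flags: list[str] = []
    vals: dict[str, float] = {}
    vals.update(amplitude_stats(x, flags))
    vals.update(hjorth(x, flags))
    vals.update(spectral_features(x, fs, flags))
    vals["ZC"] = float(zero_crossings(x))
    vals["SampEn"] = sample_entropy(x, cap=sampen_cap, flags=flags)
    return vals, flags


def compute_feature_table(windows: WindowSet, sampen_cap: float = 10.0) -> pd.DataFrame:
    """Tidy feature table: one row per (window, channel, band, feature).

    Each window is band-split, then the 14-feature battery is applied per
    channel and band — 56 values per (window, channel).  QC flags raised by
    degenerate inputs are joined into the ``qc`` column.
    """
    rows = []
    labels = windows.channel_labels or [f"ch{c}" for c in range(windows.n_channels)]
    for w in range(len(windows)):
        bands = band_split(windows.data[w], windows.fs)
        rec_id, offset = windows.provenance[w]
        for band, arr in bands.items():
            for c in range(windows.n_channels):
                vals, flags = compute_channel_features(arr[c], windows.fs,
                                                       sampen_cap=sampen_cap)
                qc = ";".join(flags)
                for feat in FEATURES:
                    rows.append((w, rec_id, offset, c, labels[c],
                                 int(windows.labels[w]), band, feat,
                                 vals[feat], qc))
    return pd.DataFrame(
        rows,
        columns=["window", "recording_id", "offset", "channel", "channel_label",
                 "label", "band", "feature", "value", "qc"],
    )


def feature_table_wide(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot the tidy table to one row per (window, channel), 56 columns."""
    wide = table.pivot_table(index=["window", "channel"],
                             columns=["band", "feature"], values="value")
    wide.columns = [f"{b}/{f}" for b, f in wide.columns]
    return wide.reset_index()
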