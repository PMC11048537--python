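"""Filtering, band separation, 2 s windowing and two-step class balancing.

The pre-processing chain mirrors common seizure-detection practice:
a power-line notch, a 0.5 Hz second-order high-pass Butterworth filter,
segmentation into 2 s windows, ictal oversampling via window overlap
(80 / 70 / 50 %), and subsampling of the majority class so both classes are
represented equally.  All filters are applied zero-phase (forward-backward)
per channel, so filtering commutes with any channel permutation and adds no
phase distortion before feature computation.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import signal as sp_signal

from .containers import ICTAL, NONICTAL, EEGRecording, WindowSet

__all__ = [
    "notch_filter",
    "highpass_filter",
    "band_split",
    "BANDS",
    "segment_windows",
    "balance_two_step",
    "split_train_val",
    "preprocess_recording",
]

logger = logging.getLogger(__name__)

#: Band edges in Hz; ``full`` is the unfiltered (primal) signal.
BANDS = {"low": (None, 12.0), "beta": (12.0, 25.0), "gamma": (25.0, None), "full": None}

STANDARD_OVERLAPS = (0.0, 0.5, 0.7, 0.8)


def notch_filter(recording: EEGRecording, line_freq: float = 60.0,
                 quality: float = 30.0) -> EEGRecording:
    """Remove the power-line component with a zero-phase IIR notch."""
    if not 0 < line_freq < recording.fs / 2:
        raise ValueError(f"line_freq {line_freq} outside (0, Nyquist)")
    b, a = sp_signal.iirnotch(line_freq, quality, fs=recording.fs)
    out = sp_signal.filtfilt(b, a, recording.data, axis=1)
    return recording.copy_with(out)


def highpass_filter(recording: EEGRecording, cutoff: float = 0.5,
                    order: int = 2) -> EEGRecording:
    """Second-order high-pass Butterworth; removes DC and slow drift."""
    if not 0 < cutoff < recording.fs / 2:
        raise ValueError(f"cutoff {cutoff} outside (0, Nyquist)")
    sos = sp_signal.butter(order, cutoff, btype="highpass", fs=recording.fs,
                           output="sos")
    out = sp_signal.sosfiltfilt(sos, recording.data, axis=1)
    return recording.copy_with(out)


def preprocess_recording(recording: EEGRecording, line_freq: float = 60.0,
                         hp_cutoff: float = 0.5) -> EEGRecording:
    """Notch then high-pass, the standard chain before windowing."""
    return highpass_filter(notch_filter(recording, line_freq), hp_cutoff)


def band_split(window: np.ndarray, fs: float, order: int = 2) -> dict[str, np.ndarray]:
    """Split a channels x L window into low (<12 Hz), beta (12-25 Hz),
    gamma (>25 Hz) and the unfiltered full band.

    Second-order Butterworth filters, zero-phase.  The gamma band is a
    high-pass at 25 Hz (the upper edge is the Nyquist frequency).
    """
    window = np.asarray(window, dtype=np.float64)
    out: dict[str, np.ndarray] = {}
    for name, edges in BANDS.items():
        if edges is None:
            out[name] = window.copy()
            continue
        lo, hi = edges
        if lo is None:
            sos = sp_signal.butter(order, hi, btype="lowpass", fs=fs, output="sos")
        elif hi is None:
            sos = sp_signal.butter(order, lo, btype="highpass", fs=fs, output="sos")
        else:
            sos = sp_signal.butter(order, [lo, hi], btype="bandpass", fs=fs,
                                   output="sos")
        out[name] = sp_signal.sosfiltfilt(sos, window, axis=-1)
    return out


def _class_intervals(recording: EEGRecording, which: int) -> list[tuple[int, int]]:
    """Sample-index intervals entirely of one class.

    Ictal intervals are the annotations; non-ictal intervals are the
    complement.  A window is labelled only if it lies entirely inside one
    such interval, so boundary-straddling windows never arise.
    """
    fs = recording.fs
    seiz = [(int(round(s * fs)), int(round(e * fs))) for s, e, _ in recording.annotations]
    if which == ICTAL:
        return seiz
    n = recording.n_samples
    out, pos = [], 0
    for s, e in seiz:
        if s > pos:
            out.append((pos, s))
        pos = max(pos, e)
    if pos < n:
        out.append((pos, n))
    return out


def window_count(D: int, L: int, stride: int) -> int:
    """Number of L-sample windows tiling a D-sample interval at a stride."""
    if D < L:
        return 0
    return (D - L) // stride + 1


def segment_windows(recording: EEGRecording, length_s: float = 2.0,
                    overlap: float = 0.0, which: str = "ictal") -> WindowSet:
    """Tile each interval of the requested class with fixed-length windows.

    stride = round(L * (1 - overlap)) samples, at least 1.  Intervals
    shorter than one window are skipped with a warning.
    """
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    if not any(abs(overlap - o) < 1e-9 for o in STANDARD_OVERLAPS):
        warnings.warn(f"non-standard overlap {overlap}", stacklevel=2)
    label = ICTAL if which == "ictal" else NONICTAL
    L = int(round(length_s * recording.fs))
    stride = max(int(round(L * (1.0 - overlap))), 1)
    data, prov = [], []
    for i0, i1 in _class_intervals(recording, label):
        D = i1 - i0
        if D < L:
            warnings.warn(
                f"interval of {D / recording.fs:.2f} s shorter than one window; skipped",
                stacklevel=2,
            )
            continue
        for k in range(window_count(D, L, stride)):
            start = i0 + k * stride
            data.append(recording.data[:, start:start + L])
            prov.append((recording.recording_id, start))
    arr = (np.stack(data) if data
           else np.empty((0, recording.n_channels, L)))
    return WindowSet(
        data=arr,
        labels=np.full(len(data), label, dtype=np.int64),
        provenance=prov,
        fs=recording.fs,
        overlap=overlap,
        channel_labels=list(recording.channel_labels),
    )


def balance_two_step(ictal: WindowSet, nonictal: WindowSet, seed: int = 0) -> WindowSet:
    """Subsample the larger class (uniform, without replacement, seeded).

    The oversampling step is the overlap applied when the ictal set was
    built; this is the second step, yielding equal class counts.  The
    minority class is always fully retained.
    """
    if len(ictal) == 0 or len(nonictal) == 0:
        raise ValueError("both classes must be non-empty")
    rng = np.random.default_rng(seed)
    n = min(len(ictal), len(nonictal))

    def pick(ws: WindowSet) -> WindowSet:
        if len(ws) == n:
            return ws
        idx = np.sort(rng.choice(len(ws), size=n, replace=False))
        return ws.subset(idx)

    return WindowSet.concatenate([pick(ictal), pick(nonictal)])


def split_train_val(windows: WindowSet, val_fraction: float = 0.2,
                    seed: int = 0) -> tuple[WindowSet, WindowSet]:
    """Stratified, seeded train/validation split (disjoint by construction)."""
    if len(windows) < 5:
        raise ValueError("need at least 5 windows to split")
    if val_fraction == 0:
        warnings.warn("val_fraction=0: empty validation set", stacklevel=2)
        return windows, windows.subset(np.array([], dtype=int))
    rng = np.random.default_rng(seed)
    train_idx, val_idx = [], []
    for cls in (NONICTAL, ICTAL):
        idx = np.flatnonzero(windows.labels == cls)
        if len(idx) == 0:
            continue
        if len(idx) < 2:
            raise ValueError("each class needs at least 2 windows to stratify")
        idx = rng.permutation(idx)
        n_val = int(round(val_fraction * len(idx)))
        n_val = min(max(n_val, 1), len(idx) - 1)
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return windows.subset(np.sort(train_idx)), windows.subset(np.sort(val_idx))
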