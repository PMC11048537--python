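"""Optional EDF interface and model persistence.

EDF reading goes through :mod:`mne` (install the ``edf`` extra).  The
portable on-disk container used throughout the pipeline is NPZ plus a
plain-text annotation file; EDF export additionally requires mne's EDF
export backend (``edfio``) and raises a clear error when it is missing.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .containers import EEGRecording, read_annotations
from .nn import ArchConfig, CNNClassifier, TrainingConfig
from .synth import LinearOracle

__all__ = ["read_edf", "write_edf", "save_model", "load_model"]


def read_edf(path: str | Path, annotation_path: str | Path | None = None,
             channels: list[str] | None = None,
             subject_id: str = "S0") -> EEGRecording:
    """Load an EDF recording (optionally restricted to named channels).

    Seizure annotations are read from ``annotation_path`` (``start stop
    label`` per line, seconds) when given, otherwise from the EDF's own
    annotation track entries labelled ``ictal``/``seizure``.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - mne is an extra
        raise ImportError("EDF reading requires mne (pip install eegxai[edf])") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    if channels is not None:
        raw.pick(channels)
    annotations: list[tuple[float, float, str]] = []
    if annotation_path is not None:
        annotations = read_annotations(annotation_path)
    else:
        for onset, dur, desc in zip(raw.annotations.onset,
                                    raw.annotations.duration,
                                    raw.annotations.description):
            if desc.lower() in ("ictal", "seizure", "sz"):
                annotations.append((float(onset), float(onset + dur), "ictal"))
    return EEGRecording(
        data=raw.get_data() * 1e6,  # volts -> microvolts
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        annotations=annotations,
        subject_id=subject_id,
        recording_id=Path(path).stem,
    )


def write_edf(recording: EEGRecording, path: str | Path) -> None:
    """Export a recording to EDF via mne (needs the ``edfio`` backend)."""
    try:
        import mne
        from mne.export import export_raw
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF export requires mne (pip install eegxai[edf])") from exc
    info = mne.create_info(recording.channel_labels, recording.fs, ch_types="eeg")
    raw = mne.io.RawArray(recording.data * 1e-6, info, verbose="error")
    raw.set_annotations(mne.Annotations(
        onset=[s for s, _, _ in recording.annotations],
        duration=[e - s for s, e, _ in recording.annotations],
        description=[lbl for _, _, lbl in recording.annotations],
    ))
    try:
        export_raw(str(path), raw, fmt="edf", verbose="error")
    except (ImportError, RuntimeError, ValueError) as exc:
        raise ImportError(
            "mne's EDF export backend (edfio) is not available; "
            "use EEGRecording.to_npz plus write_annotations instead"
        ) from exc


def save_model(model, path: str | Path) -> None:
    """Persist a classifier (linear oracle or CNN) to NPZ."""
    if isinstance(model, LinearOracle):
        np.savez(path, kind="oracle", weights=model.weights,
                 threshold=model.threshold, gain=model.gain)
    elif isinstance(model, CNNClassifier):
        arch = model.arch
        meta = dict(
            kind="cnn",
            n_channels=model.n_channels,
            window_length=model.window_length,
            conv_filters=np.array(arch.conv_filters),
            kernel_size=arch.kernel_size,
            stride=arch.stride,
            dense_units=arch.dense_units,
            dropout=arch.dropout,
            siamese=arch.siamese,
            norm=np.array(model._norm),
            seed=model.training.seed,
        )
        np.savez(path, **meta, **{f"param_{k}": v for k, v in model.params.items()})
    else:
        raise TypeError(f"cannot persist classifier of type {type(model).__name__}")


def load_model(path: str | Path):
    with np.load(path, allow_pickle=True) as z:
        kind = str(z["kind"])
        if kind == "oracle":
            return LinearOracle(z["weights"], threshold=float(z["threshold"]),
                                gain=float(z["gain"]))
        arch = ArchConfig(
            conv_filters=tuple(int(f) for f in z["conv_filters"]),
            kernel_size=int(z["kernel_size"]),
            stride=int(z["stride"]),
            dense_units=int(z["dense_units"]),
            dropout=float(z["dropout"]),
            siamese=bool(z["siamese"]),
        )
        model = CNNClassifier(int(z["n_channels"]), int(z["window_length"]),
                              arch=arch,
                              training=TrainingConfig(seed=int(z["seed"])))
        model.params = {k[len("param_"):]: z[k] for k in z.files
                        if k.startswith("param_")}
        model._norm = tuple(float(v) for v in z["norm"])
        return model
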