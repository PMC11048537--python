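"""In-memory containers for multichannel EEG recordings and 2 s windows.

An :class:`EEGRecording` is a channels x samples array with a sampling rate,
channel labels and seizure annotations (start, stop, label in seconds).
A :class:`WindowSet` holds fixed-length epochs cut from one or more
recordings together with binary class labels (ictal / non-ictal) and the
provenance of each window (recording id, start-sample offset).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["EEGRecording", "WindowSet", "write_annotations", "read_annotations"]

ICTAL = 1
NONICTAL = 0


@dataclass
class EEGRecording:
    """A continuous multichannel EEG recording.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolt-scale units; all channels share one time base.
    fs : float
        Sampling frequency in Hz.
    channel_labels : list of str
        One label per channel (bipolar montage names such as ``Fp1-F7``).
    annotations : list of (float, float, str)
        Seizure intervals ``(start_s, stop_s, label)``, sorted and
        non-overlapping.
    subject_id, recording_id : str
        Identifiers used by the leave-one-recording-out evaluation.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    annotations: list[tuple[float, float, str]] = field(default_factory=list)
    subject_id: str = "S0"
    recording_id: str = "R0"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        anns = sorted(self.annotations, key=lambda a: a[0])
        for (s0, e0, _), (s1, _, _) in zip(anns, anns[1:]):
            if s1 < e0:
                raise ValueError("annotations overlap")
        for s, e, _ in anns:
            if not (0 <= s < e <= self.duration + 1e-9):
                raise ValueError(f"annotation ({s}, {e}) outside recording")
        self.annotations = anns

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.data.shape[1] / self.fs

    def copy_with(self, data: np.ndarray) -> "EEGRecording":
        """Return a copy of this recording carrying new sample data."""
        return EEGRecording(
            data=data,
            fs=self.fs,
            channel_labels=list(self.channel_labels),
            annotations=list(self.annotations),
            subject_id=self.subject_id,
            recording_id=self.recording_id,
        )

    # -- persistence -------------------------------------------------------

    def to_npz(self, path: str | Path) -> None:
        """Save to an NPZ container (arrays + metadata)."""
        ann = np.array(
            [(s, e, lbl) for s, e, lbl in self.annotations], dtype=object
        )
        np.savez(
            path,
            data=self.data,
            fs=np.float64(self.fs),
            channel_labels=np.array(self.channel_labels, dtype=object),
            annotations=ann,
            subject_id=np.str_(self.subject_id),
            recording_id=np.str_(self.recording_id),
        )

    @classmethod
    def from_npz(cls, path: str | Path) -> "EEGRecording":
        with np.load(path, allow_pickle=True) as z:
            ann = [(float(s), float(e), str(lbl)) for s, e, lbl in z["annotations"]]
            return cls(
                data=z["data"],
                fs=float(z["fs"]),
                channel_labels=[str(c) for c in z["channel_labels"]],
                annotations=ann,
                subject_id=str(z["subject_id"]),
                recording_id=str(z["recording_id"]),
            )


def write_annotations(path: str | Path, annotations, fmt: str = "%.6f") -> None:
    """Write ``start stop label`` per line (seconds, tab-separated)."""
    with open(path, "w") as fh:
        for start, stop, label in annotations:
            fh.write(f"{fmt % start}\t{fmt % stop}\t{label}\n")


def read_annotations(path: str | Path) -> list[tuple[float, float, str]]:
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        start, stop, label = line.split("\t")
        out.append((float(start), float(stop), label))
    return out


@dataclass
class WindowSet:
    """Fixed-length multichannel epochs with binary labels and provenance."""

    data: np.ndarray  # (n_windows, n_channels, L)
    labels: np.ndarray  # (n_windows,) in {0, 1}
    provenance: list[tuple[str, int]]  # (recording_id, start-sample offset)
    fs: float
    overlap: float = 0.0
    channel_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.data.ndim != 3:
            raise ValueError("window data must be 3-D (windows x channels x L)")
        if len(self.labels) != len(self.data) or len(self.provenance) != len(self.data):
            raise ValueError("labels/provenance length mismatch")
        if self.labels.size and not np.isin(self.labels, (ICTAL, NONICTAL)).all():
            raise ValueError("labels must be binary")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def window_length(self) -> int:
        return self.data.shape[2]

    def subset(self, idx) -> "WindowSet":
        idx = np.asarray(idx)
        return WindowSet(
            data=self.data[idx],
            labels=self.labels[idx],
            provenance=[self.provenance[i] for i in idx],
            fs=self.fs,
            overlap=self.overlap,
            channel_labels=self.channel_labels,
        )

    def class_counts(self) -> tuple[int, int]:
        """(n_nonictal, n_ictal)."""
        return int(np.sum(self.labels == NONICTAL)), int(np.sum(self.labels == ICTAL))

    def to_npz(self, path: str | Path) -> None:
        prov = np.array([(rid, str(off)) for rid, off in self.provenance],
                        dtype=object)
        np.savez(
            path,
            data=self.data,
            labels=self.labels,
            provenance=prov,
            fs=np.float64(self.fs),
            overlap=np.float64(self.overlap),
            channel_labels=np.array(self.channel_labels or [], dtype=object),
        )

    @classmethod
    def from_npz(cls, path: str | Path) -> "WindowSet":
        with np.load(path, allow_pickle=True) as z:
            labels = [str(c) for c in z["channel_labels"]]
            return cls(
                data=z["data"],
                labels=z["labels"],
                provenance=[(str(r), int(o)) for r, o in z["provenance"]],
                fs=float(z["fs"]),
                overlap=float(z["overlap"]),
                channel_labels=labels or None,
            )

    @staticmethod
    def concatenate(sets: list["WindowSet"]) -> "WindowSet":
        sets = [s for s in sets if len(s)]
        if not sets:
            raise ValueError("nothing to concatenate")
        fs = sets[0].fs
        if any(s.fs != fs for s in sets):
            raise ValueError("sampling rates differ")
        return WindowSet(
            data=np.concatenate([s.data for s in sets]),
            labels=np.concatenate([s.labels for s in sets]),
            provenance=[p for s in sets for p in s.provenance],
            fs=fs,
            overlap=sets[0].overlap,
            channel_labels=sets[0].channel_labels,
        )
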