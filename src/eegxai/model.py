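"""Classifier contract, leave-one-recording-out evaluation and metrics.

Patient-specific seizure models are evaluated with leave-one-recording-out
(LORO) cross-validation: with k recordings for a subject, each fold trains
on k-1 recordings and tests on the held-out one.  Training sets are built
by oversampling ictal windows with a chosen overlap and subsampling the
majority class; test sets always use non-overlapping windows and are
balanced.  Five metrics are computed per fold: sensitivity, specificity,
accuracy, F1 and AUC-ROC.  A Friedman rank test compares accuracies across
overlap conditions within subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Protocol, runtime_checkable

import numpy as np
from scipy import stats as sp_stats
from sklearn.metrics import roc_auc_score

from .containers import ICTAL, NONICTAL, EEGRecording, WindowSet
from .nn import CNNClassifier, TrainingConfig
from .preprocess import balance_two_step, preprocess_recording, segment_windows

__all__ = [
    "Classifier",
    "MetricSet",
    "compute_metrics",
    "LOROPlan",
    "loro_evaluate",
    "FriedmanResult",
    "friedman_overlap_test",
]


@runtime_checkable
class Classifier(Protocol):
    """Binary seizure classifier: ``predict_proba`` returns P(ictal)."""

    def fit(self, windows: WindowSet): ...

    def predict_proba(self, x: np.ndarray) -> np.ndarray: ...


@dataclass(frozen=True)
class MetricSet:
    sensitivity: float
    specificity: float
    accuracy: float
    f1: float
    auc: float
    n_test: int = 0

    def as_dict(self) -> dict[str, float]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "f1": self.f1,
            "auc": self.auc,
            "n_test": self.n_test,
        }


def compute_metrics(probs, labels) -> MetricSet:
    """Threshold metrics at 0.5 plus rank-based AUC-ROC.

    AUC is undefined when only one class is present; it is reported as NaN
    with a warning.
    """
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if probs.shape != labels.shape:
        raise ValueError("probs and labels must have equal length")
    pred = (probs >= 0.5).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    acc = (tp + tn) / len(labels)
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else float("nan")
    if len(np.unique(labels)) < 2:
        warnings.warn("AUC undefined with a single class", stacklevel=2)
        auc = float("nan")
    else:
        auc = float(roc_auc_score(labels, probs))
    return MetricSet(sens, spec, acc, f1, auc, n_test=len(labels))


@dataclass
class LOROPlan:
    """Fold layout: fold i holds out recording i for testing."""

    recording_ids: list[str]

    def __post_init__(self) -> None:
        if len(self.recording_ids) < 2:
            raise ValueError("LORO needs at least 2 recordings")

    @property
    def k(self) -> int:
        return len(self.recording_ids)

    def folds(self):
        for i, rid in enumerate(self.recording_ids):
            train = [r for j, r in enumerate(self.recording_ids) if j != i]
            yield rid, train


def _windows_for_training(rec: EEGRecording, overlap: float) -> tuple[WindowSet, WindowSet]:
    # Overlap oversamples the ictal class only; the non-ictal class is cut
    # without overlap and later subsampled to balance.
    ictal = segment_windows(rec, overlap=overlap, which="ictal")
    nonictal = segment_windows(rec, overlap=0.0, which="nonictal")
    return ictal, nonictal


def loro_evaluate(
    recordings: list[EEGRecording],
    overlap: float,
    classifier_factory: Callable[[int, int], Classifier] | None = None,
    training: TrainingConfig | None = None,
    seed: int = 0,
    line_freq: float = 60.0,
    apply_filters: bool = True,
) -> list[MetricSet]:
    """Leave-one-recording-out evaluation at one training overlap rate.

    ``classifier_factory(n_channels, window_length)`` builds a fresh model
    per fold; the default is the reference CNN with ``training``.  Test
    windows are cut without overlap and balanced; folds whose held-out
    recording yields no ictal test window are skipped with a warning.
    """
    if len(recordings) < 2:
        raise ValueError("LORO needs at least 2 recordings")
    if classifier_factory is None:
        cfg = training or TrainingConfig(seed=seed)

        def classifier_factory(n_ch, L):  # noqa: F811 - default factory
            return CNNClassifier(n_ch, L, training=cfg)

    if apply_filters:
        recordings = [preprocess_recording(r, line_freq=line_freq) for r in recordings]
    plan = LOROPlan([r.recording_id for r in recordings])
    by_id = {r.recording_id: r for r in recordings}
    results = []
    for fold, (test_id, train_ids) in enumerate(plan.folds()):
        assert test_id not in train_ids
        test_rec = by_id[test_id]
        test_ictal = segment_windows(test_rec, overlap=0.0, which="ictal")
        test_nonictal = segment_windows(test_rec, overlap=0.0, which="nonictal")
        if len(test_ictal) == 0:
            warnings.warn(f"fold {fold}: no ictal test windows; skipped",
                          stacklevel=2)
            continue
        test = balance_two_step(test_ictal, test_nonictal, seed=seed + fold)

        train_ict, train_non = [], []
        for rid in train_ids:
            ict, non = _windows_for_training(by_id[rid], overlap)
            if len(ict):
                train_ict.append(ict)
            if len(non):
                train_non.append(non)
        train = balance_two_step(WindowSet.concatenate(train_ict),
                                 WindowSet.concatenate(train_non),
                                 seed=seed + fold)
        model = classifier_factory(train.n_channels, train.window_length)
        model.fit(train)
        probs = np.atleast_1d(model.predict_proba(test.data))
        results.append(compute_metrics(probs, test.labels))
    return results


@dataclass(frozen=True)
class FriedmanResult:
    statistic: float
    pvalue: float


def friedman_overlap_test(accuracies: np.ndarray) -> FriedmanResult:
    """Friedman rank test across overlap conditions (subjects x conditions).

    Within-subject ranks with average ranks for ties; chi-square reference
    distribution with (conditions - 1) degrees of freedom.
    """
    a = np.asarray(accuracies, dtype=np.float64)
    if a.ndim != 2 or a.shape[0] < 3 or a.shape[1] < 3:
        raise ValueError("need >= 3 subjects and >= 3 conditions")
    if np.isnan(a).any():
        raise ValueError("missing cells are not allowed")
    if np.all(a == a[:, [0]]):
        # every subject ranks all conditions as tied: no evidence of an effect
        return FriedmanResult(0.0, 1.0)
    stat, p = sp_stats.friedmanchisquare(*a.T)
    return FriedmanResult(float(stat), float(p))
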