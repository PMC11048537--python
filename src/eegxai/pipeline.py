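"""End-to-end experiment orchestration.

Stage order: synthesize recordings -> filter + window -> train the
per-subject classifier -> leave-one-recording-out evaluation across
overlap rates (with a Friedman test on the accuracy matrix) -> per-channel
feature table -> channel attributions for correctly classified ictal
windows -> Spearman correlation of features against importances -> report.

Each stage reads and writes open formats (NPZ arrays, plain-text
annotations, CSV tables, JSON manifest) under one output directory, so a
run can be resumed stage by stage and intermediates can be consumed by
other tooling.  All randomness flows from the master seed; a rerun with an
identical config reproduces the deterministic artifacts bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import EEGRecording, WindowSet, write_annotations
from .correlation import correlate_all, report
from .features import compute_feature_table
from .io import load_model, save_model
from .model import friedman_overlap_test, loro_evaluate
from .nn import CNNClassifier, TrainingConfig
from .preprocess import balance_two_step, preprocess_recording, segment_windows
from .synth import SynthConfig, generate_subject, oracle_for_config
from .xai import LimeConfig, MaskingPolicy, explain_correct_ictal

__all__ = ["ExperimentConfig", "DependencyError", "run_experiment", "run_stage",
           "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("synth", "preprocess", "train", "evaluate", "features", "explain",
          "correlate", "report")


class DependencyError(RuntimeError):
    """A stage was asked to run before its inputs exist."""


@dataclass
class ExperimentConfig:
    outdir: Path
    synth: SynthConfig = field(default_factory=SynthConfig)
    n_subjects: int = 2
    overlaps: tuple[float, ...] = (0.5, 0.7, 0.8)
    classifier: str = "oracle"  # {"oracle", "cnn"}
    training: TrainingConfig = field(default_factory=TrainingConfig)
    lime: LimeConfig = field(default_factory=LimeConfig)
    masking_kind: str = "zeros"
    line_freq: float = 60.0
    correlation_mode: str = "pooled"
    seed: int = 0

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        if not all(0 <= o < 1 for o in self.overlaps):
            raise ValueError("overlap rates must be in [0, 1)")
        if self.classifier not in ("oracle", "cnn"):
            raise ValueError(f"unknown classifier {self.classifier!r}")

    # -- derived -----------------------------------------------------------

    def subject_ids(self) -> list[str]:
        return [f"S{i:02d}" for i in range(self.n_subjects)]

    def subject_synth(self, i: int) -> SynthConfig:
        # independent per-subject streams, derived from the master seed
        return replace(self.synth, seed=self.synth.seed + self.seed * 7919 + 1000 * i)

    def masking(self) -> MaskingPolicy:
        return MaskingPolicy(kind=self.masking_kind)

    def explain_overlap(self) -> float:
        # the best-performing training condition: the largest overlap
        return max(self.overlaps)

    def make_classifier(self, subject_index: int, n_channels: int, L: int):
        if self.classifier == "oracle":
            return oracle_for_config(self.subject_synth(subject_index))
        return CNNClassifier(n_channels, L, training=self.training)

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["outdir"] = str(self.outdir)
        d["synth"]["informative_channels"] = sorted(
            self.synth.informative_channels)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text())
        synth = SynthConfig(**{
            **raw.get("synth", {}),
            "informative_channels":
                frozenset(raw.get("synth", {}).get("informative_channels", (0, 1))),
        })
        training = TrainingConfig(**raw.get("training", {}))
        lime = LimeConfig(**raw.get("lime", {}))
        kwargs = {k: v for k, v in raw.items()
                  if k not in ("synth", "training", "lime")}
        if "overlaps" in kwargs:
            kwargs["overlaps"] = tuple(kwargs["overlaps"])
        return cls(synth=synth, training=training, lime=lime, **kwargs)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _require(path: Path, stage: str, needed_by: str) -> Path:
    if not path.exists():
        raise DependencyError(
            f"stage '{needed_by}' needs artifacts from stage '{stage}' "
            f"({path} is missing); run it first")
    return path


def stage_synth(config: ExperimentConfig) -> Path:
    out = config.outdir / "recordings"
    out.mkdir(parents=True, exist_ok=True)
    truth = {}
    for i, sid in enumerate(config.subject_ids()):
        recs, gt = generate_subject(config.subject_synth(i), subject_id=sid)
        for rec in recs:
            rec.to_npz(out / f"{rec.recording_id}.npz")
            write_annotations(out / f"{rec.recording_id}.ann.txt",
                              rec.annotations)
        truth[sid] = {
            "informative_channels": sorted(gt.informative_channels),
            "channel_weights": gt.channel_weights.tolist(),
        }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    return out


def _load_recordings(config: ExperimentConfig, sid: str) -> list[EEGRecording]:
    rec_dir = _require(config.outdir / "recordings", "synth", "preprocess")
    paths = sorted(rec_dir.glob(f"{sid}_rec*.npz"))
    if not paths:
        raise DependencyError(f"no recordings for subject {sid} in {rec_dir}")
    return [EEGRecording.from_npz(p) for p in paths]


def stage_preprocess(config: ExperimentConfig) -> Path:
    """Filter each subject's recordings and build the fold-0 window sets.

    Fold 0 holds out the first recording as the test set (no overlap,
    balanced); the remaining recordings form the training set (ictal
    windows oversampled with the largest configured overlap, majority
    class subsampled).
    """
    out = config.outdir / "windows"
    out.mkdir(parents=True, exist_ok=True)
    overlap = config.explain_overlap()
    for i, sid in enumerate(config.subject_ids()):
        recs = [preprocess_recording(r, line_freq=config.line_freq)
                for r in _load_recordings(config, sid)]
        test_rec, train_recs = recs[0], recs[1:]
        test = balance_two_step(
            segment_windows(test_rec, overlap=0.0, which="ictal"),
            segment_windows(test_rec, overlap=0.0, which="nonictal"),
            seed=config.seed + i,
        )
        train = balance_two_step(
            WindowSet.concatenate([
                segment_windows(r, overlap=overlap, which="ictal")
                for r in train_recs]),
            WindowSet.concatenate([
                segment_windows(r, overlap=0.0, which="nonictal")
                for r in train_recs]),
            seed=config.seed + i,
        )
        test.to_npz(out / f"{sid}_test.npz")
        train.to_npz(out / f"{sid}_train.npz")
    return out


def stage_train(config: ExperimentConfig) -> Path:
    out = config.outdir / "models"
    out.mkdir(parents=True, exist_ok=True)
    for i, sid in enumerate(config.subject_ids()):
        train_path = _require(config.outdir / "windows" / f"{sid}_train.npz",
                              "preprocess", "train")
        train = WindowSet.from_npz(train_path)
        model = config.make_classifier(i, train.n_channels, train.window_length)
        model.fit(train)
        save_model(model, out / f"{sid}.npz")
    return out


def stage_evaluate(config: ExperimentConfig) -> Path:
    out = config.outdir / "metrics"
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, sid in enumerate(config.subject_ids()):
        recs = _load_recordings(config, sid)
        for overlap in config.overlaps:
            folds = loro_evaluate(
                recs, overlap,
                classifier_factory=lambda n_ch, L, i=i: config.make_classifier(i, n_ch, L),
                seed=config.seed + i,
                line_freq=config.line_freq,
            )
            for fold, m in enumerate(folds):
                rows.append({"subject": sid, "fold": fold, "overlap": overlap,
                             **m.as_dict()})
    metrics = pd.DataFrame(rows)
    metrics.to_csv(out / "metrics.csv", index=False)
    fried: dict = {"pvalue": None, "statistic": None}
    acc = (metrics.groupby(["subject", "overlap"])["accuracy"].mean()
                  .unstack("overlap"))
    if acc.shape[0] >= 3 and acc.shape[1] >= 3 and not acc.isna().any().any():
        res = friedman_overlap_test(acc.to_numpy())
        fried = {"pvalue": res.pvalue, "statistic": res.statistic}
    else:
        logger.info("Friedman test skipped: needs >= 3 subjects and >= 3 overlaps")
    (out / "friedman.json").write_text(json.dumps(fried, indent=2))
    return out


def stage_features(config: ExperimentConfig) -> Path:
    out = config.outdir / "features"
    out.mkdir(parents=True, exist_ok=True)
    for sid in config.subject_ids():
        test_path = _require(config.outdir / "windows" / f"{sid}_test.npz",
                             "preprocess", "features")
        table = compute_feature_table(WindowSet.from_npz(test_path))
        table.to_csv(out / f"{sid}_features.csv", index=False)
    return out


def stage_explain(config: ExperimentConfig) -> Path:
    out = config.outdir / "xai"
    out.mkdir(parents=True, exist_ok=True)
    for i, sid in enumerate(config.subject_ids()):
        model_path = _require(config.outdir / "models" / f"{sid}.npz",
                              "train", "explain")
        test_path = _require(config.outdir / "windows" / f"{sid}_test.npz",
                             "preprocess", "explain")
        model = load_model(model_path)
        test = WindowSet.from_npz(test_path)
        lime = replace(config.lime, seed=config.lime.seed + config.seed + 97 * i)
        imp = explain_correct_ictal(model, test, masking=config.masking(),
                                    lime_config=lime)
        imp.to_csv(out / f"{sid}_importance.csv", index=False)
    return out


def stage_correlate(config: ExperimentConfig) -> Path:
    out = config.outdir / "correlation"
    out.mkdir(parents=True, exist_ok=True)
    frames = []
    for sid in config.subject_ids():
        feat_path = _require(config.outdir / "features" / f"{sid}_features.csv",
                             "features", "correlate")
        imp_path = _require(config.outdir / "xai" / f"{sid}_importance.csv",
                            "explain", "correlate")
        features = pd.read_csv(feat_path)
        importances = pd.read_csv(imp_path)
        if importances.empty:
            warnings.warn(f"{sid}: no importances; skipped", stacklevel=2)
            continue
        frames.append(correlate_all(features, importances, subject=sid,
                                    mode=config.correlation_mode))
    results = (pd.concat(frames, ignore_index=True) if frames
               else pd.DataFrame())
    results.to_csv(out / "results.csv", index=False)
    return out


def stage_report(config: ExperimentConfig) -> Path:
    out = config.outdir / "report"
    res_path = _require(config.outdir / "correlation" / "results.csv",
                        "correlate", "report")
    results = pd.read_csv(res_path)
    report(results, outdir=out)
    return out


_STAGE_FUNCS = {
    "synth": stage_synth,
    "preprocess": stage_preprocess,
    "train": stage_train,
    "evaluate": stage_evaluate,
    "features": stage_features,
    "explain": stage_explain,
    "correlate": stage_correlate,
    "report": stage_report,
}


def run_stage(name: str, config: ExperimentConfig) -> Path:
    """Execute a single stage; raises :class:`DependencyError` when the
    artifacts of an earlier stage are missing."""
    if name not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {name!r}; choose from {STAGES}")
    logger.info("running stage %s", name)
    return _STAGE_FUNCS[name](config)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_experiment(config: ExperimentConfig) -> Path:
    """Run all stages and write a manifest of seeds, versions and hashes."""
    config.outdir.mkdir(parents=True, exist_ok=True)
    (config.outdir / "config.yaml").write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True))
    for name in STAGES:
        run_stage(name, config)
    hashes = {
        str(p.relative_to(config.outdir)): _sha256(p)
        for p in sorted(config.outdir.rglob("*.csv"))
    }
    fried = json.loads((config.outdir / "metrics" / "friedman.json").read_text())
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "numpy": np.__version__,
        "stages": list(STAGES),
        "friedman": fried,
        "artifact_sha256": hashes,
    }
    (config.outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return config.outdir
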