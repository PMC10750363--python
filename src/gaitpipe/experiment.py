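"""End-to-end experiment orchestration.

Ties the stages together: synthetic cohort -> detection stage (oracle
backend) -> clip slicing and frame sampling -> per-fold training of the
3D classifier -> metric reports and cross-validation aggregation.  One
global seed fans out deterministically (via numpy SeedSequence spawning)
to cohort generation, the fold split, weight initialization and data
order, so a run is reproducible bit-for-bit under single-threaded
execution.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import evaluation as ev
from .clips import resize_for_model, sample_frames, slice_one_second_clips
from .detection import extract_patient_clip
from .nn import ArchitectureSpec, build_model, forward
from .synthetic import CohortDataset, generate_cohort, oracle_backend
from .training import TrainConfig, TrainHistory, train_fold

LABEL_TO_INDEX = {"ASD": 0, "non-ASD": 1}


@dataclass
class CohortConfig:
    n_patients: int = 12
    class_ratio: float = 0.5
    clips_per_patient: int = 4
    separation: float = 1.0
    frame_width: int = 320
    frame_height: int = 180
    fps: int = 30
    distractor_entry_frame: int | None = None


@dataclass
class ExperimentConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    arch: ArchitectureSpec = field(default_factory=lambda: ArchitectureSpec(
        block_counts=(1, 1, 1, 1), width_multiplier=0.25, input_side=64))
    train: TrainConfig = field(default_factory=lambda: TrainConfig(
        learning_rate=1e-3, max_epochs=10))
    preprocessing: str = "detection_stage"   # or "short_side_scale"
    crop_side: int = 64                      # square crop emitted by stage 1
    temporal_size: int = 8
    k_folds: int = 5
    seed: int = 0
    transfer_checkpoint: str | None = None
    out_dir: str | None = None

    def __post_init__(self):
        if self.preprocessing not in ("detection_stage", "short_side_scale"):
            raise ValueError(f"unknown preprocessing {self.preprocessing!r}")
        if self.train.mode == "transfer" and not self.transfer_checkpoint:
            raise ValueError("transfer mode requires a checkpoint path")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["arch"] = self.arch.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        d["cohort"] = CohortConfig(**d["cohort"])
        d["arch"] = ArchitectureSpec.from_dict(d["arch"])
        d["train"] = TrainConfig(**d["train"])
        return cls(**d)


@dataclass
class FoldReport:
    fold: int
    val_patients: list[str]
    metrics: ev.MetricsReport
    confusion: ev.ConfusionMatrix
    history: TrainHistory


@dataclass
class ResultsBundle:
    config: dict
    folds: list[FoldReport]
    mean_accuracy: float
    mean_f1: float
    mean_auroc: float
    fold_assignment: ev.FoldAssignment

    def to_json(self) -> dict:
        return {
            "config": self.config,
            "fold_assignment": self.fold_assignment.to_json(),
            "folds": [
                {
                    "fold": f.fold,
                    "val_patients": f.val_patients,
                    "accuracy": f.metrics.accuracy,
                    "f1": f.metrics.f1,
                    "auroc": f.metrics.auroc,
                    "confusion": f.confusion.as_array().tolist(),
                    "history": {
                        "train_loss": f.history.train_loss,
                        "val_loss": f.history.val_loss,
                        "val_accuracy": f.history.val_accuracy,
                        "lr": f.history.lr,
                    },
                }
                for f in self.folds
            ],
            "mean": {"accuracy": self.mean_accuracy, "f1": self.mean_f1,
                     "auroc": self.mean_auroc},
        }


def prepare_clip_tensors(cohort: CohortDataset, config: ExperimentConfig
                         ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Run stages 1 + 2 preprocessing over a cohort.

    Returns (tensors (N, 3, T, side, side), label indices, patient ids).
    """
    from .clips import short_side_scale_crop
    tensors, labels, pids = [], [], []
    for pid, label, scenes in cohort.patients:
        for s_i, scene in enumerate(scenes):
            if config.preprocessing == "detection_stage":
                crops, _ = extract_patient_clip(
                    scene.frames, oracle_backend(scene), out_side=config.crop_side)
            else:
                crops = np.stack([short_side_scale_crop(f, config.crop_side)
                                  for f in scene.frames])
            for clip in slice_one_second_clips(crops, pid, label,
                                               fps=scene.config.fps,
                                               source_video=f"{pid}/s{s_i}"):
                sc = sample_frames(clip, config.temporal_size)
                tensors.append(resize_for_model(sc, config.arch.input_side))
                labels.append(LABEL_TO_INDEX[label])
                pids.append(pid)
    return np.stack(tensors), np.array(labels), pids


def run_experiment(config: ExperimentConfig) -> ResultsBundle:
    """Full cross-validated experiment on a synthetic cohort."""
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(3)]
    cohort_seed, split_seed, train_seed = seeds

    c = config.cohort
    cohort = generate_cohort(
        c.n_patients, c.class_ratio, c.clips_per_patient, cohort_seed,
        separation=c.separation, frame_width=c.frame_width,
        frame_height=c.frame_height, fps=c.fps,
        distractor_entry_frame=c.distractor_entry_frame)
    x, y, pids = prepare_clip_tensors(cohort, config)
    pids = np.array(pids)

    folds = ev.stratified_group_kfold(cohort.labels(), k=config.k_folds,
                                      seed=split_seed)
    reports: list[FoldReport] = []
    for i in range(folds.k):
        _, val_patients = folds.train_val(i)
        val_mask = np.isin(pids, val_patients)
        arch = ArchitectureSpec(**{**config.arch.to_dict(),
                                   "seed": train_seed + i})
        model = build_model(arch)
        tc = TrainConfig(**{**asdict(config.train), "seed": train_seed + i})
        model, history, _ = train_fold(model, x[~val_mask], y[~val_mask],
                                       x[val_mask], y[val_mask], tc)
        preds = forward(model, x[val_mask])
        y_true = ["ASD" if v == 0 else "non-ASD" for v in y[val_mask]]
        y_pred = ["ASD" if p.predicted == 0 else "non-ASD" for p in preds]
        scores = [p.positive_score for p in preds]
        cm = ev.confusion(y_true, y_pred)
        metrics = _fold_metrics(y_true, y_pred, scores)
        reports.append(FoldReport(fold=i, val_patients=val_patients,
                                  metrics=metrics, confusion=cm,
                                  history=history))
    bundle = ResultsBundle(
        config=config.to_dict(),
        folds=reports,
        mean_accuracy=ev.aggregate_cv([f.metrics.accuracy for f in reports]),
        mean_f1=ev.aggregate_cv([f.metrics.f1 for f in reports]),
        mean_auroc=ev.aggregate_cv([f.metrics.auroc for f in reports]),
        fold_assignment=folds,
    )
    if config.out_dir:
        write_bundle(bundle, config.out_dir)
    return bundle


def _fold_metrics(y_true, y_pred, scores) -> ev.MetricsReport:
    cm = ev.confusion(y_true, y_pred)
    try:
        p, r = ev.precision_recall(cm, "ASD")
        f1v = ev.f1(cm, "ASD")
    except ValueError:
        p = r = f1v = float("nan")
    try:
        au = ev.auroc(y_true, scores, "ASD")
    except ValueError:
        au = float("nan")
    return ev.MetricsReport(accuracy=ev.accuracy(cm), precision=p, recall=r,
                            f1=f1v, auroc=au)


def write_bundle(bundle: ResultsBundle, out_dir):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "results.json", "w") as fh:
        json.dump(bundle.to_json(), fh, indent=2)
    import pandas as pd
    rows = [{"fold": f.fold, "accuracy": f.metrics.accuracy,
             "f1": f.metrics.f1, "auroc": f.metrics.auroc}
            for f in bundle.folds]
    pd.DataFrame(rows).to_csv(out / "fold_metrics.csv", index=False)
    for f in bundle.folds:
        ev.plot_confusion(f.confusion, out / f"confusion_fold{f.fold}.png",
                          title=f"fold {f.fold}")
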