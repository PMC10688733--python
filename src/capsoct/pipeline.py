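"""Training and evaluation orchestration over image-folder datasets.

Datasets follow the ``<split>/<class>/<image>`` layout (splits ``train``,
``test``, ``val``; classes CNV, DME, DRUSEN, NORMAL for retinal OCT, but any
class folders work).  Images are resized bilinearly to the model's input
shape, grayscale is replicated to three channels, and intensities are scaled
to [0, 1].

The published recipe is the default :class:`TrainConfig`: Adam (first-moment
coefficient 0.9, per-step learning-rate decay 1e-6), learning rate 1e-4,
batch size 32, 100 epochs.  The ``tiny`` scale is the desk preset for
single-CPU runs.
"""

from __future__ import annotations

import json
import os
import time
import warnings as _warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError

from .estimators import CapsNetClassifier
from .metrics import MetricsReport, build_report, write_report
from .model_assembly import load_checkpoint, save_checkpoint

__all__ = [
    "TrainConfig",
    "RunLog",
    "load_split",
    "train",
    "evaluate",
    "evaluate_model",
    "ablate",
]

IMAGE_EXTENSIONS = (".png", ".jpg", ".jpeg")


@dataclass
class TrainConfig:
    """Everything a training run needs; defaults follow the published recipe."""

    data_dir: str = ""
    out_dir: str = "run"
    architecture: str = "clahe_capsnet"  # or 'baseline_capsnet'
    scale: str = "full"  # 'tiny' = desk preset
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-4
    lr_decay: float = 1e-6
    beta1: float = 0.9
    routing_iters: int = 3
    coupling_mode: str | None = None  # None = architecture default
    squash: str | None = None
    squash_exponent: float = 3.0
    recon_weight: float = 0.0005
    input_shape: tuple[int, int, int] = (48, 48, 3)
    seed: int = 0
    verbose: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("epochs >= 1, batch_size >= 1, learning_rate > 0")


@dataclass
class RunLog:
    """Per-epoch record of a run plus its config snapshot and seed."""

    config: dict
    seed: int
    entries: list = field(default_factory=list)  # one dict per epoch
    wall_clock_s: float = 0.0

    def write_jsonl(self, path):
        with open(path, "w") as fh:
            fh.write(json.dumps({"config": self.config, "seed": self.seed}) + "\n")
            for e in self.entries:
                fh.write(json.dumps(e) + "\n")
            fh.write(json.dumps({"wall_clock_s": self.wall_clock_s}) + "\n")


def _load_image(path, hw, channels):
    img = Image.open(path)
    img = img.convert("RGB" if channels == 3 else "L")
    img = img.resize((hw[1], hw[0]), Image.BILINEAR)
    arr = np.asarray(img, dtype=np.float32) / 255.0
    if channels == 1:
        arr = arr[:, :, None]
    return arr


def load_split(data_dir, split, input_shape=(48, 48, 3)):
    """Load one split folder into (X, y, class_names).

    Class folders are taken in sorted order.  Non-image files are skipped
    with a warning; an empty class folder is an error.
    """
    split_dir = os.path.join(data_dir, split)
    if not os.path.isdir(split_dir):
        raise FileNotFoundError(f"missing split directory: {split_dir}")
    class_names = sorted(
        d for d in os.listdir(split_dir)
        if os.path.isdir(os.path.join(split_dir, d))
    )
    if not class_names:
        raise FileNotFoundError(f"no class folders under {split_dir}")
    H, W, C = input_shape
    xs, ys = [], []
    for label, cls in enumerate(class_names):
        cls_dir = os.path.join(split_dir, cls)
        n_before = len(xs)
        for fname in sorted(os.listdir(cls_dir)):
            fpath = os.path.join(cls_dir, fname)
            if not fname.lower().endswith(IMAGE_EXTENSIONS):
                _warnings.warn(f"skipping non-image file {fpath}")
                continue
            try:
                xs.append(_load_image(fpath, (H, W), C))
            except (UnidentifiedImageError, OSError):
                _warnings.warn(f"skipping unreadable image {fpath}")
                continue
            ys.append(label)
        if len(xs) == n_before:
            raise ValueError(f"empty class folder: {cls_dir}")
    return np.stack(xs), np.asarray(ys), tuple(class_names)


def _classifier_from(cfg: TrainConfig):
    return CapsNetClassifier(
        architecture=cfg.architecture,
        scale=cfg.scale,
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        learning_rate=cfg.learning_rate,
        lr_decay=cfg.lr_decay,
        beta1=cfg.beta1,
        routing_iters=cfg.routing_iters,
        coupling_mode=cfg.coupling_mode,
        squash=cfg.squash,
        squash_exponent=cfg.squash_exponent,
        recon_weight=cfg.recon_weight,
        input_shape=tuple(cfg.input_shape),
        random_state=cfg.seed,
        verbose=cfg.verbose,
    )


def train(cfg: TrainConfig):
    """Train per config; returns (fitted classifier, RunLog).

    Uses the ``val`` split (when present) for per-epoch validation and keeps
    the best-validation-accuracy weights.  Writes a checkpoint
    (``model.npz`` + config sidecar) and a JSONL run log under
    ``cfg.out_dir``.
    """
    t0 = time.time()
    X, y, class_names = load_split(cfg.data_dir, "train", cfg.input_shape)
    validation = None
    if os.path.isdir(os.path.join(cfg.data_dir, "val")):
        Xv, yv, val_names = load_split(cfg.data_dir, "val", cfg.input_shape)
        if val_names != class_names:
            raise ValueError("val classes differ from train classes")
        validation = (Xv, yv)
    clf = _classifier_from(cfg)
    clf.fit(X, y, validation_data=validation)

    os.makedirs(cfg.out_dir, exist_ok=True)
    save_checkpoint(clf.model_, os.path.join(cfg.out_dir, "model.npz"))
    with open(os.path.join(cfg.out_dir, "classes.json"), "w") as fh:
        json.dump(list(map(str, class_names)), fh)

    h = clf.history_
    entries = []
    for i, epoch in enumerate(h["epoch"]):
        e = {"epoch": int(epoch), "train_loss": h["train_loss"][i],
             "train_acc": h["train_acc"][i]}
        if h["val_loss"]:
            e["val_loss"] = h["val_loss"][i]
            e["val_acc"] = h["val_acc"][i]
        entries.append(e)
    log = RunLog(config=asdict(cfg), seed=cfg.seed, entries=entries,
                 wall_clock_s=time.time() - t0)
    log.write_jsonl(os.path.join(cfg.out_dir, "runlog.jsonl"))
    return clf, log


def evaluate_model(model, X, y, class_names) -> MetricsReport:
    """Score a built model on arrays and assemble the metrics report."""
    scores = model.predict_scores(X)
    y_pred = np.argmax(scores, axis=1)
    return build_report(y, y_pred, scores=scores, class_names=class_names)


def evaluate(checkpoint, data_dir, split="test", out_dir=None) -> MetricsReport:
    """Evaluate a checkpoint on a dataset split; optionally write artifacts."""
    model = load_checkpoint(checkpoint) if isinstance(checkpoint, (str, os.PathLike)) else checkpoint
    X, y, class_names = load_split(data_dir, split, model.cfg.input_shape)
    if len(class_names) != model.cfg.n_classes:
        raise ValueError(
            f"dataset has {len(class_names)} classes, checkpoint expects "
            f"{model.cfg.n_classes}"
        )
    report = evaluate_model(model, X, y, class_names)
    if out_dir is not None:
        write_report(report, out_dir)
    return report


def _table_rows(method, report: MetricsReport):
    rows = []
    for i, cls in enumerate(report.class_names):
        m = report.per_class[cls]
        rows.append({
            "method": method,
            "class": cls,
            "acc_ovr": m["acc_ovr"],
            "se": m["se"],
            "pr": m["pr"],
            "sp": m["sp"],
            "auc": m.get("auc"),
            "oa": report.oa if i == 0 else None,
            "os": report.os if i == 0 else None,
            "op": report.op if i == 0 else None,
        })
    return rows


def ablate(cfg: TrainConfig):
    """Train CLAHE-CapsNet and the original-CapsNet baseline on identical
    data and seed; returns (side-by-side DataFrame, {method: report}).

    The comparison table (one block of 4 class rows per method, metric
    columns ACC/SE/PR/SP/AUC plus overall OA/OS/OP) is written to
    ``cfg.out_dir/ablation.csv``.
    """
    rows, reports = [], {}
    for method in ("clahe_capsnet", "baseline_capsnet"):
        sub = TrainConfig(**{**asdict(cfg), "architecture": method,
                             "out_dir": os.path.join(cfg.out_dir, method)})
        clf, _ = train(sub)
        report = evaluate(clf.model_, cfg.data_dir, split="test",
                          out_dir=os.path.join(cfg.out_dir, method))
        reports[method] = report
        rows.extend(_table_rows(method, report))
    table = pd.DataFrame(rows)
    os.makedirs(cfg.out_dir, exist_ok=True)
    table.to_csv(os.path.join(cfg.out_dir, "ablation.csv"), index=False)
    return table, reports
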