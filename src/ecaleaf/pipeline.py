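"""End-to-end training and robustness evaluation.

``train`` fits a chosen architecture variant on a class-per-directory
image tree (optionally after 14-fold enhancement of the training split)
and writes a checkpoint plus a loss log.  ``evaluate`` scores a trained
model separately on each of the 14 environments' test records and emits
an :class:`EnvironmentReport` — a machine-readable 14-row accuracy table
with the arithmetic-mean row, per-environment confusion counts, the
variant and its parameter count.  ``crop_leaves`` consumes an upstream
detector's bounding boxes and produces the single-leaf crops the
classifier expects.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .augment import (
    AugmentedDataset,
    ENVIRONMENT_NAMES,
    ImageRecord,
    default_environments,
    expand_dataset,
    read_image_tree,
    split_per_class,
)
from .classifier import LeafDiseaseClassifier
from .network import VARIANTS, count_parameters, NetworkSpec

logger = logging.getLogger("ecaleaf")


@dataclass
class RunConfig:
    """Everything a training run needs; the seed drives all randomness."""

    data_dir: str
    out_dir: str
    variant: str = "full"
    epochs: int = 3
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    image_size: int = 64
    dropout_rate: float = 0.2
    augment: bool = True
    validation_fraction: float = 0.1
    transform_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class EnvironmentReport:
    """Accuracy per environment plus the arithmetic mean (the tables' twin)."""

    rows: dict[str, float]
    confusion: dict[str, dict]
    variant: str
    parameter_count: int
    seed: int | None = None
    config_hash: str | None = None

    @property
    def average(self) -> float:
        return float(np.mean(list(self.rows.values())))

    def to_frame(self) -> pd.DataFrame:
        rows = [{"environment": k, "accuracy": v} for k, v in self.rows.items()]
        rows.append({"environment": "average", "accuracy": self.average})
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path=None):
        payload = {
            "rows": self.rows,
            "average": self.average,
            "confusion": self.confusion,
            "variant": self.variant,
            "parameter_count": self.parameter_count,
            "seed": self.seed,
            "config_hash": self.config_hash,
        }
        if path is None:
            return json.dumps(payload, indent=2)
        Path(path).write_text(json.dumps(payload, indent=2))
        return None


def _records_to_arrays(records, dataset: AugmentedDataset | None = None):
    if dataset is None:
        X = np.stack([r.load() for r in records])
    else:
        X = np.stack([dataset.load(r) for r in records])
    y = np.array([r.label for r in records])
    return X, y


def train(config: RunConfig):
    """Fit a variant per the config; returns (classifier, log DataFrame).

    The training split is carved per class; with ``augment`` on it is
    expanded over the 14 environments before fitting.  A validation slice
    (``validation_fraction`` of the training images) selects nothing here
    beyond being logged — with few epochs the final weights are saved.
    """
    records = read_image_tree(config.data_dir)
    labels = {r.label for r in records}
    if len(labels) < 2:
        raise ValueError(
            f"training needs at least two classes, found {sorted(labels)}"
        )
    if any(sum(r.label == l for r in records) < 2 for l in labels):
        raise ValueError("every class needs at least two images")

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rng_seed = config.seed
    train_recs, val_recs = split_per_class(
        records, 1.0 - config.validation_fraction, seed=rng_seed
    )
    envs = default_environments(config.transform_overrides)
    if config.augment:
        aug = expand_dataset(train_recs, envs, seed=rng_seed)
        X, y = _records_to_arrays(aug.records, aug)
    else:
        X, y = _records_to_arrays(train_recs)

    clf = LeafDiseaseClassifier(
        variant=config.variant,
        image_size=config.image_size,
        epochs=config.epochs,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        dropout_rate=config.dropout_rate,
        random_state=rng_seed,
    )
    clf.fit(X, y)  # epochs == 0 leaves initialised weights and an empty log

    val_acc = float(clf.score(*_records_to_arrays(val_recs))) if val_recs else np.nan
    log = pd.DataFrame(
        {"epoch": np.arange(1, len(clf.loss_curve_) + 1),
         "train_loss": clf.loss_curve_}
    )
    log.to_csv(out_dir / "training_log.csv", index=False)
    clf.save(out_dir / "checkpoint.npz")
    meta = {"seed": config.seed, "variant": config.variant,
            "config_hash": config.config_hash(), "validation_accuracy": val_acc,
            "n_train": int(len(y)), "classes": sorted(labels)}
    (out_dir / "run.json").write_text(json.dumps(meta, indent=2))
    logger.info("trained %s: %d records, val acc %.3f", config.variant, len(y), val_acc)
    return clf, log


def evaluate(model, test_records, dataset: AugmentedDataset | None = None,
             seed: int | None = None, config_hash: str | None = None) -> EnvironmentReport:
    """Score a model on each environment's test subset.

    ``test_records`` carry an ``environment`` attribute (e.g. the records
    of an expanded test set); records may also be plain source records, in
    which case they are expanded over all 14 environments first.  A missing
    environment yields no row (with a warning); the mean runs over the
    rows present.
    """
    if test_records and not hasattr(test_records[0], "environment"):
        dataset = expand_dataset(list(test_records), seed=seed or 0)
        test_records = dataset.records
    by_env: dict[str, list] = {}
    for r in test_records:
        by_env.setdefault(r.environment, []).append(r)
    missing = [e for e in ENVIRONMENT_NAMES if e not in by_env]
    if missing:
        warnings.warn(f"environments absent from manifest: {missing}", stacklevel=2)

    classes = list(getattr(model, "classes_", []))
    rows: dict[str, float] = {}
    confusion: dict[str, dict] = {}
    for env in ENVIRONMENT_NAMES:
        if env not in by_env:
            continue
        recs = by_env[env]
        X, y = _records_to_arrays(recs, dataset)
        pred = model.predict(X)
        rows[env] = float(np.mean(pred == y))
        conf: dict[str, dict[str, int]] = {}
        for t, p in zip(y, pred):
            conf.setdefault(str(t), {})
            conf[str(t)][str(p)] = conf[str(t)].get(str(p), 0) + 1
        confusion[env] = conf

    pc = (model.parameter_count() if hasattr(model, "parameter_count")
          else count_parameters(variant=getattr(model, "variant", "full")))
    return EnvironmentReport(rows=rows, confusion=confusion,
                             variant=getattr(model, "variant", "full"),
                             parameter_count=int(pc), seed=seed,
                             config_hash=config_hash)


def crop_leaves(items, out_dir) -> list[Path]:
    """Cut single-leaf crops from (image path, bounding boxes) pairs.

    Boxes are (left, top, right, bottom) pixel coordinates.  Images with
    zero boxes produce no output (logged); degenerate boxes are skipped
    with a warning.  Crops are named ``<source-stem>_crop<i>.png``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for path, boxes in items:
        img = np.asarray(Image.open(path).convert("RGB"))
        h, w = img.shape[:2]
        if not boxes:
            logger.info("no leaves detected in %s; image not saved", path)
            continue
        for i, (l, t, r, b) in enumerate(boxes):
            if not (0 <= l < r <= w and 0 <= t < b <= h):
                warnings.warn(
                    f"degenerate or out-of-bounds box {(l, t, r, b)} in {path}; skipped",
                    stacklevel=2,
                )
                continue
            crop = img[t:b, l:r]
            dest = out_dir / f"{Path(path).stem}_crop{i}.png"
            Image.fromarray(crop, "RGB").save(dest)
            written.append(dest)
    return written
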