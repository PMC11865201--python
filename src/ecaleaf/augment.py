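"""The 14-environment image-enhancement protocol.

An "environment" is one of 14 deterministic test conditions: the untouched
image plus 13 photometric/geometric transforms (flips; brightness, chroma
(saturation), contrast and sharpness each increased by 50% or reduced to
50%; Laplacian edge sharpening; gamma correction; CLAHE).  Expanding an
image set over all environments multiplies it by exactly 14; the expansion
of the training split forms the enhanced training set and the per-
environment expansions of the test split form the robustness test suites.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from PIL import Image, ImageEnhance
from scipy import ndimage
from skimage import exposure

ENVIRONMENT_NAMES = (
    "original",
    "vertical_flip",
    "horizontal_flip",
    "brightness_increase",
    "brightness_reduction",
    "chroma_increase",
    "chroma_reduction",
    "contrast_increase",
    "contrast_reduction",
    "sharpness_increase",
    "sharpness_reduction",
    "laplace",
    "gamma",
    "clahe",
)

#: Default transform settings: enhancement factor 1.5 for each "increase"
#: and 0.5 for each "reduction"; gamma exponent 1.5; CLAHE clip limit 0.02
#: (normalised) on an 8x8 tile grid; 3x3 Laplacian sharpening.
DEFAULT_PARAMS: dict[str, dict] = {
    "brightness_increase": {"factor": 1.5},
    "brightness_reduction": {"factor": 0.5},
    "chroma_increase": {"factor": 1.5},
    "chroma_reduction": {"factor": 0.5},
    "contrast_increase": {"factor": 1.5},
    "contrast_reduction": {"factor": 0.5},
    "sharpness_increase": {"factor": 1.5},
    "sharpness_reduction": {"factor": 0.5},
    "gamma": {"gamma": 1.5},
    "clahe": {"clip_limit": 0.02, "tiles": 8},
    "laplace": {"strength": 1.0},
}


@dataclass(frozen=True)
class Environment:
    """One evaluation condition: a named deterministic transform."""

    name: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.name not in ENVIRONMENT_NAMES:
            raise ValueError(f"unknown environment {self.name!r}")

    def merged_params(self) -> dict:
        return {**DEFAULT_PARAMS.get(self.name, {}), **self.params}


def default_environments(overrides: dict[str, dict] | None = None) -> list[Environment]:
    overrides = overrides or {}
    return [Environment(n, overrides.get(n, {})) for n in ENVIRONMENT_NAMES]


def _as_uint8(img: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def _enhance(img: np.ndarray, enhancer, factor: float) -> np.ndarray:
    pil = Image.fromarray(img, "RGB")
    return np.asarray(enhancer(pil).enhance(factor))


def apply_environment(image: np.ndarray, env: Environment | str, seed: int = 0) -> np.ndarray:
    """Apply one environment transform to an (H, W, 3) uint8 RGB image.

    Deterministic given (image, env, seed); output has the input's spatial
    size and channel count.  The seed is accepted for interface symmetry —
    every transform in the suite is deterministic.
    """
    if isinstance(env, str):
        env = Environment(env)
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) RGB image, got shape {image.shape}")
    if image.shape[0] == 0 or image.shape[1] == 0:
        raise ValueError("image has zero extent")
    if image.dtype != np.uint8:
        image = _as_uint8(image)
    p = env.merged_params()
    name = env.name

    if name == "original":
        return image.copy()
    if name == "vertical_flip":
        return image[::-1].copy()
    if name == "horizontal_flip":
        return image[:, ::-1].copy()
    if name.startswith("brightness"):
        return _enhance(image, ImageEnhance.Brightness, p["factor"])
    if name.startswith("chroma"):
        return _enhance(image, ImageEnhance.Color, p["factor"])
    if name.startswith("contrast"):
        return _enhance(image, ImageEnhance.Contrast, p["factor"])
    if name.startswith("sharpness"):
        return _enhance(image, ImageEnhance.Sharpness, p["factor"])
    if name == "laplace":
        # sharpened = original + strength * Laplacian response
        kernel = np.array([[0, -1, 0], [-1, 4, -1], [0, -1, 0]], np.float32)
        f = image.astype(np.float32)
        resp = np.stack(
            [ndimage.convolve(f[..., c], kernel, mode="nearest") for c in range(3)],
            axis=-1,
        )
        return _as_uint8(f + p["strength"] * resp)
    if name == "gamma":
        return _as_uint8(255.0 * exposure.adjust_gamma(image / 255.0, p["gamma"]))
    if name == "clahe":
        if image.min() == image.max():
            # degenerate histogram: equalization is the identity
            return image.copy()
        tiles = int(p["tiles"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = exposure.equalize_adapthist(
                image,
                kernel_size=(max(image.shape[0] // tiles, 1),
                             max(image.shape[1] // tiles, 1)),
                clip_limit=p["clip_limit"],
            )
        return _as_uint8(255.0 * out)
    raise ValueError(f"unknown environment {name!r}")  # pragma: no cover


# ---------------------------------------------------------------------------
# dataset records and expansion


@dataclass(frozen=True)
class ImageRecord:
    """One labelled source image, loadable on demand."""

    image_id: str
    label: str
    path: str | None = None
    image: np.ndarray | None = None

    def load(self) -> np.ndarray:
        if self.image is not None:
            return np.asarray(self.image)
        if self.path is None:
            raise ValueError(f"record {self.image_id} has neither pixels nor a path")
        return np.asarray(Image.open(self.path).convert("RGB"))


@dataclass(frozen=True)
class AugmentedRecord:
    """One expanded record: a (source image, environment) pair."""

    record_id: str
    source_id: str
    label: str
    environment: str


class AugmentedDataset:
    """The 14-fold expansion of a labelled image set.

    Records are metadata (source id, label, environment); pixel data is
    produced lazily by :meth:`load` or written out by :meth:`materialize`,
    so counting and bookkeeping never touch pixels.
    """

    def __init__(self, sources: list[ImageRecord],
                 environments: list[Environment] | None = None, seed: int = 0):
        self.sources = list(sources)
        self.environments = environments or default_environments()
        self.seed = seed
        self._by_id = {s.image_id: s for s in self.sources}
        if len(self._by_id) != len(self.sources):
            raise ValueError("duplicate source image ids")
        if not self.sources:
            warnings.warn("expanding an empty image set", stacklevel=2)
        self.records: list[AugmentedRecord] = [
            AugmentedRecord(f"{s.image_id}__{env.name}", s.image_id, s.label, env.name)
            for s in self.sources
            for env in self.environments
        ]

    def __len__(self) -> int:
        return len(self.records)

    def per_class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.records:
            counts[r.label] = counts.get(r.label, 0) + 1
        return counts

    def load(self, record: AugmentedRecord) -> np.ndarray:
        env = next(e for e in self.environments if e.name == record.environment)
        return apply_environment(self._by_id[record.source_id].load(), env, self.seed)

    def iter_images(self):
        for rec in self.records:
            yield rec, self.load(rec)

    def materialize(self, out_dir) -> pd.DataFrame:
        """Write every record as ``<class>/<source-id>__<environment>.png`` + manifest."""
        out_dir = Path(out_dir)
        rows = []
        for rec, img in self.iter_images():
            cls_dir = out_dir / rec.label
            cls_dir.mkdir(parents=True, exist_ok=True)
            stem = rec.source_id.rsplit("/", 1)[-1]
            path = cls_dir / f"{stem}__{rec.environment}.png"
            Image.fromarray(img, "RGB").save(path)
            rows.append(
                {"record_id": rec.record_id, "source_id": rec.source_id,
                 "class": rec.label, "environment": rec.environment,
                 "path": str(path)}
            )
        manifest = pd.DataFrame(
            rows, columns=["record_id", "source_id", "class", "environment", "path"]
        )
        manifest.to_csv(out_dir / "manifest.csv", index=False)
        return manifest


def expand_dataset(sources: list[ImageRecord],
                   environments: list[Environment] | None = None,
                   seed: int = 0) -> AugmentedDataset:
    """Expand a labelled image set over original + 13 transforms (14 per source)."""
    return AugmentedDataset(sources, environments, seed)


def split_per_class(records: list[ImageRecord], train_fraction: float = 0.8,
                    seed: int = 0) -> tuple[list[ImageRecord], list[ImageRecord]]:
    """Stratified random split; each class gets ceil(train_fraction * n) training images.

    The split is disjoint and exhaustive; assignment within a class is a
    seeded random permutation.  Classes with zero images are dropped with a
    warning (nothing to split).
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    by_class: dict[str, list[ImageRecord]] = {}
    for r in records:
        by_class.setdefault(r.label, []).append(r)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for label in sorted(by_class):
        members = by_class[label]
        if not members:  # pragma: no cover - empty class list cannot arise from records
            warnings.warn(f"class {label!r} has no images; excluded", stacklevel=2)
            continue
        n_train = math.ceil(train_fraction * len(members))
        order = rng.permutation(len(members))
        train.extend(members[i] for i in order[:n_train])
        test.extend(members[i] for i in order[n_train:])
    return train, test


def read_image_tree(root) -> list[ImageRecord]:
    """Read a class-per-directory image tree into records (lazy loading)."""
    root = Path(root)
    records = []
    for cls_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        for path in sorted(cls_dir.iterdir()):
            if path.suffix.lower() in {".png", ".jpg", ".jpeg"}:
                records.append(
                    ImageRecord(f"{cls_dir.name}/{path.stem}", cls_dir.name, str(path))
                )
    return records
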