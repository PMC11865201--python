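"""Procedural 4-class synthetic leaf images.

Generates labelled RGB images of a single leaf on a soil-toned background
with class-distinctive textures: healthy leaves are veined green; powdery
mildew adds a bright whitish high-frequency speckle; late blight adds
large dark irregular blotches; leaf mould adds mid-tone yellow-brown
patches.  The textures are simple parametric noise fields, deliberately
not photorealistic: they exist so the classifier, augmentation suite and
evaluation harness can be exercised end to end with data whose classes
are genuinely learnable from pixels, without any download.

Every image is fully determined by (seed, class, index).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

CLASS_NAMES = ("healthy", "late_blight", "leaf_mould", "powdery_mildew")


@dataclass(frozen=True)
class SyntheticLeafParams:
    """Generator settings; the seed fully determines every pixel."""

    image_size: int = 448
    seed: int = 0
    spot_density: float = 0.10    # powdery-mildew speckle coverage fraction
    spot_sigma: float = 0.6       # speckle softening (px at 64; scales with size)
    blotch_scale: float = 10.0    # late-blight blotch correlation length (px at 64)
    blotch_coverage: float = 0.40 # late-blight blotch coverage fraction of the leaf
    patch_scale: float = 6.0      # leaf-mould patch correlation length (px at 64)
    patch_coverage: float = 0.40  # leaf-mould patch coverage fraction
    hue_jitter: float = 8.0      # per-image jitter of the base green (8-bit units)

    def __post_init__(self):
        if self.image_size < 8:
            raise ValueError("image_size must be at least 8")


def _class_rng(params: SyntheticLeafParams, class_name: str, index: int):
    ci = CLASS_NAMES.index(class_name)
    return np.random.default_rng(
        np.random.SeedSequence(params.seed, spawn_key=(ci, index))
    )


def _smooth_noise(rng, size, sigma):
    f = ndimage.gaussian_filter(rng.normal(size=(size, size)), sigma)
    s = f.std()
    return f / s if s > 0 else f


def generate_leaf(class_name: str, params: SyntheticLeafParams | None = None,
                  index: int = 0) -> np.ndarray:
    """One (S, S, 3) uint8 leaf image of the given class."""
    if params is None:
        params = SyntheticLeafParams()
    if class_name not in CLASS_NAMES:
        raise ValueError(f"unknown class {class_name!r}; choose from {CLASS_NAMES}")
    rng = _class_rng(params, class_name, index)
    s = params.image_size
    scale = s / 64.0  # texture lengths are stated at the 64-px test scale

    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    cy = s / 2 + rng.uniform(-0.04, 0.04) * s
    cx = s / 2 + rng.uniform(-0.04, 0.04) * s
    theta = rng.uniform(0, np.pi)
    a = s * rng.uniform(0.38, 0.45)
    b = s * rng.uniform(0.26, 0.33)
    u = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
    v = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
    wobble = 1.0 + 0.06 * _smooth_noise(rng, s, 6 * scale)
    leaf = ((u / a) ** 2 + (v / b) ** 2) * wobble < 1.0

    # soil-toned background with mild texture
    img = np.empty((s, s, 3))
    bg = 0.15 * _smooth_noise(rng, s, 2 * scale)
    for c, base in enumerate((96, 78, 58)):
        img[..., c] = base * (1.0 + bg)

    # base green with veins (brightness ridges along the major axis)
    jit = rng.uniform(-params.hue_jitter, params.hue_jitter)
    green = np.array([52.0 + jit * 0.4, 128.0 + jit, 56.0 + jit * 0.3])
    veins = 0.10 * np.cos(v / (1.5 * scale)) * np.exp(-np.abs(v) / (s * 0.3))
    shading = 1.0 + 0.08 * _smooth_noise(rng, s, 8 * scale) + veins
    for c in range(3):
        img[..., c] = np.where(leaf, green[c] * shading, img[..., c])

    if class_name == "powdery_mildew":
        # bright high-frequency speckle overlay
        noise = _smooth_noise(rng, s, params.spot_sigma * scale)
        thr = np.quantile(noise[leaf], 1.0 - params.spot_density)
        spots = np.clip((noise - thr) / (0.35 * noise.std() + 1e-9), 0, 1) * leaf
        white = np.array([232.0, 232.0, 218.0])
        for c in range(3):
            img[..., c] += spots * (white[c] - img[..., c])
    elif class_name == "late_blight":
        # large dark irregular blotches
        noise = _smooth_noise(rng, s, params.blotch_scale * scale)
        thr = np.quantile(noise[leaf], 1.0 - params.blotch_coverage)
        blotch = ((noise > thr) & leaf).astype(np.float64)
        blotch = ndimage.gaussian_filter(blotch, 1.0 * scale)
        dark = np.array([44.0, 32.0, 22.0])
        for c in range(3):
            img[..., c] += 0.95 * blotch * (dark[c] - img[..., c])
    elif class_name == "leaf_mould":
        # mid-tone yellow-brown patches
        noise = _smooth_noise(rng, s, params.patch_scale * scale)
        thr = np.quantile(noise[leaf], 1.0 - params.patch_coverage)
        patch = ((noise > thr) & leaf).astype(np.float64)
        patch = ndimage.gaussian_filter(patch, 0.8 * scale)
        ochre = np.array([178.0, 146.0, 52.0])
        for c in range(3):
            img[..., c] += 0.85 * patch * (ochre[c] - img[..., c])

    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_records(per_class: dict[str, int] | int,
                     params: SyntheticLeafParams | None = None):
    """In-memory labelled records (lazy image materialisation not needed: tiny)."""
    from .augment import ImageRecord

    if params is None:
        params = SyntheticLeafParams()
    if isinstance(per_class, int):
        per_class = {c: per_class for c in CLASS_NAMES}
    records = []
    for cls in CLASS_NAMES:
        n = per_class.get(cls, 0)
        for i in range(n):
            records.append(
                ImageRecord(f"{cls}/{cls}_{i:05d}", cls,
                            image=generate_leaf(cls, params, i))
            )
    return records


def generate_dataset(out_dir, per_class: dict[str, int] | int,
                     params: SyntheticLeafParams | None = None,
                     overwrite: bool = False) -> pd.DataFrame:
    """Write a class-per-directory PNG tree plus a manifest CSV.

    Refuses to write into an existing non-empty directory unless
    ``overwrite`` is set.  A class with count 0 gets no directory.
    """
    if params is None:
        params = SyntheticLeafParams()
    if isinstance(per_class, int):
        per_class = {c: per_class for c in CLASS_NAMES}
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise FileExistsError(
            f"{out_dir} exists and is not empty; pass overwrite=True to replace"
        )
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for cls in CLASS_NAMES:
        n = per_class.get(cls, 0)
        if n == 0:
            warnings.warn(f"class {cls!r} has count 0; directory omitted", stacklevel=2)
            continue
        cls_dir = out_dir / cls
        cls_dir.mkdir(exist_ok=True)
        for i in range(n):
            img = generate_leaf(cls, params, i)
            name = f"{cls}_{i:05d}.png"
            Image.fromarray(img, "RGB").save(cls_dir / name)
            rows.append({"path": str(cls_dir / name), "class": cls,
                         "index": i, "seed": params.seed})
    manifest = pd.DataFrame(rows, columns=["path", "class", "index", "seed"])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
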