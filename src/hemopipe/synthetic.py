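"""Synthetic inputs with the structure each pipeline stage assumes.

Three generators, none of which require downloads:

* :func:`make_feature_dataset` — labeled feature matrices emulating a
  fused deep-feature table: a small planted set of informative columns
  whose class-conditional means are separated by a chosen effect size (in
  noise-sigma units), optional redundant near-copies of them, and
  label-independent Gaussian noise columns.  The ground-truth informative
  indices are returned so selection quality can be scored.
* :func:`make_cell_image` — low-contrast blood-smear-like RGB canvases:
  elliptical "cells" with darker nuclei on a noisy background, with the
  intensity range compressed by a contrast knob so the enhancement stage
  has something to recover.
* :func:`augment_to_count` — class-count-matched augmentation by random
  rotation, flipping, intensity modification and brightness correction.

The defaults (effect size 3 sigma, 10 informative of 100 columns, 60
samples per class) put the fixture in a near-separable regime where the
wrapper error term can reach zero and parsimony drives selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .features import FeatureMatrix

__all__ = [
    "PlantedFeatureSpec",
    "CellImageSpec",
    "AugmentConfig",
    "make_feature_dataset",
    "make_cell_image",
    "augment_to_count",
]


@dataclass(frozen=True)
class PlantedFeatureSpec:
    """Shape and signal strength of a planted feature matrix.

    effect is the class-mean separation of informative columns in units
    of the within-class standard deviation (which is 1).
    """

    classes: int = 2
    per_class: int = 60
    dims: int = 100
    informative: int = 10
    effect: float = 3.0
    redundant: int = 0
    jitter: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.classes < 2:
            raise ValueError("need at least two classes")
        if self.effect < 0:
            raise ValueError("effect size must be non-negative")
        if self.informative + self.redundant > self.dims:
            raise ValueError("informative + redundant columns exceed total dims")


def make_feature_dataset(spec: PlantedFeatureSpec) -> tuple[FeatureMatrix, np.ndarray]:
    """Generate a planted-signal feature matrix and its truth indices.

    Informative column j gives class c the mean ``effect * c`` (classes
    are effect-sigma apart along every informative axis); redundant
    columns are informative columns plus N(0, jitter^2); the rest is
    standard Gaussian noise.  Column positions are shuffled by the seed.
    Returns the matrix and the sorted informative column indices.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.classes * spec.per_class
    labels = np.repeat(np.arange(spec.classes), spec.per_class)

    x = rng.standard_normal((n, spec.dims))
    info = np.arange(spec.informative)
    for j in info:
        x[:, j] += spec.effect * labels
    for r in range(spec.redundant):
        src = info[r % spec.informative]
        x[:, spec.informative + r] = x[:, src] + spec.jitter * rng.standard_normal(n)

    perm = rng.permutation(spec.dims)
    x = x[:, perm]
    col_of = np.argsort(perm)  # col_of[old] = new position
    truth = np.sort(col_of[info])

    origins = [("planted", int(j)) for j in range(spec.dims)]
    return FeatureMatrix(values=x, labels=labels, origins=origins), truth


@dataclass(frozen=True)
class CellImageSpec:
    """Layout of a synthetic low-contrast blood-smear canvas."""

    size: tuple[int, int] = (64, 64)
    cells: int = 4
    contrast: float = 0.2
    noise: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.size) < 32:
            raise ValueError("canvas must be at least 32 x 32")
        if not 0 <= self.contrast <= 1:
            raise ValueError("contrast must lie in [0, 1]")


def make_cell_image(spec: CellImageSpec) -> np.ndarray:
    """Render an RGB image of elliptical cells with darker nuclei.

    The full-range scene (background 1.0, cytoplasm 0.55, nucleus 0.15)
    is compressed around mid-grey by the contrast knob, then Gaussian
    noise is added; contrast 0 leaves only the noisy flat canvas.
    """
    rng = np.random.default_rng(spec.seed)
    m, n = spec.size
    scene = np.ones((m, n))

    yy, xx = np.mgrid[0:m, 0:n]
    for _ in range(spec.cells):
        cy, cx = rng.uniform(0.15, 0.85) * m, rng.uniform(0.15, 0.85) * n
        ry, rx = rng.uniform(0.08, 0.16) * m, rng.uniform(0.08, 0.16) * n
        cell = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
        scene[cell] = 0.55
        nucleus = ((yy - cy) / (0.55 * ry)) ** 2 + ((xx - cx) / (0.55 * rx)) ** 2 <= 1.0
        scene[nucleus] = 0.15

    grey = 0.5 + spec.contrast * (scene - 0.5)
    grey = np.clip(grey + spec.noise * rng.standard_normal((m, n)), 0.0, 1.0)
    # faint purple cast so the RGB image is not perfectly achromatic
    rgb = np.stack([grey * 0.98, grey * 0.95, np.clip(grey * 1.0, 0, 1)], axis=-1)
    return np.clip(rgb, 0.0, 1.0)


@dataclass(frozen=True)
class AugmentConfig:
    """Magnitudes of the four augmentation operations."""

    ops: tuple[str, ...] = ("rotate", "flip", "intensity", "brightness")
    intensity_range: float = 0.2  # multiplicative +/- fraction
    brightness_range: float = 0.1  # additive +/- offset
    max_small_angle: float = 15.0  # degrees, on top of quarter turns

    _KNOWN = frozenset({"rotate", "flip", "intensity", "brightness"})

    def __post_init__(self) -> None:
        unknown = set(self.ops) - self._KNOWN
        if unknown:
            raise ValueError(f"unknown augmentation ops: {sorted(unknown)}")


def _augment_one(img: np.ndarray, cfg: AugmentConfig, rng: np.random.Generator) -> np.ndarray:
    out = img.copy()
    op = cfg.ops[rng.integers(len(cfg.ops))]
    if op == "rotate":
        out = np.rot90(out, k=int(rng.integers(1, 4)), axes=(0, 1))
        if cfg.max_small_angle > 0:
            angle = rng.uniform(-cfg.max_small_angle, cfg.max_small_angle)
            out = ndimage.rotate(out, angle, axes=(1, 0), reshape=False, mode="nearest", order=1)
    elif op == "flip":
        out = np.flip(out, axis=int(rng.integers(2)))
    elif op == "intensity":
        out = out * (1.0 + rng.uniform(-cfg.intensity_range, cfg.intensity_range))
    else:  # brightness
        out = out + rng.uniform(-cfg.brightness_range, cfg.brightness_range)
    return np.clip(np.ascontiguousarray(out), 0.0, 1.0)


def augment_to_count(
    images: list[np.ndarray],
    labels,
    targets: dict,
    cfg: AugmentConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Grow each class to its target count with seeded random augmentation.

    Originals are retained unchanged; each new image is a randomly chosen
    operation applied to a randomly chosen original of the same class.
    """
    cfg = cfg or AugmentConfig()
    labels = np.asarray(labels)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out_images: list[np.ndarray] = list(images)
    out_labels: list = list(labels)
    for cls, target in targets.items():
        idx = np.flatnonzero(labels == cls)
        if idx.size == 0:
            raise ValueError(f"class {cls!r} has no original images")
        if target < idx.size:
            raise ValueError(f"target {target} below original count {idx.size} for class {cls!r}")
        for _ in range(target - idx.size):
            src = images[int(rng.choice(idx))]
            out_images.append(_augment_one(src, cfg, rng))
            out_labels.append(cls)
    return out_images, np.asarray(out_labels)
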