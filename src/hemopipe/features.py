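"""Feature extraction interface, fusion, and feature-matrix I/O.

Transfer-learning feature extraction treats a pretrained CNN as a fixed
map from an image to the activations of a late pooling layer.  The two
extractors the pipeline is built around are InceptionV3 (2,048-dim
"avg_pool" activations) and DenseNet201 (1,920-dim global-average-pool
activations); their horizontal concatenation yields the 3,968-dim fused
vector the selection stage consumes.

Real CNN inference lives behind the optional ``cnn`` extra (torch /
torchvision); the core package ships a deterministic mock extractor that
is content-sensitive (a fixed random projection of a downsampled copy of
the image) so every downstream stage can be exercised without model
weights or downloads.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ExtractorSpec",
    "DEFAULT_EXTRACTORS",
    "FeatureMatrix",
    "mock_extract",
    "fuse",
    "save_features",
    "load_features",
]


@dataclass(frozen=True)
class ExtractorSpec:
    """Identity and output shape of one feature extractor."""

    name: str
    output_dim: int
    layer: str = ""

    def __post_init__(self) -> None:
        if self.output_dim < 1:
            raise ValueError("output_dim must be positive")


#: Registry order fixes the fusion order: InceptionV3 block first.
DEFAULT_EXTRACTORS: tuple[ExtractorSpec, ...] = (
    ExtractorSpec("inception_v3", 2048, "avg_pool"),
    ExtractorSpec("densenet201", 1920, "global_average_pool"),
)


@dataclass
class FeatureMatrix:
    """n_t samples x d_max fused features with labels and per-column origin.

    ``origins`` records, for every column, the extractor it came from and
    its index within that extractor's block, so a selection mask can be
    traced back to concrete network activations.
    """

    values: np.ndarray
    labels: np.ndarray
    origins: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ValueError("feature values must be a 2-D matrix")
        if self.values.shape[0] != self.labels.shape[0]:
            raise ValueError(
                f"{self.values.shape[0]} feature rows but {self.labels.shape[0]} labels"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite entries")
        if not self.origins:
            self.origins = [("feature", j) for j in range(self.values.shape[1])]
        if len(self.origins) != self.values.shape[1]:
            raise ValueError("one origin tag required per column")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def _image_digest(image: np.ndarray) -> int:
    h = hashlib.blake2b(digest_size=8)
    arr = np.ascontiguousarray(np.asarray(image, dtype=np.float64))
    h.update(str(arr.shape).encode())
    h.update(arr.tobytes())
    return int.from_bytes(h.digest(), "little")


def _thumbnail(image: np.ndarray, side: int = 8) -> np.ndarray:
    """Grey-scale block-mean downsample to a side x side patch."""
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=-1)
    m, n = img.shape
    rows = np.linspace(0, m, side + 1).astype(int)
    cols = np.linspace(0, n, side + 1).astype(int)
    out = np.empty((side, side))
    for i in range(side):
        for j in range(side):
            block = img[rows[i] : max(rows[i + 1], rows[i] + 1),
                        cols[j] : max(cols[j + 1], cols[j] + 1)]
            out[i, j] = block.mean()
    return out


def mock_extract(image: np.ndarray, spec: ExtractorSpec, seed: int = 0) -> np.ndarray:
    """Deterministic stand-in for CNN activations.

    Projects an 8x8 thumbnail of the image through a random matrix fixed by
    (extractor name, seed), then adds a small perturbation keyed to a hash
    of the exact pixel content.  Identical images give identical vectors;
    any pixel difference changes the output.
    """
    spec_key = int.from_bytes(hashlib.blake2b(
        f"{spec.name}:{seed}".encode(), digest_size=8).digest(), "little")
    proj_rng = np.random.default_rng(spec_key)
    w = proj_rng.standard_normal((spec.output_dim, 64))

    thumb = _thumbnail(image).ravel()
    content_rng = np.random.default_rng(_image_digest(image) ^ spec_key)
    return w @ thumb + 0.01 * content_rng.standard_normal(spec.output_dim)


def fuse(vectors: list[np.ndarray] | tuple[np.ndarray, ...]) -> np.ndarray:
    """Horizontal concatenation of per-extractor feature vectors, in order."""
    if len(vectors) == 0:
        raise ValueError("need at least one feature vector to fuse")
    return np.concatenate([np.asarray(v, dtype=float).ravel() for v in vectors])


def fuse_origins(specs: list[ExtractorSpec] | tuple[ExtractorSpec, ...]) -> list[tuple[str, int]]:
    """Column origin tags for a fused matrix built from ``specs`` in order."""
    tags: list[tuple[str, int]] = []
    for spec in specs:
        tags.extend((spec.name, j) for j in range(spec.output_dim))
    return tags


def save_features(fm: FeatureMatrix, prefix: str | Path, fmt: str = "tsv") -> tuple[Path, ...]:
    """Write a feature matrix to disk.

    ``fmt="tsv"``: ``<prefix>.features.tsv`` holds one header row of
    ``origin:index`` tags and one row per sample; ``<prefix>.labels.tsv``
    is the label sidecar.  ``fmt="npz"``: a single binary array container.
    """
    prefix = Path(prefix)
    if fmt == "npz":
        path = prefix.with_suffix(prefix.suffix + ".features.npz")
        np.savez(path, values=fm.values, labels=fm.labels,
                 origin_names=np.array([n for n, _ in fm.origins]),
                 origin_idx=np.array([i for _, i in fm.origins]))
        return (path,)
    if fmt != "tsv":
        raise ValueError(f"unknown feature format {fmt!r}")
    fpath = prefix.with_suffix(prefix.suffix + ".features.tsv")
    lpath = prefix.with_suffix(prefix.suffix + ".labels.tsv")
    header = "\t".join(f"{name}:{idx}" for name, idx in fm.origins)
    np.savetxt(fpath, fm.values, delimiter="\t", header=header, comments="#", fmt="%.17g")
    np.savetxt(lpath, fm.labels.astype(str), fmt="%s")
    return fpath, lpath


def load_features(prefix: str | Path, fmt: str = "tsv") -> FeatureMatrix:
    """Read a feature matrix written by :func:`save_features`."""
    prefix = Path(prefix)
    if fmt == "npz":
        with np.load(prefix.with_suffix(prefix.suffix + ".features.npz")) as z:
            origins = list(zip((str(n) for n in z["origin_names"]),
                               (int(i) for i in z["origin_idx"])))
            return FeatureMatrix(values=z["values"], labels=z["labels"], origins=origins)
    if fmt != "tsv":
        raise ValueError(f"unknown feature format {fmt!r}")
    fpath = prefix.with_suffix(prefix.suffix + ".features.tsv")
    lpath = prefix.with_suffix(prefix.suffix + ".labels.tsv")
    with open(fpath) as fh:
        header = fh.readline()
    if not header.startswith("#"):
        raise ValueError(f"{fpath}: missing origin-tag header row")
    origins = []
    for tok in header.lstrip("#").strip().split("\t"):
        if ":" not in tok:
            raise ValueError(f"{fpath}: malformed origin tag {tok!r}")
        name, idx = tok.rsplit(":", 1)
        origins.append((name, int(idx)))
    values = np.loadtxt(fpath, delimiter="\t", ndmin=2)
    labels = np.loadtxt(lpath, dtype=str, ndmin=1)
    if values.shape[1] != len(origins):
        raise ValueError(
            f"{fpath}: header lists {len(origins)} columns but data has {values.shape[1]}"
        )
    try:
        labels = labels.astype(int)
    except ValueError:
        pass
    return FeatureMatrix(values=values, labels=labels, origins=origins)
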