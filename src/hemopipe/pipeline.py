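"""End-to-end orchestration: enhance -> extract -> fuse -> select -> evaluate.

A run is driven by a :class:`PipelineConfig` (loadable from a flat YAML
file), executes only the enabled stages in pipeline order, writes every
stage artifact under a run directory, and finishes with a deterministic
``manifest.json`` echoing the configuration, package version, seeds and
the content hashes of all artifacts — so two runs with the same config
produce byte-identical manifests and any run can be reproduced from its
manifest alone.

The feature stage has two entry points: ``simulate_features`` (planted
feature matrix, the self-contained test path) or ``extract`` + ``fuse``
on images (mock extractor by default).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .de import enhance_rgb
from .enhancement import EnhancementConfig
from .features import DEFAULT_EXTRACTORS, FeatureMatrix, fuse, fuse_origins, load_features, mock_extract, save_features
from .gwo import FitnessConfig, GAConfig, GWOConfig, ga_select, gwo_select, save_history, save_mask
from .image_io import read_image, write_image
from .metrics import stratified_split, train_eval
from .synthetic import CellImageSpec, PlantedFeatureSpec, make_cell_image, make_feature_dataset

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("hemopipe")


@dataclass
class PipelineConfig:
    """Stage toggles and per-stage parameters of one pipeline run."""

    seed: int = 0
    out_dir: str = "hemopipe_run"

    # stage toggles
    simulate_images: bool = False
    enhance: bool = False
    extract: bool = False
    simulate_features: bool = True
    select: bool = True
    evaluate: bool = True

    # inputs for non-simulated paths
    image_paths: list[str] = field(default_factory=list)
    features_path: str | None = None

    # stage parameters
    n_images: int = 4
    image: dict = field(default_factory=dict)  # CellImageSpec overrides
    enhancement: dict = field(default_factory=dict)  # EnhancementConfig overrides
    extractors: list[str] = field(default_factory=lambda: [s.name for s in DEFAULT_EXTRACTORS])
    planted: dict = field(default_factory=dict)  # PlantedFeatureSpec overrides
    selector: str = "gwo"  # 'gwo' or 'ga'
    gwo: dict = field(default_factory=dict)  # n_pop / t_max
    fitness: dict = field(default_factory=dict)  # FitnessConfig overrides
    classifier: str = "knn-cosine"
    split_fraction: float = 0.7

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute the enabled stages in order; return the run directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    summaries: dict[str, dict] = {}

    # --- images ---------------------------------------------------------
    images: list[np.ndarray] = []
    if cfg.simulate_images:
        for i in range(cfg.n_images):
            spec = CellImageSpec(**{**cfg.image, "seed": cfg.seed + i})
            img = make_cell_image(spec)
            path = out / f"sim_{i:03d}.png"
            write_image(path, img)
            images.append(img)
        summaries["simulate_images"] = {"n": cfg.n_images, "seed": cfg.seed}
        log.info("simulated %d cell images", cfg.n_images)
    elif cfg.image_paths:
        images = [read_image(p) for p in cfg.image_paths]

    if cfg.enhance:
        if not images:
            raise RuntimeError("stage 'enhance' needs images from 'simulate_images' or image_paths")
        enh_cfg = EnhancementConfig(**cfg.enhancement)
        enhanced = []
        best_f = []
        for i, img in enumerate(images):
            rgb, params, history = enhance_rgb(img, enh_cfg, seed=cfg.seed + i)
            write_image(out / f"enhanced_{i:03d}.png", rgb)
            enhanced.append(rgb)
            best_f.append(history[-1])
        images = enhanced
        summaries["enhance"] = {
            "n": len(images),
            "best_objective": [round(f, 6) for f in best_f],
            "window": enh_cfg.window,
        }
        log.info("enhanced %d images; best F per image: %s", len(images), best_f)

    # --- features -------------------------------------------------------
    features: FeatureMatrix | None = None
    truth = None
    if cfg.extract:
        if not images:
            raise RuntimeError("stage 'extract' needs images from an upstream stage")
        specs = [s for s in DEFAULT_EXTRACTORS if s.name in cfg.extractors]
        rows = [fuse([mock_extract(img, s, seed=cfg.seed) for s in specs]) for img in images]
        labels = np.zeros(len(rows), dtype=int)  # unlabeled image path
        features = FeatureMatrix(np.array(rows), labels, fuse_origins(specs))
        save_features(features, out / "features")
        summaries["extract"] = {"extractors": [s.name for s in specs],
                                "fused_dim": features.n_features}
        log.info("extracted fused features of dimension %d", features.n_features)
    elif cfg.simulate_features:
        spec = PlantedFeatureSpec(**{**cfg.planted, "seed": cfg.seed})
        features, truth = make_feature_dataset(spec)
        save_features(features, out / "features")
        np.savetxt(out / "planted_truth.txt", truth, fmt="%d")
        summaries["simulate_features"] = {"spec": asdict(spec)}
        log.info("simulated planted features: %d x %d", features.n_samples, features.n_features)
    elif cfg.features_path:
        features = load_features(cfg.features_path)

    # --- selection ------------------------------------------------------
    mask = None
    if cfg.select:
        if features is None:
            raise RuntimeError("stage 'select' needs a feature matrix from an upstream stage")
        fit_cfg = FitnessConfig(**cfg.fitness)
        if cfg.selector == "gwo":
            mask, history = gwo_select(
                features, GWOConfig(**cfg.gwo, fitness=fit_cfg), seed=cfg.seed)
        elif cfg.selector == "ga":
            mask, history = ga_select(
                features, GAConfig(**cfg.gwo, fitness=fit_cfg), seed=cfg.seed)
        else:
            raise ValueError(f"unknown selector {cfg.selector!r}")
        save_mask(mask, out / "mask.txt", gamma=history.f_alpha[-1])
        save_history(history, out / "history.tsv")
        summaries["select"] = {
            "algorithm": cfg.selector,
            "final_gamma": history.f_alpha[-1],
            "q_s": int(mask.sum()),
            "q_t": int(mask.size),
        }
        log.info("selection: Gamma=%.4f, q_s=%d/%d", history.f_alpha[-1],
                 int(mask.sum()), mask.size)

    # --- evaluation -----------------------------------------------------
    if cfg.evaluate:
        if features is None:
            raise RuntimeError("stage 'evaluate' needs a feature matrix from an upstream stage")
        split = stratified_split(features.labels, cfg.split_fraction, seed=rng)
        report = train_eval(features.values, features.labels, split,
                            spec=cfg.classifier, seed=cfg.seed, mask=mask)
        report.save(out / "report.json")
        summaries["evaluate"] = {
            "classifier": cfg.classifier,
            "accuracy": report.overall_accuracy,
            "macro_f1": report.macro_f1,
            "q_s": report.selected_features,
            "q_t": report.total_features,
        }
        log.info("evaluation: accuracy=%.4f macro-F1=%.4f", report.overall_accuracy,
                 report.macro_f1)

    # --- manifest -------------------------------------------------------
    artifacts = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    manifest = {
        "hemopipe_version": __version__,
        "config": asdict(cfg),
        "stages": summaries,
        "artifacts": {name: _sha256(out / name) for name in artifacts},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
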