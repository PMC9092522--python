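"""Run configuration: a single YAML tree covering every stage.

All published protocol settings appear here as documented defaults:
512 time bins over 12.5 ns, 240 ps FWHM Gaussian IRF, 3x3 spatial
binning, nucleus detection with threshold 0.3 / smoothing 1 px / size
filter 15-500 px, 15-fold cross-validation with 100 repeats, UMAP with
20 neighbors and min_dist 0.3.  Unknown keys are rejected; validation
errors are aggregated into one readable report.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .classify import ForestConfig
from .core import IRFModel, TimeAxis
from .decayfit import FitConfig
from .features import NeighborConfig
from .segmentation import SegConfig
from .synthetic import SceneSpec
from .trajectory import EmbeddingConfig

__all__ = ["RunConfig", "ConfigError", "validate_config", "load_config"]

STAGES = ("simulate", "fit", "segment", "features", "classify", "trajectory")

DEFAULTS: dict = {
    "seed": 0,
    "outdir": "flimcyte_run",
    "log_level": "INFO",
    "stages": list(STAGES),
    "axis": {"n_bins": 512, "bin_width": 12.5 / 512, "origin": 0.0},
    "irf": {"shape": "gaussian", "fwhm": 0.240, "t0": 0.6},
    "scene": {
        "field_shape": [192, 192],
        "ufeature_radius": 90.0,
        "cells_per_class": {"EPC": 10, "IM": 10, "iPSC": 10},
        "cell_radius_range": [7.0, 10.0],
        "nucleus_fraction": 0.45,
        "cytoplasm_photons": 1000.0,
        "nucleus_dimming": 0.15,
        "ambient_per_bin": 0.1,
        "noise": True,
    },
    "fit": {
        "model": "biexponential",
        "objective": "wls",
        "bin_radius": 1,
        "peak_threshold": 50.0,
    },
    "segmentation": {
        "smooth_sigma": 1.0,
        "prob_threshold": 0.3,
        "size_min": 15,
        "size_max": 500,
        "foreground_threshold": 120.0,
        "propagation_reg": 0.05,
        "edge_margin": 3,
    },
    "features": {"neighbor_distance": 5.0, "redox_mode": "ratio_of_means"},
    "classify": {
        "n_folds": 15,
        "n_repeats": 100,
        "method": "random_forest",
        "n_trees": 100,
        "max_features": "sqrt",
    },
    "trajectory": {
        "n_neighbors": 20,
        "min_dist": 0.3,
        "metric": "weighted_jaccard",
        "n_components": 2,
        "cluster_method": "leiden",
        "k_or_resolution": 1.0,
        "disconnect_factor": 3.0,
        "moran_k": 10,
    },
}


class ConfigError(ValueError):
    """Aggregated configuration errors."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(errors))


@dataclass
class RunConfig:
    """Validated run configuration with per-module config objects."""

    seed: int
    outdir: Path
    log_level: str
    stages: list[str]
    axis: TimeAxis
    irf: IRFModel
    scene: SceneSpec
    fit: FitConfig
    segmentation: SegConfig
    neighbor: NeighborConfig
    redox_mode: str
    n_folds: int
    n_repeats: int
    classify_method: str
    forest: ForestConfig
    embedding: EmbeddingConfig
    cluster_method: str
    k_or_resolution: float
    disconnect_factor: float
    moran_k: int
    raw: dict = field(default_factory=dict, repr=False)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        return (self.seed * 1000003 + STAGES.index(stage) + 1) % (2**31)


def _merge(defaults: dict, user: dict, errors: list[str], path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, val in (user or {}).items():
        where = f"{path}.{key}" if path else key
        if key not in defaults:
            errors.append(f"unknown key {where!r}")
            continue
        if isinstance(defaults[key], dict) and key != "cells_per_class":
            if not isinstance(val, dict):
                errors.append(f"{where!r} must be a mapping")
            else:
                out[key] = _merge(defaults[key], val, errors, where)
        else:
            out[key] = val
    return out


def validate_config(source) -> RunConfig:
    """Build a RunConfig from a YAML file path, YAML text, or dict.

    Fills defaults, rejects unknown keys, checks every invariant, and
    raises :class:`ConfigError` listing all problems at once.  An empty
    file yields the full default configuration.
    """
    if isinstance(source, (str, Path)) and Path(source).exists():
        user = yaml.safe_load(Path(source).read_text()) or {}
    elif isinstance(source, dict):
        user = source
    elif isinstance(source, str):
        user = yaml.safe_load(source) or {}
    else:
        raise ConfigError([f"unreadable config source: {source!r}"])
    if not isinstance(user, dict):
        raise ConfigError(["top level of the config must be a mapping"])

    errors: list[str] = []
    cfg = _merge(DEFAULTS, user, errors)

    def build(name, fn):
        try:
            return fn()
        except (TypeError, ValueError) as exc:
            errors.append(f"{name}: {exc}")
            return None

    axis = build("axis", lambda: TimeAxis(**cfg["axis"]))
    irf = build("irf", lambda: IRFModel(**cfg["irf"]))
    sc = cfg["scene"]
    scene = build("scene", lambda: SceneSpec(
        field_shape=tuple(sc["field_shape"]),
        ufeature_radius=sc["ufeature_radius"],
        cells_per_class=dict(sc["cells_per_class"]),
        cell_radius_range=tuple(sc["cell_radius_range"]),
        nucleus_fraction=sc["nucleus_fraction"],
        cytoplasm_photons=sc["cytoplasm_photons"],
        nucleus_dimming=sc["nucleus_dimming"],
        ambient_per_bin=sc["ambient_per_bin"],
        noise=sc["noise"],
        axis=axis or TimeAxis(), irf=irf or IRFModel(),
        seed=cfg["seed"]))
    fit = build("fit", lambda: FitConfig(**cfg["fit"]))
    seg = cfg["segmentation"]
    if not (isinstance(seg.get("size_min"), (int, float))
            and isinstance(seg.get("size_max"), (int, float))
            and 0 < seg["size_min"] < seg["size_max"]):
        errors.append("segmentation: require 0 < size_min < size_max "
                      f"(got size_min={seg.get('size_min')}, "
                      f"size_max={seg.get('size_max')})")
        segcfg = None
    else:
        segcfg = build("segmentation", lambda: SegConfig(**seg))
    feat = cfg["features"]
    neighbor = build("features", lambda: NeighborConfig(
        distance=feat["neighbor_distance"]))
    if feat["redox_mode"] not in ("ratio_of_means", "mean_of_ratios"):
        errors.append(f"features.redox_mode: unknown mode {feat['redox_mode']!r}")
    cl = cfg["classify"]
    if cl["n_folds"] < 2:
        errors.append("classify.n_folds: cross-validation requires n_folds >= 2")
    if cl["n_repeats"] < 1:
        errors.append("classify.n_repeats must be >= 1")
    forest = build("classify", lambda: ForestConfig(
        n_trees=cl["n_trees"], max_features=cl["max_features"]))
    tr = cfg["trajectory"]
    embedding = build("trajectory", lambda: EmbeddingConfig(
        n_neighbors=tr["n_neighbors"], min_dist=tr["min_dist"],
        metric=tr["metric"], n_components=tr["n_components"],
        seed=cfg["seed"]))
    unknown_stages = [s for s in cfg["stages"] if s not in STAGES]
    if unknown_stages:
        errors.append(f"unknown stages: {unknown_stages}")

    if errors:
        raise ConfigError(errors)
    return RunConfig(
        seed=int(cfg["seed"]), outdir=Path(cfg["outdir"]),
        log_level=str(cfg["log_level"]), stages=list(cfg["stages"]),
        axis=axis, irf=irf, scene=scene, fit=fit, segmentation=segcfg,
        neighbor=neighbor, redox_mode=feat["redox_mode"],
        n_folds=int(cl["n_folds"]), n_repeats=int(cl["n_repeats"]),
        classify_method=cl["method"], forest=forest, embedding=embedding,
        cluster_method=tr["cluster_method"],
        k_or_resolution=float(tr["k_or_resolution"]),
        disconnect_factor=float(tr["disconnect_factor"]),
        moran_k=int(tr["moran_k"]), raw=cfg)


def load_config(path=None, **overrides) -> RunConfig:
    """Load (or default) a config, with top-level keyword overrides."""
    base = {} if path is None else path
    cfg = validate_config(base)
    if overrides:
        merged = copy.deepcopy(cfg.raw)
        for k, v in overrides.items():
            if v is not None:
                merged[k] = v
        cfg = validate_config(merged)
    return cfg
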