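"""End-to-end orchestration: simulate -> fit -> segment -> features ->
classify -> trajectory, with on-disk artifacts between stages.

Each stage reads the previous stage's files, so a run can resume from
any completed point.  A manifest records the configuration snapshot,
package version, and a SHA-256 checksum of every file written; rerunning
with the same configuration and seed reproduces identical checksums for
the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, load_config
from .decayfit import fit_cube, integrate_intensity
from .features import extract_cell_features
from .io import (read_cube_h5, read_lifetime_image, read_masks, write_masks,
                 write_lifetime_image, write_scene_h5, _jsonable)
from .segmentation import foreground_mask, segment_scene
from .synthetic import generate_scene
from .trajectory import infer_trajectory

__all__ = ["run_pipeline", "StageError"]

log = logging.getLogger("flimcyte")


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _outputs(cfg: RunConfig, stage: str) -> list[Path]:
    out = cfg.outdir
    return {
        "simulate": [out / "scene.h5", out / "truth_nuclei.tif",
                     out / "truth_cells.tif", out / "truth_cytoplasm.tif",
                     out / "truth_table.csv"],
        "fit": [out / "lifetime_nadph.tif", out / "lifetime_fad.tif"],
        "segment": [out / "nuclei.tif", out / "cells.tif",
                    out / "cytoplasm.tif", out / "objects.csv"],
        "features": [out / "cells_features.csv"],
        "classify": [out / "classifier_report.json", out / "roc_curves.csv"],
        "trajectory": [out / "cells_trajectory.csv", out / "graph_edges.txt",
                       out / "morans_ranking.csv"],
    }[stage]


def _stage_simulate(cfg: RunConfig) -> None:
    scene = generate_scene(cfg.scene)
    out = cfg.outdir
    write_scene_h5(out / "scene.h5", scene.cubes, cfg.axis)
    write_masks(out, scene.truth_masks, prefix="truth_")
    scene.truth_table.to_csv(out / "truth_table.csv", index=False)
    log.info("simulate: %d cells on %s field",
             len(scene.truth_table), cfg.scene.field_shape)


def _stage_fit(cfg: RunConfig) -> None:
    out = cfg.outdir
    for ch in ("nadph", "fad"):
        cube, axis = read_cube_h5(out / "scene.h5", ch)
        # restrict fitting to cell-bearing pixels; background pixels are
        # below the photon threshold anyway
        inten = integrate_intensity(cube)
        fg = foreground_mask(inten, cfg.segmentation)
        img = fit_cube(cube, axis, cfg.irf, cfg.fit, pixels=fg)
        write_lifetime_image(out / f"lifetime_{ch}.tif", img,
                             config={"fit": cfg.fit, "channel": ch})
        log.info("fit[%s]: %d valid pixels", ch, int(img.valid.sum()))


def _stage_segment(cfg: RunConfig) -> None:
    out = cfg.outdir
    img = read_lifetime_image(out / "lifetime_nadph.tif")
    masks = segment_scene(img.intensity, cfg.segmentation)
    write_masks(out, masks)
    from skimage import measure

    rows = [{"label": r.label, "centroid_row": r.centroid[0],
             "centroid_col": r.centroid[1], "area": r.area}
            for r in measure.regionprops(masks.cells)]
    pd.DataFrame(rows, columns=["label", "centroid_row", "centroid_col",
                                "area"]).to_csv(out / "objects.csv",
                                                index=False)
    log.info("segment: %d cells", len(rows))


def _match_truth_labels(cells: np.ndarray, truth_cells: np.ndarray,
                        truth_table: pd.DataFrame) -> dict[int, str]:
    """Assign each segmented cell the class of the truth cell it
    overlaps most (majority pixel vote); 'unknown' without overlap."""
    class_of = dict(zip(truth_table["label"], truth_table["cell_class"]))
    out = {}
    for k in np.unique(cells[cells > 0]):
        overlap = truth_cells[cells == k]
        overlap = overlap[overlap > 0]
        if overlap.size == 0:
            out[int(k)] = "unknown"
        else:
            vals, counts = np.unique(overlap, return_counts=True)
            out[int(k)] = class_of.get(int(vals[np.argmax(counts)]), "unknown")
    return out


def _stage_features(cfg: RunConfig) -> None:
    out = cfg.outdir
    nadph = read_lifetime_image(out / "lifetime_nadph.tif")
    fad = read_lifetime_image(out / "lifetime_fad.tif")
    masks = read_masks(out)
    df = extract_cell_features(nadph, fad, masks, cfg.neighbor,
                               redox_mode=cfg.redox_mode)
    truth_path = out / "truth_cells.tif"
    if truth_path.exists():
        import tifffile

        truth_cells = tifffile.imread(truth_path)
        truth_table = pd.read_csv(out / "truth_table.csv")
        mapping = _match_truth_labels(masks.cells, truth_cells, truth_table)
        df["cell_class"] = df["cell_id"].map(mapping).fillna("unknown")
    else:
        df["cell_class"] = "unknown"
    df.to_csv(out / "cells_features.csv", index=False)
    log.info("features: %d cells, %d flagged",
             len(df), int(df["flagged"].sum()))


def _stage_classify(cfg: RunConfig) -> None:
    from .classify import make_cv_plan, train_forest

    out = cfg.outdir
    df = pd.read_csv(out / "cells_features.csv")
    from .features import METABOLIC_COLUMNS, NUCLEAR_COLUMNS

    feat_cols = [c for c in METABOLIC_COLUMNS + NUCLEAR_COLUMNS
                 if c in df.columns]
    df = df[df["cell_class"] != "unknown"].dropna(subset=feat_cols)
    df = df.reset_index(drop=True)
    y = df["cell_class"].to_numpy()
    n_folds = min(cfg.n_folds, len(df))
    cv = make_cv_plan(len(df), n_folds=n_folds, n_repeats=cfg.n_repeats,
                      seed=cfg.stage_seed("classify"), labels=y)
    report = train_forest(df, cv=cv, forest_cfg=cfg.forest,
                          method=cfg.classify_method)
    (out / "classifier_report.json").write_text(
        json.dumps(_jsonable(report.to_dict()), indent=2))
    rows = []
    for cls, curve in report.roc.items():
        for fp, tp in zip(curve["fpr"], curve["tpr"]):
            rows.append({"class": cls, "fpr": fp, "tpr": tp})
    pd.DataFrame(rows).to_csv(out / "roc_curves.csv", index=False)
    log.info("classify: accuracy %.3f over %d cells",
             report.accuracy, report.n_cells)


def _stage_trajectory(cfg: RunConfig) -> None:
    out = cfg.outdir
    df = pd.read_csv(out / "cells_features.csv")
    feat_cols = [c for c in df.columns
                 if c not in ("cell_id", "cell_class", "flagged",
                              "centroid_row", "centroid_col")]
    keep = df[feat_cols].notna().all(axis=1)
    df = df[keep].reset_index(drop=True)
    n_neighbors = min(cfg.embedding.n_neighbors, max(len(df) - 1, 2))
    emb_cfg = cfg.embedding if n_neighbors == cfg.embedding.n_neighbors else \
        type(cfg.embedding)(n_neighbors=n_neighbors,
                            min_dist=cfg.embedding.min_dist,
                            metric=cfg.embedding.metric,
                            n_components=cfg.embedding.n_components,
                            seed=cfg.embedding.seed)
    traj = infer_trajectory(df, emb_cfg, cluster_method=cfg.cluster_method,
                            k_or_resolution=cfg.k_or_resolution,
                            disconnect_factor=cfg.disconnect_factor,
                            moran_k=min(cfg.moran_k, len(df) - 1))
    df["umap_1"] = traj.embedding[:, 0]
    df["umap_2"] = traj.embedding[:, 1]
    df["cluster_id"] = traj.cluster_id
    df["component"] = traj.components
    df["pseudotime"] = traj.pseudotime
    df.to_csv(out / "cells_trajectory.csv", index=False)
    with open(out / "graph_edges.txt", "w") as f:
        for u, v, d in traj.graph.edges(data=True):
            f.write(f"{u}\t{v}\t{d['length']:.6f}\n")
    traj.morans.to_csv(out / "morans_ranking.csv", index=False)
    log.info("trajectory: %d clusters, %d branch points, root %d",
             traj.cluster_id.max() + 1, len(traj.branch_points),
             traj.root_node)


_STAGE_FN = {
    "simulate": _stage_simulate,
    "fit": _stage_fit,
    "segment": _stage_segment,
    "features": _stage_features,
    "classify": _stage_classify,
    "trajectory": _stage_trajectory,
}


def run_pipeline(config: RunConfig | dict | str | None = None,
                 resume: bool = False) -> dict:
    """Execute the configured stages in order and write the manifest.

    With ``resume=True``, a stage whose outputs already exist is
    skipped.  On stage failure a :class:`StageError` names the stage;
    outputs of completed stages remain on disk.  Returns the manifest.
    """
    cfg = config if isinstance(config, RunConfig) else load_config(config)
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), 20))
    manifest: dict = {
        "version": __version__,
        "config": _jsonable(cfg.raw),
        "stages": {},
    }
    for stage in _STAGE_FN:
        if stage not in cfg.stages:
            continue
        outputs = _outputs(cfg, stage)
        if resume and all(p.exists() for p in outputs):
            log.info("%s: outputs present, resumed past", stage)
            manifest["stages"][stage] = {
                "skipped": True,
                "outputs": {p.name: _sha256(p) for p in outputs}}
            continue
        t0 = time.time()
        try:
            _STAGE_FN[stage](cfg)
        except Exception as exc:
            manifest["stages"][stage] = {"error": str(exc)}
            (cfg.outdir / "manifest.json").write_text(
                json.dumps(manifest, indent=2))
            raise StageError(stage, exc) from exc
        manifest["stages"][stage] = {
            "seconds": round(time.time() - t0, 3),
            "outputs": {p.name: _sha256(p) for p in outputs if p.exists()},
        }
    (cfg.outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
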