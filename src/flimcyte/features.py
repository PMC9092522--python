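"""Single-cell metabolic and nuclear feature extraction.

Eleven metabolic parameters are measured over each cell's cytoplasm
mask (intensity, alpha_1, tau_1, tau_2, tau_m for each of the NAD(P)H
and FAD channels, plus the optical redox ratio
I_NADPH / (I_NADPH + I_FAD)), and eight nuclear morphometry parameters
over each nucleus (area, perimeter, mean radius, nuclear shape index,
solidity, extent, number of neighbors, distance to closest neighbor).

Conventions recorded in ``FEATURE_METADATA``:

* NSI = perimeter / (2 * sqrt(pi * area)) — 1 for a perfect disc,
  larger for any other shape (isoperimetric inequality).
* mean radius = mean distance-to-boundary over nucleus pixels.
* perimeter = isotropically corrected boundary-step length.
* redox ratio per cell = ratio of cytoplasm-mean intensities (robust to
  photon noise); a per-pixel-ratio variant is exposed as an option.
* z-scores use the population (N) standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.cluster import hierarchy
from scipy.spatial.distance import cdist

from .core import LabelMasks, LifetimeImage

__all__ = [
    "METABOLIC_COLUMNS",
    "NUCLEAR_COLUMNS",
    "NeighborConfig",
    "redox_ratio",
    "mean_lifetime",
    "extract_cell_features",
    "zscore_table",
    "hierarchical_order",
]

METABOLIC_COLUMNS = (
    "I_nadph", "nadph_alpha1", "nadph_tau1", "nadph_tau2", "nadph_tau_m",
    "I_fad", "fad_alpha1", "fad_tau1", "fad_tau2", "fad_tau_m",
    "redox_ratio",
)
NUCLEAR_COLUMNS = (
    "area", "perimeter", "mean_radius", "nsi", "solidity", "extent",
    "n_neighbors", "dist_first_neighbor",
)

FEATURE_METADATA = {
    "nsi": "perimeter / (2*sqrt(pi*area)); 1.0 for a disc",
    "mean_radius": "mean distance-to-boundary over object pixels",
    "perimeter": "isotropically corrected boundary-step length (Crofton)",
    "redox_ratio": "ratio of cytoplasm-mean intensities",
}


@dataclass(frozen=True)
class NeighborConfig:
    """Neighborhood definition for nuclear context features: another
    nucleus is a neighbor when its boundary comes within ``distance``
    pixels of this nucleus's boundary."""

    distance: float = 5.0


def redox_ratio(i_nadph, i_fad):
    """Optical redox ratio I_NADPH / (I_NADPH + I_FAD), in [0, 1].

    NaN (flagged undefined) when both intensities are zero; raises on
    negative input.
    """
    i_nadph = np.asarray(i_nadph, dtype=float)
    i_fad = np.asarray(i_fad, dtype=float)
    if np.any(i_nadph < 0) or np.any(i_fad < 0):
        raise ValueError("intensities must be nonnegative")
    total = i_nadph + i_fad
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, i_nadph / np.where(total > 0, total, 1.0),
                       np.nan)
    return float(out) if out.ndim == 0 else out


def mean_lifetime(alpha1, tau1, tau2):
    """Amplitude-weighted mean lifetime tau_m = a1*tau1 + (1-a1)*tau2."""
    alpha1 = np.asarray(alpha1, dtype=float)
    if np.any((alpha1 < 0) | (alpha1 > 1)):
        raise ValueError("alpha1 must be in [0, 1]")
    out = alpha1 * np.asarray(tau1, float) + (1.0 - alpha1) * np.asarray(tau2, float)
    return float(out) if out.ndim == 0 else out


def _nuclear_morphometry(nuclei: np.ndarray) -> pd.DataFrame:
    from skimage import measure

    rows = []
    for region in measure.regionprops(nuclei):
        mask = region.image
        # distance to the outside of the object, per object pixel
        dist = ndimage.distance_transform_edt(np.pad(mask, 1))[1:-1, 1:-1]
        area = float(region.area)
        perim = float(region.perimeter_crofton)
        rows.append({
            "label": region.label,
            "area": area,
            "perimeter": perim,
            "mean_radius": float(dist[mask].mean()),
            "nsi": perim / (2.0 * np.sqrt(np.pi * area)),
            "solidity": float(region.solidity),
            "extent": float(region.extent),
            "centroid_row": region.centroid[0],
            "centroid_col": region.centroid[1],
        })
    return pd.DataFrame(rows)


def _neighbor_features(nuclei: np.ndarray, centroids: np.ndarray,
                       labels: np.ndarray, distance: float) -> pd.DataFrame:
    n = len(labels)
    n_neighbors = np.zeros(n)
    first = np.full(n, np.nan)
    if n > 1:
        d = cdist(centroids, centroids)
        np.fill_diagonal(d, np.inf)
        first = d.min(axis=1)
        for i, lab in enumerate(labels):
            # boundary-to-boundary proximity via the distance transform
            # to this nucleus
            dt = ndimage.distance_transform_edt(nuclei != lab)
            others = (nuclei > 0) & (nuclei != lab)
            near = others & (dt <= distance)
            n_neighbors[i] = len(np.unique(nuclei[near]))
    return pd.DataFrame({"label": labels, "n_neighbors": n_neighbors,
                         "dist_first_neighbor": first})


def extract_cell_features(
    lifetime_nadph: LifetimeImage,
    lifetime_fad: LifetimeImage,
    masks: LabelMasks,
    neighbor_cfg: NeighborConfig = NeighborConfig(),
    redox_mode: str = "ratio_of_means",
) -> pd.DataFrame:
    """One row per cell: 11 metabolic + 8 nuclear parameters.

    Metabolic parameters are means of the per-pixel lifetime maps over
    *valid* cytoplasm pixels; intensities are cytoplasm means of the
    integrated-intensity images (valid on every pixel); the redox ratio
    uses the cell's mean intensities (or the mean of per-pixel ratios
    when ``redox_mode='mean_of_ratios'``).  Cells with no valid
    cytoplasm pixels are kept but flagged, with NaN metabolic fields.
    """
    if lifetime_nadph.shape != masks.cells.shape:
        raise ValueError("images and masks must share shape")
    if redox_mode not in ("ratio_of_means", "mean_of_ratios"):
        raise ValueError(f"unknown redox_mode {redox_mode!r}")
    labels = masks.labels()
    nuc = _nuclear_morphometry(masks.nuclei)
    neigh = _neighbor_features(
        masks.nuclei,
        nuc[["centroid_row", "centroid_col"]].to_numpy(),
        nuc["label"].to_numpy(), neighbor_cfg.distance)
    nuc = nuc.merge(neigh, on="label")

    records = []
    for k in labels:
        cyto = masks.cytoplasm == k
        rec: dict[str, float] = {"cell_id": int(k)}
        valid_any = False
        for ch, img in (("nadph", lifetime_nadph), ("fad", lifetime_fad)):
            sel = cyto & img.valid
            rec[f"I_{ch}"] = float(img.intensity[cyto].mean()) if cyto.any() else np.nan
            for name in ("alpha1", "tau1", "tau2", "tau_m"):
                vals = getattr(img, name)[sel]
                rec[f"{ch}_{name}"] = float(vals.mean()) if vals.size else np.nan
            valid_any |= bool(sel.any())
        if redox_mode == "ratio_of_means":
            rec["redox_ratio"] = redox_ratio(rec["I_nadph"], rec["I_fad"]) \
                if cyto.any() else np.nan
        else:
            inn = lifetime_nadph.intensity[cyto]
            inf_ = lifetime_fad.intensity[cyto]
            rec["redox_ratio"] = float(np.nanmean(redox_ratio(inn, inf_))) \
                if cyto.any() else np.nan
        rec["flagged"] = not valid_any
        records.append(rec)
    df = pd.DataFrame(records)
    df = df.merge(nuc.rename(columns={"label": "cell_id"}), on="cell_id",
                  how="left")
    ordered = (["cell_id"] + list(METABOLIC_COLUMNS) + list(NUCLEAR_COLUMNS)
               + ["centroid_row", "centroid_col", "flagged"])
    return df[ordered]


def zscore_table(
    records: pd.DataFrame,
    columns: list[str] | None = None,
    grouping: str | list[str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Parameters-by-observations z-score table.

    Rows are parameters, columns are cells (or group means when
    ``grouping`` names label columns).  Each row is standardized with
    the population (N-denominator) standard deviation.  Zero-variance
    rows are set to 0 and returned in the flag list.
    """
    cols = columns or [c for c in records.columns
                       if c in METABOLIC_COLUMNS + NUCLEAR_COLUMNS]
    data = records[cols]
    if grouping is not None:
        data = records.groupby(grouping, observed=True)[cols].mean()
    if len(data) < 2:
        raise ValueError("need at least 2 observations per parameter row")
    mat = data.to_numpy(dtype=float).T  # rows = parameters
    mu = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, keepdims=True)  # population sigma
    flagged = [cols[i] for i in np.nonzero(sd.ravel() == 0)[0]]
    z = np.where(sd > 0, (mat - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    table = pd.DataFrame(z, index=cols, columns=data.index)
    return table, flagged


def hierarchical_order(table: pd.DataFrame) -> dict:
    """Average-linkage Euclidean agglomerative clustering of a z-table.

    Returns leaf orders for rows and columns plus the scipy-format merge
    trees (linkage matrices).  NaN values are rejected.
    """
    mat = np.asarray(table, dtype=float)
    if not np.isfinite(mat).all():
        raise ValueError("table contains non-finite values")
    out = {}
    for name, data in (("row", mat), ("col", mat.T)):
        if data.shape[0] < 2:
            out[f"{name}_linkage"] = np.empty((0, 4))
            out[f"{name}_order"] = list(range(data.shape[0]))
            continue
        link = hierarchy.linkage(data, method="average", metric="euclidean")
        out[f"{name}_linkage"] = link
        out[f"{name}_order"] = hierarchy.leaves_list(link).tolist()
    return out
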