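"""Nucleus detection, seeded cell propagation, and cytoplasm masks.

Cells on the micropattern appear in the NAD(P)H intensity image as
bright cytoplasm surrounding a dark nucleus (NAD(P)H is predominantly
cytosolic).  The chain is:

1. ``nucleus_probability`` — rule-based nucleus-likeness map: inverted,
   min-max normalized, Gaussian-smoothed intensity, zeroed outside the
   (hole-filled) foreground.  The backend is pluggable so a trained
   pixel classifier can be substituted.
2. ``extract_nuclei`` — smooth, threshold, label connected components
   (8-connectivity), and filter by area, the "Simple" object-detection
   recipe with threshold 0.3, smoothing 1 px, and a 15-500 px area
   filter as defaults.
3. ``propagate_cells`` — assign every foreground pixel to the nucleus
   reachable at minimal regularized geodesic cost (distance penalized by
   intensity drops), the classic seeded "propagate" secondary-object
   algorithm.
4. ``make_cytoplasm`` — cytoplasm(k) = cell(k) minus nucleus(k).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import ndimage
from skimage import filters, graph, measure, morphology

from .core import LabelMasks

__all__ = [
    "SegConfig",
    "nucleus_probability",
    "extract_nuclei",
    "propagate_cells",
    "make_cytoplasm",
    "segment_scene",
]


@dataclass(frozen=True)
class SegConfig:
    """Segmentation parameters.

    ``prob_threshold``, ``smooth_sigma`` and the size filter act on the
    nucleus-probability map; ``foreground_threshold`` (intensity units)
    defines cell-bearing pixels; ``propagation_reg`` is the weight
    balancing pure distance against intensity-gradient cost during cell
    growth; ``edge_margin`` zeroes nucleus probability within that many
    pixels of the foreground boundary, where smoothing mixes cell and
    background intensities.
    """

    smooth_sigma: float = 1.0
    prob_threshold: float = 0.3
    size_min: int = 15
    size_max: int = 500
    foreground_threshold: float = 120.0
    propagation_reg: float = 0.05
    edge_margin: int = 3

    def __post_init__(self) -> None:
        if not (0.0 <= self.prob_threshold <= 1.0):
            raise ValueError("prob_threshold must be in [0, 1]")
        if not (0 < self.size_min < self.size_max):
            raise ValueError("require 0 < size_min < size_max")
        if self.propagation_reg < 0:
            raise ValueError("propagation_reg must be >= 0")


def foreground_mask(intensity: np.ndarray, cfg: SegConfig) -> np.ndarray:
    """Cell-bearing pixels: smoothed intensity above threshold, holes
    filled so dark nuclei enclosed by bright cytoplasm stay inside."""
    smoothed = ndimage.gaussian_filter(
        np.asarray(intensity, dtype=float), cfg.smooth_sigma)
    return ndimage.binary_fill_holes(smoothed >= cfg.foreground_threshold)


def nucleus_probability(
    intensity: np.ndarray,
    cfg: SegConfig = SegConfig(),
    backend: Callable[[np.ndarray, SegConfig], np.ndarray] | None = None,
) -> np.ndarray:
    """Per-pixel nucleus probability in [0, 1] from NAD(P)H intensity.

    Default backend: Gaussian-smooth the intensity, invert and min-max
    normalize it over the foreground, and zero everything outside the
    (slightly eroded) foreground mask.  Dark intensity minima enclosed
    by bright cytoplasm therefore score high.  A constant image has no
    contrast and maps to all zeros.  Pass ``backend`` to substitute e.g.
    a trained pixel classifier; it must return values in [0, 1].
    """
    intensity = np.asarray(intensity, dtype=float)
    if np.any(intensity < 0):
        raise ValueError("intensity must be nonnegative")
    if backend is not None:
        prob = np.asarray(backend(intensity, cfg), dtype=float)
        return np.clip(prob, 0.0, 1.0)
    fg = foreground_mask(intensity, cfg)
    if cfg.edge_margin > 0:
        fg = ndimage.binary_erosion(
            fg, morphology.disk(cfg.edge_margin), border_value=1)
    smoothed = ndimage.gaussian_filter(intensity, cfg.smooth_sigma)
    if not fg.any():
        return np.zeros_like(smoothed)
    lo = smoothed[fg].min()
    hi = smoothed[fg].max()
    if hi - lo <= 0:
        return np.zeros_like(smoothed)
    prob = np.where(fg, (hi - smoothed) / (hi - lo), 0.0)
    return np.clip(prob, 0.0, 1.0)


def extract_nuclei(prob: np.ndarray, cfg: SegConfig = SegConfig()) -> np.ndarray:
    """Label nuclei in a probability map: smooth, threshold, label
    8-connected components, drop components outside [size_min, size_max].

    Surviving labels are renumbered consecutively from 1 in raster order
    of first occurrence; raising ``size_min`` can only reduce the count.
    """
    prob = np.asarray(prob, dtype=float)
    if prob.min() < 0 or prob.max() > 1:
        raise ValueError("probability map must lie in [0, 1]")
    smoothed = ndimage.gaussian_filter(prob, cfg.smooth_sigma)
    binary = smoothed >= cfg.prob_threshold
    labeled = measure.label(binary, connectivity=2)
    out = np.zeros_like(labeled, dtype=np.uint16)
    next_id = 1
    for region in measure.regionprops(labeled):
        if cfg.size_min <= region.area <= cfg.size_max:
            out[labeled == region.label] = next_id
            next_id += 1
    return out


def propagate_cells(
    nuclei: np.ndarray,
    intensity: np.ndarray,
    cfg: SegConfig = SegConfig(),
) -> np.ndarray:
    """Grow cell regions outward from nuclei over the foreground.

    Every foreground pixel is assigned to the nucleus whose seeds reach
    it at minimal cumulative geodesic cost; the per-pixel step cost is
    ``propagation_reg + |grad I| / max|grad I|``, so growth follows flat
    or bright terrain and is penalized across intensity drops.  Nucleus
    pixels always keep their own label.  Ties in cumulative cost are
    resolved deterministically (stable raster ordering of equal-cost
    pixels).  Returns an empty image (with a warning) when no nuclei are
    present.
    """
    nuclei = np.asarray(nuclei)
    intensity = np.asarray(intensity, dtype=float)
    if nuclei.shape != intensity.shape:
        raise ValueError("nuclei and intensity must share shape")
    cells = np.zeros_like(nuclei, dtype=np.uint16)
    if nuclei.max() == 0:
        warnings.warn("no nuclei to propagate from; empty cell image")
        return cells
    fg = foreground_mask(intensity, cfg) | (nuclei > 0)

    grad = filters.sobel(ndimage.gaussian_filter(intensity, cfg.smooth_sigma))
    gmax = grad[fg].max()
    step = cfg.propagation_reg + (grad / gmax if gmax > 0 else 0.0)
    costs = np.where(fg, step, np.inf)

    seeds = np.argwhere(nuclei > 0)
    mcp = graph.MCP_Geometric(costs, fully_connected=True)
    cum, traceback = mcp.find_costs(starts=[tuple(s) for s in seeds])

    cells[nuclei > 0] = nuclei[nuclei > 0]
    offsets = np.asarray(mcp.offsets, dtype=np.int64)
    flat = cum.ravel()
    reachable = np.nonzero(np.isfinite(flat))[0]
    order = reachable[np.argsort(flat[reachable], kind="stable")]
    tb = traceback.ravel()
    w = cells.shape[1]
    cflat = cells.ravel()
    for idx in order:
        if cflat[idx]:
            continue
        t = tb[idx]
        if t < 0:
            continue
        dy, dx = offsets[t]
        pred = idx - dy * w - dx
        cflat[idx] = cflat[pred]
    return cells


def make_cytoplasm(nuclei: np.ndarray, cells: np.ndarray) -> LabelMasks:
    """Cytoplasm = cell minus nucleus, per label.

    Labels whose cytoplasm is empty (cell == nucleus) are flagged in
    ``empty_cytoplasm``.  A label present in nuclei but absent from
    cells indicates inconsistent inputs and raises.
    """
    nuclei = np.asarray(nuclei)
    cells = np.asarray(cells)
    nuc_labels = set(np.unique(nuclei[nuclei > 0]).tolist())
    cell_labels = set(np.unique(cells[cells > 0]).tolist())
    missing = nuc_labels - cell_labels
    if missing:
        raise ValueError(f"labels in nuclei but not in cells: {sorted(missing)}")
    cytoplasm = np.where(nuclei > 0, 0, cells).astype(cells.dtype)
    empty = sorted(cell_labels - set(np.unique(cytoplasm[cytoplasm > 0]).tolist()))
    return LabelMasks(nuclei=nuclei, cells=cells, cytoplasm=cytoplasm,
                      empty_cytoplasm=[int(k) for k in empty])


def segment_scene(
    intensity: np.ndarray,
    cfg: SegConfig = SegConfig(),
    backend: Callable[[np.ndarray, SegConfig], np.ndarray] | None = None,
) -> LabelMasks:
    """Full chain: probability -> nuclei -> cells -> cytoplasm."""
    prob = nucleus_probability(intensity, cfg, backend=backend)
    nuclei = extract_nuclei(prob, cfg)
    cells = propagate_cells(nuclei, intensity, cfg)
    return make_cytoplasm(nuclei, cells)
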