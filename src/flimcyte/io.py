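"""On-disk formats for scenes, lifetime images, masks, and tables.

* Decay cubes: one HDF5 file with datasets ``/nadph`` and ``/fad``
  (shape T x Y x X) and attrs ``bin_width_ns``, ``origin_ns``; or
  per-channel multi-page TIFF (one page per time bin).
* Label masks: 16-bit single-page TIFF per compartment.
* Lifetime images: multi-channel 32-bit float TIFF (one page per
  parameter map) plus a JSON sidecar recording the fit configuration
  and page order.  Invalid pixels are NaN.
* Tables: CSV with a fixed, documented column order.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import LabelMasks, LifetimeImage, TimeAxis

__all__ = [
    "write_scene_h5", "read_cube_h5",
    "write_cube_tiff", "read_cube_tiff",
    "write_masks", "read_masks",
    "write_lifetime_image", "read_lifetime_image",
]


def write_scene_h5(path, cubes: dict[str, np.ndarray], axis: TimeAxis) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        for name, cube in cubes.items():
            d = f.create_dataset(name, data=np.asarray(cube),
                                 compression="gzip", compression_opts=4)
            d.attrs["bin_width_ns"] = axis.bin_width
            d.attrs["origin_ns"] = axis.origin


def read_cube_h5(path, channel: str) -> tuple[np.ndarray, TimeAxis]:
    import h5py

    with h5py.File(path, "r") as f:
        d = f[channel]
        cube = d[...]
        axis = TimeAxis(n_bins=cube.shape[0],
                        bin_width=float(d.attrs["bin_width_ns"]),
                        origin=float(d.attrs.get("origin_ns", 0.0)))
    return cube, axis


def write_cube_tiff(path, cube: np.ndarray, axis: TimeAxis) -> None:
    tifffile.imwrite(path, np.asarray(cube, dtype=np.float32),
                     metadata={"bin_width_ns": axis.bin_width,
                               "origin_ns": axis.origin})


def read_cube_tiff(path, axis: TimeAxis | None = None) -> tuple[np.ndarray, TimeAxis]:
    with tifffile.TiffFile(path) as tf:
        cube = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if axis is None:
        axis = TimeAxis(n_bins=cube.shape[0],
                        bin_width=float(meta.get("bin_width_ns", 12.5 / cube.shape[0])),
                        origin=float(meta.get("origin_ns", 0.0)))
    return cube, axis


def write_masks(outdir, masks: LabelMasks, prefix: str = "") -> dict[str, Path]:
    outdir = Path(outdir)
    paths = {}
    for name in ("nuclei", "cells", "cytoplasm"):
        p = outdir / f"{prefix}{name}.tif"
        tifffile.imwrite(p, getattr(masks, name).astype(np.uint16))
        paths[name] = p
    return paths


def read_masks(outdir, prefix: str = "") -> LabelMasks:
    outdir = Path(outdir)
    arrs = {name: tifffile.imread(outdir / f"{prefix}{name}.tif")
            for name in ("nuclei", "cells", "cytoplasm")}
    return LabelMasks(**arrs)


def write_lifetime_image(path, img: LifetimeImage, config: dict | None = None) -> None:
    """Multi-page float32 TIFF in MAPS order + validity page, with a
    JSON sidecar describing pages and fit configuration."""
    pages = [np.asarray(getattr(img, m), dtype=np.float32) for m in img.MAPS]
    pages.append(img.valid.astype(np.float32))
    tifffile.imwrite(path, np.stack(pages))
    sidecar = Path(str(path) + ".json")
    meta = {"pages": list(img.MAPS) + ["valid"],
            "invalid_sentinel": "NaN",
            "config": _jsonable(config or {})}
    sidecar.write_text(json.dumps(meta, indent=2))


def read_lifetime_image(path) -> LifetimeImage:
    stack = tifffile.imread(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    pages = {name: stack[i] for i, name in enumerate(meta["pages"])}
    valid = pages.pop("valid") > 0.5
    return LifetimeImage(valid=valid,
                         intensity=pages.pop("intensity").astype(np.float64),
                         **{k: v for k, v in pages.items()})


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (pd.DataFrame,)):
        return obj.to_dict(orient="records")
    return obj
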