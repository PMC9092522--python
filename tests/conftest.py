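"""Shared fixtures: small rendered scenes and tabular cell populations.

Expensive artifacts (rendered + fitted scenes, UMAP trajectories) are
session-scoped so the suite pays for them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from flimcyte.core import IRFModel, TimeAxis
from flimcyte.decayfit import FitConfig, fit_cube, integrate_intensity
from flimcyte.segmentation import SegConfig, foreground_mask
from flimcyte.synthetic import (SceneSpec, generate_scene,
                                sample_feature_table, sample_progression)

SMALL_AXIS = TimeAxis(n_bins=256, bin_width=12.5 / 256)


@pytest.fixture(scope="session")
def small_scene_spec() -> SceneSpec:
    return SceneSpec(
        field_shape=(96, 96), ufeature_radius=44.0,
        cells_per_class={"EPC": 3, "IM": 3, "iPSC": 3},
        axis=SMALL_AXIS, irf=IRFModel(), seed=11)


@pytest.fixture(scope="session")
def scene(small_scene_spec):
    return generate_scene(small_scene_spec)


@pytest.fixture(scope="session")
def fitted_scene(scene):
    """Both channels of the small scene fitted per pixel."""
    cfg = FitConfig()
    out = {}
    for ch in ("nadph", "fad"):
        cube = scene.cubes[ch]
        fg = foreground_mask(integrate_intensity(cube), SegConfig())
        out[ch] = fit_cube(cube, scene.spec.axis, scene.spec.irf, cfg,
                           pixels=fg)
    return out


@pytest.fixture(scope="session")
def feature_table():
    return sample_feature_table(150, seed=3)


@pytest.fixture(scope="session")
def progression():
    df, t = sample_progression(250, seed=5)
    return df, t


@pytest.fixture(scope="session")
def trajectory_result(progression):
    from flimcyte.trajectory import EmbeddingConfig, infer_trajectory

    df, _ = progression
    return infer_trajectory(df, EmbeddingConfig(seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
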