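"""Feature extraction: metabolic/nuclear parameters, z-scores, linkage."""

import numpy as np
import pandas as pd
import pytest

from flimcyte.core import LabelMasks
from flimcyte.features import (METABOLIC_COLUMNS, NUCLEAR_COLUMNS,
                               NeighborConfig, extract_cell_features,
                               hierarchical_order, mean_lifetime,
                               redox_ratio, zscore_table)


class TestRedoxRatio:
    @pytest.mark.parametrize("inadph,ifad,expected", [
        (100, 100, 0.5), (0, 7, 0.0), (300, 100, 0.75),
    ])
    def test_values(self, inadph, ifad, expected):
        assert redox_ratio(inadph, ifad) == pytest.approx(expected)

    def test_both_zero_flagged_nan(self):
        assert np.isnan(redox_ratio(0.0, 0.0))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            redox_ratio(-1.0, 5.0)

    def test_always_in_unit_interval(self, rng):
        a = rng.uniform(0, 1e4, 200)
        b = rng.uniform(0, 1e4, 200)
        r = redox_ratio(a, b)
        assert np.all((r >= 0) & (r <= 1))


class TestMeanLifetime:
    @pytest.mark.parametrize("a1,t1,t2,expected", [
        (1.0, 0.5, 9.9, 0.5), (0.5, 0.4, 2.0, 1.2), (0.7, 0.4, 2.5, 1.03),
    ])
    def test_values(self, a1, t1, t2, expected):
        assert mean_lifetime(a1, t1, t2) == pytest.approx(expected)

    def test_alpha_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mean_lifetime(1.5, 0.4, 2.0)


def _disc_mask(shape, center, radius):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2


class TestNuclearMorphometry:
    def test_perfect_disc_geometry(self):
        from flimcyte.features import _nuclear_morphometry

        m = _disc_mask((40, 40), (20, 20), 10).astype(np.uint16)
        row = _nuclear_morphometry(m).iloc[0]
        assert row["nsi"] == pytest.approx(1.0, abs=0.05)
        assert row["solidity"] == pytest.approx(1.0, abs=0.1)
        assert row["extent"] == pytest.approx(np.pi / 4, abs=0.08)
        assert row["area"] == pytest.approx(np.pi * 100, rel=0.05)

    def test_nsi_at_least_one_for_simply_connected_shapes(self, rng):
        """Isoperimetric inequality: discs minimize NSI; irregular
        blobs exceed 1 (up to 2% discretization tolerance)."""
        from scipy import ndimage

        from flimcyte.features import _nuclear_morphometry

        for seed in range(5):
            r = np.random.default_rng(seed)
            blob = ndimage.binary_dilation(
                r.random((32, 32)) > 0.8, iterations=2)
            lab, n = ndimage.label(blob)
            big = np.argmax(np.bincount(lab.ravel())[1:]) + 1
            mask = ndimage.binary_fill_holes(lab == big).astype(np.uint16)
            if mask.sum() < 20:
                continue
            row = _nuclear_morphometry(mask).iloc[0]
            assert row["nsi"] >= 0.98


class TestExtractCellFeatures:
    def test_schema_locked(self, fitted_scene, scene):
        """Exactly 11 metabolic and 8 nuclear parameters per record."""
        df = extract_cell_features(fitted_scene["nadph"], fitted_scene["fad"],
                                   scene.truth_masks)
        assert len(METABOLIC_COLUMNS) == 11
        assert len(NUCLEAR_COLUMNS) == 8
        assert [c for c in df.columns if c in METABOLIC_COLUMNS] == \
            list(METABOLIC_COLUMNS)
        assert [c for c in df.columns if c in NUCLEAR_COLUMNS] == \
            list(NUCLEAR_COLUMNS)
        assert len(df) == len(scene.truth_table)

    def test_redox_ratio_recovers_truth(self, fitted_scene, scene):
        """Per-cell measured redox ratio within 0.05 of generator truth
        (median over cells)."""
        df = extract_cell_features(fitted_scene["nadph"], fitted_scene["fad"],
                                   scene.truth_masks)
        truth = scene.truth_table.set_index("label")["redox_ratio"]
        err = np.abs(df.set_index("cell_id")["redox_ratio"] - truth)
        assert err.median() < 0.05

    def test_fad_alpha1_recovers_truth(self, fitted_scene, scene):
        """Mean absolute error of per-cell FAD alpha1 below 0.02."""
        df = extract_cell_features(fitted_scene["nadph"], fitted_scene["fad"],
                                   scene.truth_masks)
        truth = scene.truth_table.set_index("label")["fad_alpha1"]
        err = np.abs(df.set_index("cell_id")["fad_alpha1"] - truth)
        assert err.mean() < 0.02

    def test_bounded_features_in_unit_interval(self, fitted_scene, scene):
        df = extract_cell_features(fitted_scene["nadph"], fitted_scene["fad"],
                                   scene.truth_masks)
        for col in ("redox_ratio", "solidity", "extent"):
            assert df[col].between(0, 1).all()

    def test_single_cell_has_no_neighbors(self, fitted_scene, scene):
        """With one cell in the scene, n_neighbors = 0 and the distance
        to the first neighbor is undefined."""
        m = scene.truth_masks
        keep = 1
        solo = LabelMasks(
            nuclei=np.where(m.nuclei == keep, keep, 0).astype(np.uint16),
            cells=np.where(m.cells == keep, keep, 0).astype(np.uint16),
            cytoplasm=np.where(m.cytoplasm == keep, keep, 0).astype(np.uint16))
        df = extract_cell_features(fitted_scene["nadph"], fitted_scene["fad"],
                                   solo, NeighborConfig())
        assert df["n_neighbors"].iloc[0] == 0
        assert np.isnan(df["dist_first_neighbor"].iloc[0])

    def test_empty_cytoplasm_flagged_with_nan_metabolics(self, fitted_scene):
        shape = fitted_scene["nadph"].shape
        nuc = np.zeros(shape, np.uint16)
        nuc[_disc_mask(shape, (20, 20), 4)] = 1
        masks = LabelMasks(nuclei=nuc, cells=nuc.copy(),
                           cytoplasm=np.zeros(shape, np.uint16))
        df = extract_cell_features(fitted_scene["nadph"], fitted_scene["fad"],
                                   masks)
        assert bool(df["flagged"].iloc[0])
        assert np.isnan(df["fad_alpha1"].iloc[0])


class TestZScoreTable:
    def test_hand_computed_row(self):
        df = pd.DataFrame({"p": [1.0, 2.0, 3.0]})
        table, flagged = zscore_table(df, columns=["p"])
        np.testing.assert_allclose(table.loc["p"].to_numpy(),
                                   [-1.2247, 0.0, 1.2247], atol=1e-4)
        assert flagged == []

    def test_constant_row_flagged_zero(self):
        df = pd.DataFrame({"p": [1.0, 2.0, 3.0], "q": [4.0, 4.0, 4.0]})
        table, flagged = zscore_table(df, columns=["p", "q"])
        assert flagged == ["q"]
        assert np.all(table.loc["q"].to_numpy() == 0)

    def test_rows_centered_and_unit_scaled(self, feature_table):
        table, flagged = zscore_table(feature_table)
        mat = table.to_numpy()
        np.testing.assert_allclose(mat.mean(axis=1), 0, atol=1e-9)
        ok = [i for i, c in enumerate(table.index) if c not in flagged]
        np.testing.assert_allclose(mat[ok].std(axis=1), 1, atol=1e-9)

    def test_single_observation_rejected(self):
        with pytest.raises(ValueError):
            zscore_table(pd.DataFrame({"p": [1.0]}), columns=["p"])

    def test_grouped_means(self, feature_table):
        table, _ = zscore_table(feature_table, grouping="cell_class")
        assert table.shape[1] == feature_table["cell_class"].nunique()


def naive_average_linkage(X):
    """O(n^3) reference agglomeration: merge the pair of clusters with
    the smallest mean pairwise Euclidean distance."""
    from itertools import combinations

    clusters = {i: [i] for i in range(len(X))}
    heights = []
    next_id = len(X)
    d = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
    while len(clusters) > 1:
        best = None
        for a, b in combinations(sorted(clusters), 2):
            dist = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or dist < best[0]:
                best = (dist, a, b)
        dist, a, b = best
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        heights.append(dist)
        next_id += 1
    return np.array(heights)


class TestHierarchicalOrder:
    def test_identical_rows_merge_first_at_zero(self):
        X = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [8.0, 9.0]])
        out = hierarchical_order(X)
        assert out["row_linkage"][0, 2] == 0.0
        assert set(out["row_linkage"][0, :2]) == {0, 1}

    def test_close_pair_merges_before_far_row(self):
        X = pd.DataFrame([[0.0], [1.0], [11.0]])
        out = hierarchical_order(X)
        assert set(out["row_linkage"][0, :2]) == {0, 1}

    def test_merge_heights_match_naive_oracle(self, rng):
        X = rng.normal(size=(6, 4))
        out = hierarchical_order(pd.DataFrame(X))
        np.testing.assert_allclose(np.sort(out["row_linkage"][:, 2]),
                                   np.sort(naive_average_linkage(X)),
                                   rtol=1e-10)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_order(pd.DataFrame([[1.0, np.nan], [0.0, 1.0]]))
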