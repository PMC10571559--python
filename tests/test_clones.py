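"""Clone calling: DBSCAN semantics, automatic eps, clone metrics."""

import numpy as np
import pandas as pd
import pytest

from clonoscope import clones as clone_mod
from tests.conftest import assert_matches_oracle, brute_force_dbscan


def records_from_points(pts, color="R", major=12.0):
    pts = np.asarray(pts, dtype=float)
    colors = [color] * len(pts) if isinstance(color, str) else list(color)
    return pd.DataFrame({"x": pts[:, 0], "y": pts[:, 1],
                         "area": 85.0, "major_axis": major,
                         "color_class": colors})


class TestDbscanSemantics:
    def test_three_collinear_points_at_half_eps_form_one_cluster(self):
        recs = records_from_points([[0, 0], [0.5, 0], [1.0, 0]])
        out = clone_mod.cluster_clones_dbscan(recs, eps=1.0, min_samples=2,
                                              color_constrained=False)
        assert out["clone_id"].nunique() == 1
        assert not out["unclustered"].any()

    def test_two_distant_same_color_groups_form_two_clusters(self):
        a = [[0, 0], [1, 0], [0, 1]]
        b = [[30, 30], [31, 30], [30, 31]]
        recs = records_from_points(a + b)
        out = clone_mod.cluster_clones_dbscan(recs, eps=3.0, min_samples=3,
                                              color_constrained=False)
        assert out["clone_id"].nunique() == 2

    def test_color_constraint_separates_overlapping_clones(self):
        # two clones sharing the same area but carrying different barcodes:
        # the motivating case for color-constrained clustering
        rng = np.random.default_rng(0)
        pts_r = rng.normal(0, 3, (10, 2))
        pts_g = rng.normal(0, 3, (10, 2))
        recs = records_from_points(np.vstack([pts_r, pts_g]),
                                   color=["R"] * 10 + ["G"] * 10)
        split = clone_mod.cluster_clones_dbscan(recs, eps=6.0, min_samples=3,
                                                color_constrained=True)
        merged = clone_mod.cluster_clones_dbscan(recs, eps=6.0, min_samples=3,
                                                 color_constrained=False)
        assert split["clone_id"].nunique() == 2
        assert merged["clone_id"].nunique() == 1
        by_color = split.groupby("color_class")["clone_id"].nunique()
        assert (by_color == 1).all()

    def test_trash_records_excluded_from_clustering(self):
        recs = records_from_points([[0, 0], [1, 0], [0, 1], [0.5, 0.5]],
                                   color=["R", "R", "R", "TRASH"])
        out = clone_mod.cluster_clones_dbscan(recs, eps=3.0, min_samples=3)
        assert out.loc[3, "clone_id"] == -1
        assert out.loc[:2, "clone_id"].nunique() == 1

    @pytest.mark.parametrize("bad", [dict(eps=0.0), dict(eps=-1.0),
                                     dict(min_samples=0)])
    def test_invalid_parameters_rejected(self, bad):
        recs = records_from_points([[0, 0], [1, 1]])
        kwargs = dict(eps=1.0, min_samples=2)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            clone_mod.cluster_clones_dbscan(recs, **kwargs)

    def test_partition_covers_every_non_trash_nucleus(self):
        rng = np.random.default_rng(4)
        recs = records_from_points(rng.uniform(0, 100, (60, 2)),
                                   color=rng.choice(["R", "G", "TRASH"], 60))
        out = clone_mod.cluster_clones_dbscan(recs, eps=8.0, min_samples=3)
        non_trash = out[out["color_class"] != "TRASH"]
        assert (non_trash["clone_id"] >= 0).all()
        clones = clone_mod.clone_metrics(out, 85.0)
        assert clones["n_cells"].sum() == len(non_trash)


class TestOracleEquivalence:
    def test_matches_brute_force_on_random_configurations(self):
        # independent oracle: explicit density reachability over all pairs
        rng = np.random.default_rng(42)
        for _ in range(60):
            n = int(rng.integers(5, 100))
            pts = rng.uniform(0, 60, (n, 2))
            eps = float(rng.uniform(2, 12))
            min_samples = int(rng.integers(2, 6))
            recs = records_from_points(pts)
            out = clone_mod.cluster_clones_dbscan(
                recs, eps=eps, min_samples=min_samples,
                color_constrained=False)
            assert_matches_oracle(recs, out, eps, min_samples)

    def test_oracle_itself_labels_isolated_point_as_noise(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [50.0, 50.0]])
        labels, core, border = brute_force_dbscan(pts, 2.0, 2)
        assert core[0] and core[1] and not core[2]
        assert border[2] == set()


class TestEstimateEps:
    def test_regular_grid_knee_between_one_and_two_spacings(self):
        d = 10.0
        yy, xx = np.mgrid[0:8, 0:8].astype(float) * d
        recs = records_from_points(np.column_stack([xx.ravel(), yy.ravel()]),
                                   major=3.0)
        eps, curve = clone_mod.estimate_eps(recs, min_samples=3)
        assert d <= eps <= 2 * d
        assert len(curve) == 64

    def test_duplicate_points_floored_by_nucleus_size(self):
        recs = records_from_points(np.zeros((10, 2)), major=12.0)
        eps, _ = clone_mod.estimate_eps(recs, min_samples=3)
        assert eps == 2 * 12.0

    def test_eps_scales_with_coordinates(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 100, (50, 2))
        r1 = records_from_points(pts, major=1e-6)
        r3 = records_from_points(pts * 3, major=1e-6)
        e1, _ = clone_mod.estimate_eps(r1, 3)
        e3, _ = clone_mod.estimate_eps(r3, 3)
        assert e3 == pytest.approx(3 * e1, rel=1e-9)

    def test_too_few_records_rejected(self):
        recs = records_from_points([[0, 0], [1, 1]])
        with pytest.raises(ValueError, match="min_samples"):
            clone_mod.estimate_eps(recs, min_samples=3)


class TestCloneMetrics:
    def test_singleton_clone_uses_nucleus_area(self):
        recs = records_from_points([[5, 5]]).assign(clone_id=0)
        clones = clone_mod.clone_metrics(recs, median_nucleus_area=85.0)
        assert clones.loc[0, "area_px2"] == 85.0
        assert clones.loc[0, "compactness"] == pytest.approx(1.0)

    def test_unit_square_corners_metric_arithmetic(self):
        pts = [[0, 0], [1, 0], [1, 1], [0, 1]]
        recs = records_from_points(pts).assign(clone_id=0, area=0.5)
        clones = clone_mod.clone_metrics(recs, median_nucleus_area=0.5)
        assert clones.loc[0, "area_px2"] == pytest.approx(1.0)
        assert clones.loc[0, "norm_area"] == pytest.approx(2.0)
        assert clones.loc[0, "compactness"] == pytest.approx(2.0)

    def test_translation_leaves_metrics_unchanged(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 10, (7, 2))
        a = clone_mod.clone_metrics(
            records_from_points(pts).assign(clone_id=0), 85.0)
        b = clone_mod.clone_metrics(
            records_from_points(pts + 1000).assign(clone_id=0), 85.0)
        for col in ("n_cells", "area_px2", "norm_area", "compactness"):
            assert a.loc[0, col] == pytest.approx(b.loc[0, col])

    def test_collinear_members_fall_back_to_summed_area(self):
        recs = records_from_points([[0, 0], [5, 0], [10, 0]]).assign(
            clone_id=0, area=40.0)
        clones = clone_mod.clone_metrics(recs, 85.0)
        assert clones.loc[0, "area_px2"] == pytest.approx(120.0)

    def test_dominant_color_reported(self):
        recs = records_from_points([[0, 0], [1, 0], [2, 0]],
                                   color=["G", "G", "R"]).assign(clone_id=0)
        clones = clone_mod.clone_metrics(recs, 85.0)
        assert clones.loc[0, "color_class"] == "G"


class TestLongitudinal:
    def _clones(self, sizes):
        return pd.DataFrame({"clone_id": range(len(sizes)),
                             "n_cells": sizes})

    def test_identical_days_give_identical_summaries(self):
        day = self._clones([3, 5, 8])
        out = clone_mod.longitudinal_link({2: day, 4: day.copy()})
        assert out.loc[0, "clone_count"] == out.loc[1, "clone_count"]
        assert out.loc[0, "median_cells_per_clone"] == \
            out.loc[1, "median_cells_per_clone"]

    def test_doubling_growth_doubles_median(self):
        out = clone_mod.longitudinal_link({
            2: self._clones([2, 4, 6]),
            4: self._clones([4, 8, 12]),
        })
        assert out.loc[1, "median_cells_per_clone"] == \
            2 * out.loc[0, "median_cells_per_clone"]

    def test_clone_merging_decreases_count_by_one(self):
        # day 6: two clones fused into one (sizes add), as happens when
        # growing colonies touch
        out = clone_mod.longitudinal_link({
            4: self._clones([10, 12, 20]),
            6: self._clones([22, 20]),
        })
        assert out.loc[1, "clone_count"] == out.loc[0, "clone_count"] - 1


class TestRecoveryOnSyntheticWell(object):
    def test_ground_truth_clones_recovered_as_single_clusters(
            self, small_lego_well):
        _, truth, nuclei, clones = small_lego_well
        n_true = truth.surviving_clones
        assert abs(len(clones) - n_true) / n_true <= 0.05
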