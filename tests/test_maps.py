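"""Spatial axes, smoothing, interpolation, correlations and joint analysis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hgmap import maps, synth


class TestAlongAxis:
    def test_sites_on_a_line_get_arc_positions(self):
        t = np.array([0.0, 1.0, 2.5, 4.0])
        coords = np.column_stack([t, t]) / np.sqrt(2)
        along = maps.along_hg_distance(coords)
        assert np.allclose(along, t - t[0], atol=1e-9)

    def test_planted_axis_angle_recovered(self):
        rng = np.random.default_rng(0)
        theta = np.deg2rad(40.0)
        u = np.array([np.cos(theta), np.sin(theta)])
        pos = rng.uniform(0, 30, 100)
        coords = (pos[:, None] * u + rng.normal(0, 1.0, (100, 2)))
        centred = coords - coords.mean(axis=0)
        along = maps.along_hg_distance(coords)
        slope = np.linalg.lstsq(
            np.column_stack([along, np.ones_like(along)]), centred,
            rcond=None)[0][0]
        angle = np.degrees(np.arctan2(slope[1], slope[0])) % 180
        assert abs(angle - 40.0) <= 5.0

    def test_isotropic_cloud_warns(self):
        ang = np.linspace(0, 2 * np.pi, 24, endpoint=False)
        coords = np.column_stack([np.cos(ang), np.sin(ang)])
        with pytest.warns(UserWarning, match="isotropic"):
            maps.along_hg_distance(coords)

    def test_ml_distance_zero_minimum(self):
        ml = maps.ml_distance(np.array([-42.0, -45.0, 44.0]))
        assert ml.min() == 0.0
        assert np.all(ml >= 0.0)


class TestSmoothing:
    def test_constant_field_unchanged(self):
        rng = np.random.default_rng(2)
        coords = rng.uniform(0, 10, (20, 2))
        out = maps.knn_smooth(np.full(20, 3.3), coords, k=4)
        assert np.allclose(out, 3.3)

    def test_outlier_replaced_by_neighbour_mean(self):
        coords = np.array([[0.0, 0], [1, 0], [0, 1], [1, 1], [0.5, 0.5]])
        values = np.array([2.0, 2.0, 2.0, 2.0, 50.0])
        out = maps.knn_smooth(values, coords, k=4)
        assert out[4] == pytest.approx(2.0)

    def test_k_equals_n_minus_one_gives_leave_one_out_mean(self):
        rng = np.random.default_rng(3)
        coords = rng.uniform(0, 10, (8, 2))
        values = rng.normal(size=8)
        out = maps.knn_smooth(values, coords, k=7)
        loo = (values.sum() - values) / 7
        assert np.allclose(out, loo)

    @given(seed=st.integers(0, 500))
    @settings(max_examples=20, deadline=None)
    def test_smoothing_contracts_variance(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(0, 10, (15, 2))
        values = rng.normal(size=15)
        out = maps.knn_smooth(values, coords, k=4)
        assert out.var() <= values.var() + 1e-12


class TestInterpolation:
    def test_planar_field_reproduced_exactly(self):
        rng = np.random.default_rng(4)
        coords = rng.uniform(0, 10, (30, 2))
        values = 2.0 * coords[:, 0] - 0.5 * coords[:, 1] + 3.0
        grid = np.linspace(3, 7, 5)
        z = maps.interpolate_surface(values, coords, grid, grid)
        gx, gy = np.meshgrid(grid, grid)
        expect = 2.0 * gx - 0.5 * gy + 3.0
        inside = ~z.mask
        assert np.allclose(z[inside], expect[inside], atol=1e-8)

    def test_outside_hull_masked(self):
        coords = np.array([[0.0, 0], [1, 0], [0, 1]])
        z = maps.interpolate_surface(np.ones(3), coords,
                                     np.array([5.0]), np.array([5.0]))
        assert z.mask.all()

    def test_imputation_copies_nearest_neighbour(self):
        coords = np.array([[0.0, 0], [0.1, 0], [10, 10]])
        values = np.array([np.nan, 3.2, 7.0])
        out = maps.impute_missing(values, coords)
        assert out[0] == 3.2

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            maps.impute_missing(np.full(3, np.nan), np.zeros((3, 2)))


class TestCorrelationsAndHemispheres:
    def test_identity_correlation(self):
        x = np.linspace(0, 10, 20)
        r, p = maps.feature_axis_correlation(x, x)
        assert r == pytest.approx(1.0)

    def test_permuted_values_within_null_band(self):
        rng = np.random.default_rng(5)
        along = np.linspace(0, 20, 60)
        rs = [maps.feature_axis_correlation(rng.permutation(along), along)[0]
              for _ in range(50)]
        assert np.abs(rs).max() < 4.0 / np.sqrt(60)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            maps.feature_axis_correlation(np.ones(20), np.arange(20.0))

    def test_shifted_hemisphere_detected(self):
        rng = np.random.default_rng(6)
        values = np.concatenate([rng.normal(0, 1, 40),
                                 rng.normal(5, 1, 40)])
        hemi = np.array(["L"] * 40 + ["R"] * 40)
        stat, p, nl, nr = maps.compare_hemispheres(values, hemi)
        assert p < 1e-6
        assert (nl, nr) == (40, 40)

    def test_null_hemisphere_p_roughly_uniform(self):
        rng = np.random.default_rng(7)
        ps = []
        for _ in range(200):
            values = rng.normal(size=40)
            hemi = np.array(["L"] * 20 + ["R"] * 20)
            ps.append(maps.compare_hemispheres(values, hemi)[1])
        # a uniform p-value under the null: mean 0.5, ~10% below 0.1
        assert abs(np.mean(ps) - 0.5) < 0.08
        assert 0.03 < np.mean(np.array(ps) < 0.1) < 0.2


class TestJointAnalysis:
    def test_correlated_pair_dominates_pc1(self):
        rng = np.random.default_rng(8)
        n = 200
        shared = rng.normal(size=n)
        X = np.column_stack([shared + 0.05 * rng.normal(size=n),
                             shared + 0.05 * rng.normal(size=n),
                             rng.normal(size=n), rng.normal(size=n)])
        fm = maps.FeatureMapSet(X=X, coords=rng.uniform(0, 10, (n, 2)),
                                feature_names=["a", "b", "c", "d"])
        pca = maps.joint_pca(fm, log_features=())
        w = np.abs(pca.weights[0])
        assert w[0] > 2 * w[2] and w[1] > 2 * w[3]

    def test_variance_fractions_invariant_to_feature_order(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(100, 4)) @ np.diag([3.0, 2.0, 1.0, 0.5])
        coords = rng.uniform(0, 5, (100, 2))
        fm1 = maps.FeatureMapSet(X=X, coords=coords,
                                 feature_names=list("abcd"))
        perm = [2, 0, 3, 1]
        fm2 = maps.FeatureMapSet(X=X[:, perm], coords=coords,
                                 feature_names=[list("abcd")[j] for j in perm])
        v1 = maps.joint_pca(fm1, log_features=()).variance_fractions
        v2 = maps.joint_pca(fm2, log_features=()).variance_fractions
        assert np.allclose(v1, v2, atol=1e-9)
        assert v1.sum() == pytest.approx(1.0)

    def test_constant_column_named_in_error(self):
        fm = maps.FeatureMapSet(
            X=np.column_stack([np.ones(30), np.arange(30.0)]),
            coords=np.random.default_rng(10).uniform(0, 5, (30, 2)),
            feature_names=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            maps.joint_pca(fm, log_features=())

    def test_cca_recovers_pure_ml_direction(self):
        rng = np.random.default_rng(11)
        coords = rng.uniform(0, 10, (60, 2))
        a, r = maps.cca_best_direction(coords[:, 0], coords)
        assert np.allclose(np.abs(a), [1.0, 0.0], atol=1e-6)
        assert r == pytest.approx(1.0)

    def test_cca_diagonal_direction_within_ten_degrees(self):
        rng = np.random.default_rng(12)
        coords = rng.uniform(0, 10, (80, 2))
        y = (coords[:, 0] + coords[:, 1]) / np.sqrt(2)
        y = y + 0.3 * rng.normal(size=80)
        a, _ = maps.cca_best_direction(y, coords)
        assert abs(maps.direction_angle_deg(a) - 45.0) <= 10.0

    def test_degenerate_coords_rejected(self):
        coords = np.tile([[1.0, 2.0]], (10, 1))
        with pytest.raises(ValueError):
            maps.cca_best_direction(np.arange(10.0), coords)

    def test_gradient_report_on_planted_elongated_array(self):
        # elongated electrode array whose long axis carries the gradients
        rng = np.random.default_rng(13)
        theta = np.deg2rad(30.0)
        u = np.array([np.cos(theta), np.sin(theta)])
        pos = rng.uniform(0, 25, 60)
        coords = pos[:, None] * u + rng.normal(0, 1.0, (60, 2))
        frac = (pos - pos.min()) / np.ptp(pos)
        jitter = lambda: 0.15 * rng.normal(size=60)  # noqa: E731
        X = np.column_stack([
            2.0 ** (12.0 - 3.0 * (frac + jitter())),   # bf decreasing
            40.0 + 120.0 * (frac + jitter()),          # latency increasing
            12.0 - 9.0 * (frac + jitter()),            # btm decreasing
            0.5 + 0.5 * (frac + jitter()),             # si increasing
            4.0 * (frac + jitter())])                  # ss increasing
        fm = maps.FeatureMapSet(X=X, coords=coords,
                                feature_names=["bf", "latency", "btm",
                                               "si", "ss"],
                                hemisphere=list(np.where(
                                    rng.random(60) < 0.5, "L", "R")))
        rep = maps.gradient_report(fm)
        signs = dict(zip(rep["feature"], np.sign(rep["r"])))
        assert signs == {"bf": -1, "latency": 1, "btm": -1, "si": 1, "ss": 1}
        assert (rep["p"] < 0.01).all()
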