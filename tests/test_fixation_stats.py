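"""Fixation-table pipeline: filtering, covariances, SPD metric, conversion."""

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import logm, sqrtm

from vergence import EyeGeometry, NoiseSpec, simulate
from vergence import fixation_stats as fs


def make_table(xy, durations=None, target_id=1, **overrides):
    """Minimal single-cluster fixation table around the given points."""
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    base = {
        "observer_id": 1,
        "distance_cm": 70.0,
        "condition": "BL",
        "repetition": 1,
        "target_id": target_id,
        "eye": "L",
        "t_start_ms": np.arange(n) * 1000.0,
        "duration_ms": durations if durations is not None else np.full(n, 500.0),
        "raw_x": xy[:, 0],
        "raw_y": xy[:, 1],
    }
    base.update(overrides)
    return pd.DataFrame(base)


def random_spd(rng, scale=1.0):
    A = rng.normal(size=(2, 2))
    return A @ A.T * scale + np.eye(2) * 0.05


class TestPreprocess:
    def test_duration_boundary_is_strict(self):
        t = make_table(np.zeros((3, 2)), durations=[90.0, 100.0, 150.0])
        res = fs.preprocess(t)
        assert res.n_short_removed == 1
        assert set(res.table["duration_ms"]) == {100.0, 150.0}

    def test_identical_points_remove_nothing(self):
        t = make_table(np.ones((10, 2)) * 3.3)
        res = fs.preprocess(t)
        assert res.n_outliers_removed == 0 and len(res.table) == 10

    def test_far_outlier_is_removed_exactly(self, rng):
        pts = rng.normal(0, 1.0, size=(100, 2))
        pts = np.vstack([pts, [8.0, 8.0]])  # ~ 8 pooled SDs out
        t = make_table(pts)
        res = fs.preprocess(t)
        assert res.n_outliers_removed == 1
        assert not ((res.table["raw_x"] == 8.0) & (res.table["raw_y"] == 8.0)).any()

    def test_small_cluster_skips_outlier_rule(self):
        t = make_table(np.array([[0.0, 0.0]]), durations=[500.0])
        res = fs.preprocess(t)
        assert res.n_clusters_skipped == 1 and len(res.table) == 1

    def test_duration_filter_idempotent(self):
        t = make_table(np.zeros((5, 2)), durations=[90, 100, 120, 99, 500])
        once = fs.preprocess(t)
        twice = fs.preprocess(once.table)
        assert twice.n_short_removed == 0


class TestCovariance:
    def test_collinear_points_give_degenerate_ellipse(self):
        pts = np.stack([np.linspace(0, 1, 10), np.zeros(10)], axis=1)
        c = fs.covariance(pts)
        assert c.semi_axes[1] == pytest.approx(0, abs=1e-9)
        assert c.angle == pytest.approx(0, abs=1e-9)

    def test_isotropic_sample_matches_chi2_ellipse(self, rng):
        pts = rng.normal(0, 1.0, size=(200_000, 2))
        c = fs.covariance(pts)
        assert c.semi_axes[0] == pytest.approx(np.sqrt(5.991), rel=0.02)
        assert c.semi_axes[1] == pytest.approx(np.sqrt(5.991), rel=0.02)

    def test_vertical_noise_dominant_tilts_ellipse_vertical(self, rng):
        pts = rng.normal(0, [0.3, 1.5], size=(5000, 2))
        c = fs.covariance(pts)
        assert abs(c.angle) == pytest.approx(np.pi / 2, abs=0.1)
        assert c.semi_axes[0] > c.semi_axes[1]

    def test_recovers_generating_covariance(self, rng):
        sigma = np.array([[1.0, 0.6], [0.6, 2.0]])
        pts = rng.multivariate_normal([0, 0], sigma, size=20_000)
        c = fs.covariance(pts)
        assert np.allclose(c.sigma, sigma, atol=5 * np.sqrt(2 / 20_000) * 2.0)

    def test_too_few_points_raise(self):
        with pytest.raises(ValueError):
            fs.covariance([[0.0, 0.0]])


class TestCovDistance:
    def test_identity_of_indiscernibles(self, rng):
        for _ in range(20):
            s = random_spd(rng)
            assert fs.cov_distance(s, s) == pytest.approx(0, abs=1e-9)

    def test_commuting_closed_form(self):
        assert fs.cov_distance(np.eye(2), 4 * np.eye(2)) == pytest.approx(
            np.sqrt(2) * np.log(4), abs=1e-12
        )

    def test_matches_scipy_matrix_log_oracle(self, rng):
        for _ in range(50):
            s1, s2 = random_spd(rng), random_spd(rng)
            inv_sqrt = np.linalg.inv(sqrtm(s1))
            ref = np.linalg.norm(logm(inv_sqrt @ s2 @ inv_sqrt), "fro")
            assert fs.cov_distance(s1, s2) == pytest.approx(ref, abs=1e-8)

    def test_metric_axioms_and_invariances(self, rng):
        for _ in range(200):
            s1, s2 = random_spd(rng), random_spd(rng)
            d = fs.cov_distance(s1, s2)
            assert d >= 0
            assert d == pytest.approx(fs.cov_distance(s2, s1), abs=1e-9)
            A = rng.normal(size=(2, 2))
            while abs(np.linalg.det(A)) < 0.1:
                A = rng.normal(size=(2, 2))
            assert fs.cov_distance(A @ s1 @ A.T, A @ s2 @ A.T) == pytest.approx(d, abs=1e-8)
            assert fs.cov_distance(np.linalg.inv(s1), np.linalg.inv(s2)) == pytest.approx(
                d, abs=1e-8
            )

    def test_non_spd_input_names_eigenvalue(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        with pytest.raises(ValueError, match="-1"):
            fs.cov_distance(bad, np.eye(2))


class TestMeanAndPairwise:
    def test_single_matrix_mean_is_itself(self):
        s = np.array([[2.0, 0.3], [0.3, 1.0]])
        assert np.allclose(fs.mean_covariance([s]), s)

    def test_arithmetic_mean_of_two_diagonals(self):
        m = fs.mean_covariance([np.diag([1.0, 0.01]), np.diag([0.01, 1.0])])
        assert np.allclose(m, np.diag([0.505, 0.505]))

    def test_empty_set_raises(self):
        with pytest.raises(ValueError):
            fs.mean_covariance([])

    def test_twelve_matrices_give_66_distances(self, rng):
        sigmas = {i: random_spd(rng) for i in range(12)}
        dd = fs.pairwise_distances(sigmas)
        assert len(dd.values) == 66 and len(dd.labels) == 66

    def test_identical_set_gives_zeros(self):
        dd = fs.pairwise_distances([np.eye(2)] * 5)
        assert np.allclose(dd.values, 0, atol=1e-9)

    def test_matches_brute_force_double_loop(self, rng):
        sigmas = [random_spd(rng) for _ in range(6)]
        dd = fs.pairwise_distances(sigmas)
        ref = {}
        for i in range(6):
            for j in range(6):
                if i < j:
                    ref[(i, j)] = fs.cov_distance(sigmas[i], sigmas[j])
        assert {lab: v for lab, v in zip(dd.labels, dd.values)} == pytest.approx(ref)


class TestKSCompare:
    def test_identical_distributions_give_zero_statistic(self):
        v = np.arange(10.0)
        r = fs.ks_compare(v, v)
        assert r.statistic == pytest.approx(0, abs=1e-12)
        assert not r.significant_at_0_05

    def test_disjoint_supports_give_unit_statistic(self):
        r = fs.ks_compare(np.arange(30.0), np.arange(30.0) + 100)
        assert r.statistic == pytest.approx(1.0)
        assert r.significant_at_0_05

    def test_matches_manual_cdf_sweep(self, rng):
        a = rng.normal(size=200)
        b = rng.normal(0.3, 1.2, size=150)
        grid = np.sort(np.concatenate([a, b]))
        cdf_a = np.searchsorted(np.sort(a), grid, side="right") / len(a)
        cdf_b = np.searchsorted(np.sort(b), grid, side="right") / len(b)
        assert fs.ks_compare(a, b).statistic == pytest.approx(
            np.abs(cdf_a - cdf_b).max(), abs=1e-12
        )

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            fs.ks_compare(np.array([]), np.arange(3.0))


class TestToDegrees:
    @staticmethod
    def ring_table(px_per_deg, n_per_target=30, jitter_deg=0.05, seed=0, distance=70.0):
        rng = np.random.default_rng(seed)
        frames = []
        for t in range(1, 13):
            ang = np.pi / 2 - (t - 1) * np.pi / 6
            center = 7.0 * np.array([np.cos(ang), np.sin(ang)])  # degrees
            pts = (center + rng.normal(0, jitter_deg, size=(n_per_target, 2))) * px_per_deg
            frames.append(make_table(pts, target_id=t, distance_cm=distance))
        return pd.concat(frames, ignore_index=True)

    def test_round_trip_recovers_scale(self):
        table = self.ring_table(px_per_deg=45.0)
        res = fs.to_degrees(table)
        assert res.deg_per_unit[70.0] == pytest.approx(1 / 45.0, rel=0.01)

    def test_identity_when_already_in_degrees(self):
        table = self.ring_table(px_per_deg=1.0)
        res = fs.to_degrees(table)
        assert res.deg_per_unit[70.0] == pytest.approx(1.0, rel=0.01)

    def test_invariant_to_translation(self):
        table = self.ring_table(px_per_deg=45.0)
        shifted = table.copy()
        shifted["raw_x"] += 500
        shifted["raw_y"] -= 123
        a = fs.to_degrees(table).deg_per_unit[70.0]
        b = fs.to_degrees(shifted).deg_per_unit[70.0]
        assert a == pytest.approx(b, rel=1e-12)

    def test_per_distance_scales(self):
        t = pd.concat(
            [self.ring_table(45.0, distance=70.0), self.ring_table(71.0, distance=110.0)],
            ignore_index=True,
        )
        res = fs.to_degrees(t)
        assert res.deg_per_unit[70.0] == pytest.approx(1 / 45.0, rel=0.01)
        assert res.deg_per_unit[110.0] == pytest.approx(1 / 71.0, rel=0.01)

    def test_missing_opposite_pairs_raise(self):
        table = make_table(np.random.default_rng(0).normal(size=(10, 2)), target_id=3)
        with pytest.raises(ValueError, match="opposite"):
            fs.to_degrees(table)


class TestResampleVergence:
    GEOM = EyeGeometry(interocular_distance=6.0, target=[0, 0, 70.0])

    def test_zero_covariance_gives_zero_error(self):
        res = fs.resample_vergence(np.zeros((2, 2)), 1.0, self.GEOM, n=50, rng=0)
        assert res.summary.mean_error == pytest.approx(0, abs=1e-9)

    def test_diagonal_covariance_matches_noise_spec_path(self):
        sh, sv = 0.8, 1.2
        cov = np.diag([sh**2, sv**2])
        # request the scale the covariance already has, so no rescaling occurs
        target_deg = 0.5 * (sh + sv)
        a = fs.resample_vergence(cov, target_deg, self.GEOM, n=2000, rng=9)
        b = simulate(self.GEOM, NoiseSpec.symmetric(sh, sv), n=2000, rng=9)
        assert np.allclose(a.points, b.points, equal_nan=True)

    def test_vertical_dominant_covariance_biases_toward_viewer(self):
        cov = np.array([[0.8, 0.1], [0.1, 1.3]])  # deg^2, vertical dominant
        res = fs.resample_vergence(cov, 1.0, self.GEOM, n=20_000, rng=11)
        assert res.summary.mean_point[2] < 70.0


class TestPerTargetCovariances:
    def test_groups_and_minimum_counts(self, rng):
        frames = []
        for cond, eye in [("BL", "L"), ("BR", "R")]:
            for t in range(1, 13):
                pts = rng.normal(size=(12, 2))
                frames.append(make_table(pts, target_id=t, condition=cond, eye=eye))
        table = pd.concat(frames, ignore_index=True)
        covs = fs.per_target_covariances(table)
        assert set(covs) == {(70.0, "BL"), (70.0, "BR")}
        assert set(covs[(70.0, "BL")]) == set(range(1, 13))
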