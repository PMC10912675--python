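import numpy as np
import pytest
from scipy import ndimage, stats

from myoscore.config import PipelineConfig
from myoscore.rft import (
    FWHM_PER_SIGMA,
    TrajectoryField,
    build_field,
    critical_threshold,
    ec_exceedance,
    estimate_fwhm,
    residual_field,
    rft_compare,
    smooth_trajectories,
    t_field,
)


def _field(data, label="g"):
    data = np.asarray(data, dtype=float)
    return TrajectoryField(label, data, np.arange(data.shape[1], dtype=float))


class TestSmoothing:
    def test_sigma_zero_is_identity(self, rng):
        f = _field(rng.normal(size=(5, 40)))
        out = smooth_trajectories(f, 0.0)
        np.testing.assert_array_equal(out.data, f.data)

    def test_constant_row_unchanged(self):
        f = _field(np.full((2, 30), 0.4))
        out = smooth_trajectories(f, 3.0)
        np.testing.assert_allclose(out.data, 0.4)

    def test_impulse_gives_gaussian_kernel(self):
        n = 41
        data = np.zeros((2, n))
        data[0, 20] = 1.0
        out = smooth_trajectories(_field(data), 2.0).data[0]
        # discrete Gaussian kernel, truncated at 4 sigma as in the smoother
        x = np.arange(-8.0, 9.0)
        kernel = np.exp(-(x**2) / 8.0)
        kernel /= kernel.sum()
        np.testing.assert_allclose(out[12:29], kernel, atol=1e-6)
        np.testing.assert_allclose(out[:12], 0.0, atol=1e-12)


class TestTField:
    def test_identical_groups_give_zero(self):
        a = _field(np.tile([0.2, 0.4, 0.6], (4, 1)))
        t, dof = t_field(a, a)
        np.testing.assert_array_equal(t, 0.0)
        assert dof == 6

    def test_single_node_matches_scipy_ttest(self, rng):
        xa = rng.normal(0, 1, (8, 1))
        xb = rng.normal(1, 1, (6, 1))
        t, dof = t_field(_field(xa), _field(xb))
        ref = stats.ttest_ind(xa[:, 0], xb[:, 0], equal_var=True)
        assert t[0] == pytest.approx(ref.statistic)
        assert dof == 12

    def test_mean_shift_t_magnitude(self, rng):
        n = 50
        tvals = []
        for _ in range(200):
            a = _field(rng.normal(0, 1, (n, 1)))
            b = _field(rng.normal(1, 1, (n, 1)))
            tvals.append(t_field(a, b)[0][0])
        expected = -1.0 / np.sqrt(2.0 / n)
        assert np.mean(tvals) == pytest.approx(expected, abs=3 * np.std(tvals) / np.sqrt(200))


class TestFWHM:
    def test_white_noise_fwhm(self, rng):
        f = estimate_fwhm(rng.standard_normal((5000, 101)))
        assert f == pytest.approx(np.sqrt(4 * np.log(2) / 2), rel=0.05)

    @pytest.mark.parametrize("sigma", [2.0, 4.0])
    def test_smoothed_noise_fwhm_recovery(self, rng, sigma):
        noise = ndimage.gaussian_filter1d(
            rng.standard_normal((2000, 101)), sigma, axis=1, mode="wrap"
        )
        f = estimate_fwhm(noise)
        assert f == pytest.approx(FWHM_PER_SIGMA * sigma, rel=0.10)

    def test_linear_residuals_give_large_fwhm(self):
        rows = np.outer([1.0, -1.0, 2.0], np.linspace(0, 1, 50))
        rows -= rows.mean(axis=0)
        assert estimate_fwhm(rows) > 1e3 or np.isinf(estimate_fwhm(rows))


class TestCriticalThreshold:
    def test_smooth_limit_approaches_t_quantile(self):
        # resel count -> 0: u* -> upper-alpha t quantile
        u = critical_threshold(dof=30, n_nodes=50, fwhm=1e9, alpha=0.05)
        assert u == pytest.approx(stats.t.ppf(0.95, 30), abs=1e-4)

    def test_monotone_in_node_count(self):
        us = [critical_threshold(38, n, 8.0, 0.05) for n in (10, 30, 73, 200)]
        assert all(a < b for a, b in zip(us, us[1:]))

    def test_always_at_least_pointwise_quantile(self, rng):
        for _ in range(20):
            dof = int(rng.integers(3, 60))
            nodes = int(rng.integers(5, 200))
            fwhm = float(rng.uniform(1.0, 20.0))
            alpha = float(rng.uniform(0.01, 0.2))
            u = critical_threshold(dof, nodes, fwhm, alpha)
            assert u >= stats.t.ppf(1 - alpha, dof) - 1e-9

    def test_root_reproduced_by_independent_bisection(self):
        dof, nodes, fwhm, alpha = 38, 73, 8.0, 0.05
        u = critical_threshold(dof, nodes, fwhm, alpha)
        # independent solver: plain bisection on the same exceedance probability
        lo, hi = 0.5, 20.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if ec_exceedance(mid, dof, nodes, fwhm) > alpha:
                lo = mid
            else:
                hi = mid
        assert u == pytest.approx(0.5 * (lo + hi), abs=1e-5)


class TestCompare:
    def test_identical_groups_not_rejected(self, rng):
        data = rng.normal(0.3, 0.05, (15, 80))
        a = TrajectoryField("a", data, np.linspace(4, 20, 80))
        b = TrajectoryField("b", data + rng.normal(0, 1e-4, data.shape), np.linspace(4, 20, 80))
        reports = rft_compare(a, b, [(5.0, 18.0)], PipelineConfig(), n_monte_carlo=100, seed=0)
        assert not reports[0].reject
        assert reports[0].set_level_p > 0.05

    def test_strong_separation_rejected_with_clusters(self, rng):
        t_nodes = np.linspace(4, 20, 80)
        a = TrajectoryField("a", rng.normal(0.2, 0.05, (20, 80)), t_nodes)
        shift = np.where(t_nodes > 12, 0.4, 0.0)
        b = TrajectoryField("b", rng.normal(0.2, 0.05, (20, 80)) + shift, t_nodes)
        reports = rft_compare(a, b, [(13.0, 19.0)], PipelineConfig(), n_monte_carlo=500, seed=0)
        r = reports[0]
        assert r.reject and len(r.clusters) >= 1
        assert min(c["p"] for c in r.clusters) < 0.05

    def test_group_order_flips_t_sign_only(self, rng):
        a = TrajectoryField("a", rng.normal(0.2, 0.05, (12, 60)), np.arange(60.0))
        b = TrajectoryField("b", rng.normal(0.5, 0.05, (12, 60)), np.arange(60.0))
        sa = smooth_trajectories(a, 2.0)
        sb = smooth_trajectories(b, 2.0)
        t_ab, _ = t_field(sa, sb)
        t_ba, _ = t_field(sb, sa)
        np.testing.assert_allclose(t_ab, -t_ba, atol=1e-12)
        rep_ab = rft_compare(a, b, [(5, 55)], n_monte_carlo=100, seed=1)[0]
        rep_ba = rft_compare(b, a, [(5, 55)], n_monte_carlo=100, seed=1)[0]
        assert rep_ab.reject == rep_ba.reject
        assert rep_ab.u_star == pytest.approx(rep_ba.u_star)

    def test_interval_outside_span_raises(self, rng):
        a = _field(rng.normal(size=(5, 20)))
        with pytest.raises(ValueError, match="outside"):
            rft_compare(a, a, [(100.0, 120.0)])


class TestBuildField:
    def test_build_field_from_trajectories(self, rng):
        from myoscore.classifier import ScoreTrajectory

        t = 4.0 + np.arange(50) / 12
        trajs = [
            ScoreTrajectory(f"c{i}", t, np.clip(rng.normal(0.4, 0.05, 50), 0, 1))
            for i in range(6)
        ]
        f = build_field(trajs, (5.0, 7.0), "grp")
        assert f.n_cells == 6
        assert np.all((f.t_nodes >= 5.0) & (f.t_nodes <= 7.0))

    def test_partial_coverage_excluded(self, rng):
        from myoscore.classifier import ScoreTrajectory

        t_full = 4.0 + np.arange(50) / 12
        t_short = 5.5 + np.arange(10) / 12
        trajs = [
            ScoreTrajectory("full1", t_full, np.full(50, 0.5)),
            ScoreTrajectory("full2", t_full, np.full(50, 0.6)),
            ScoreTrajectory("short", t_short, np.full(10, 0.7)),
        ]
        f = build_field(trajs, (5.0, 7.0))
        assert f.n_cells == 2
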