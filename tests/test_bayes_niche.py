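"""Bayesian niche model: closed forms, recovery, summaries, Welch test."""

import numpy as np
import pytest
from scipy import stats

from isoniche.bayes_niche import (
    bayes_layman,
    fit_bivariate_posterior,
    posterior_summary,
    sea_metrics,
    seac,
    standard_ellipse_area,
    welch_compare,
)
from isoniche.layman_metrics import PointSet2D

TRUE_MU = np.array([-28.0, 6.0])
TRUE_SIGMA = np.array([[2.0, 0.5], [0.5, 1.0]])


def _cloud(n, seed=0, mu=TRUE_MU, sigma=TRUE_SIGMA):
    rng = np.random.default_rng(seed)
    return PointSet2D(rng.multivariate_normal(mu, sigma, size=n), label="g")


class TestStandardEllipseArea:
    def test_identity_covariance_gives_pi(self):
        assert standard_ellipse_area(np.eye(2)) == pytest.approx(np.pi)

    def test_diagonal_and_rotation_invariance(self):
        assert standard_ellipse_area(np.diag([4.0, 1.0])) == pytest.approx(2 * np.pi)
        th = 0.7
        r = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        rotated = r @ np.diag([4.0, 1.0]) @ r.T
        assert standard_ellipse_area(rotated) == pytest.approx(2 * np.pi)

    def test_theoretical_coverage_is_one_minus_exp_half(self, rng):
        """The 1-SD standard ellipse covers 1 - e^(-1/2) ~ 39.35% of a
        bivariate-normal population (the '40% of the data' ellipse)."""
        pts = rng.multivariate_normal(TRUE_MU, TRUE_SIGMA, size=200_000)
        d = pts - TRUE_MU
        inv = np.linalg.inv(TRUE_SIGMA)
        inside = np.einsum("ni,ij,nj->n", d, inv, d) <= 1.0
        assert inside.mean() == pytest.approx(1 - np.exp(-0.5), abs=0.005)

    def test_seac_inflation_factor(self, rng):
        ps = _cloud(10, seed=4)
        cov = np.cov(ps.points.T, ddof=1)
        assert seac(ps) == pytest.approx(standard_ellipse_area(cov) * 9 / 8)
        big = _cloud(5000, seed=4)
        # correction vanishes as n grows
        assert seac(big) / standard_ellipse_area(np.cov(big.points.T, ddof=1)) == pytest.approx(
            1.0, abs=1e-3
        )


class TestPosteriorFit:
    def test_parameter_recovery_at_n200(self):
        n = 200
        ps = _cloud(n, seed=1)
        ens = fit_bivariate_posterior(ps, n_draws=4000, seed=9)
        mu_mean = ens.mu.mean(axis=0)
        mu_sd = ens.mu.std(axis=0)
        assert np.all(np.abs(mu_mean - TRUE_MU) < 3 * mu_sd)
        # the posterior mean of sigma must track the data: close to the
        # sample covariance, and within 3 data-sampling SEs of the truth
        sig_mean = ens.sigma.mean(axis=0)
        sample_cov = np.cov(ps.points.T, ddof=1)
        assert np.all(np.abs(sig_mean - sample_cov) <= 0.05 * np.abs(sample_cov) + 0.02)
        s11, s22, s12 = TRUE_SIGMA[0, 0], TRUE_SIGMA[1, 1], TRUE_SIGMA[0, 1]
        se = np.array(
            [[np.sqrt(2 / n) * s11, np.sqrt((s11 * s22 + s12**2) / n)],
             [np.sqrt((s11 * s22 + s12**2) / n), np.sqrt(2 / n) * s22]]
        )
        assert np.all(np.abs(sig_mean - TRUE_SIGMA) <= 3 * se)

    def test_same_seed_is_bitwise_identical(self):
        ps = _cloud(50, seed=2)
        a = fit_bivariate_posterior(ps, n_draws=500, seed=7)
        b = fit_bivariate_posterior(ps, n_draws=500, seed=7)
        assert np.array_equal(a.mu, b.mu) and np.array_equal(a.sigma, b.sigma)

    def test_doubling_draws_keeps_posterior_means_stable(self):
        ps = _cloud(100, seed=3)
        a = fit_bivariate_posterior(ps, n_draws=4000, seed=1)
        b = fit_bivariate_posterior(ps, n_draws=8000, seed=2)
        se = a.mu.std(axis=0) / np.sqrt(a.n_draws)
        assert np.all(np.abs(a.mu.mean(0) - b.mu.mean(0)) < 6 * se)

    def test_degenerate_axis_is_fatal(self):
        pts = np.column_stack([np.arange(5.0), np.ones(5)])
        with pytest.raises(ValueError, match="zero variance"):
            fit_bivariate_posterior(PointSet2D(pts), n_draws=100, seed=0)

    def test_n3_fit_warns_about_prior_influence(self):
        with pytest.warns(UserWarning, match="n=3"):
            fit_bivariate_posterior(_cloud(3, seed=5), n_draws=100, seed=0)

    def test_all_sigma_draws_are_spd(self):
        ens = fit_bivariate_posterior(_cloud(30, seed=6), n_draws=1000, seed=3)
        assert np.all(np.linalg.det(ens.sigma) > 0)
        assert np.allclose(ens.sigma, np.swapaxes(ens.sigma, 1, 2))


class TestSeaMetrics:
    def test_recovery_and_nesting_at_n50(self):
        true_sea = standard_ellipse_area(TRUE_SIGMA)
        ps = _cloud(50, seed=8)
        ens = fit_bivariate_posterior(ps, n_draws=4000, seed=11)
        summ = sea_metrics(ps, ens)
        lo95, hi95 = summ.credible[95]
        assert lo95 <= true_sea <= hi95
        # nesting 50 in 75 in 95
        for small, big in ((50, 75), (75, 95)):
            assert summ.credible[big][0] <= summ.credible[small][0]
            assert summ.credible[small][1] <= summ.credible[big][1]
        assert summ.sea_c >= summ.sea_ml  # (n-1)/(n-2) inflation over ML area
        # SEAc is noisy per dataset; its replicate mean lands within 15%
        seacs = [seac(_cloud(50, seed=800 + r)) for r in range(15)]
        assert np.mean(seacs) == pytest.approx(true_sea, rel=0.15)

    def test_posterior_mode_converges_with_n(self):
        """Relative error of the SEA.B mode shrinks in expectation as the
        sample grows (checked over 20 replicates at n = 10, 50, 200)."""
        true_sea = standard_ellipse_area(TRUE_SIGMA)
        mean_err = []
        for n in (10, 50, 200):
            errs = []
            for rep in range(20):
                ps = _cloud(n, seed=1000 * n + rep)
                ens = fit_bivariate_posterior(ps, n_draws=1500, seed=rep)
                summ = sea_metrics(ps, ens)
                errs.append(abs(summ.sea_b_mode - true_sea) / true_sea)
            mean_err.append(np.mean(errs))
        assert mean_err[0] > mean_err[1] > mean_err[2]


class TestPosteriorSummary:
    def test_symmetric_density_mode_near_median(self, rng):
        draws = rng.normal(3.0, 1.0, size=20_000)
        mode, _ = posterior_summary(draws)
        assert mode == pytest.approx(np.median(draws), abs=0.1)

    def test_constant_draws_give_zero_width_intervals(self):
        mode, cred = posterior_summary(np.full(2000, 4.2))
        assert mode == 4.2
        assert all(lo == hi == 4.2 for lo, hi in cred.values())

    def test_hdi_matches_grid_search_oracle_on_lognormal(self, rng):
        draws = rng.lognormal(0.0, 0.5, size=40_000)
        _, cred = posterior_summary(draws, levels=(95,))
        lo, hi = cred[95]
        # oracle: exhaustive scan of every contiguous 95% window
        s = np.sort(draws)
        k = int(np.ceil(0.95 * s.size))
        widths = s[k - 1:] - s[: s.size - k + 1]
        i = int(np.argmin(widths))
        assert lo == pytest.approx(s[i], abs=0.02)
        assert hi == pytest.approx(s[i + k - 1], abs=0.05)
        # and the sample HDI approximates the analytic lognormal HDI
        dist = stats.lognorm(0.5)
        grid = np.linspace(1e-4, dist.ppf(0.9995), 20_000)
        pdf = dist.pdf(grid)
        order = np.argsort(pdf)[::-1]
        mass = np.cumsum(pdf[order]) * (grid[1] - grid[0])
        sel = grid[order[: np.searchsorted(mass, 0.95) + 1]]
        assert lo == pytest.approx(sel.min(), abs=0.05)
        assert hi == pytest.approx(sel.max(), rel=0.05)

    def test_few_draws_warn(self):
        with pytest.warns(UserWarning, match="fewer than 1000"):
            posterior_summary(np.random.default_rng(0).normal(size=200))


class TestBayesLayman:
    def _tight_ensembles(self, centers, n_draws=1200, scale=1e-3):
        out = []
        rng = np.random.default_rng(0)
        for i, c in enumerate(centers):
            pts = rng.multivariate_normal(c, scale * np.eye(2), size=400)
            out.append(
                fit_bivariate_posterior(PointSet2D(pts, label=f"g{i}"), n_draws=n_draws, seed=i)
            )
        return out

    def test_concentrated_groups_recover_diamond_geometry(self):
        diamond = [(1, 0), (-1, 0), (0, 1), (0, -1)]
        res = bayes_layman({"c": self._tight_ensembles(diamond)})["c"]
        assert res.modes["CD"] == pytest.approx(1.0, abs=0.01)
        assert res.modes["TA"] == pytest.approx(2.0, abs=0.02)
        assert all(np.all(v >= 0) for v in res.metric_draws.values())

    def test_two_group_community_has_zero_hull_area(self):
        res = bayes_layman({"c": self._tight_ensembles([(0, 0), (3, 4)])})["c"]
        assert np.all(res.metric_draws["TA"] == 0.0)
        assert res.modes["MNND"] == pytest.approx(5.0, abs=0.02)

    def test_scaled_community_has_quadrupled_hull_area(self):
        base = [(0, 0), (2, 0), (1, 2)]
        scaled = [(0, 0), (4, 0), (2, 4)]
        res = bayes_layman(
            {"A": self._tight_ensembles(scaled), "B": self._tight_ensembles(base)}
        )
        ratio = res["A"].modes["TA"] / res["B"].modes["TA"]
        assert ratio == pytest.approx(4.0, abs=0.1)

    def test_mismatched_draw_counts_fatal(self):
        a = self._tight_ensembles([(0, 0), (1, 1)], n_draws=1000)
        b = self._tight_ensembles([(2, 2)], n_draws=1500)
        with pytest.raises(ValueError, match="n_draws"):
            bayes_layman({"c": a + b})


class TestWelchCompare:
    def test_identical_samples(self):
        res = welch_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["t"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        a = np.array([1.0, 2, 3, 4, 5])
        b = np.array([2.0, 3, 4, 5, 6])
        # hand calculation: se = sqrt(2.5/5 + 2.5/5) = 1, t = -1, dof = 8
        res = welch_compare(a, b)
        assert res["t"] == pytest.approx(-1.0)
        assert res["dof"] == pytest.approx(8.0)
        assert res["ci_low"] == pytest.approx(-1 - stats.t.ppf(0.975, 8), abs=1e-9)

    def test_antisymmetry(self, rng):
        a, b = rng.normal(size=20), rng.normal(1.0, 2.0, size=15)
        r1, r2 = welch_compare(a, b), welch_compare(b, a)
        assert r1["t"] == pytest.approx(-r2["t"])
        assert r1["p"] == pytest.approx(r2["p"])

    def test_zero_variance_both_fatal(self):
        with pytest.raises(ValueError):
            welch_compare([1.0, 1.0], [2.0, 2.0])
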