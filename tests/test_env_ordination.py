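"""Scaling, dissimilarities, BIOENV, dbRDA and permutation tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from isoniche.env_ordination import (
    DissimilarityMatrix,
    EnvMatrix,
    bioenv_search,
    dbrda_fit,
    dissimilarity,
    permutation_test,
    zscore_env,
)


def _env(values, names=None, sites=None):
    values = np.asarray(values, float)
    names = names or [f"v{j}" for j in range(values.shape[1])]
    sites = sites or [str(i) for i in range(values.shape[0])]
    return EnvMatrix(sites=sites, variables=names, values=values)


class TestZscore:
    def test_simple_column(self):
        out = zscore_env(_env([[1.0], [2.0], [3.0]]))
        assert np.allclose(out.values.ravel(), [-1, 0, 1])

    def test_idempotent_and_contract(self, rng):
        raw = _env(rng.normal(2, 5, size=(9, 4)))
        once = zscore_env(raw)
        assert np.allclose(once.values.mean(0), 0, atol=1e-12)
        assert np.allclose(once.values.std(0, ddof=1), 1)
        twice = zscore_env(once)
        assert np.allclose(once.values, twice.values)

    def test_constant_column_named_in_error(self):
        with pytest.raises(ValueError, match="v1"):
            zscore_env(_env([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]]))


class TestDissimilarity:
    def test_identical_rows_zero(self):
        d = dissimilarity(np.ones((3, 2)) * 4.0, metric="euclidean")
        assert np.allclose(d.d, 0.0)

    def test_whitening_identity_for_uncorrelated_unit_columns(self, rng):
        x = rng.normal(size=(400, 2))
        # force exactly unit variance, zero correlation
        x = (x - x.mean(0)) / x.std(0, ddof=1)
        q, _ = np.linalg.qr(x)
        x = q * np.sqrt(len(x) - 1)  # orthonormal columns scaled to unit variance
        de = dissimilarity(x, metric="euclidean").d
        dm = dissimilarity(x, metric="mahalanobis").d
        assert np.allclose(de, dm, atol=1e-8)

    def test_mahalanobis_matches_direct_formula(self, rng):
        x = rng.normal(size=(10, 3))
        d = dissimilarity(x, metric="mahalanobis").d
        sinv = np.linalg.inv(np.cov(x.T, ddof=1))
        for i in range(10):
            for j in range(10):
                ref = np.sqrt((x[i] - x[j]) @ sinv @ (x[i] - x[j]))
                assert d[i, j] == pytest.approx(ref, abs=1e-9)

    def test_singular_covariance_warns_by_default_and_fatal_in_strict(self, rng):
        x = rng.normal(size=(4, 6))  # more metrics than sites
        with pytest.warns(UserWarning, match="pseudo-inverse"):
            dissimilarity(x, metric="mahalanobis")
        with pytest.raises(ValueError, match="singular"):
            dissimilarity(x, metric="mahalanobis", strict=True)


class TestBioenv:
    def test_planted_subset_recovered_with_perfect_rho(self, rng):
        env = zscore_env(_env(rng.normal(size=(10, 5)), names=list("ABCDE")))
        resp = dissimilarity(env.to_frame()[["B", "D"]], metric="euclidean")
        res = bioenv_search(env, resp)
        assert res.best_subset == ("B", "D")
        assert res.rho == pytest.approx(1.0)
        assert res.rho == max(r for _, r in res.all_subsets)

    def test_single_variable_self_correlation(self, rng):
        env = zscore_env(_env(rng.normal(size=(8, 1)), names=["A"]))
        resp = dissimilarity(env.to_frame(), metric="euclidean")
        res = bioenv_search(env, resp)
        assert res.rho == pytest.approx(1.0)

    def test_null_response_has_near_zero_mean_best_rho(self):
        """Response independent of the environment: over many seeds the
        mean Spearman rho of single-variable subsets is ~0."""
        rhos = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            env = zscore_env(_env(rng.normal(size=(8, 1)), names=["A"]))
            noise = rng.normal(size=(8, 3))
            resp = dissimilarity(noise, metric="euclidean")
            rhos.append(bioenv_search(env, resp).rho)
        # each rho has SD ~ 1/sqrt(n_pairs-1) ~ 0.2; mean over 100 ~ 0.02
        assert abs(np.mean(rhos)) < 0.06

    def test_spearman_invariant_to_monotone_transform_of_response(self, rng):
        env = zscore_env(_env(rng.normal(size=(9, 3))))
        base = dissimilarity(rng.normal(size=(9, 2)), metric="euclidean")
        transformed = DissimilarityMatrix(base.sites, np.sqrt(base.d), metric="euclidean")
        r1 = bioenv_search(env, base)
        r2 = bioenv_search(env, transformed)
        assert r1.best_subset == r2.best_subset
        assert r1.rho == pytest.approx(r2.rho)

    def test_site_mismatch_fatal(self, rng):
        env = zscore_env(_env(rng.normal(size=(6, 2))))
        resp = dissimilarity(rng.normal(size=(6, 2)), sites=list("abcdef"))
        with pytest.raises(ValueError, match="site"):
            bioenv_search(env, resp)


class TestDbrda:
    def test_full_rank_constraints_explain_everything(self, rng):
        data = rng.normal(size=(9, 3))
        resp = dissimilarity(data, metric="euclidean")
        cons = _env(data)
        fit = dbrda_fit(resp, cons)
        assert fit.constrained_inertia / fit.total_inertia == pytest.approx(1.0, abs=1e-8)

    def test_orthogonal_constraints_explain_nothing(self, rng):
        # data varies only in the first column-space direction; the
        # constraint is constructed orthogonal to the site scores
        n = 8
        u = np.linspace(-1, 1, n)  # centered gradient
        data = u[:, None] @ np.array([[1.0, 2.0]])
        resp = dissimilarity(data, metric="euclidean")
        w = u**2
        w -= w.mean()
        w -= (w @ u) / (u @ u) * u  # orthogonal to the data's only direction
        fit = dbrda_fit(resp, _env(w[:, None], names=["orth"]))
        assert fit.constrained_inertia / fit.total_inertia == pytest.approx(0.0, abs=1e-8)

    def test_matches_classical_rda_oracle_on_euclidean_input(self, rng):
        """dbRDA of a Euclidean distance equals RDA: regress the (centered)
        coordinates on the constraints, then PCA the fitted values."""
        n = 12
        y = rng.normal(size=(n, 4))
        x = rng.normal(size=(n, 3))
        resp = dissimilarity(y, metric="euclidean")
        fit = dbrda_fit(resp, _env(x))
        yc = y - y.mean(0)
        xc = x - x.mean(0)
        fitted = xc @ np.linalg.pinv(xc.T @ xc) @ xc.T @ yc
        oracle = np.sort(np.linalg.eigvalsh(fitted.T @ fitted))[::-1]
        k = fit.constrained_eigenvalues.size
        assert np.allclose(fit.constrained_eigenvalues, oracle[:k], atol=1e-8)
        # residual part likewise
        resid = yc - fitted
        oracle_r = np.sort(np.linalg.eigvalsh(resid.T @ resid))[::-1]
        kr = fit.unconstrained_eigenvalues.size
        assert np.allclose(fit.unconstrained_eigenvalues, oracle_r[:kr], atol=1e-8)

    def test_proportions_sum_to_one(self, rng):
        y = rng.normal(size=(10, 3))
        fit = dbrda_fit(dissimilarity(y, metric="euclidean"), _env(rng.normal(size=(10, 2))))
        assert fit.prop_explained.sum() == pytest.approx(1.0, abs=1e-8)

    def test_needs_more_sites_than_constraints(self, rng):
        y = rng.normal(size=(4, 2))
        with pytest.raises(ValueError, match="more sites"):
            dbrda_fit(dissimilarity(y, metric="euclidean"), _env(rng.normal(size=(4, 4))))


class TestPermutationTest:
    def test_strong_planted_gradient_is_significant(self, rng):
        n = 20
        grad = np.linspace(0, 1, n)[:, None]
        y = grad @ np.array([[3.0, 1.0]]) + 0.05 * rng.normal(size=(n, 2))
        resp = dissimilarity(y, metric="euclidean")
        p = permutation_test(resp, _env(grad, names=["g"]), n_perm=999, seed=5).iloc[0]["p"]
        assert p <= 0.01

    def test_reproducible_under_seed(self, rng):
        y = rng.normal(size=(10, 2))
        x = _env(rng.normal(size=(10, 2)))
        resp = dissimilarity(y, metric="euclidean")
        p1 = permutation_test(resp, x, n_perm=99, seed=3)
        p2 = permutation_test(resp, x, n_perm=99, seed=3)
        pd.testing.assert_frame_equal(p1, p2)

    def test_relabeling_sites_leaves_p_unchanged(self, rng):
        y = rng.normal(size=(10, 2))
        x = rng.normal(size=(10, 2))
        resp = dissimilarity(y, metric="euclidean")
        p1 = permutation_test(resp, _env(x), n_perm=199, seed=7).iloc[0]["p"]
        resp2 = DissimilarityMatrix([f"t{i}" for i in range(10)], resp.d)
        env2 = EnvMatrix(resp2.sites, ["v0", "v1"], x)
        p2 = permutation_test(resp2, env2, n_perm=199, seed=7).iloc[0]["p"]
        assert p1 == p2

    def test_type_i_error_near_nominal(self):
        """Pure-noise constraints: rejection rate at alpha = 0.05 over 200
        null replicates stays inside the binomial 99% band."""
        rejections = 0
        n_rep = 200
        for rep in range(n_rep):
            rng = np.random.default_rng(10_000 + rep)
            y = rng.normal(size=(10, 2))
            x = rng.normal(size=(10, 2))
            resp = dissimilarity(y, metric="euclidean")
            p = permutation_test(resp, _env(x), n_perm=99, seed=rep).iloc[0]["p"]
            rejections += p <= 0.05
        lo, hi = stats.binom.interval(0.99, n_rep, 0.05)
        assert lo <= rejections <= hi

    def test_terms_and_axes_scopes_return_one_row_each(self, rng):
        y = rng.normal(size=(12, 3))
        x = _env(rng.normal(size=(12, 2)), names=["a", "b"])
        resp = dissimilarity(y, metric="euclidean")
        terms = permutation_test(resp, x, n_perm=99, seed=1, scope="terms")
        assert list(terms["term"]) == ["a", "b"]
        axes = permutation_test(resp, x, n_perm=99, seed=1, scope="axes")
        assert list(axes["term"]) == ["dbRDA1", "dbRDA2"]
        assert ((terms["p"] > 0) & (terms["p"] <= 1)).all()
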