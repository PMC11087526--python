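"""Confirmatory factor analysis: discrepancy, fit indices, factor scores."""

import numpy as np
import pandas as pd
import pytest

import cantokit as ck
from cantokit.cfa import LatentModelSpec, fit_indices


def exact_cov_data(sigma, n, rng):
    """Data whose sample covariance equals ``sigma`` exactly (whitened draw)."""
    p = sigma.shape[0]
    z = rng.normal(size=(n, p))
    z -= z.mean(axis=0)
    # whiten the empirical covariance, then color with the target
    cov = np.cov(z, rowvar=False, ddof=1)
    w = np.linalg.cholesky(np.linalg.inv(cov))
    return (z @ w) @ np.linalg.cholesky(sigma).T


def two_factor_spec(n_ind=6):
    half = n_ind // 2
    return LatentModelSpec(loadings={
        "F1": [f"x{i}" for i in range(half)],
        "F2": [f"x{i}" for i in range(half, n_ind)],
    })


def two_factor_sigma(n_ind=6, loading=0.8, phi12=0.3):
    lam = np.zeros((n_ind, 2))
    lam[: n_ind // 2, 0] = loading
    lam[n_ind // 2:, 1] = loading
    phi = np.array([[1.0, phi12], [phi12, 1.0]])
    theta = np.diag(np.full(n_ind, 1 - loading**2))
    return lam @ phi @ lam.T + theta


class TestFitCfa:
    def test_saturated_truth_limit(self, rng):
        """Data generated exactly from the model covariance: perfect fit."""
        sigma = two_factor_sigma()
        data = exact_cov_data(sigma, 500, rng)
        df = pd.DataFrame(data, columns=[f"x{i}" for i in range(6)])
        fit = ck.fit_cfa(df, two_factor_spec(), n_restarts=3)
        assert fit.fmin == pytest.approx(0.0, abs=1e-5)
        assert fit.rmsea == pytest.approx(0.0, abs=1e-3)
        assert fit.cfi == pytest.approx(1.0, abs=1e-3)
        assert fit.srmr == pytest.approx(0.0, abs=1e-3)

    def test_parameter_recovery(self, rng):
        sigma = two_factor_sigma(loading=0.7, phi12=0.4)
        data = rng.multivariate_normal(np.zeros(6), sigma, size=4000)
        df = pd.DataFrame(data, columns=[f"x{i}" for i in range(6)])
        fit = ck.fit_cfa(df, two_factor_spec(), n_restarts=2)
        std = fit.standardized_loadings
        assert np.allclose(std.loc[["x0", "x1", "x2"], "F1"], 0.7, atol=0.05)
        assert np.allclose(std.loc[["x3", "x4", "x5"], "F2"], 0.7, atol=0.05)
        assert fit.latent_corr.loc["F1", "F2"] == pytest.approx(0.4, abs=0.07)

    def test_indicator_order_invariance(self, rng):
        sigma = two_factor_sigma()
        data = rng.multivariate_normal(np.zeros(6), sigma, size=400)
        cols = [f"x{i}" for i in range(6)]
        df = pd.DataFrame(data, columns=cols)
        f1 = ck.fit_cfa(df, two_factor_spec(), n_restarts=2)
        shuffled = df[cols[::-1]]
        f2 = ck.fit_cfa(shuffled, two_factor_spec(), n_restarts=2)
        assert f1.fmin == pytest.approx(f2.fmin, abs=1e-6)

    def test_extra_free_parameter_never_hurts(self, rng):
        sigma = two_factor_sigma()
        data = rng.multivariate_normal(np.zeros(6), sigma, size=300)
        df = pd.DataFrame(data, columns=[f"x{i}" for i in range(6)])
        base = ck.fit_cfa(df, two_factor_spec(), n_restarts=3)
        richer_spec = LatentModelSpec(
            loadings=two_factor_spec().loadings,
            residual_covariances=[("x0", "x3")],
        )
        richer = ck.fit_cfa(df, richer_spec, n_restarts=3)
        assert base.fmin >= 0.0
        assert richer.fmin <= base.fmin + 1e-6
        assert richer.df == base.df - 1

    def test_nonconvergent_n_too_small(self, rng):
        df = pd.DataFrame(rng.normal(size=(10, 6)), columns=[f"x{i}" for i in range(6)])
        with pytest.raises(ValueError, match="free parameters"):
            ck.fit_cfa(df, two_factor_spec())


class TestFitIndices:
    def test_plugin_arithmetic(self):
        out = fit_indices(200.0, 100, 101, 1100.0, 120)
        assert out["rmsea"] == pytest.approx(0.1, abs=1e-12)
        # CFI = 1 - (200-100)/(1100-120)
        assert out["cfi"] == pytest.approx(1.0 - 100.0 / 980.0, abs=1e-12)

    def test_chi2_equal_df_gives_zero_rmsea(self):
        out = fit_indices(50.0, 50, 200, 500.0, 60)
        assert out["rmsea"] == 0.0

    def test_srmr_zero_when_matrices_match(self, rng):
        s = two_factor_sigma()
        out = fit_indices(10.0, 5, 100, 100.0, 15, sample_cov=s, implied_cov=s)
        assert out["srmr"] == 0.0

    def test_df_zero_warns(self):
        with pytest.warns(UserWarning, match="saturated"):
            out = fit_indices(5.0, 0, 100, 50.0, 10)
        assert out["rmsea"] == 0.0

    def test_rmsea_ci_brackets_point_estimate(self):
        out = fit_indices(200.0, 100, 101, 1100.0, 120)
        lo, hi = out["rmsea_ci"]
        assert lo <= out["rmsea"] <= hi


class TestFactorScores:
    def test_mean_vector_scores_zero(self, rng):
        sigma = two_factor_sigma()
        data = rng.multivariate_normal(np.zeros(6), sigma, size=300)
        df = pd.DataFrame(data, columns=[f"x{i}" for i in range(6)])
        fit = ck.fit_cfa(df, two_factor_spec(), n_restarts=2)
        at_mean = pd.DataFrame([fit.means], columns=fit.means.index)
        scores = ck.factor_scores(fit, at_mean)
        assert np.allclose(scores.to_numpy(), 0.0, atol=1e-10)

    def test_single_indicator_latent_is_standardized_passthrough(self, rng):
        spec = LatentModelSpec(loadings={"F1": ["x0", "x1", "x2"], "Solo": ["x3"]})
        lam = np.array([[0.8, 0], [0.8, 0], [0.8, 0], [0, 1.0]])
        phi = np.array([[1.0, 0.2], [0.2, 1.0]])
        theta = np.diag([0.36, 0.36, 0.36, 0.0])
        sigma = lam @ phi @ lam.T + theta
        data = rng.multivariate_normal(np.zeros(4), sigma, size=500)
        df = pd.DataFrame(data, columns=["x0", "x1", "x2", "x3"])
        fit = ck.fit_cfa(df, spec, n_restarts=2)
        scores = ck.factor_scores(fit, df)
        standardized = (df["x3"] - df["x3"].mean()) / df["x3"].std(ddof=1)
        r = np.corrcoef(scores["Solo"], standardized)[0, 1]
        assert r > 0.999

    def test_score_truth_correlation(self, rng):
        """At loading 0.7 with 6 indicators, scores track the true latent."""
        n = 2000
        eta = rng.normal(size=n)
        x = 0.7 * eta[:, None] + rng.normal(0, np.sqrt(1 - 0.49), size=(n, 6))
        df = pd.DataFrame(x, columns=[f"x{i}" for i in range(6)])
        spec = LatentModelSpec(loadings={"F": [f"x{i}" for i in range(6)]})
        fit = ck.fit_cfa(df, spec, n_restarts=2)
        scores = ck.factor_scores(fit, df)
        assert abs(np.corrcoef(scores["F"], eta)[0, 1]) > 0.8

    def test_dropping_one_indicator_keeps_scores_stable(self, rng):
        """Reliability-style robustness: a 5-of-6-indicator model scores alike."""
        sigma = two_factor_sigma(n_ind=6, loading=0.75)
        data = rng.multivariate_normal(np.zeros(6), sigma, size=800)
        df = pd.DataFrame(data, columns=[f"x{i}" for i in range(6)])
        full = ck.fit_cfa(df, two_factor_spec(), n_restarts=2)
        reduced_spec = LatentModelSpec(loadings={
            "F1": ["x0", "x1"], "F2": ["x3", "x4", "x5"],
        })
        reduced = ck.fit_cfa(df, reduced_spec, n_restarts=2)
        s_full = ck.factor_scores(full, df)
        s_red = ck.factor_scores(reduced, df)
        for col in ("F1", "F2"):
            assert abs(np.corrcoef(s_full[col], s_red[col])[0, 1]) > 0.9
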