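"""Maximum-likelihood confirmatory factor analysis for latent song dimensions.

The measurement model is the classic linear factor structure

    x = Lambda eta + eps,   Sigma(theta) = Lambda Phi Lambda' + Theta

with each indicator loading on exactly one latent dimension (five, in the
default musical model: Articulation, Tension, Ornamentation, Rhythm,
Dynamics), freely correlating latents (Phi a correlation matrix), diagonal
residual variances plus an explicit list of extra residual covariances.
Latents are identified by unit variance, so the solution is completely
standardized on the latent side.  The ML discrepancy

    F_ML = ln|Sigma| - ln|S| + tr(S Sigma^-1) - p

is minimized by quasi-Newton iteration with log-parameterized variances and a
Cholesky parameterization of Phi.  Ordinal 0-1 indicators are treated as
continuous (ML on Pearson covariances).

A latent with a single indicator is handled as a passthrough: its loading is
fixed to the indicator's standard deviation and the residual variance to
zero, so the latent *is* the standardized indicator.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "LatentModelSpec",
    "CfaFit",
    "ConfirmatoryFactorAnalysis",
    "fit_cfa",
    "fit_indices",
    "factor_scores",
]


@dataclass
class LatentModelSpec:
    """Indicator->latent map plus extra residual covariances."""

    loadings: dict[str, list[str]]  # latent name -> indicator names
    residual_covariances: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        seen: dict[str, str] = {}
        for latent, inds in self.loadings.items():
            if not inds:
                raise ValueError(f"latent {latent!r} has no indicators")
            for ind in inds:
                if ind in seen:
                    raise ValueError(f"indicator {ind!r} mapped to both {seen[ind]!r} and {latent!r}")
                seen[ind] = latent
        self.residual_covariances = [tuple(p) for p in self.residual_covariances]
        for a, b in self.residual_covariances:
            if a == b:
                raise ValueError(f"residual covariance pair ({a!r}, {b!r}) must be distinct")
            if a not in seen or b not in seen:
                raise ValueError(f"residual covariance names unknown indicator in ({a!r}, {b!r})")

    @property
    def latent_names(self) -> list[str]:
        return list(self.loadings)

    @property
    def indicator_names(self) -> list[str]:
        return [ind for inds in self.loadings.values() for ind in inds]

    @classmethod
    def from_yaml(cls, path) -> "LatentModelSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            loadings={k: list(v) for k, v in raw["loadings"].items()},
            residual_covariances=[tuple(p) for p in raw.get("residual_covariances", [])],
        )

    def to_yaml(self, path) -> None:
        raw = {
            "loadings": {k: list(v) for k, v in self.loadings.items()},
            "residual_covariances": [list(p) for p in self.residual_covariances],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh)


@dataclass
class CfaFit:
    """Converged (or flagged) CFA solution with fit statistics."""

    spec: LatentModelSpec
    loadings: pd.DataFrame          # indicator x latent, raw metric
    latent_corr: pd.DataFrame       # latent x latent
    residual_cov: pd.DataFrame      # indicator x indicator (Theta)
    fmin: float
    chi2: float
    df: int
    n_obs: int
    rmsea: float
    rmsea_ci: tuple[float, float]
    srmr: float
    cfi: float
    converged: bool
    means: pd.Series                # indicator sample means (for scoring)
    sample_cov: pd.DataFrame

    @property
    def implied_cov(self) -> pd.DataFrame:
        lam = self.loadings.to_numpy()
        phi = self.latent_corr.to_numpy()
        theta = self.residual_cov.to_numpy()
        sigma = lam @ phi @ lam.T + theta
        names = self.loadings.index
        return pd.DataFrame(sigma, index=names, columns=names)

    @property
    def standardized_loadings(self) -> pd.DataFrame:
        """Completely standardized loadings: lambda / sd(implied indicator)."""
        sd = np.sqrt(np.diag(self.implied_cov.to_numpy()))
        return self.loadings.div(sd, axis=0)

    def to_json(self, path) -> None:
        payload = {
            "loadings": self.loadings.to_dict(),
            "latent_corr": self.latent_corr.to_dict(),
            "residual_cov": self.residual_cov.to_dict(),
            "fmin": self.fmin,
            "chi2": self.chi2,
            "df": self.df,
            "n_obs": self.n_obs,
            "rmsea": self.rmsea,
            "rmsea_ci": list(self.rmsea_ci),
            "srmr": self.srmr,
            "cfi": self.cfi,
            "converged": self.converged,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _rmsea_ci(chi2: float, df: int, n_obs: int, level: float = 0.90) -> tuple[float, float]:
    """Noncentral-chi2 inversion interval for RMSEA."""
    if df == 0 or chi2 <= 0:
        return (0.0, 0.0)
    alpha = (1.0 - level) / 2.0
    scale = df * (n_obs - 1)

    def bound(target_cdf: float) -> float:
        # find noncentrality nc with ncx2.cdf(chi2, df, nc) = target_cdf
        if stats.chi2.cdf(chi2, df) < target_cdf:  # nc=0 already below target
            return 0.0
        lo, hi = 0.0, max(4.0 * chi2, 10.0)
        while stats.ncx2.cdf(chi2, df, hi) > target_cdf:
            hi *= 2.0
            if hi > 1e8:
                break
        nc = optimize.brentq(lambda x: stats.ncx2.cdf(chi2, df, x) - target_cdf, lo, hi)
        return nc

    nc_lo = bound(1.0 - alpha)
    nc_hi = bound(alpha)
    return (float(np.sqrt(max(nc_lo, 0.0) / scale)), float(np.sqrt(max(nc_hi, 0.0) / scale)))


def fit_indices(
    chi2: float,
    df: int,
    n_obs: int,
    chi2_baseline: float,
    df_baseline: int,
    sample_cov: np.ndarray | None = None,
    implied_cov: np.ndarray | None = None,
) -> dict:
    """RMSEA (+90% CI), CFI, and (when both covariances are given) SRMR.

    RMSEA = sqrt(max(chi2 - df, 0) / (df (N-1))); CFI compares the excess
    noncentrality of the model with that of the independence baseline; SRMR
    is the root mean square of correlation-metric residuals of S vs Sigma
    over the p(p+1)/2 unique elements.
    """
    if df == 0:
        warnings.warn("df = 0: RMSEA defined as 0 for the saturated model")
        rmsea = 0.0
        ci = (0.0, 0.0)
    else:
        rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * (n_obs - 1))))
        ci = _rmsea_ci(chi2, df, n_obs)
    denom = max(chi2_baseline - df_baseline, chi2 - df, 0.0)
    cfi = 1.0 if denom == 0 else 1.0 - max(chi2 - df, 0.0) / denom
    out = {"rmsea": rmsea, "rmsea_ci": ci, "cfi": float(cfi)}
    if sample_cov is not None and implied_cov is not None:
        s = np.asarray(sample_cov, dtype=float)
        sig = np.asarray(implied_cov, dtype=float)
        ds = np.sqrt(np.diag(s))
        dsig = np.sqrt(np.diag(sig))
        rs = s / np.outer(ds, ds)
        rsig = sig / np.outer(dsig, dsig)
        iu = np.triu_indices(s.shape[0])
        out["srmr"] = float(np.sqrt(np.mean((rs[iu] - rsig[iu]) ** 2)))
    return out


class ConfirmatoryFactorAnalysis(TransformerMixin, BaseEstimator):
    """sklearn-style CFA estimator.

    Parameters
    ----------
    spec : LatentModelSpec
        Indicator->latent map and extra residual covariances.
    n_restarts : int, default 10
        Random restarts around the deterministic start; the best minimum wins.
    tol : float, default 1e-8
        Convergence tolerance on F_ML.
    random_state : int, default 0
        Seed for restart perturbations.

    Attributes (after ``fit``)
    --------------------------
    fit_result_ : CfaFit
    loadings_, latent_corr_, residual_cov_ : DataFrames of the solution.
    """

    def __init__(
        self,
        spec: LatentModelSpec | None = None,
        n_restarts: int = 10,
        tol: float = 1e-8,
        max_iter: int = 2000,
        random_state: int = 0,
    ):
        self.spec = spec
        self.n_restarts = n_restarts
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    # -- internal parameter plumbing -----------------------------------------
    def _layout(self, spec: LatentModelSpec, s_diag: np.ndarray):
        inds = spec.indicator_names
        lats = spec.latent_names
        p, k = len(inds), len(lats)
        ind_pos = {name: i for i, name in enumerate(inds)}
        singleton = {lat for lat, ii in spec.loadings.items() if len(ii) == 1}
        free_load = []   # (row, col) of free loadings
        fixed_load = []  # (row, col, value)
        for c, lat in enumerate(lats):
            for ind in spec.loadings[lat]:
                r = ind_pos[ind]
                if lat in singleton:
                    fixed_load.append((r, c, float(np.sqrt(s_diag[r]))))
                else:
                    free_load.append((r, c))
        fixed_zero_theta = {ind_pos[spec.loadings[lat][0]] for lat in singleton}
        free_theta = [i for i in range(p) if i not in fixed_zero_theta]
        rescov = [(ind_pos[a], ind_pos[b]) for a, b in spec.residual_covariances]
        n_phi = k * (k - 1) // 2
        return {
            "inds": inds, "lats": lats, "p": p, "k": k,
            "free_load": free_load, "fixed_load": fixed_load,
            "free_theta": free_theta, "rescov": rescov, "n_phi": n_phi,
        }

    @staticmethod
    def _unpack(theta_vec, lay):
        p, k = lay["p"], lay["k"]
        nl = len(lay["free_load"])
        nphi = lay["n_phi"]
        nt = len(lay["free_theta"])
        lam = np.zeros((p, k))
        for (r, c), v in zip(lay["free_load"], theta_vec[:nl]):
            lam[r, c] = v
        for r, c, v in lay["fixed_load"]:
            lam[r, c] = v
        # Phi via row-normalized lower-triangular Cholesky factor
        L = np.eye(k)
        pos = nl
        for i in range(1, k):
            row = np.zeros(k)
            row[:i] = theta_vec[pos: pos + i]
            row[i] = 1.0
            row /= np.linalg.norm(row[: i + 1])
            L[i, : i + 1] = row[: i + 1]
            pos += i
        phi = L @ L.T
        theta = np.zeros((p, p))
        for i, v in zip(lay["free_theta"], theta_vec[pos: pos + nt]):
            theta[i, i] = np.exp(v)
        pos += nt
        for (a, b), v in zip(lay["rescov"], theta_vec[pos:]):
            theta[a, b] = theta[b, a] = v
        return lam, phi, theta

    @staticmethod
    def _discrepancy(lam, phi, theta, s, logdet_s):
        p = s.shape[0]
        sigma = lam @ phi @ lam.T + theta
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            return np.inf, sigma
        try:
            sol = np.linalg.solve(sigma, s)
        except np.linalg.LinAlgError:
            return np.inf, sigma
        f = logdet - logdet_s + np.trace(sol) - p
        return max(f, 0.0) if f > -1e-8 else f, sigma

    # -- public API -----------------------------------------------------------
    def fit(self, X, y=None):
        if self.spec is None:
            raise ValueError("a LatentModelSpec is required")
        spec = self.spec
        if isinstance(X, pd.DataFrame):
            missing = [c for c in spec.indicator_names if c not in X.columns]
            if missing:
                raise ValueError(f"indicators missing from data: {missing}")
            data = X[spec.indicator_names].to_numpy(dtype=float)
        else:
            data = np.asarray(X, dtype=float)
            if data.shape[1] != len(spec.indicator_names):
                raise ValueError("column count does not match spec indicators")
        n, p = data.shape
        s = np.cov(data, rowvar=False, ddof=1)
        sign, logdet_s = np.linalg.slogdet(s)
        if sign <= 0:
            raise ValueError("sample covariance matrix is not positive definite")
        lay = self._layout(spec, np.diag(s))
        n_free = len(lay["free_load"]) + lay["n_phi"] + len(lay["free_theta"]) + len(lay["rescov"])
        if n <= n_free:
            raise ValueError(f"N={n} must exceed the {n_free} free parameters")
        df = p * (p + 1) // 2 - n_free
        if df < 0:
            raise ValueError(f"model has negative degrees of freedom ({df})")

        def objective(vec):
            lam, phi, theta = self._unpack(vec, lay)
            f, _ = self._discrepancy(lam, phi, theta, s, logdet_s)
            return f if np.isfinite(f) else 1e10

        # deterministic start: loadings ~ 0.7 sd, residual variance half of s_ii
        start = np.concatenate([
            [0.7 * np.sqrt(s[r, r]) for r, _ in lay["free_load"]],
            np.zeros(lay["n_phi"]),
            [np.log(0.5 * s[i, i]) for i in lay["free_theta"]],
            np.zeros(len(lay["rescov"])),
        ])
        rng = np.random.default_rng(self.random_state)
        best = None
        starts = [start] + [
            start + rng.normal(0.0, 0.2, size=start.size) for _ in range(max(self.n_restarts - 1, 0))
        ]
        for s0 in starts:
            res = optimize.minimize(
                objective, s0, method="L-BFGS-B",
                options={"maxiter": self.max_iter, "ftol": self.tol, "gtol": 1e-7},
            )
            if best is None or res.fun < best.fun - 1e-12:
                best = res
        converged = bool(best.success or best.fun < 1e10)
        lam, phi, theta = self._unpack(best.x, lay)
        # sign convention: majority-positive loadings per latent
        for c in range(lay["k"]):
            col = lam[:, c]
            if col.sum() < 0:
                lam[:, c] = -col
                phi[c, :] *= -1
                phi[:, c] *= -1
                np.fill_diagonal(phi, 1.0)
        fmin = float(best.fun)
        chi2 = (n - 1) * fmin
        sigma = lam @ phi @ lam.T + theta
        # independence baseline: Sigma_b = diag(S), closed form
        f_b = float(np.sum(np.log(np.diag(s))) - logdet_s)
        chi2_b = (n - 1) * f_b
        df_b = p * (p - 1) // 2
        idx = fit_indices(chi2, df, n, chi2_b, df_b, sample_cov=s, implied_cov=sigma)

        inds, lats = lay["inds"], lay["lats"]
        self.fit_result_ = CfaFit(
            spec=spec,
            loadings=pd.DataFrame(lam, index=inds, columns=lats),
            latent_corr=pd.DataFrame(phi, index=lats, columns=lats),
            residual_cov=pd.DataFrame(theta, index=inds, columns=inds),
            fmin=fmin,
            chi2=float(chi2),
            df=int(df),
            n_obs=int(n),
            rmsea=idx["rmsea"],
            rmsea_ci=idx["rmsea_ci"],
            srmr=idx["srmr"],
            cfi=idx["cfi"],
            converged=converged,
            means=pd.Series(data.mean(axis=0), index=inds),
            sample_cov=pd.DataFrame(s, index=inds, columns=inds),
        )
        self.loadings_ = self.fit_result_.loadings
        self.latent_corr_ = self.fit_result_.latent_corr
        self.residual_cov_ = self.fit_result_.residual_cov
        self.n_features_in_ = p
        return self

    def transform(self, X) -> pd.DataFrame:
        """Regression-method factor scores for each row (song)."""
        return factor_scores(self.fit_result_, X)

    def fit_transform(self, X, y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)


def factor_scores(fit: CfaFit, X) -> pd.DataFrame:
    """Regression-method scores eta_hat = Phi Lambda' Sigma^-1 (x - xbar)."""
    spec = fit.spec
    if isinstance(X, pd.DataFrame):
        data = X[spec.indicator_names].to_numpy(dtype=float)
        index = X.index
    else:
        data = np.asarray(X, dtype=float)
        index = pd.RangeIndex(data.shape[0])
    lam = fit.loadings.to_numpy()
    phi = fit.latent_corr.to_numpy()
    sigma = fit.implied_cov.to_numpy()
    sign, _ = np.linalg.slogdet(sigma)
    if sign <= 0:
        raise np.linalg.LinAlgError("implied covariance is singular; cannot score")
    centered = data - fit.means.to_numpy()
    weights = np.linalg.solve(sigma, lam @ phi).T  # k x p? -> (Phi Lam' Sigma^-1)
    scores = centered @ weights.T
    return pd.DataFrame(scores, index=index, columns=spec.latent_names)


def fit_cfa(data, spec: LatentModelSpec, **kwargs) -> CfaFit:
    """Functional wrapper: fit the CFA and return the :class:`CfaFit`."""
    est = ConfirmatoryFactorAnalysis(spec=spec, **kwargs)
    est.fit(data)
    return est.fit_result_
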