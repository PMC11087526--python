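"""Matrix association: principal coordinates, Mantel tests and partial RDA.

Distance matrices are first embedded by principal coordinates analysis
(eigendecomposition of the Gower-centered squared distances); axes explaining
more than a threshold share (default 10%) of the positive-eigenvalue variance
feed the redundancy analysis.  Mantel statistics correlate the off-diagonal
entries of two matrices directly, with significance from simultaneous
row/column permutations; the partial variants control a third matrix by
linear residualization.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations as _all_perms

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .core import DistanceMatrix, gower_center

__all__ = [
    "PcoaResult",
    "PrincipalCoordinates",
    "pcoa",
    "AssociationResult",
    "mantel",
    "partial_mantel",
    "partial_rda",
]


@dataclass
class PcoaResult:
    """Principal-coordinate embedding of a distance matrix."""

    coordinates: pd.DataFrame     # society x axis, positive axes only
    eigenvalues: np.ndarray       # all, sorted descending
    percent_variance: np.ndarray  # per positive axis, of positive-eigenvalue total

    def selected_axes(self, threshold_percent: float = 10.0) -> pd.DataFrame:
        """Axes explaining more than ``threshold_percent`` of the variance."""
        keep = self.percent_variance > threshold_percent
        if not keep.any():
            keep = np.zeros_like(keep, dtype=bool)
            keep[0] = True  # always keep the dominant axis
        return self.coordinates.loc[:, keep]


def pcoa(d: DistanceMatrix, eig_tol: float = 1e-9) -> PcoaResult:
    """Classical scaling: eigendecomposition of the Gower-centered matrix.

    Negative eigenvalues (non-Euclidean distances) are dropped from both the
    coordinates and the variance denominator.
    """
    if d.n < 3:
        raise ValueError("PCoA needs at least 3 points")
    c = gower_center(d)
    eigval, eigvec = np.linalg.eigh(c)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    scale = max(abs(eigval[0]), 1.0)
    pos = eigval > eig_tol * scale
    if not pos.any():
        raise ValueError("no positive eigenvalues: degenerate distance matrix")
    lam = eigval[pos]
    coords = eigvec[:, pos] * np.sqrt(lam)
    pct = 100.0 * lam / lam.sum()
    cols = [f"axis{i + 1}" for i in range(coords.shape[1])]
    return PcoaResult(
        coordinates=pd.DataFrame(coords, index=d.labels, columns=cols),
        eigenvalues=eigval,
        percent_variance=pct,
    )


class PrincipalCoordinates(BaseEstimator):
    """sklearn-style wrapper over :func:`pcoa`.

    ``fit`` takes a :class:`DistanceMatrix`; fitted attributes expose the
    embedding (``coordinates_``, ``eigenvalues_``, ``percent_variance_``).
    """

    def __init__(self, axis_threshold_percent: float = 10.0):
        self.axis_threshold_percent = axis_threshold_percent

    def fit(self, X: DistanceMatrix, y=None):
        res = pcoa(X)
        self.result_ = res
        self.coordinates_ = res.coordinates
        self.eigenvalues_ = res.eigenvalues
        self.percent_variance_ = res.percent_variance
        self.selected_axes_ = res.selected_axes(self.axis_threshold_percent)
        return self

    def fit_transform(self, X: DistanceMatrix, y=None) -> np.ndarray:
        return self.fit(X).selected_axes_.to_numpy()


@dataclass
class AssociationResult:
    """A matrix-association statistic with its permutation p-value."""

    statistic_name: str           # "mantel_r" or "rda_adjusted_r2"
    statistic: float
    p_value: float
    n_permutations: int
    n: int
    conditioning: str = "none"
    details: dict | None = None


def _align(*mats: DistanceMatrix) -> list[DistanceMatrix]:
    shared = DistanceMatrix.shared_labels(*mats)
    if len(shared) < 4:
        raise ValueError(f"need >= 4 shared labels, got {len(shared)}")
    return [m.select(shared) for m in mats]


def _upper(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise ValueError("constant distance matrix: correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def mantel(
    a: DistanceMatrix,
    b: DistanceMatrix,
    n_permutations: int = 999,
    seed: int = 0,
    exact: bool = False,
) -> AssociationResult:
    """Mantel correlation between two distance matrices.

    Pearson r over the upper-triangle entries; the null distribution permutes
    rows and columns of ``b`` simultaneously.  Two-sided p.  ``exact=True``
    enumerates every permutation (feasible only for small n).
    """
    a, b = _align(a, b)
    n = a.n
    va = _upper(a.values)
    r_obs = _pearson(va, _upper(b.values))
    if exact:
        perms = list(_all_perms(range(n)))
        stats = []
        for order in perms:
            order = np.array(order)
            stats.append(_pearson(va, _upper(b.values[np.ix_(order, order)])))
        stats = np.array(stats)
        p = float(np.mean(np.abs(stats) >= abs(r_obs) - 1e-12))
        n_used = len(perms)
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            order = rng.permutation(n)
            rp = _pearson(va, _upper(b.values[np.ix_(order, order)]))
            if abs(rp) >= abs(r_obs) - 1e-12:
                count += 1
        p = (count + 1) / (n_permutations + 1)
        n_used = n_permutations
    return AssociationResult("mantel_r", r_obs, p, n_used, n)


def _residualize(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(len(x)), x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coef


def partial_mantel(
    a: DistanceMatrix,
    b: DistanceMatrix,
    c: DistanceMatrix,
    n_permutations: int = 999,
    seed: int = 0,
) -> AssociationResult:
    """Correlation of ``a`` and ``b`` after removing the influence of ``c``.

    Both matrices are residualized on ``c`` entrywise (upper triangle); the
    residuals of ``a`` are permuted as a matrix (rows and columns together)
    to preserve the distance structure under the null.  Two-sided p.
    """
    a, b, c = _align(a, b, c)
    n = a.n
    vc = _upper(c.values)
    res_a = _residualize(_upper(a.values), vc)
    res_b = _residualize(_upper(b.values), vc)
    tol = 1e-12
    a_flat = res_a.std() <= tol * max(1.0, np.abs(_upper(a.values)).max())
    b_flat = res_b.std() <= tol * max(1.0, np.abs(_upper(b.values)).max())
    if a_flat and b_flat:
        raise ValueError("zero residual variance: partial correlation undefined")
    if a_flat or b_flat:
        # one side is fully explained by the conditioning matrix (e.g. b == c):
        # nothing remains to correlate
        return AssociationResult("mantel_r", 0.0, 1.0, 0, n, conditioning="matrix c")
    r_obs = _pearson(res_a, res_b)
    # put a's residuals back in matrix form so permutations act on societies
    mat_a = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    mat_a[iu] = res_a
    mat_a = mat_a + mat_a.T
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        order = rng.permutation(n)
        rp = _pearson(mat_a[np.ix_(order, order)][iu], res_b)
        if abs(rp) >= abs(r_obs) - 1e-12:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return AssociationResult("mantel_r", r_obs, p, n_permutations, n, conditioning="matrix c")


def _fit_r2(y: np.ndarray, x: np.ndarray) -> float:
    """Redundancy R^2: share of total variance of Y explained by X."""
    yc = y - y.mean(axis=0)
    xc = x - x.mean(axis=0)
    coef, *_ = np.linalg.lstsq(xc, yc, rcond=None)
    fitted = xc @ coef
    total = (yc**2).sum()
    if total == 0:
        raise ValueError("response has zero variance")
    return float((fitted**2).sum() / total)


def _ezekiel(r2: float, n: int, m: int) -> float:
    if n - m - 1 <= 0:
        raise ValueError(f"overparameterized: n={n}, m={m} explanatory axes")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


def partial_rda(
    response: DistanceMatrix,
    explanatory: DistanceMatrix,
    conditioning: DistanceMatrix | None = None,
    n_permutations: int = 999,
    seed: int = 0,
    axis_threshold_percent: float = 10.0,
    adjust: str = "ezekiel",
) -> AssociationResult:
    """Redundancy analysis between the principal coordinates of two matrices.

    Each matrix is reduced to its PCoA axes above ``axis_threshold_percent``;
    with a conditioning matrix both sides are first residualized on its axes.
    R^2 is trace(fitted SS)/trace(total SS); ``adjust='ezekiel'`` applies
    1 - (1-R^2)(n-1)/(n-m-1), ``adjust='semipartial'`` reports the difference
    of Ezekiel-adjusted R^2 between the full and conditioning-only models.
    The permutation null shuffles rows of the explanatory axes (upper-tail p,
    the statistic being nonnegative).
    """
    mats = [response, explanatory] + ([conditioning] if conditioning is not None else [])
    aligned = _align(*mats)
    resp, expl = aligned[0], aligned[1]
    cond = aligned[2] if conditioning is not None else None
    n = resp.n
    y = pcoa(resp).selected_axes(axis_threshold_percent).to_numpy()
    x = pcoa(expl).selected_axes(axis_threshold_percent).to_numpy()
    z = pcoa(cond).selected_axes(axis_threshold_percent).to_numpy() if cond is not None else None
    m = x.shape[1]
    if z is not None:
        y_w = _residualize(y, z)
        x_w = _residualize(x, z)
    else:
        y_w, x_w = y, x

    r2 = _fit_r2(y_w, x_w)
    if adjust == "ezekiel":
        stat = _ezekiel(r2, n, m)
    elif adjust == "semipartial":
        if z is None:
            stat = _ezekiel(r2, n, m)
        else:
            r2_full = _fit_r2(y, np.column_stack([x, z]))
            r2_cond = _fit_r2(y, z)
            stat = _ezekiel(r2_full, n, m + z.shape[1]) - _ezekiel(r2_cond, n, z.shape[1])
    else:
        raise ValueError(f"unknown adjust mode {adjust!r}")

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        order = rng.permutation(n)
        if _fit_r2(y_w, x_w[order]) >= r2 - 1e-12:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return AssociationResult(
        "rda_adjusted_r2", stat, p, n_permutations, n,
        conditioning="none" if cond is None else "matrix",
        details={"r2": r2, "n_axes_explanatory": m, "n_axes_response": y.shape[1]},
    )
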