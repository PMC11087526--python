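"""Shared geometric and algebraic primitives.

Labeled distance matrices are the lingua franca of the package: great-circle
(Haversine) distances between societies, patristic distances on a phylogeny,
fixation-index matrices (F_ST, Phi_ST) and trait distances all travel through
:class:`DistanceMatrix`.  The Gower double-centering used by principal
coordinates and the distance-class autocorrelation, and the Matern
distance-decay correlation, live here too.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gamma as _gamma_fn
from scipy.special import kv as _bessel_kv

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "DistanceMatrix",
    "GeoTable",
    "haversine_matrix",
    "patristic_matrix",
    "matern_correlation",
    "gower_center",
    "EARTH_RADIUS_KM",
]


class DistanceMatrix:
    """A square, symmetric, zero-diagonal matrix with unique row labels.

    Parameters
    ----------
    values : array-like of shape (n, n)
        Nonnegative distances (units depend on the source: km, branch length,
        F_ST, Phi_ST, ...).  Symmetry is enforced within ``sym_tol`` and the
        matrix is then symmetrized by averaging.
    labels : sequence of str
        Unique identifiers, one per row/column.
    """

    def __init__(self, values, labels: Sequence[str], *, sym_tol: float = 1e-8):
        values = np.asarray(values, dtype=float)
        labels = [str(x) for x in labels]
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError(f"distance matrix must be square, got shape {values.shape}")
        if len(labels) != values.shape[0]:
            raise ValueError(
                f"{len(labels)} labels for a {values.shape[0]}x{values.shape[1]} matrix"
            )
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate labels: {dupes}")
        if not np.all(np.isfinite(values) | np.isnan(values)):
            raise ValueError("distance matrix contains non-finite values")
        asym = np.nanmax(np.abs(values - values.T)) if values.size else 0.0
        if asym > sym_tol:
            raise ValueError(f"matrix not symmetric (max asymmetry {asym:.3g} > {sym_tol:.3g})")
        values = 0.5 * (values + values.T)
        diag = np.abs(np.diagonal(values))
        if values.size and np.nanmax(diag) > sym_tol:
            raise ValueError("distance matrix has a nonzero diagonal")
        np.fill_diagonal(values, 0.0)
        self.values = values
        self.labels = labels
        self._index = {lab: i for i, lab in enumerate(labels)}

    # -- container-ish surface ------------------------------------------------
    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n(self) -> int:
        return len(self.labels)

    def __getitem__(self, pair) -> float:
        i, j = pair
        return float(self.values[self._index[str(i)], self._index[str(j)]])

    def __eq__(self, other) -> bool:  # exact; tests use allclose on .values
        return (
            isinstance(other, DistanceMatrix)
            and self.labels == other.labels
            and np.array_equal(self.values, other.values, equal_nan=True)
        )

    def __repr__(self) -> str:
        return f"DistanceMatrix(n={self.n}, labels={self.labels[:4]}{'...' if self.n > 4 else ''})"

    def select(self, labels: Iterable[str]) -> "DistanceMatrix":
        """Submatrix restricted to ``labels``, in the given order."""
        labels = [str(x) for x in labels]
        missing = [x for x in labels if x not in self._index]
        if missing:
            raise KeyError(f"labels not in matrix: {missing}")
        idx = np.array([self._index[x] for x in labels])
        return DistanceMatrix(self.values[np.ix_(idx, idx)], labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries (i < j), row-major."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, *, sym_tol: float = 1e-8) -> "DistanceMatrix":
        if list(df.index) != list(df.columns):
            raise ValueError("row and column labels disagree")
        return cls(df.to_numpy(dtype=float), [str(x) for x in df.index], sym_tol=sym_tol)

    @staticmethod
    def shared_labels(*mats: "DistanceMatrix") -> list[str]:
        """Labels present in every matrix, in the order of the first."""
        common = set(mats[0].labels)
        for m in mats[1:]:
            common &= set(m.labels)
        return [x for x in mats[0].labels if x in common]


class GeoTable:
    """Society locations: unique ids with longitude/latitude in degrees."""

    def __init__(self, ids: Sequence[str], lon, lat):
        ids = [str(x) for x in ids]
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        if not (len(ids) == lon.shape[0] == lat.shape[0]):
            raise ValueError("ids, lon and lat must have equal length")
        if len(set(ids)) != len(ids):
            dupes = sorted({x for x in ids if ids.count(x) > 1})
            raise ValueError(f"duplicate society ids: {dupes}")
        for i, (x, y) in enumerate(zip(lon, lat)):
            if not (-180.0 <= x <= 180.0):
                raise ValueError(f"row {i} ({ids[i]}): longitude {x} outside [-180, 180]")
            if not (-90.0 <= y <= 90.0):
                raise ValueError(f"row {i} ({ids[i]}): latitude {y} outside [-90, 90]")
        self.ids = ids
        self.lon = lon
        self.lat = lat

    def __len__(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"society": self.ids, "lon": self.lon, "lat": self.lat})


def haversine_matrix(geo: GeoTable, radius_km: float = EARTH_RADIUS_KM) -> DistanceMatrix:
    """Great-circle distance (km) between every pair of societies.

    Uses the haversine formulation, numerically stable for small separations.
    """
    if radius_km <= 0:
        raise ValueError("radius_km must be positive")
    lon = np.radians(geo.lon)
    lat = np.radians(geo.lat)
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2.0) ** 2
    a = np.clip(a, 0.0, 1.0)
    d = 2.0 * radius_km * np.arcsin(np.sqrt(a))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, geo.ids, sym_tol=1e-6)


def patristic_matrix(tree, tips: Sequence[str] | None = None) -> DistanceMatrix:
    """Tip-to-tip path-length (patristic) distances on a phylogeny.

    Parameters
    ----------
    tree : dendropy.Tree
        Rooted tree with labeled tips and nonnegative branch lengths.
    tips : sequence of str, optional
        Restrict (and order) the output to these tip labels.
    """
    import dendropy

    if not isinstance(tree, dendropy.Tree):
        raise TypeError("tree must be a dendropy.Tree")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError(f"negative branch length {edge.length}")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    all_tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(all_tips)) != len(all_tips):
        raise ValueError("tip labels are not unique")
    if tips is None:
        tips = all_tips
    else:
        tips = [str(t) for t in tips]
        absent = [t for t in tips if t not in taxa]
        if absent:
            raise KeyError(f"tips not present in tree: {absent}")
    n = len(tips)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[tips[i]], taxa[tips[j]])
    return DistanceMatrix(d, tips)


def matern_correlation(d: DistanceMatrix | np.ndarray, kappa: float, phi: float):
    """Matern distance-decay correlation rho(u).

    rho(u) = 2^(1-kappa)/Gamma(kappa) * (u/phi)^kappa * K_kappa(u/phi) for
    u > 0, rho(0) = 1, with smoothness ``kappa`` and range ``phi`` (the
    geostatistical (kappa, phi) parameterization).  At kappa = 1/2 this is the
    exponential decay exp(-u/phi).
    """
    if kappa <= 0 or phi <= 0:
        raise ValueError("kappa and phi must be positive")
    is_dm = isinstance(d, DistanceMatrix)
    u = d.values if is_dm else np.asarray(d, dtype=float)
    if np.any(u < 0):
        raise ValueError("distances must be nonnegative")
    scaled = u / phi
    with np.errstate(invalid="ignore"):
        rho = (2.0 ** (1.0 - kappa) / _gamma_fn(kappa)) * scaled**kappa * _bessel_kv(kappa, scaled)
    rho = np.where(u == 0.0, 1.0, rho)
    rho = np.clip(rho, 0.0, 1.0)
    if is_dm:
        out = rho.copy()
        return pd.DataFrame(out, index=d.labels, columns=d.labels)
    return rho


def gower_center(d: DistanceMatrix | np.ndarray) -> np.ndarray:
    """Gower double-centered inner-product matrix C = -1/2 J D^(2) J.

    ``D^(2)`` is the elementwise square of the distances and ``J = I - 11'/n``
    the centering projector; rows and columns of C sum to zero.  This is the
    matrix whose eigendecomposition yields principal coordinates, and whose
    entries feed the distance-class autocorrelation coefficient.
    """
    values = d.values if isinstance(d, DistanceMatrix) else np.asarray(d, dtype=float)
    n = values.shape[0]
    d2 = values**2
    row_mean = d2.mean(axis=1, keepdims=True)
    col_mean = d2.mean(axis=0, keepdims=True)
    grand = d2.mean()
    return -0.5 * (d2 - row_mean - col_mean + grand)
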