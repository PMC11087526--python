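"""Quartet delta scores: departure of a distance matrix from additivity.

For any four taxa {x, y, u, v} the three pairings give sums
s1 = d(x,y)+d(u,v), s2 = d(x,u)+d(y,v), s3 = d(x,v)+d(y,u).  On a tree
(additive distances) the two largest are equal; the delta score of the
quartet is

    delta = (m1 - m2) / (m1 - m3),   m1 >= m2 >= m3,

0 for a perfectly treelike quartet (with the convention delta = 0 when
m1 = m3, the fully degenerate case) and 1 for maximal conflict.  The
delta score of a matrix is the mean over quartets — small values mean the
data look vertically transmitted, large values indicate reticulation
(borrowing, horizontal transmission).
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .core import DistanceMatrix

__all__ = ["quartet_delta", "delta_score", "delta_by_region"]


def quartet_delta(d: DistanceMatrix, x, y, u, v) -> float:
    """Delta score of a single quartet of labels."""
    labels = [str(t) for t in (x, y, u, v)]
    if len(set(labels)) != 4:
        raise ValueError(f"quartet labels must be distinct, got {labels}")
    s = sorted([
        d[labels[0], labels[1]] + d[labels[2], labels[3]],
        d[labels[0], labels[2]] + d[labels[1], labels[3]],
        d[labels[0], labels[3]] + d[labels[1], labels[2]],
    ], reverse=True)
    m1, m2, m3 = s
    if m1 - m3 == 0:
        return 0.0
    return (m1 - m2) / (m1 - m3)


def _delta_from_quartets(values: np.ndarray, quartets: np.ndarray):
    """Vectorized per-quartet deltas; returns (deltas, quartets)."""
    a, b, c, e = quartets.T
    s = np.stack([
        values[a, b] + values[c, e],
        values[a, c] + values[b, e],
        values[a, e] + values[b, c],
    ])
    s.sort(axis=0)
    m3, m2, m1 = s
    spread = m1 - m3
    with np.errstate(invalid="ignore", divide="ignore"):
        delta = np.where(spread > 0, (m1 - m2) / spread, 0.0)
    return delta


def delta_score(
    d: DistanceMatrix,
    sample_size: int | None = None,
    seed: int = 0,
    max_quartets: int = 1_000_000,
    n_quartet_subsample: int = 100_000,
) -> tuple[float, pd.Series]:
    """Mean delta over quartets, plus per-taxon means.

    ``sample_size`` subsamples taxa (without replacement, seeded) before
    enumeration.  All C(n, 4) quartets are enumerated when their count is at
    most ``max_quartets``; beyond that, ``n_quartet_subsample`` random
    quartets are drawn instead.
    """
    rng = np.random.default_rng(seed)
    labels = list(d.labels)
    if sample_size is not None:
        if sample_size > len(labels):
            raise ValueError(f"sample_size {sample_size} exceeds {len(labels)} taxa")
        keep = sorted(rng.choice(len(labels), size=sample_size, replace=False))
        labels = [labels[i] for i in keep]
    if len(labels) < 4:
        raise ValueError(f"need at least 4 taxa, got {len(labels)}")
    sub = d.select(labels)
    n = len(labels)
    if comb(n, 4) <= max_quartets:
        quartets = np.array(list(combinations(range(n), 4)), dtype=int)
    else:
        picks = np.empty((n_quartet_subsample, 4), dtype=int)
        for row in range(n_quartet_subsample):
            picks[row] = rng.choice(n, size=4, replace=False)
        quartets = picks
    deltas = _delta_from_quartets(sub.values, quartets)
    taxon_sum = np.zeros(n)
    taxon_cnt = np.zeros(n)
    for col in range(4):
        np.add.at(taxon_sum, quartets[:, col], deltas)
        np.add.at(taxon_cnt, quartets[:, col], 1)
    per_taxon = pd.Series(taxon_sum / taxon_cnt, index=labels, name="mean_delta")
    return float(deltas.mean()), per_taxon


def delta_by_region(
    latents: pd.DataFrame,
    regions: pd.Series,
    sample_size: int = 50,
    seed: int = 0,
    region_names: list[str] | None = None,
    variable_matrices: dict[str, DistanceMatrix] | None = None,
) -> pd.DataFrame:
    """Mean delta per region and latent variable (Table-style layout).

    For each region, ``sample_size`` societies are drawn without replacement
    (deterministic given ``seed``).  By default each latent column uses 1-D
    absolute differences as the distance; note that scalar distances are
    always additive (any four collinear points satisfy the four-point
    condition), so those rows are exactly 0 — pass per-variable society
    distance matrices (e.g. per-dimension Phi_ST, which aggregate song-level
    spread) via ``variable_matrices`` for a non-degenerate per-variable
    score.  The ``All`` row always uses Euclidean distance over all latent
    columns jointly.
    """
    regions = regions.astype(str)
    if region_names is None:
        region_names = sorted(regions.unique())
    out = {}
    for k, region in enumerate(region_names):
        socs = regions.index[regions == region]
        socs = [s for s in socs if s in latents.index]
        if len(socs) < sample_size:
            raise ValueError(f"region {region!r} has {len(socs)} societies < sample_size {sample_size}")
        rng = np.random.default_rng(np.random.SeedSequence([seed, k]))
        take = sorted(rng.choice(len(socs), size=sample_size, replace=False))
        chosen = [socs[i] for i in take]
        block = latents.loc[chosen]
        col = {}
        for var in latents.columns:
            if variable_matrices is not None and var in variable_matrices:
                dm = variable_matrices[var].select(chosen)
            else:
                dm = DistanceMatrix(
                    squareform(pdist(block[[var]].to_numpy(), metric="euclidean")), chosen
                )
            col[var], _ = delta_score(dm)
        dm_all = DistanceMatrix(
            squareform(pdist(block.to_numpy(), metric="euclidean")), chosen
        )
        col["All"], _ = delta_score(dm_all)
        out[region] = col
    return pd.DataFrame(out)
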