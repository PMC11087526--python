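"""Hierarchical analysis of variance on song-level distances (AMOVA).

Squared Euclidean distances between songs are decomposed into within-society,
among-society (optionally within macro-group) and among-group components
using the standard unequal-sample-size coefficients.  The derived Phi
statistics are the distance-based analogue of F-statistics:

    Phi_ST = (sigma2_a + sigma2_b) / sigma2_total   (among societies, total)
    Phi_SC = sigma2_b / (sigma2_b + sigma2_w)       (societies within groups)
    Phi_CT = sigma2_a / sigma2_total                (among groups)

Negative variance components are reported raw (no clamping) and a Phi whose
denominator is <= 0 is NaN, matching standard AMOVA software.  Significance
is assessed by permuting songs across societies (within groups for the
nested level, whole societies across groups for Phi_CT).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .core import DistanceMatrix

logger = logging.getLogger(__name__)

__all__ = ["AmovaResult", "amova", "pairwise_phist", "fixation_comparison"]


@dataclass
class AmovaResult:
    """Variance components, Phi statistics and permutation p-values."""

    ss: dict[str, float]
    df: dict[str, int]
    sigma2: dict[str, float]      # keys: among_groups (two-level only), among_societies, within
    percent: dict[str, float]
    phi: dict[str, float]         # phi_st always; phi_sc/phi_ct for two-level
    p_values: dict[str, float] = field(default_factory=dict)
    n_permutations: int = 0

    def to_json(self, path) -> None:
        import json

        payload = {
            "ss": self.ss, "df": self.df, "sigma2": self.sigma2,
            "percent": self.percent, "phi": self.phi,
            "p_values": self.p_values, "n_permutations": self.n_permutations,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=float)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for comp in self.sigma2:
            rows.append({
                "component": comp,
                "df": self.df.get(comp),
                "SS": self.ss.get(comp),
                "sigma2": self.sigma2[comp],
                "percent": self.percent.get(comp),
            })
        out = pd.DataFrame(rows)
        for name, val in self.phi.items():
            out.loc[out.index[-1] + 1 if len(out) else 0, "component"] = name
            out.loc[out.index[-1], "sigma2"] = val
            out.loc[out.index[-1], "percent"] = self.p_values.get(name)
        return out


def _one_level(d2: np.ndarray, pops: np.ndarray):
    """One-level AMOVA sums of squares and components from squared distances."""
    labels, inv = np.unique(pops, return_inverse=True)
    n_tot = len(pops)
    n_pop = len(labels)
    counts = np.bincount(inv)
    ss_total = 0.5 * d2.sum() / n_tot
    ss_within = 0.0
    for p in range(n_pop):
        idx = np.flatnonzero(inv == p)
        ss_within += 0.5 * d2[np.ix_(idx, idx)].sum() / counts[p]
    ss_among = ss_total - ss_within
    df_a, df_w = n_pop - 1, n_tot - n_pop
    sigma_w = ss_within / df_w if df_w > 0 else np.nan
    n0 = (n_tot - (counts**2).sum() / n_tot) / df_a
    sigma_a = (ss_among / df_a - sigma_w) / n0
    return ss_total, ss_among, ss_within, df_a, df_w, sigma_a, sigma_w


def amova(
    values,
    society,
    group=None,
    n_permutations: int = 999,
    seed: int = 0,
) -> AmovaResult:
    """AMOVA on a song x trait matrix with one- or two-level hierarchy.

    Parameters
    ----------
    values : array-like (n_songs, n_traits)
        Trait values per song (a single column for one latent dimension).
    society : sequence of labels, length n_songs
    group : sequence of labels or None
        Macro-group per song (language family or region); enables the nested
        two-level decomposition.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] == 1 and values.shape[1] > 1:
        values = values.T
    society = np.asarray([str(x) for x in society])
    if values.shape[0] != society.shape[0]:
        raise ValueError("values and society labels disagree in length")
    if len(np.unique(society)) < 2:
        raise ValueError("AMOVA needs at least two societies")
    d2 = squareform(pdist(values, metric="sqeuclidean"))
    if d2.max() == 0.0:
        raise ValueError("all songs identical: AMOVA variance components undefined")

    rng = np.random.default_rng(seed)
    if group is None:
        res = _amova_one_level(d2, society)
        if n_permutations:
            obs = res.phi["phi_st"]
            count = 0
            for _ in range(n_permutations):
                perm = rng.permutation(society)
                r = _amova_one_level(d2, perm)
                if r.phi["phi_st"] >= obs - 1e-12:
                    count += 1
            res.p_values["phi_st"] = (count + 1) / (n_permutations + 1)
            res.n_permutations = n_permutations
        return res

    group = np.asarray([str(x) for x in group])
    if group.shape[0] != society.shape[0]:
        raise ValueError("group labels disagree in length")
    res = _amova_two_level(d2, society, group)
    if n_permutations:
        obs = res.phi
        counts = {k: 0 for k in ("phi_st", "phi_sc", "phi_ct")}
        soc_group = pd.Series(group, index=society).groupby(level=0).first()
        societies = soc_group.index.to_numpy()
        for _ in range(n_permutations):
            # phi_st: songs across all societies (society->group map stays fixed)
            perm_st = rng.permutation(society)
            r = _amova_two_level(d2, perm_st, soc_group.loc[perm_st].to_numpy())
            if np.isnan(obs["phi_st"]) or r.phi["phi_st"] >= obs["phi_st"] - 1e-12:
                counts["phi_st"] += 1
            # phi_sc: songs across societies within their group
            perm_sc = society.copy()
            for g in np.unique(group):
                idx = np.flatnonzero(group == g)
                perm_sc[idx] = perm_sc[rng.permutation(idx)]
            r = _amova_two_level(d2, perm_sc, group)
            if np.isnan(obs["phi_sc"]) or r.phi["phi_sc"] >= obs["phi_sc"] - 1e-12:
                counts["phi_sc"] += 1
            # phi_ct: whole societies across groups
            shuffled = pd.Series(rng.permutation(soc_group.to_numpy()), index=societies)
            r = _amova_two_level(d2, society, shuffled.loc[society].to_numpy())
            if np.isnan(obs["phi_ct"]) or r.phi["phi_ct"] >= obs["phi_ct"] - 1e-12:
                counts["phi_ct"] += 1
        for k, c in counts.items():
            res.p_values[k] = (c + 1) / (n_permutations + 1)
        res.n_permutations = n_permutations
    return res


def _amova_one_level(d2: np.ndarray, society: np.ndarray) -> AmovaResult:
    ss_total, ss_among, ss_within, df_a, df_w, sigma_a, sigma_w = _one_level(d2, society)
    total = sigma_a + sigma_w
    phi_st = sigma_a / total if total > 0 else np.nan
    percent = {
        "among_societies": 100.0 * sigma_a / total if total > 0 else np.nan,
        "within": 100.0 * sigma_w / total if total > 0 else np.nan,
    }
    return AmovaResult(
        ss={"among_societies": ss_among, "within": ss_within, "total": ss_total},
        df={"among_societies": df_a, "within": df_w},
        sigma2={"among_societies": sigma_a, "within": sigma_w},
        percent=percent,
        phi={"phi_st": phi_st},
    )


def _amova_two_level(d2: np.ndarray, society: np.ndarray, group: np.ndarray) -> AmovaResult:
    n_tot = len(society)
    groups = np.unique(group)
    pops, pop_inv = np.unique(society, return_inverse=True)
    counts = np.bincount(pop_inv).astype(float)
    n_g = len(groups)
    n_p = len(pops)
    # a society must sit inside a single group
    soc_group = {}
    for s, g in zip(society, group):
        if s in soc_group and soc_group[s] != g:
            raise ValueError(f"society {s!r} appears in more than one group")
        soc_group[s] = g
    if n_p - n_g <= 0:
        logger.warning("every group holds a single society: within-group component flagged NaN")

    ss_total = 0.5 * d2.sum() / n_tot
    ss_wp = 0.0
    for p_idx, p in enumerate(pops):
        idx = np.flatnonzero(pop_inv == p_idx)
        ss_wp += 0.5 * d2[np.ix_(idx, idx)].sum() / counts[p_idx]
    ss_groups_total = 0.0
    group_sizes = {}
    sum_np2_over_ng = 0.0
    for g in groups:
        idx = np.flatnonzero(group == g)
        n_gsize = len(idx)
        group_sizes[g] = n_gsize
        ss_groups_total += 0.5 * d2[np.ix_(idx, idx)].sum() / n_gsize
        members = [i for i, p in enumerate(pops) if soc_group[p] == g]
        sum_np2_over_ng += sum(counts[i] ** 2 for i in members) / n_gsize
    ss_ag = ss_total - ss_groups_total
    ss_apwg = ss_groups_total - ss_wp

    df_ag = n_g - 1
    df_apwg = n_p - n_g
    df_wp = n_tot - n_p
    sigma_c = ss_wp / df_wp if df_wp > 0 else np.nan
    sum_np2_over_n = (counts**2).sum() / n_tot
    sum_ng2_over_n = sum(v**2 for v in group_sizes.values()) / n_tot
    n_coef = (n_tot - sum_np2_over_ng) / df_apwg if df_apwg > 0 else np.nan
    np_coef = (sum_np2_over_ng - sum_np2_over_n) / df_ag if df_ag > 0 else np.nan
    npp_coef = (n_tot - sum_ng2_over_n) / df_ag if df_ag > 0 else np.nan
    sigma_b = (ss_apwg / df_apwg - sigma_c) / n_coef if df_apwg > 0 else np.nan
    sigma_a = (
        (ss_ag / df_ag - sigma_c - np_coef * sigma_b) / npp_coef if df_ag > 0 else np.nan
    )
    total = sigma_a + sigma_b + sigma_c
    phi = {
        "phi_st": (sigma_a + sigma_b) / total if total > 0 else np.nan,
        "phi_sc": sigma_b / (sigma_b + sigma_c) if (sigma_b + sigma_c) > 0 else np.nan,
        "phi_ct": sigma_a / total if total > 0 else np.nan,
    }
    percent = {
        "among_groups": 100.0 * sigma_a / total if total > 0 else np.nan,
        "among_societies": 100.0 * sigma_b / total if total > 0 else np.nan,
        "within": 100.0 * sigma_c / total if total > 0 else np.nan,
    }
    return AmovaResult(
        ss={
            "among_groups": ss_ag,
            "among_societies": ss_apwg,
            "within": ss_wp,
            "total": ss_total,
        },
        df={"among_groups": df_ag, "among_societies": df_apwg, "within": df_wp},
        sigma2={"among_groups": sigma_a, "among_societies": sigma_b, "within": sigma_c},
        percent=percent,
        phi=phi,
    )


def pairwise_phist(values, society, min_songs: int = 2) -> DistanceMatrix:
    """Pairwise Phi_ST between all societies via two-population AMOVA.

    Societies with fewer than ``min_songs`` songs are refused (the standard
    inclusion filter).  Pairs with zero total variance get NaN with a warning.
    Negative Phi_ST is reported raw.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] == 1 and values.shape[1] > 1:
        values = values.T
    society = np.asarray([str(x) for x in society])
    labels, inv = np.unique(society, return_inverse=True)
    counts = np.bincount(inv)
    small = [str(l) for l, c in zip(labels, counts) if c < min_songs]
    if small:
        raise ValueError(f"societies with fewer than {min_songs} songs: {small}")
    d2 = squareform(pdist(values, metric="sqeuclidean"))
    n = len(labels)
    out = np.zeros((n, n))
    idx_by_pop = [np.flatnonzero(inv == i) for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            idx = np.concatenate([idx_by_pop[i], idx_by_pop[j]])
            sub = d2[np.ix_(idx, idx)]
            pops = np.concatenate([
                np.zeros(len(idx_by_pop[i]), dtype=int),
                np.ones(len(idx_by_pop[j]), dtype=int),
            ])
            if sub.max() == 0.0:
                warnings.warn(f"zero total variance for pair ({labels[i]}, {labels[j]}): Phi_ST NaN")
                out[i, j] = out[j, i] = np.nan
                continue
            *_, sigma_a, sigma_w = _one_level(sub, pops)
            total = sigma_a + sigma_w
            out[i, j] = out[j, i] = sigma_a / total if total > 0 else np.nan
    return DistanceMatrix(out, [str(l) for l in labels])


def fixation_comparison(phist: DistanceMatrix, fst: DistanceMatrix) -> pd.DataFrame:
    """Paired comparison of musical Phi_ST against genetic F_ST per society pair.

    Returns a tidy frame with one row per shared pair: both statistics, their
    difference and their ratio (NaN where F_ST <= 0), plus summary quantiles
    accessible via ``.attrs['quantiles']``.
    """
    shared = DistanceMatrix.shared_labels(phist, fst)
    n_pairs = len(shared) * (len(shared) - 1) // 2
    if n_pairs < 3:
        raise ValueError(f"only {n_pairs} shared society pairs; need at least 3")
    a = phist.select(shared)
    b = fst.select(shared)
    rows = []
    for i in range(len(shared)):
        for j in range(i + 1, len(shared)):
            pv, fv = a.values[i, j], b.values[i, j]
            rows.append({
                "society_a": shared[i],
                "society_b": shared[j],
                "phi_st": pv,
                "f_st": fv,
                "difference": pv - fv,
                "ratio": pv / fv if fv > 0 else np.nan,
            })
    out = pd.DataFrame(rows)
    qs = [0.1, 0.25, 0.5, 0.75, 0.9]
    out.attrs["quantiles"] = {
        "difference": out["difference"].quantile(qs).to_dict(),
        "ratio": out["ratio"].quantile(qs).to_dict(),
    }
    return out
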