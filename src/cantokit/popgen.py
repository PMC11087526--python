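"""Weir-Cockerham F_ST from biallelic genotype dosages.

The theta estimator of Weir & Cockerham (1984) decomposes allelic variance
per SNP into among-population (a), among-individual-within-population (b)
and within-individual (c) components from allele frequencies, sample sizes
and observed heterozygosity, and combines SNPs as a ratio of averages:

    theta = sum_l a_l / sum_l (a_l + b_l + c_l)

(never the average of per-SNP ratios, which is biased).  Missing dosages are
excluded per SNP per population; a SNP is skipped for a pair when either
population has fewer than two called individuals or when it is monomorphic
across both populations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import DistanceMatrix

__all__ = ["wc_fst_pair", "wc_fst_matrix", "wc_components"]

MIN_RECOMMENDED = 5  # warn below this many individuals per population


def _dosage_matrix(panel: pd.DataFrame, pop: str) -> np.ndarray:
    sub = panel[panel["population"].astype(str) == str(pop)]
    if sub.empty:
        raise KeyError(f"population {pop!r} not in panel")
    snp_cols = [c for c in panel.columns if c not in ("individual", "population")]
    return sub[snp_cols].to_numpy(dtype=float)


def wc_components(gA: np.ndarray, gB: np.ndarray):
    """Per-SNP Weir-Cockerham variance components a, b, c for two populations.

    ``gA``/``gB`` are individuals x SNPs dosage matrices (0/1/2, NaN missing).
    Returns (a, b, c, usable) arrays; ``usable`` flags SNPs contributing to
    the ratio (>=2 called individuals in both populations, polymorphic).
    """
    r = 2
    out_a = np.zeros(gA.shape[1])
    out_b = np.zeros(gA.shape[1])
    out_c = np.zeros(gA.shape[1])
    nA = np.sum(~np.isnan(gA), axis=0).astype(float)
    nB = np.sum(~np.isnan(gB), axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pA = np.nansum(gA, axis=0) / (2 * nA)
        pB = np.nansum(gB, axis=0) / (2 * nB)
        hA = np.sum(gA == 1, axis=0) / nA  # observed heterozygote proportion
        hB = np.sum(gB == 1, axis=0) / nB
    usable = (nA >= 2) & (nB >= 2)
    # monomorphic across both populations contributes nothing
    usable &= ~((pA == 0) & (pB == 0)) & ~((pA == 1) & (pB == 1))
    n_bar = (nA + nB) / r
    n_c = (r * n_bar - (nA**2 + nB**2) / (r * n_bar)) / (r - 1)
    p_bar = (nA * pA + nB * pB) / (r * n_bar)
    s2 = (nA * (pA - p_bar) ** 2 + nB * (pB - p_bar) ** 2) / ((r - 1) * n_bar)
    h_bar = (nA * hA + nB * hB) / (r * n_bar)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4) / (n_bar - 1)
        )
        b = (n_bar / (n_bar - 1)) * (
            p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
        )
        c = h_bar / 2
    usable &= np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    out_a[usable] = a[usable]
    out_b[usable] = b[usable]
    out_c[usable] = c[usable]
    return out_a, out_b, out_c, usable


def wc_fst_pair(
    panel: pd.DataFrame,
    pop_a: str,
    pop_b: str,
    min_individuals: int = 2,
) -> tuple[float, int]:
    """Weir-Cockerham theta between two labeled populations.

    Returns ``(theta, n_snps_used)``.  Negative theta is reported raw.
    Populations below :data:`MIN_RECOMMENDED` individuals trigger a warning
    (small samples make theta noisy); below ``min_individuals`` it is an error.
    """
    import warnings

    gA = _dosage_matrix(panel, pop_a)
    gB = _dosage_matrix(panel, pop_b)
    for name, g in ((pop_a, gA), (pop_b, gB)):
        if g.shape[0] < min_individuals:
            raise ValueError(f"population {name!r} has {g.shape[0]} individuals; need >= {min_individuals}")
        if g.shape[0] < MIN_RECOMMENDED:
            warnings.warn(f"population {name!r} has {g.shape[0]} < {MIN_RECOMMENDED} individuals")
    a, b, c, usable = wc_components(gA, gB)
    n_used = int(usable.sum())
    if n_used == 0:
        raise ValueError(f"no usable SNPs for pair ({pop_a!r}, {pop_b!r})")
    denom = (a + b + c)[usable].sum()
    if denom == 0:
        raise ValueError(f"zero total variance over usable SNPs for ({pop_a!r}, {pop_b!r})")
    return float(a[usable].sum() / denom), n_used


def wc_fst_matrix(panel: pd.DataFrame, min_individuals: int = 2) -> DistanceMatrix:
    """Pairwise Weir-Cockerham theta over every population pair."""
    pops = sorted(panel["population"].astype(str).unique())
    n = len(pops)
    if n < 2:
        raise ValueError("need at least two populations")
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            theta, _ = wc_fst_pair(panel, pops[i], pops[j], min_individuals=min_individuals)
            out[i, j] = out[j, i] = theta
    return DistanceMatrix(out, pops)
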