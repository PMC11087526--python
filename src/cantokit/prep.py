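"""Preparation of ordinal song codings for analysis.

Raw Cantometrics-style tables rate each song on ~24 ordinal features whose
code values are non-consecutive integers (e.g. {1, 4, 7, 10, 13}) and where a
song may carry several codes on one feature.  This module turns such a table
into the analysis-ready form: a single randomly chosen code per cell, ordinal
ranks rescaled to [0, 1] (reversed where the scheme says high codes mean *less*
of the trait), societies filtered to a minimum song count, unreliable features
dropped, and per-society mean profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, TransformerMixin

from .io import feature_columns

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureSpec",
    "CodingScheme",
    "select_single_code",
    "standardize",
    "CantometricScaler",
    "filter_min_songs",
    "filter_reliability",
    "society_profile",
]


@dataclass
class FeatureSpec:
    """One ordinal feature: its ordered code values and bookkeeping flags."""

    codes: list[float]
    reversed: bool = False
    kappa: float | None = None
    include: bool = True

    def __post_init__(self):
        if not self.codes:
            raise ValueError("feature code set must be non-empty")
        self.codes = sorted(float(c) for c in self.codes)
        if self.kappa is not None and not (-1.0 <= self.kappa <= 1.0):
            raise ValueError(f"kappa {self.kappa} outside [-1, 1]")


@dataclass
class CodingScheme:
    """Per-feature coding metadata plus the reliability keep-list."""

    features: dict[str, FeatureSpec] = field(default_factory=dict)
    keep_list: list[str] = field(default_factory=list)

    def included(self) -> list[str]:
        return [name for name, f in self.features.items() if f.include]

    @classmethod
    def from_yaml(cls, path) -> "CodingScheme":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        feats = {
            name: FeatureSpec(
                codes=spec["codes"],
                reversed=spec.get("reversed", False),
                kappa=spec.get("kappa"),
                include=spec.get("include", True),
            )
            for name, spec in raw.get("features", {}).items()
        }
        return cls(features=feats, keep_list=list(raw.get("keep_list", [])))

    def to_yaml(self, path) -> None:
        raw = {
            "features": {
                name: {
                    "codes": f.codes,
                    "reversed": f.reversed,
                    "kappa": f.kappa,
                    "include": f.include,
                }
                for name, f in self.features.items()
            },
            "keep_list": self.keep_list,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh)


def _parse_cell(cell) -> list[float]:
    if isinstance(cell, float) and np.isnan(cell):
        return []
    parts = str(cell).split("|")
    try:
        return [float(p) for p in parts if p != ""]
    except ValueError as exc:
        raise ValueError(f"cannot parse code cell {cell!r}") from exc


def select_single_code(table: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Resolve multi-coded cells to one code each, uniformly at random.

    Deterministic given ``seed``; singleton cells pass through unchanged.  The
    fraction of affected cells is logged (a few percent on real codings).
    """
    rng = np.random.default_rng(seed)
    out = table.copy()
    feats = feature_columns(table)
    n_multi = 0
    n_cells = 0
    for col in feats:
        resolved = []
        for cell in table[col]:
            codes = _parse_cell(cell)
            if not codes:
                raise ValueError(f"empty code list in column {col!r}")
            n_cells += 1
            if len(codes) > 1:
                n_multi += 1
                resolved.append(codes[int(rng.integers(len(codes)))])
            else:
                resolved.append(codes[0])
        out[col] = resolved
    if n_cells:
        logger.info(
            "select_single_code: %d/%d cells (%.1f%%) were multi-coded",
            n_multi, n_cells, 100.0 * n_multi / n_cells,
        )
    return out


def standardize(table: pd.DataFrame, scheme: CodingScheme) -> pd.DataFrame:
    """Rescale ordinal codes to [0, 1] by rank within the declared code set.

    value = rank(code) / (n_codes - 1); reversed features use the reversed
    rank so that high values always mean a more frequent occurrence of what
    the feature measures.  Idempotent: already-rescaled values pass through.
    Constant features (a single declared code) are dropped with a warning.
    """
    out = table.copy()
    for col in feature_columns(table):
        if col not in scheme.features or not scheme.features[col].include:
            out = out.drop(columns=col)
            continue
        spec = scheme.features[col]
        codes = spec.codes
        if len(codes) == 1:
            logger.warning("standardize: feature %r is constant, dropping", col)
            out = out.drop(columns=col)
            continue
        denom = len(codes) - 1
        mapping = {}
        for rank, c in enumerate(codes):
            scaled = rank / denom
            if spec.reversed:
                scaled = 1.0 - scaled
            mapping[c] = scaled
        vals = pd.to_numeric(out[col])
        observed = set(np.asarray(vals))
        # idempotence: a column whose values are scaled ranks (and not plain
        # codes) has been standardized already and passes through unchanged
        if observed <= set(mapping.values()) and not observed <= set(mapping):
            out[col] = vals.astype(float)
            continue
        unknown = sorted(observed - set(mapping))
        if unknown:
            raise ValueError(f"feature {col!r}: codes {unknown} not in declared code set")
        out[col] = vals.map(mapping).astype(float)
    return out


class CantometricScaler(TransformerMixin, BaseEstimator):
    """sklearn-style wrapper around :func:`select_single_code` + :func:`standardize`.

    Stateless apart from the coding scheme; ``fit`` only validates, so the
    scaler can sit at the head of a pipeline feeding the latent-variable model.
    """

    def __init__(self, scheme: CodingScheme | None = None, seed: int = 0):
        self.scheme = scheme
        self.seed = seed

    def fit(self, X: pd.DataFrame, y=None):
        if self.scheme is None:
            raise ValueError("a CodingScheme is required")
        self.feature_names_in_ = [c for c in feature_columns(X) if c in self.scheme.features]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return standardize(select_single_code(X, self.seed), self.scheme)


def filter_min_songs(table: pd.DataFrame, k: int) -> pd.DataFrame:
    """Keep only societies with at least ``k`` songs."""
    if k < 1:
        raise ValueError("k must be >= 1")
    counts = table.groupby("society").size()
    keep = counts.index[counts >= k]
    out = table[table["society"].isin(keep)].reset_index(drop=True)
    logger.info(
        "filter_min_songs(k=%d): %d songs / %d societies -> %d songs / %d societies",
        k, len(table), counts.size, len(out), len(keep),
    )
    if out.empty:
        raise ValueError(f"no society has >= {k} songs")
    return out


def filter_reliability(scheme: CodingScheme, threshold: float = 0.4) -> CodingScheme:
    """Exclude features whose inter-rater kappa falls below ``threshold``.

    Features on the scheme's keep-list are retained regardless (with a
    warning) — some low-reliability features are needed for the latent model
    to converge at all.
    """
    feats = {}
    for name, f in scheme.features.items():
        keep = f.include
        if keep and f.kappa is None:
            raise ValueError(f"feature {name!r} has no kappa; cannot reliability-filter")
        if keep and f.kappa < threshold:
            if name in scheme.keep_list:
                logger.warning(
                    "filter_reliability: %r kept despite kappa=%.2f < %.2f (keep-list)",
                    name, f.kappa, threshold,
                )
            else:
                keep = False
        feats[name] = FeatureSpec(codes=f.codes, reversed=f.reversed, kappa=f.kappa, include=keep)
    return CodingScheme(features=feats, keep_list=list(scheme.keep_list))


def society_profile(table: pd.DataFrame) -> pd.DataFrame:
    """Per-society mean over songs of each (standardized) feature.

    The resulting society x feature matrix is the 'modal profile' used for
    aggregate musical similarity.
    """
    feats = feature_columns(table)
    return table.groupby("society")[feats].mean()
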