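"""Readers and writers for the package's plain-text formats.

Conventions
-----------
* Song tables are TSV.  Reserved metadata columns are ``song``, ``society``,
  ``family``, ``region`` and (optionally) ``glottocode``; every other column is
  a feature.  A cell carrying several ordinal codes joins them with ``|``
  (e.g. ``"1|5"``).
* Distance matrices are square CSV with labels both in the header and in the
  first column; symmetry is checked to 1e-8 and the matrix averaged.
* Geographic tables are CSV with columns ``society, lon, lat``.
* Trees are Newick, parsed with dendropy; negative branch lengths are refused.
* Genotype panels are CSV with an ``individual`` and a ``population`` column
  followed by one column per SNP holding dosages in {0, 1, 2} or blank for
  missing.
"""

from __future__ import annotations

import os
import numpy as np
import pandas as pd

from .core import DistanceMatrix, GeoTable

META_COLUMNS = ("song", "society", "family", "region", "glottocode")

__all__ = [
    "META_COLUMNS",
    "feature_columns",
    "read_song_table",
    "write_song_table",
    "read_distance_matrix",
    "write_distance_matrix",
    "read_geo_table",
    "write_geo_table",
    "read_tree",
    "write_tree",
    "read_genotype_panel",
    "write_genotype_panel",
]


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Columns of a song table that carry feature codes (non-metadata)."""
    return [c for c in table.columns if c not in META_COLUMNS]


class ParseError(ValueError):
    """Malformed input file; carries the offending line when known."""


def read_song_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[""])
    if "society" not in table.columns:
        raise ParseError(f"{path}: song table must have a 'society' column")
    if table["society"].isna().any():
        row = int(table.index[table["society"].isna()][0]) + 2  # 1-based + header
        raise ParseError(f"{path}: empty society id at line {row}")
    return table


def write_song_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_distance_matrix(path, *, sym_tol: float = 1e-8) -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        return DistanceMatrix.from_frame(df, sym_tol=sym_tol)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_distance_matrix(d: DistanceMatrix, path) -> None:
    d.to_frame().to_csv(path, float_format=None)  # full repr precision


def read_geo_table(path) -> GeoTable:
    df = pd.read_csv(path)
    required = {"society", "lon", "lat"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: geographic table needs columns {sorted(required)}")
    return GeoTable(df["society"].astype(str).tolist(), df["lon"].to_numpy(), df["lat"].to_numpy())


def write_geo_table(geo: GeoTable, path) -> None:
    geo.to_frame().to_csv(path, index=False)


def read_tree(path_or_string):
    """Parse a rooted Newick tree (path or literal string)."""
    import dendropy

    if isinstance(path_or_string, (str, os.PathLike)) and os.path.exists(path_or_string):
        with open(path_or_string) as fh:
            newick = fh.read()
    else:
        newick = str(path_or_string)
    tree = dendropy.Tree.get(data=newick, schema="newick")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ParseError(f"negative branch length {edge.length} in Newick input")
    return tree


def write_tree(tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def read_genotype_panel(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"individual": str, "population": str})
    for col in ("individual", "population"):
        if col not in df.columns:
            raise ParseError(f"{path}: genotype panel needs an '{col}' column")
    snp_cols = [c for c in df.columns if c not in ("individual", "population")]
    for c in snp_cols:
        vals = pd.to_numeric(df[c], errors="coerce")
        bad = vals.dropna()[~vals.dropna().isin([0, 1, 2])]
        if len(bad):
            row = int(bad.index[0]) + 2
            raise ParseError(f"{path}: dosage {bad.iloc[0]} outside {{0,1,2}} at line {row}, column {c}")
        df[c] = vals
    if (df.groupby("population").size() < 1).any():
        raise ParseError(f"{path}: empty population")
    return df


def write_genotype_panel(panel: pd.DataFrame, path) -> None:
    panel.to_csv(path, index=False)
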