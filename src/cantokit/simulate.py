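"""Synthetic worlds with known ground truth for every pipeline stage.

A world is built in layers, all hanging off one phylogeny:

1. A Yule (pure-birth) society tree, rescaled to unit root-to-tip depth.
2. Brownian evolution of the latent trait means along the branches
   (rate ``trait_rate``), one dimension per latent musical axis.
3. Geographic placement by 2-D Brownian diffusion along the same tree
   (``geo_scale`` degrees per unit depth), so geography mirrors ancestry.
4. Horizontal transmission: for each society, each latent dimension is
   independently replaced, with probability ``h``, by that dimension's value
   in a random one of the society's ``n_neighbors`` nearest geographic
   neighbors (0 = purely vertical descent).  Because different dimensions
   then inherit from different donors — the classic signature of borrowing —
   this measurably breaks treelikeness, which simple neighbor *averaging*
   does not (averaging smooths the trait field and lowers quartet conflict).
5. Songs: per-song latent values are the society mean plus within-society
   noise ``song_noise``; latent song scores are standardized over the whole
   song population and mapped to 24 ordinal indicators through the true
   loading matrix plus unique noise sd sqrt(1 - lambda^2), then binned to 13
   ordinal code levels.  A fraction of cells gets a second adjacent code, to
   exercise the single-code selection step.  ``song_noise = 0`` produces a
   noise-free world (songs are exact copies of the society profile).
6. Genotypes: per-SNP ancestral frequencies drift down the same tree under
   the Balding-Nichols model with per-branch F = 1 - exp(-drift_f * length);
   individual dosages are binomial draws from the tip frequencies.

One global seed fans out to independent per-layer streams via
``numpy.random.SeedSequence(seed).spawn``, so e.g. changing the genetic
layer's parameters never perturbs the songs.
"""

from __future__ import annotations

import json
import random as _pyrandom
from dataclasses import asdict, dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .core import GeoTable, haversine_matrix
from .io import (
    write_genotype_panel,
    write_geo_table,
    write_song_table,
    write_tree,
)
from .prep import CodingScheme, FeatureSpec

__all__ = ["SimConfig", "SimWorld", "simulate_world", "emit_fixtures"]

N_CODE_LEVELS = 13  # ordinal granularity of the emitted song codes


@dataclass
class SimConfig:
    """Generating parameters of a synthetic world."""

    n_societies: int = 30
    songs_per_society: int = 10
    birth_rate: float = 1.0
    trait_rate: float = 1.0          # Brownian rate of latent means on the tree
    h: float = 0.0                   # horizontal transmission probability in [0, 1]
    n_neighbors: int = 5
    song_noise: float = 0.5          # within-society sd on the latent scale
    n_latent: int = 5
    n_indicators: int = 24
    loading: float = 0.7             # true standardized loading of each indicator
    geo_scale: float = 30.0          # degrees of Brownian diffusion per unit depth
    n_snps: int = 500
    drift_f: float = 0.05            # Balding-Nichols F per unit branch length
    n_individuals: int = 10
    multi_code_fraction: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if self.songs_per_society < 2:
            raise ValueError("songs_per_society must be >= 2")
        if not 0.0 <= self.h <= 1.0:
            raise ValueError("h must lie in [0, 1]")
        for name in ("birth_rate", "trait_rate", "song_noise", "geo_scale", "drift_f"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_societies < 4:
            raise ValueError("need at least 4 societies")
        if self.n_indicators < self.n_latent:
            raise ValueError("need at least one indicator per latent")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class SimWorld:
    """A fully generated world plus its ground truth."""

    config: SimConfig
    tree: dendropy.Tree
    geo: GeoTable
    latent_means: pd.DataFrame        # society x latent, after horizontal mixing
    latent_means_vertical: pd.DataFrame  # before mixing (pure tree signal)
    song_table: pd.DataFrame
    genotypes: pd.DataFrame
    allele_freqs: pd.DataFrame        # society x SNP tip frequencies
    loadings_true: pd.DataFrame       # indicator x latent
    scheme: CodingScheme
    latent_names: list[str] = field(default_factory=list)

    @property
    def newick(self) -> str:
        return self.tree.as_string(schema="newick").strip()


LATENT_NAMES = ["Articulation", "Tension", "Ornamentation", "Rhythm", "Dynamics"]


def _latent_names(k: int) -> list[str]:
    if k <= len(LATENT_NAMES):
        return LATENT_NAMES[:k]
    return LATENT_NAMES + [f"Latent{i}" for i in range(len(LATENT_NAMES) + 1, k + 1)]


def _yule_tree(cfg: SimConfig, seed: int) -> dendropy.Tree:
    from dendropy.model import birthdeath

    tree = birthdeath.birth_death_tree(
        birth_rate=cfg.birth_rate,
        death_rate=0.0,
        num_extant_tips=cfg.n_societies,
        rng=_pyrandom.Random(int(seed)),
    )
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"S{i + 1:03d}"
    depth = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    if depth > 0:
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length = edge.length / depth
    return tree


def _brownian_on_tree(tree: dendropy.Tree, rate: float, ndim: int, rng) -> dict[str, np.ndarray]:
    values: dict[int, np.ndarray] = {}
    out = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            values[id(node)] = np.zeros(ndim)
        else:
            length = node.edge.length or 0.0
            step = rng.normal(0.0, np.sqrt(max(rate, 0.0) * length), size=ndim)
            values[id(node)] = values[id(node.parent_node)] + step
        if node.is_leaf():
            out[node.taxon.label] = values[id(node)]
    return out


def _balding_nichols_on_tree(tree, cfg: SimConfig, rng) -> dict[str, np.ndarray]:
    eps = 1e-6
    p_root = rng.uniform(0.1, 0.9, size=cfg.n_snps)
    freqs: dict[int, np.ndarray] = {}
    out = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            freqs[id(node)] = p_root
        else:
            length = node.edge.length or 0.0
            f = 1.0 - np.exp(-cfg.drift_f * length)
            parent = np.clip(freqs[id(node.parent_node)], eps, 1 - eps)
            if f < 1e-9:
                child = parent.copy()
            else:
                shape = (1.0 - f) / f
                child = rng.beta(parent * shape, (1.0 - parent) * shape)
            freqs[id(node)] = np.clip(child, 0.0, 1.0)
        if node.is_leaf():
            out[node.taxon.label] = freqs[id(node)]
    return out


def simulate_world(cfg: SimConfig) -> SimWorld:
    """Generate a :class:`SimWorld` from ``cfg`` (deterministic given seed)."""
    ss = np.random.SeedSequence(cfg.seed)
    seeds = ss.spawn(6)
    rng_tree = np.random.default_rng(seeds[0])
    rng_trait = np.random.default_rng(seeds[1])
    rng_geo = np.random.default_rng(seeds[2])
    rng_song = np.random.default_rng(seeds[3])
    rng_gene = np.random.default_rng(seeds[4])
    rng_multi = np.random.default_rng(seeds[5])

    tree = _yule_tree(cfg, int(rng_tree.integers(2**31 - 1)))
    societies = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    lat_names = _latent_names(cfg.n_latent)

    # latent trait means on the tree
    trait_tips = _brownian_on_tree(tree, cfg.trait_rate, cfg.n_latent, rng_trait)
    vertical = pd.DataFrame(
        np.array([trait_tips[s] for s in societies]), index=societies, columns=lat_names
    )

    # geography: Brownian diffusion along the same tree, wrapped/clamped
    geo_tips = _brownian_on_tree(tree, cfg.geo_scale**2, 2, rng_geo)
    lon = np.array([geo_tips[s][0] for s in societies])
    lat = np.array([geo_tips[s][1] for s in societies])
    lon = (lon + 180.0) % 360.0 - 180.0
    lat = np.clip(lat, -80.0, 80.0)
    geo = GeoTable(societies, lon, lat)

    # horizontal transmission: per-dimension borrowing from nearest neighbors
    mixed = vertical.copy()
    if cfg.h > 0:
        geo_d = haversine_matrix(geo)
        k = min(cfg.n_neighbors, len(societies) - 1)
        vert = vertical.to_numpy()
        out = vert.copy()
        for i in range(len(societies)):
            order = np.argsort(geo_d.values[i])
            nb = [j for j in order if j != i][:k]
            for dim in range(cfg.n_latent):
                if rng_trait.random() < cfg.h:
                    out[i, dim] = vert[nb[int(rng_trait.integers(k))], dim]
        mixed = pd.DataFrame(out, index=societies, columns=lat_names)

    # true loading matrix: indicators split evenly over latents
    lam = np.zeros((cfg.n_indicators, cfg.n_latent))
    assign = [i % cfg.n_latent for i in range(cfg.n_indicators)]
    for row, col in enumerate(assign):
        lam[row, col] = cfg.loading
    indicators = [f"line{row + 1:02d}" for row in range(cfg.n_indicators)]
    loadings_true = pd.DataFrame(lam, index=indicators, columns=lat_names)

    # songs
    n_songs = cfg.n_societies * cfg.songs_per_society
    song_soc = np.repeat(societies, cfg.songs_per_society)
    eta = mixed.loc[song_soc].to_numpy()
    if cfg.song_noise > 0:
        eta = eta + rng_song.normal(0.0, cfg.song_noise, size=eta.shape)
    # standardize latent song scores so true standardized loadings = cfg.loading
    eta_std = (eta - eta.mean(axis=0)) / np.where(eta.std(axis=0) > 0, eta.std(axis=0), 1.0)
    x = eta_std @ lam.T
    if cfg.song_noise > 0:
        unique_sd = np.sqrt(np.clip(1.0 - cfg.loading**2, 0.0, None))
        x = x + rng_song.normal(0.0, unique_sd, size=x.shape)
    # ordinal binning over a +-3 sd window into 1..N_CODE_LEVELS
    codes = np.clip(
        np.floor((x + 3.0) / 6.0 * N_CODE_LEVELS), 0, N_CODE_LEVELS - 1
    ).astype(int) + 1

    cells = codes.astype(object)
    if cfg.multi_code_fraction > 0:
        mask = rng_multi.random(codes.shape) < cfg.multi_code_fraction
        for r, c in zip(*np.nonzero(mask)):
            first = codes[r, c]
            second = first + 1 if first < N_CODE_LEVELS else first - 1
            cells[r, c] = f"{first}|{second}"

    # macro-group labels: family from the root split, region from longitude terciles
    root_children = tree.seed_node.child_nodes()
    fam_of = {}
    for ci, child in enumerate(root_children):
        for leaf in child.leaf_iter():
            fam_of[leaf.taxon.label] = f"F{ci + 1}"
    terciles = np.quantile(lon, [1 / 3, 2 / 3])
    region_of = {
        s: ("West" if lo <= terciles[0] else "Central" if lo <= terciles[1] else "East")
        for s, lo in zip(societies, lon)
    }
    song_table = pd.DataFrame({
        "song": [f"song{i + 1:04d}" for i in range(n_songs)],
        "society": song_soc,
        "family": [fam_of[s] for s in song_soc],
        "region": [region_of[s] for s in song_soc],
    })
    for j, name in enumerate(indicators):
        song_table[name] = cells[:, j]

    # coding scheme: full 13-level ordinal codes, plausible per-feature kappas
    kappas = rng_multi.uniform(0.3, 0.95, size=cfg.n_indicators)
    scheme = CodingScheme(
        features={
            name: FeatureSpec(codes=list(range(1, N_CODE_LEVELS + 1)), kappa=float(k))
            for name, k in zip(indicators, kappas)
        },
        keep_list=[indicators[0]],
    )

    # genotypes
    tip_freqs = _balding_nichols_on_tree(tree, cfg, rng_gene)
    freq_df = pd.DataFrame(
        np.array([tip_freqs[s] for s in societies]),
        index=societies,
        columns=[f"snp{j + 1:04d}" for j in range(cfg.n_snps)],
    )
    rows = []
    for s in societies:
        dosages = rng_gene.binomial(2, freq_df.loc[s].to_numpy(),
                                    size=(cfg.n_individuals, cfg.n_snps))
        for ind in range(cfg.n_individuals):
            rows.append([f"{s}_i{ind + 1:02d}", s, *dosages[ind]])
    genotypes = pd.DataFrame(rows, columns=["individual", "population", *freq_df.columns])

    return SimWorld(
        config=cfg,
        tree=tree,
        geo=geo,
        latent_means=mixed,
        latent_means_vertical=vertical,
        song_table=song_table,
        genotypes=genotypes,
        allele_freqs=freq_df,
        loadings_true=loadings_true,
        scheme=scheme,
        latent_names=lat_names,
    )


def emit_fixtures(world: SimWorld, out_dir) -> dict[str, str]:
    """Write the world to plain-text files; returns a name -> path manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "songs": out / "songs.tsv",
        "geo": out / "geo.csv",
        "tree": out / "tree.nwk",
        "genotypes": out / "genotypes.csv",
        "scheme": out / "scheme.yaml",
        "truth": out / "truth.json",
    }
    write_song_table(world.song_table, paths["songs"])
    write_geo_table(world.geo, paths["geo"])
    write_tree(world.tree, paths["tree"])
    write_genotype_panel(world.genotypes, paths["genotypes"])
    world.scheme.to_yaml(paths["scheme"])
    truth = {
        "config": asdict(world.config),
        "latent_names": world.latent_names,
        "loadings_true": world.loadings_true.to_dict(),
        "latent_means": world.latent_means.to_dict(),
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=2)
    return {k: str(v) for k, v in paths.items()}
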