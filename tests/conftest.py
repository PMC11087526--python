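import numpy as np
import pandas as pd
import pytest

import cantokit as ck
from cantokit.io import feature_columns
from cantokit.pipeline import default_model_spec


@pytest.fixture(scope="session")
def world():
    """A default synthetic world shared by read-only tests."""
    return ck.simulate_world(ck.SimConfig(seed=1))


@pytest.fixture(scope="session")
def prepped(world):
    """Analysis-ready standardized song table for the default world."""
    table = ck.select_single_code(world.song_table, seed=7)
    return ck.standardize(table, world.scheme)


@pytest.fixture(scope="session")
def cfa_fit(world, prepped):
    spec = default_model_spec(feature_columns(prepped), world.latent_names)
    return ck.fit_cfa(prepped, spec, n_restarts=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_distance_matrix(rng, n, euclidean=False):
    """A valid random DistanceMatrix (optionally Euclidean-embeddable)."""
    if euclidean:
        pts = rng.normal(size=(n, 3))
        from scipy.spatial.distance import pdist, squareform

        vals = squareform(pdist(pts))
    else:
        vals = rng.uniform(0.1, 2.0, size=(n, n))
        vals = 0.5 * (vals + vals.T)
        np.fill_diagonal(vals, 0.0)
    return ck.DistanceMatrix(vals, [f"t{i}" for i in range(n)])


# keep hypothesis runs reproducible across environments
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")
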