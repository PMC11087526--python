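"""PCoA, Mantel and partial RDA: oracles, analytic limits, null behavior."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

import cantokit as ck
from cantokit.association import _ezekiel

from conftest import random_distance_matrix


def euclid_dm(pts, labels=None):
    labels = labels or [f"t{i}" for i in range(len(pts))]
    return ck.DistanceMatrix(squareform(pdist(np.asarray(pts, float))), labels)


class TestPcoa:
    def test_collinear_points_one_axis(self):
        d = euclid_dm([[0.0], [1.0], [2.0]])
        res = ck.pcoa(d)
        assert res.coordinates.shape[1] == 1
        assert res.percent_variance[0] == pytest.approx(100.0)
        # axis reproduces the centered coordinates -1, 0, 1 up to sign
        axis = res.coordinates.iloc[:, 0].to_numpy()
        assert np.allclose(np.abs(axis), [1.0, 0.0, 1.0], atol=1e-10)

    def test_euclidean_embedding_reproduces_distances(self, rng):
        pts = rng.normal(size=(8, 2))
        d = euclid_dm(pts)
        res = ck.pcoa(d)
        recon = squareform(pdist(res.coordinates.to_numpy()))
        assert np.allclose(recon, d.values, atol=1e-8)

    def test_equilateral_triple_two_equal_axes(self):
        d = ck.DistanceMatrix(np.ones((3, 3)) - np.eye(3), list("abc"))
        res = ck.pcoa(d)
        assert len(res.percent_variance) == 2
        assert np.allclose(res.percent_variance, 50.0, atol=1e-8)
        assert res.selected_axes(10.0).shape[1] == 2

    def test_matches_skbio_oracle(self, rng):
        import skbio

        d = random_distance_matrix(rng, 7, euclidean=True)
        res = ck.pcoa(d)
        ref = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d.values, d.labels))
        npos = res.coordinates.shape[1]
        ref_eig = np.sort(ref.eigvals.to_numpy())[::-1][:npos]
        assert np.allclose(np.sort(res.eigenvalues)[::-1][:npos], ref_eig, atol=1e-8)
        for k in range(min(3, npos)):
            mine = res.coordinates.iloc[:, k].to_numpy()
            theirs = ref.samples.iloc[:, k].to_numpy()
            assert abs(np.corrcoef(mine, theirs)[0, 1]) > 1 - 1e-8

    def test_estimator_wrapper(self, rng):
        d = random_distance_matrix(rng, 6, euclidean=True)
        est = ck.PrincipalCoordinates(axis_threshold_percent=10.0).fit(d)
        assert est.coordinates_.shape[0] == 6
        assert est.selected_axes_.shape[1] >= 1


def mantel_exact_oracle(a, b):
    """Exhaustive-permutation Mantel p by explicit loops (n=4: 24 perms)."""
    n = a.shape[0]
    iu = np.triu_indices(n, 1)
    va = a[iu]

    def corr(mat):
        vb = mat[iu]
        return np.corrcoef(va, vb)[0, 1]

    r_obs = corr(b)
    hits = 0
    total = 0
    for perm in permutations(range(n)):
        p = np.array(perm)
        if abs(corr(b[np.ix_(p, p)])) >= abs(r_obs) - 1e-12:
            hits += 1
        total += 1
    return r_obs, hits / total


class TestMantel:
    def test_self_correlation_is_one(self, rng):
        a = random_distance_matrix(rng, 6)
        res = ck.mantel(a, a, n_permutations=0)
        assert res.statistic == pytest.approx(1.0)

    def test_symmetric_in_arguments(self, rng):
        a = random_distance_matrix(rng, 8)
        b = random_distance_matrix(rng, 8)
        r1 = ck.mantel(a, b, n_permutations=0).statistic
        r2 = ck.mantel(b, a, n_permutations=0).statistic
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_exact_enumeration_matches_oracle(self, rng):
        for _ in range(10):
            a = random_distance_matrix(rng, 4)
            b = random_distance_matrix(rng, 4)
            res = ck.mantel(a, b, exact=True)
            r_ref, p_ref = mantel_exact_oracle(a.values, b.values)
            assert res.statistic == pytest.approx(r_ref, abs=1e-12)
            assert res.p_value == pytest.approx(p_ref, abs=1e-12)

    def test_matches_skbio_r(self, rng):
        import skbio

        a = random_distance_matrix(rng, 10)
        b = random_distance_matrix(rng, 10)
        res = ck.mantel(a, b, n_permutations=0)
        r_ref, _, _ = skbio.stats.distance.mantel(
            skbio.DistanceMatrix(a.values, a.labels),
            skbio.DistanceMatrix(b.values, b.labels),
            permutations=0,
        )
        assert res.statistic == pytest.approx(r_ref, abs=1e-10)

    def test_independent_matrices_rarely_significant(self, rng):
        ok = 0
        for _ in range(100):
            a = random_distance_matrix(rng, 50, euclidean=True)
            b = random_distance_matrix(rng, 50, euclidean=True)
            res = ck.mantel(a, b, n_permutations=99,
                            seed=int(rng.integers(2**31)))
            if abs(res.statistic) < 0.3 and res.p_value > 0.01:
                ok += 1
        assert ok >= 95

    def test_constant_matrix_is_error(self):
        a = ck.DistanceMatrix(np.ones((4, 4)) - np.eye(4), list("abcd"))
        b = ck.DistanceMatrix(np.ones((4, 4)) - np.eye(4), list("abcd"))
        with pytest.raises(ValueError, match="constant"):
            ck.mantel(a, b, n_permutations=0)

    def test_null_p_uniform(self, rng):
        ps = []
        for _ in range(100):
            a = random_distance_matrix(rng, 15)
            b = random_distance_matrix(rng, 15)
            ps.append(ck.mantel(a, b, n_permutations=99,
                                seed=int(rng.integers(2**31))).p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestPartialMantel:
    def test_uncorrelated_control_leaves_r_alone(self, rng):
        pts = rng.normal(size=(20, 2))
        a = euclid_dm(pts)
        b = euclid_dm(pts + rng.normal(0, 0.3, size=pts.shape))
        c = random_distance_matrix(rng, 20)
        c = ck.DistanceMatrix(c.values, a.labels)
        plain = ck.mantel(a, b, n_permutations=0).statistic
        partial = ck.partial_mantel(a, b, c, n_permutations=0).statistic
        assert partial == pytest.approx(plain, abs=0.1)

    def test_controlling_for_itself_kills_r(self, rng):
        a = random_distance_matrix(rng, 12)
        b = random_distance_matrix(rng, 12)
        res = ck.partial_mantel(a, b, b, n_permutations=0)
        assert abs(res.statistic) < 1e-8

    def test_fully_degenerate_is_error(self, rng):
        a = random_distance_matrix(rng, 8)
        with pytest.raises(ValueError, match="residual"):
            ck.partial_mantel(a, a, a, n_permutations=0)


class TestPartialRda:
    def test_self_prediction_gives_adjusted_one(self, rng):
        a = random_distance_matrix(rng, 10, euclidean=True)
        res = ck.partial_rda(a, a, n_permutations=0)
        assert res.statistic == pytest.approx(1.0, abs=1e-10)

    def test_ezekiel_arithmetic(self):
        # R2=0.5, n=11, m=1 -> 1 - 0.5 * 10/9
        assert _ezekiel(0.5, 11, 1) == pytest.approx(1.0 - 0.5 * 10 / 9, abs=1e-12)

    def test_overparameterized_is_error(self):
        with pytest.raises(ValueError, match="overparameterized"):
            _ezekiel(0.5, 4, 3)

    def test_single_axis_equals_adjusted_squared_pearson(self, rng):
        # 1-D configurations: a single positive axis each
        xa = np.sort(rng.normal(size=12))
        xb = xa * 1.7 + rng.normal(0, 0.5, size=12)
        a = euclid_dm(xa[:, None])
        b = euclid_dm(xb[:, None])
        res = ck.partial_rda(a, b, n_permutations=0)
        ax_a = ck.pcoa(a).selected_axes(10.0).to_numpy()[:, 0]
        ax_b = ck.pcoa(b).selected_axes(10.0).to_numpy()[:, 0]
        r2 = np.corrcoef(ax_a, ax_b)[0, 1] ** 2
        assert res.statistic == pytest.approx(_ezekiel(r2, 12, 1), abs=1e-10)

    def test_semipartial_option_runs(self, rng):
        a = random_distance_matrix(rng, 12, euclidean=True)
        b = random_distance_matrix(rng, 12, euclidean=True)
        c = random_distance_matrix(rng, 12, euclidean=True)
        b = ck.DistanceMatrix(b.values, a.labels)
        c = ck.DistanceMatrix(c.values, a.labels)
        res = ck.partial_rda(a, b, c, n_permutations=0, adjust="semipartial")
        assert np.isfinite(res.statistic)

    def test_null_p_uniform(self, rng):
        ps = []
        for _ in range(80):
            a = random_distance_matrix(rng, 15, euclidean=True)
            b = random_distance_matrix(rng, 15, euclidean=True)
            b = ck.DistanceMatrix(b.values, a.labels)
            ps.append(ck.partial_rda(a, b, n_permutations=99,
                                     seed=int(rng.integers(2**31))).p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01
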