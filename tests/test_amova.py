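"""AMOVA variance decomposition and pairwise Phi_ST against explicit-loop oracles."""

import numpy as np
import pytest

import cantokit as ck


# ---------------------------------------------------------------------------
# brute-force oracle: explicit double loops, no matrix shortcuts
# ---------------------------------------------------------------------------

def sqdist(a, b):
    return sum((x - y) ** 2 for x, y in zip(a, b))


def amova_brute_one_level(values, society):
    """One-level AMOVA from first principles (loops over song pairs)."""
    values = [list(np.atleast_1d(v)) for v in values]
    n = len(values)
    pops = sorted(set(society))
    idx = {p: [i for i, s in enumerate(society) if s == p] for p in pops}
    ss_total = 0.0
    for i in range(n):
        for j in range(n):
            ss_total += sqdist(values[i], values[j])
    ss_total /= 2 * n
    ss_within = 0.0
    for p in pops:
        members = idx[p]
        acc = 0.0
        for i in members:
            for j in members:
                acc += sqdist(values[i], values[j])
        ss_within += acc / (2 * len(members))
    ss_among = ss_total - ss_within
    df_a = len(pops) - 1
    df_w = n - len(pops)
    ms_a = ss_among / df_a
    ms_w = ss_within / df_w
    n0 = (n - sum(len(idx[p]) ** 2 for p in pops) / n) / df_a
    sigma_a = (ms_a - ms_w) / n0
    sigma_w = ms_w
    phi = sigma_a / (sigma_a + sigma_w)
    return dict(ss_total=ss_total, ss_among=ss_among, ss_within=ss_within,
                sigma_a=sigma_a, sigma_w=sigma_w, phi_st=phi)


def amova_brute_two_level(values, society, group):
    values = [list(np.atleast_1d(v)) for v in values]
    n = len(values)
    pops = sorted(set(society))
    groups = sorted(set(group))
    pop_idx = {p: [i for i, s in enumerate(society) if s == p] for p in pops}
    grp_idx = {g: [i for i, s in enumerate(group) if s == g] for g in groups}
    pop_grp = {}
    for s, g in zip(society, group):
        pop_grp[s] = g

    def ss_of(members):
        acc = 0.0
        for i in members:
            for j in members:
                acc += sqdist(values[i], values[j])
        return acc / (2 * len(members))

    ss_total = ss_of(range(n))
    ss_wp = sum(ss_of(pop_idx[p]) for p in pops)
    ss_wg = sum(ss_of(grp_idx[g]) for g in groups)
    ss_ag = ss_total - ss_wg
    ss_apwg = ss_wg - ss_wp
    df_ag = len(groups) - 1
    df_apwg = len(pops) - len(groups)
    df_wp = n - len(pops)
    sigma_c = ss_wp / df_wp
    sum_np2_over_ng = sum(
        sum(len(pop_idx[p]) ** 2 for p in pops if pop_grp[p] == g) / len(grp_idx[g])
        for g in groups
    )
    n_c = (n - sum_np2_over_ng) / df_apwg
    np_c = (sum_np2_over_ng - sum(len(pop_idx[p]) ** 2 for p in pops) / n) / df_ag
    npp_c = (n - sum(len(grp_idx[g]) ** 2 for g in groups) / n) / df_ag
    sigma_b = (ss_apwg / df_apwg - sigma_c) / n_c
    sigma_a = (ss_ag / df_ag - sigma_c - np_c * sigma_b) / npp_c
    tot = sigma_a + sigma_b + sigma_c
    return dict(
        ss_total=ss_total, ss_ag=ss_ag, ss_apwg=ss_apwg, ss_wp=ss_wp,
        sigma_a=sigma_a, sigma_b=sigma_b, sigma_c=sigma_c,
        phi_st=(sigma_a + sigma_b) / tot, phi_ct=sigma_a / tot,
        phi_sc=sigma_b / (sigma_b + sigma_c),
    )


# ---------------------------------------------------------------------------


class TestAmova:
    def test_all_identical_songs_is_error(self):
        vals = np.ones((6, 2))
        with pytest.raises(ValueError, match="identical"):
            ck.amova(vals, ["A"] * 3 + ["B"] * 3, n_permutations=0)

    def test_perfect_separation(self):
        vals = np.array([[0.0], [0.0], [1.0], [1.0]])
        res = ck.amova(vals, ["A", "A", "B", "B"], n_permutations=0)
        assert res.sigma2["within"] == 0.0
        assert res.percent["among_societies"] == pytest.approx(100.0)
        assert res.phi["phi_st"] == pytest.approx(1.0)

    def test_single_society_is_error(self):
        with pytest.raises(ValueError, match="two societies"):
            ck.amova(np.random.default_rng(0).normal(size=(5, 2)), ["A"] * 5,
                     n_permutations=0)

    def test_matches_brute_force_oracle_one_level(self, rng):
        for _ in range(25):
            n = int(rng.integers(6, 13))
            n_pop = int(rng.integers(2, 4))
            society = [f"P{rng.integers(n_pop)}" for _ in range(n)]
            while len(set(society)) < 2:
                society = [f"P{rng.integers(n_pop)}" for _ in range(n)]
            vals = rng.normal(size=(n, 2))
            mine = ck.amova(vals, society, n_permutations=0)
            ref = amova_brute_one_level(vals, society)
            assert mine.ss["total"] == pytest.approx(ref["ss_total"], abs=1e-9)
            assert mine.sigma2["among_societies"] == pytest.approx(ref["sigma_a"], abs=1e-9)
            assert mine.sigma2["within"] == pytest.approx(ref["sigma_w"], abs=1e-9)
            assert mine.phi["phi_st"] == pytest.approx(ref["phi_st"], abs=1e-9)

    def test_matches_brute_force_oracle_two_level(self, rng):
        for _ in range(15):
            # 2 groups x 2-3 societies x 2-3 songs
            society, group, vals = [], [], []
            for g in range(2):
                for p in range(int(rng.integers(2, 4))):
                    for _ in range(int(rng.integers(2, 4))):
                        society.append(f"G{g}P{p}")
                        group.append(f"G{g}")
                        vals.append(rng.normal(size=2))
            vals = np.array(vals)
            mine = ck.amova(vals, society, group=group, n_permutations=0)
            ref = amova_brute_two_level(vals, society, group)
            for key, mkey in [("sigma_a", "among_groups"),
                              ("sigma_b", "among_societies"),
                              ("sigma_c", "within")]:
                assert mine.sigma2[mkey] == pytest.approx(ref[key], abs=1e-9)
            for k in ("phi_st", "phi_sc", "phi_ct"):
                assert mine.phi[k] == pytest.approx(ref[k], abs=1e-9)

    def test_ss_additivity_exact(self, rng):
        vals = rng.normal(size=(12, 3))
        society = ["A"] * 4 + ["B"] * 4 + ["C"] * 4
        group = ["G1"] * 8 + ["G2"] * 4
        res = ck.amova(vals, society, group=group, n_permutations=0)
        parts = res.ss["among_groups"] + res.ss["among_societies"] + res.ss["within"]
        assert parts == pytest.approx(res.ss["total"], abs=1e-10)

    def test_percentages_sum_to_100(self, rng):
        vals = rng.normal(size=(12, 2))
        society = ["A"] * 4 + ["B"] * 4 + ["C"] * 4
        res = ck.amova(vals, society, n_permutations=0)
        assert sum(res.percent.values()) == pytest.approx(100.0, abs=1e-6)

    def test_null_phi_centers_on_zero(self, rng):
        """Pooled identical populations: permuted Phi_ST averages ~ 0."""
        pool = rng.normal(size=(24, 2))
        phis = []
        for _ in range(200):
            society = rng.permutation(["A"] * 12 + ["B"] * 12)
            res = ck.amova(pool, society, n_permutations=0)
            phis.append(res.phi["phi_st"])
        assert abs(np.mean(phis)) < 0.02

    def test_permutation_p_detects_structure(self, rng):
        vals = np.concatenate([rng.normal(0, 0.2, size=(10, 1)),
                               rng.normal(3, 0.2, size=(10, 1))])
        res = ck.amova(vals, ["A"] * 10 + ["B"] * 10, n_permutations=199, seed=0)
        assert res.p_values["phi_st"] < 0.05


class TestPairwisePhist:
    def test_identical_song_sets_give_no_differentiation(self, rng):
        block = rng.normal(size=(5, 2))
        vals = np.vstack([block, block])
        society = ["A"] * 5 + ["B"] * 5
        m = ck.pairwise_phist(vals, society)
        assert m["A", "B"] <= 1e-9  # raw, possibly slightly negative

    def test_complete_fixation(self):
        vals = np.array([[0.0], [0.0], [1.0], [1.0]])
        m = ck.pairwise_phist(vals, ["A", "A", "B", "B"])
        assert m["A", "B"] == pytest.approx(1.0)

    def test_matches_two_level_oracle_on_pairs(self, rng):
        vals = rng.normal(size=(9, 2))
        society = ["A"] * 3 + ["B"] * 3 + ["C"] * 3
        m = ck.pairwise_phist(vals, society)
        for a, b in [("A", "B"), ("A", "C"), ("B", "C")]:
            idx = [i for i, s in enumerate(society) if s in (a, b)]
            ref = amova_brute_one_level(vals[idx], [society[i] for i in idx])
            assert m[a, b] == pytest.approx(ref["phi_st"], abs=1e-9)

    def test_min_songs_enforced(self, rng):
        vals = rng.normal(size=(3, 1))
        with pytest.raises(ValueError, match="fewer than 2"):
            ck.pairwise_phist(vals, ["A", "A", "B"])

    def test_zero_variance_pair_is_nan(self):
        vals = np.array([[1.0], [1.0], [1.0], [1.0], [0.0], [2.0]])
        society = ["A", "A", "B", "B", "C", "C"]
        with pytest.warns(UserWarning, match="zero total variance"):
            m = ck.pairwise_phist(vals, society)
        assert np.isnan(m["A", "B"])
        assert np.isfinite(m["A", "C"])


class TestFixationComparison:
    def _mat(self, vals, labels):
        return ck.DistanceMatrix(vals, labels)

    def test_equal_matrices_ratio_one(self, rng):
        labels = list("abcd")
        vals = np.abs(rng.normal(size=(4, 4)))
        vals = 0.5 * (vals + vals.T)
        np.fill_diagonal(vals, 0)
        m = self._mat(vals, labels)
        out = ck.fixation_comparison(m, m)
        assert np.allclose(out["ratio"], 1.0)
        assert np.allclose(out["difference"], 0.0)

    def test_scaled_matrix_ratio(self, rng):
        labels = list("abcd")
        vals = np.abs(rng.normal(size=(4, 4))) + 0.1
        vals = 0.5 * (vals + vals.T)
        np.fill_diagonal(vals, 0)
        a = self._mat(1.2 * vals, labels)
        b = self._mat(vals, labels)
        out = ck.fixation_comparison(a, b)
        assert np.allclose(out["ratio"], 1.2)
        assert out.attrs["quantiles"]["ratio"][0.5] == pytest.approx(1.2)

    def test_too_few_shared_pairs(self):
        a = self._mat([[0, 1], [1, 0]], ["a", "b"])
        with pytest.raises(ValueError, match="shared society pairs"):
            ck.fixation_comparison(a, a)
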