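"""Diversity and differentiation statistics against hand calculations
and independent brute-force oracles."""

import itertools

import numpy as np
import pytest

from conftest import make_gm, make_popmap
from ghostpop import (
    global_fst,
    DegenerateStatisticWarning,
    GhostpopError,
    SummaryStatSchema,
    diversity,
    f3_admixture,
    nei_distance,
    pairwise_fst,
    private_alleles,
    summary_vector,
)
from oracles import amova_phist_bruteforce, random_instance, wc84_theta_bruteforce


def two_group_gm(pop_a, pop_b, **kw):
    """Stack per-population genotype arrays into one matrix + popmap."""
    a = np.asarray(pop_a)
    b = np.asarray(pop_b)
    gm = make_gm(np.hstack([a, b]), **kw)
    pm = make_popmap(
        {
            **{f"s{j}": "A" for j in range(a.shape[1])},
            **{f"s{a.shape[1] + j}": "B" for j in range(b.shape[1])},
        }
    )
    return gm, pm


class TestDiversity:
    def test_hand_enumeration_single_site(self):
        # genotypes 0/0, 0/1, 1/1: 6 alleles, p = 0.5
        gm = make_gm([[0, 1, 2]])
        pm = make_popmap({"s0": "A", "s1": "A", "s2": "A"})
        div = diversity(gm, pm)
        assert div.loc["A", "Ho"] == pytest.approx(1 / 3)
        assert div.loc["A", "He"] == pytest.approx(0.5)
        assert div.loc["A", "FIS"] == pytest.approx(1 / 3)
        # 9 mismatching of 15 allele pairs
        assert div.loc["A", "pi"] == pytest.approx(0.6)

    def test_all_hets_give_negative_fis(self):
        gm = make_gm([[1, 1, 1, 1]])
        pm = make_popmap({f"s{j}": "A" for j in range(4)})
        div = diversity(gm, pm)
        assert div.loc["A", "Ho"] == 1.0
        assert div.loc["A", "He"] == pytest.approx(0.5)
        assert div.loc["A", "FIS"] == pytest.approx(-1.0)

    def test_monomorphic_group(self):
        gm = make_gm([[0, 0], [2, 2]])
        pm = make_popmap({"s0": "A", "s1": "A"})
        div = diversity(gm, pm)
        assert div.loc["A", "polymorphic_fraction"] == 0.0
        assert div.loc["A", "He"] == 0.0
        assert div.loc["A", "pi"] == 0.0

    def test_empty_group_is_an_error(self):
        gm = make_gm([[0, 1]])
        pm = make_popmap({"s0": "A", "s1": "A", "zz": "B"})
        with pytest.raises(GhostpopError, match="B"):
            diversity(gm, pm, groups=["A", "B"])


class TestPrivateAlleles:
    def test_enumeration(self):
        # site: A carries ref+alt (het), B only ref -> alt private to A
        gm, pm = two_group_gm([[1]], [[0]])
        counts = private_alleles(gm, pm)
        assert counts == {"A": 1, "B": 0}

    def test_identical_allele_sets_all_zero(self):
        gm, pm = two_group_gm([[1], [1]], [[1], [1]])
        assert private_alleles(gm, pm) == {"A": 0, "B": 0}

    def test_missing_elsewhere_still_private(self):
        # alt seen in one sample of A; B entirely missing at that site,
        # so both of A's observed alleles are unobserved anywhere else
        gm, pm = two_group_gm([[1, 0]], [[-1, -1]])
        counts = private_alleles(gm, pm)
        assert counts["A"] == 2
        assert counts["B"] == 0

    def test_single_group_is_an_error(self):
        gm = make_gm([[0, 1]])
        pm = make_popmap({"s0": "A", "s1": "A"})
        with pytest.raises(GhostpopError):
            private_alleles(gm, pm)


class TestDifferentiation:
    def test_fixed_difference_gives_one(self):
        gm, pm = two_group_gm([[0, 0], [0, 0]], [[2, 2], [2, 2]])
        for est in ("WC84", "PhiST", "FST_std"):
            mat = pairwise_fst(gm, pm, estimator=est)
            assert mat.loc["A", "B"] == pytest.approx(1.0), est

    def test_identical_groups_theta_near_zero(self):
        # all-het identical groups: the finite-sample correction terms
        # cancel exactly and theta is 0
        gm, pm = two_group_gm([[1, 1, 1]], [[1, 1, 1]])
        mat = pairwise_fst(gm, pm, estimator="WC84")
        assert mat.loc["A", "B"] == pytest.approx(0.0, abs=1e-12)
        # identical large groups: theta small (the estimator carries an
        # O(1/n) finite-sample term, so exact zero is not expected)
        rng = np.random.default_rng(8)
        block = rng.integers(0, 3, size=(50, 200))
        gm, pm = two_group_gm(block, block)
        mat = pairwise_fst(gm, pm, estimator="WC84")
        assert abs(mat.loc["A", "B"]) < 0.01

    def test_no_variation_flags_nan(self):
        # a fully monomorphic matrix must give NaN, not 0
        gm2, pm2 = two_group_gm([[0, 0]], [[0, 0]])
        with pytest.warns(DegenerateStatisticWarning):
            mat = pairwise_fst(gm2, pm2, estimator="WC84")
        assert np.isnan(mat.loc["A", "B"])

    @staticmethod
    def _instance_popmap(pops):
        pm = {}
        j = 0
        for k, p in enumerate(pops):
            for _ in range(p.shape[1]):
                pm[f"s{j}"] = chr(65 + k)
                j += 1
        return make_popmap(pm)

    @pytest.mark.parametrize("n_groups", [2, 3, 4])
    def test_wc84_matches_bruteforce(self, n_groups):
        rng = np.random.default_rng(100 + n_groups)
        for _ in range(50 if n_groups == 2 else 20):
            pops = random_instance(rng, n_groups=n_groups)
            expected = wc84_theta_bruteforce(pops)
            gm = make_gm(np.hstack(pops))
            pm = self._instance_popmap(pops)
            got = global_fst(gm, pm, estimator="WC84")
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("n_groups", [2, 3, 4])
    def test_phist_matches_bruteforce(self, n_groups):
        rng = np.random.default_rng(200 + n_groups)
        for _ in range(50 if n_groups == 2 else 20):
            pops = random_instance(rng, n_groups=n_groups)
            expected = amova_phist_bruteforce(pops)
            gm = make_gm(np.hstack(pops))
            pm = self._instance_popmap(pops)
            got = global_fst(gm, pm, estimator="PhiST")
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-10)

    def test_order_invariance(self):
        rng = np.random.default_rng(5)
        pops = random_instance(rng, n_groups=2, max_samples=6, max_sites=8)
        gm = make_gm(np.hstack(pops))
        n_tot = gm.n_samples
        pm = make_popmap(
            {f"s{j}": ("A" if j < pops[0].shape[1] else "B") for j in range(n_tot)}
        )
        base = pairwise_fst(gm, pm).loc["A", "B"]
        site_perm = rng.permutation(gm.n_sites)
        assert pairwise_fst(gm.take_sites(site_perm), pm).loc[
            "A", "B"
        ] == pytest.approx(base, abs=1e-14)
        samp_perm = rng.permutation(n_tot)
        assert pairwise_fst(gm.take_samples(samp_perm), pm).loc[
            "A", "B"
        ] == pytest.approx(base, abs=1e-14)


class TestNeiDistance:
    def test_identical_frequencies_zero(self):
        block = [[0, 1], [1, 2], [1, 1]]
        gm, pm = two_group_gm(block, block)
        assert nei_distance(gm, pm).loc["A", "B"] == pytest.approx(0.0)

    def test_fixed_opposite_is_infinite(self):
        gm, pm = two_group_gm([[0, 0]], [[2, 2]])
        with pytest.warns(DegenerateStatisticWarning):
            mat = nei_distance(gm, pm)
        assert np.isinf(mat.loc["A", "B"])

    def test_hand_calculation(self):
        # p1 = 0.8 (4 of 5... use 8 of 10 copies), p2 = 0.6
        gm, pm = two_group_gm(
            [[2, 2, 2, 1, 1]], [[2, 2, 1, 1, 0]]
        )
        jx = 0.8**2 + 0.2**2
        jy = 0.6**2 + 0.4**2
        jxy = 0.8 * 0.6 + 0.2 * 0.4
        expected = -np.log(jxy / np.sqrt(jx * jy))
        assert nei_distance(gm, pm).loc["A", "B"] == pytest.approx(expected)


class TestF3:
    def three_group_gm(self, t, s1, s2):
        t, s1, s2 = np.asarray(t), np.asarray(s1), np.asarray(s2)
        gm = make_gm(np.hstack([t, s1, s2]))
        pops = (
            ["T"] * t.shape[1] + ["S1"] * s1.shape[1] + ["S2"] * s2.shape[1]
        )
        pm = make_popmap({f"s{j}": p for j, p in enumerate(pops)})
        return gm, pm

    def test_identical_populations_near_zero(self):
        rng = np.random.default_rng(0)
        block = rng.integers(0, 3, size=(200, 20))
        gm, pm = self.three_group_gm(block, block, block)
        assert abs(f3_admixture(gm, pm, "T", "S1", "S2")) < 0.01

    def test_intermediate_target_is_negative(self):
        # pT halfway between well-separated sources at every site
        s1 = np.zeros((50, 10), dtype=int)
        s2 = np.full((50, 10), 2, dtype=int)
        t = np.tile([0, 2], (50, 5))  # p = 0.5
        gm, pm = self.three_group_gm(t, s1, s2)
        assert f3_admixture(gm, pm, "T", "S1", "S2") < -0.1

    def test_target_copy_of_source_not_strongly_negative(self):
        rng = np.random.default_rng(1)
        s1 = rng.integers(0, 3, size=(300, 10))
        s2 = rng.integers(0, 3, size=(300, 10))
        gm, pm = self.three_group_gm(s1, s1, s2)
        assert f3_admixture(gm, pm, "T", "S1", "S2") > -0.02

    def test_overlapping_groups_rejected(self):
        gm = make_gm([[0, 1]])
        pm = make_popmap({"s0": "A", "s1": "B"})
        with pytest.raises(GhostpopError):
            f3_admixture(gm, pm, "A", "A", "B")


class TestSummaryVector:
    def make_five_group(self):
        rng = np.random.default_rng(3)
        g = rng.integers(0, 3, size=(40, 15))
        gm = make_gm(g)
        pops = [f"G{j % 5}" for j in range(15)]
        pm = make_popmap({f"s{j}": p for j, p in enumerate(pops)})
        return gm, pm

    def test_length_formula_five_groups(self):
        gm, pm = self.make_five_group()
        schema = SummaryStatSchema(groups=tuple(sorted(pm.groups)))
        vec = summary_vector(gm, pm, schema)
        assert len(vec.values) == 4 * 5 + 2 * 10 + 3 * 10 == 70
        assert len(vec.names) == 70

    def test_sample_order_invariance_and_determinism(self):
        gm, pm = self.make_five_group()
        schema = SummaryStatSchema(groups=tuple(sorted(pm.groups)))
        v1 = summary_vector(gm, pm, schema)
        v2 = summary_vector(gm, pm, schema)
        np.testing.assert_array_equal(v1.values, v2.values)
        rng = np.random.default_rng(9)
        perm = rng.permutation(gm.n_samples)
        v3 = summary_vector(gm.take_samples(perm), pm, schema)
        np.testing.assert_allclose(v1.values, v3.values, atol=1e-14)

    def test_unknown_group_is_an_error(self):
        gm, pm = self.make_five_group()
        schema = SummaryStatSchema(groups=("G0", "NOPE"))
        with pytest.raises(GhostpopError, match="NOPE"):
            summary_vector(gm, pm, schema)


def test_fis_sign_matches_ho_he_order():
    rng = np.random.default_rng(12)
    for _ in range(20):
        g = rng.integers(0, 3, size=(30, 8))
        gm = make_gm(g)
        pm = make_popmap({f"s{j}": "A" for j in range(8)})
        div = diversity(gm, pm)
        if div.loc["A", "He"] > 0:
            assert (div.loc["A", "FIS"] >= 0) == (
                div.loc["A", "He"] >= div.loc["A", "Ho"]
            )
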