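"""Coalescent SNP simulator, sequencing layer and reference tables."""

import numpy as np
import pytest
from scipy import stats as sps

from ghostpop import (
    Deme,
    GhostpopError,
    Merge,
    Prior,
    PriorSet,
    ScenarioSpec,
    SizeChange,
    build_reference_table,
    add_sequencing_layer,
    filter_cascade,
    pairwise_fst,
    simulate_snps,
    summary_vector,
    thin_one_per_locus,
)
from ghostpop.sumstats import SummaryStatSchema


def two_pop_spec(t_split, ne=500, n=5, label="two"):
    return ScenarioSpec(
        label,
        [Deme("A", ne, samples=n), Deme("B", ne, samples=n)],
        [Merge(t_split, "B", "A")] if t_split > 0 else [Merge(1e-9, "B", "A")],
    )


def test_all_loci_polymorphic_by_construction():
    spec = ScenarioSpec("one", [Deme("A", 1000, samples=5)])
    gm = simulate_snps(spec, n_loci=100, maf_min=0.0, seed=1)
    assert gm.n_sites == 100
    alt = gm.genotypes.sum(axis=1)
    assert ((alt > 0) & (alt < 2 * gm.n_samples)).all()


def test_split_at_time_zero_gives_no_differentiation():
    spec = two_pop_spec(0)
    gm = simulate_snps(spec, n_loci=2000, maf_min=0.05, seed=2)
    pm = spec.population_map()
    fst = pairwise_fst(gm, pm, estimator="WC84").loc["A", "B"]
    assert abs(fst) < 0.01


def test_deep_split_fst_consistent_across_scales():
    # the same model at 10x the loci is an independent self-consistency
    # oracle: the two Monte-Carlo estimates must agree
    spec = two_pop_spec(2000, ne=500)
    pm = spec.population_map()
    f_small = pairwise_fst(
        simulate_snps(spec, n_loci=2000, seed=3), pm, estimator="WC84"
    ).loc["A", "B"]
    f_large = pairwise_fst(
        simulate_snps(spec, n_loci=20000, seed=4), pm, estimator="WC84"
    ).loc["A", "B"]
    assert f_small == pytest.approx(f_large, abs=0.02)
    assert f_large > 0.5  # t = 4Ne generations is deep divergence


def test_seed_determinism():
    spec = two_pop_spec(100)
    a = simulate_snps(spec, n_loci=50, seed=7)
    b = simulate_snps(spec, n_loci=50, seed=7)
    np.testing.assert_array_equal(a.genotypes, b.genotypes)


def test_maf_rejection_respected():
    spec = ScenarioSpec("one", [Deme("A", 1000, samples=20)])
    gm = simulate_snps(spec, n_loci=300, maf_min=0.1, seed=5)
    ac = gm.genotypes.sum(axis=1)
    n_hap = 2 * gm.n_samples
    # compare on allele counts to avoid float round-off at the threshold
    assert (np.minimum(ac, n_hap - ac) >= 0.1 * n_hap - 1e-9).all()


def test_divergence_time_increases_fst():
    pmap = two_pop_spec(1).population_map()
    means = []
    for t in (10, 200, 2000):
        f = pairwise_fst(
            simulate_snps(two_pop_spec(t), n_loci=1000, seed=11),
            pmap,
            estimator="WC84",
        ).loc["A", "B"]
        means.append(f)
    assert means[0] < means[1] < means[2]


def test_exchangeability_of_deme_labels():
    # relabeling demes consistently leaves summary statistics invariant
    spec1 = two_pop_spec(300)
    spec2 = ScenarioSpec(
        "relabeled",
        [Deme("X", 500, samples=5), Deme("Y", 500, samples=5)],
        [Merge(300, "Y", "X")],
    )
    g1 = simulate_snps(spec1, n_loci=400, seed=21)
    g2 = simulate_snps(spec2, n_loci=400, seed=21)
    v1 = summary_vector(
        g1, spec1.population_map(), SummaryStatSchema(groups=("A", "B"))
    )
    v2 = summary_vector(
        g2, spec2.population_map(), SummaryStatSchema(groups=("X", "Y"))
    )
    np.testing.assert_allclose(v1.values, v2.values, atol=1e-14)


def test_bottleneck_reduces_descendant_diversity():
    # stronger founder bottlenecks monotonically depress polymorphism in
    # the descendant deme (averaged over replicates)
    def poly_fraction(nf, db, seed):
        spec = ScenarioSpec(
            "b",
            [Deme("SRC", 2000, samples=4), Deme("NEW", 2000, samples=4)],
            [SizeChange(40 - db, "NEW", nf), Merge(40, "NEW", "SRC")],
        )
        pm = spec.population_map()
        vals = []
        rng = np.random.default_rng(seed)
        for _ in range(60):
            gm = simulate_snps(
                spec, n_loci=60, seed=int(rng.integers(1, 2**31))
            )
            idx = pm.group_indices(gm.samples)["NEW"]
            sub = gm.genotypes[:, idx]
            p = sub.sum(axis=1) / (2 * len(idx))
            vals.append(((p > 0) & (p < 1)).mean())
        return np.mean(vals)

    mild = poly_fraction(nf=100, db=1, seed=1)
    severe = poly_fraction(nf=5, db=5, seed=2)
    assert severe < mild


class TestSequencingLayer:
    def test_depth_distribution_matches_negative_binomial(self):
        spec = ScenarioSpec("one", [Deme("A", 1000, samples=50)])
        gm = simulate_snps(spec, n_loci=2000, seed=31)
        out = add_sequencing_layer(
            gm, depth_mean=22, depth_overdispersion=7, missing_rate=0.0,
            seed=32,
        )
        # P(DP < 5) under NB(k=7, mean=22)
        k, m = 7.0, 22.0
        expected = sps.nbinom.cdf(4, k, k / (k + m))
        observed = (out.depth < 5).mean()
        assert observed == pytest.approx(expected, abs=0.01)
        assert out.depth.size >= 1e5

    def test_clean_data_passes_cascade_unchanged(self):
        spec = ScenarioSpec("one", [Deme("A", 1000, samples=6)])
        gm = simulate_snps(spec, n_loci=80, maf_min=0.1, seed=33)
        out = add_sequencing_layer(
            gm, depth_mean=60, depth_overdispersion=50, missing_rate=0.0,
            seed=34,
        )
        filtered, _ = filter_cascade(out, seed=1)
        assert filtered.n_sites == gm.n_sites

    def test_linked_snps_thin_back_to_locus_count(self):
        spec = ScenarioSpec("one", [Deme("A", 1000, samples=5)])
        gm = simulate_snps(spec, n_loci=40, seed=35)
        out = add_sequencing_layer(
            gm, n_extra_snps_per_locus=3, seed=36
        )
        assert out.n_sites == 160
        thin = thin_one_per_locus(out, seed=1)
        assert thin.n_sites == 40

    def test_ad_consistent_with_genotype_and_depth(self):
        spec = ScenarioSpec("one", [Deme("A", 1000, samples=10)])
        gm = simulate_snps(spec, n_loci=100, seed=37)
        out = add_sequencing_layer(gm, missing_rate=0.1, seed=38)
        ad_sum = out.allele_depth.sum(axis=2)
        np.testing.assert_array_equal(ad_sum, out.depth)
        hom_ref = out.genotypes == 0
        assert (out.allele_depth[..., 1][hom_ref] == 0).all()
        missing = out.genotypes == -1
        assert (out.depth[missing] == 0).all()

    def test_bad_rates_rejected(self):
        spec = ScenarioSpec("one", [Deme("A", 1000, samples=3)])
        gm = simulate_snps(spec, n_loci=10, seed=39)
        with pytest.raises(GhostpopError):
            add_sequencing_layer(gm, missing_rate=1.5)


class TestReferenceTable:
    def test_bookkeeping_and_determinism(self):
        scen = [two_pop_spec(50, label="shallow"), two_pop_spec(2000, label="deep")]
        priors = PriorSet(priors={})
        schema = SummaryStatSchema(groups=("A", "B"))
        t1 = build_reference_table(
            scen, priors, n_per_scenario=5, schema=schema, seed=9, n_loci=30
        )
        t2 = build_reference_table(
            scen, priors, n_per_scenario=5, schema=schema, seed=9, n_loci=30
        )
        assert t1.n_rows == 10
        assert (t1.labels == ["shallow"] * 5 + ["deep"] * 5).all()
        np.testing.assert_array_equal(t1.stats, t2.stats)

    def test_bottleneck_scenario_shifts_he_column(self):
        base = ScenarioSpec(
            "const",
            [Deme("SRC", 2000, samples=4), Deme("NEW", 2000, samples=4)],
            [Merge(40, "NEW", "SRC")],
        )
        bott = ScenarioSpec(
            "bottle",
            [Deme("SRC", 2000, samples=4), Deme("NEW", 2000, samples=4)],
            [SizeChange(35, "NEW", 5), Merge(40, "NEW", "SRC")],
        )
        schema = SummaryStatSchema(groups=("SRC", "NEW"))
        tab = build_reference_table(
            [base, bott],
            PriorSet(priors={}),
            n_per_scenario=150,
            schema=schema,
            seed=17,
            n_loci=100,
        )
        col = tab.stat_names.index("He_mean:NEW")
        he_const = tab.stats[tab.labels == "const", col]
        he_bott = tab.stats[tab.labels == "bottle", col]
        test = sps.mannwhitneyu(he_bott, he_const, alternative="less")
        assert test.pvalue < 0.01

    def test_tsv_round_trip(self, tmp_path):
        scen = [two_pop_spec(50, label="s1"), two_pop_spec(500, label="s2")]
        priors = PriorSet(priors={})
        schema = SummaryStatSchema(groups=("A", "B"))
        tab = build_reference_table(
            scen, priors, n_per_scenario=3, schema=schema, seed=1, n_loci=20
        )
        from ghostpop import ReferenceTable

        tab.to_tsv(tmp_path / "ref.tsv", sidecar=tmp_path / "ref.json")
        back = ReferenceTable.from_tsv(tmp_path / "ref.tsv", tmp_path / "ref.json")
        np.testing.assert_allclose(back.stats, tab.stats, rtol=1e-12)
        assert list(back.labels) == list(tab.labels)
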