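"""Regression-adjusted parameter posteriors and posterior-predictive
model checking."""

import numpy as np
import pandas as pd
import pytest

from ghostpop import (
    Deme,
    GhostpopError,
    Merge,
    Prior,
    PriorSet,
    ScenarioSpec,
    SizeChange,
    estimate_parameters,
    model_check,
    simulate_snps,
    summary_vector,
)
from ghostpop.simulate import ReferenceTable
from ghostpop.sumstats import SummaryStatSchema


def gaussian_reftable(rng, n=2000, d=4):
    """theta ~ U[0,1]; first statistic tracks theta, the rest are noise."""
    theta = rng.uniform(0, 1, n)
    S = np.column_stack(
        [theta + rng.normal(0, 0.1, n)]
        + [rng.normal(0, 1, n) for _ in range(d - 1)]
    )
    return ReferenceTable(
        labels=np.array(["m"] * n, dtype=object),
        params=pd.DataFrame({"theta": theta}),
        stats=S,
        stat_names=[f"s{i}" for i in range(d)],
        schema=SummaryStatSchema(groups=("A", "B")),
    )


PRIORS = PriorSet(priors={"theta": Prior("uniform", 0, 1)})


class TestEstimateParameters:
    def test_nearest_neighbour_limit(self):
        rng = np.random.default_rng(0)
        ref = gaussian_reftable(rng, n=500)
        row = 123
        obs = ref.stats[row]
        post = estimate_parameters(ref, obs, PRIORS, tolerance=2 / 500)
        # with the observation sitting exactly on one reference row, the
        # posterior concentrates near that row's parameter
        assert post.point_estimate("median")["theta"] == pytest.approx(
            ref.params["theta"][row], abs=0.15
        )

    def test_adjusted_draws_respect_prior_bounds(self):
        rng = np.random.default_rng(1)
        ref = gaussian_reftable(rng)
        for obs_theta in (0.02, 0.5, 0.98):
            obs = np.array([obs_theta, 0, 0, 0.0])
            post = estimate_parameters(ref, obs, PRIORS, tolerance=0.01)
            assert (post.draws["theta"] >= 0).all()
            assert (post.draws["theta"] <= 1).all()

    def test_quantiles_ordered_and_point_inside(self):
        rng = np.random.default_rng(2)
        ref = gaussian_reftable(rng)
        post = estimate_parameters(
            ref, np.array([0.4, 0, 0, 0.0]), PRIORS, tolerance=0.02
        )
        q = post.quantiles([0.05, 0.5, 0.95])["theta"]
        assert q[0.05] <= q[0.5] <= q[0.95]
        assert q[0.05] <= post.point_estimate("mean")["theta"] <= q[0.95]

    def test_adjustment_sharpens_posterior(self):
        rng = np.random.default_rng(3)
        ref = gaussian_reftable(rng, n=4000)
        obs = np.array([0.6, 0, 0, 0.0])
        post = estimate_parameters(ref, obs, PRIORS, tolerance=0.02)
        spread_adj = post.draws["theta"].std()
        spread_raw = post.raw_draws["theta"].std()
        assert spread_adj < spread_raw

    def test_zero_variance_statistic_dropped_with_warning(self):
        rng = np.random.default_rng(4)
        ref = gaussian_reftable(rng)
        ref.stats[:, 2] = 3.3
        with pytest.warns(UserWarning, match="zero-variance"):
            post = estimate_parameters(
                ref, np.array([0.5, 0, 3.3, 0.0]), PRIORS, tolerance=0.02
            )
        assert np.isfinite(post.draws["theta"]).all()

    def test_too_small_table_rejected(self):
        rng = np.random.default_rng(5)
        ref = gaussian_reftable(rng, n=50)
        with pytest.raises(GhostpopError, match="tolerance"):
            estimate_parameters(ref, ref.stats[0], PRIORS, tolerance=0.01)

    def test_mixed_scenario_table_rejected(self):
        rng = np.random.default_rng(6)
        ref = gaussian_reftable(rng)
        ref.labels[:10] = "other"
        with pytest.raises(GhostpopError, match="restrict"):
            estimate_parameters(ref, ref.stats[0], PRIORS)


def small_scenario():
    spec = ScenarioSpec(
        "b",
        [
            Deme("SRC", "ne", samples=4),
            Deme("NEW", "ne", samples=4),
        ],
        [SizeChange("t - db", "NEW", "nf"), Merge("t", "NEW", "SRC")],
    )
    priors = PriorSet(
        priors={
            "ne": Prior("loguniform", 1e3, 4e3),
            "t": Prior("uniform", 38, 45, integer=True),
            "db": Prior("uniform", 1, 5, integer=True),
            "nf": Prior("uniform", 5, 30, integer=True),
        },
        constraints=["db < t"],
    )
    return spec, priors, SummaryStatSchema(groups=("SRC", "NEW"))


class TestModelCheck:
    def make_posterior(self, priors, rng, n=200):
        draws = pd.DataFrame([priors.sample(rng) for _ in range(n)])
        from ghostpop.estimate import ParameterPosterior

        return ParameterPosterior(
            draws=draws,
            raw_draws=draws,
            weights=np.ones(n),
            tolerance=0.01,
            bounds={},
        )

    def test_rejects_too_few_simulations(self):
        spec, priors, schema = small_scenario()
        rng = np.random.default_rng(7)
        post = self.make_posterior(priors, rng)
        obs = summary_vector(
            simulate_snps(spec, priors.sample(rng), n_loci=30, seed=1),
            spec.population_map(),
            schema,
        )
        with pytest.raises(GhostpopError, match="n_sims"):
            model_check(spec, post, obs, n_sims=50, n_loci=30, seed=2)

    def test_pvalues_valid_and_order_invariant(self):
        spec, priors, schema = small_scenario()
        rng = np.random.default_rng(8)
        post = self.make_posterior(priors, rng)
        obs = summary_vector(
            simulate_snps(spec, priors.sample(rng), n_loci=40, seed=3),
            spec.population_map(),
            schema,
        )
        rep = model_check(
            spec, post, obs, n_sims=120, n_loci=40, seed=4
        )
        p = rep.table["p_value"].to_numpy()
        assert ((p >= 0) & (p <= 1)).all()
        assert rep.n_statistics == len(schema)
        assert rep.n_significant == int((p < rep.alpha).sum())
        # statistic order never affects per-statistic p-values
        rep2 = model_check(
            spec, post, obs, n_sims=120, n_loci=40, seed=4
        )
        assert (
            rep.table.set_index("statistic")["p_value"]
            .sort_index()
            .equals(
                rep2.table.set_index("statistic")["p_value"].sort_index()
            )
        )

    def test_gross_misfit_detected(self):
        spec, priors, schema = small_scenario()
        rng = np.random.default_rng(9)
        post = self.make_posterior(priors, rng)
        # observed data from a wildly different model: deep split, no
        # bottleneck, tiny Ne -> statistics far outside the posterior
        other = ScenarioSpec(
            "other",
            [Deme("SRC", 200, samples=4), Deme("NEW", 200, samples=4)],
            [Merge(4000, "NEW", "SRC")],
        )
        obs = summary_vector(
            simulate_snps(other, n_loci=40, seed=5),
            other.population_map(),
            schema,
        )
        rep = model_check(spec, post, obs, n_sims=150, n_loci=40, seed=6)
        assert rep.n_significant > rep.n_statistics / 2

    def test_holdout_subset_reported(self):
        spec, priors, schema = small_scenario()
        rng = np.random.default_rng(10)
        post = self.make_posterior(priors, rng)
        obs = summary_vector(
            simulate_snps(spec, priors.sample(rng), n_loci=30, seed=7),
            spec.population_map(),
            schema,
        )
        holdout = schema.stat_names()[:3]
        rep = model_check(
            spec, post, obs, n_sims=100, n_loci=30, seed=8, holdout=holdout
        )
        assert rep.holdout_total == 3
        assert 0 <= rep.holdout_significant <= 3
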