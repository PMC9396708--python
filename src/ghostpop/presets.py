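"""Ready-made introduction scenarios for a two-step plant invasion.

The system modelled here is a coastal shrub introduced from its native
range (three sampled native region groups) first into an eastern region
(EAU) around 38-45 generations before sampling and later into a western
region (WAU) around 8-10 generations before sampling, each introduction
passing through a founder bottleneck.  Unsampled "ghost" populations
absorb the possibility that the true native source was never sampled,
and the western population may descend from the eastern one (a
bridgehead) with or without admixture from the ghost source.

:func:`introduction_scenarios` builds the three competing scenario
classes used throughout the examples and tests:

``direct``
    EAU founded from the sampled native source; WAU founded from EAU.
``ghost``
    EAU founded from an unsampled ghost population that diverged from
    the native source earlier; WAU founded from EAU.
``admixed``
    as ``ghost``, but WAU's founders are a mixture of EAU and ghost
    ancestry (admixed bridgehead).

Historical first-observation records anchor the time priors:
introduction times U{38..45} generations (east) and U{8..10} (west),
founder sizes bounded below by 5, bottleneck durations U{1..5}.
Effective sizes use log-uniform priors where no published value
exists; :func:`separated_priors` narrows them to a
well-separated, strongly drifting parameterization convenient for
method demonstrations and recovery studies.  A generation is taken as
3 years for any calendar conversion.
"""

from __future__ import annotations

from typing import Dict, Tuple

from .genotypes import GenotypeMatrix, PopulationMap
from .scenarios import (
    Admixture,
    Deme,
    Merge,
    Prior,
    PriorSet,
    ScenarioSpec,
    SizeChange,
)
from .simulate import add_sequencing_layer, simulate_snps
from .sumstats import SummaryStatSchema

GENERATION_TIME_YEARS = 3.0


def years_to_generations(years: float) -> float:
    return years / GENERATION_TIME_YEARS


def introduction_scenarios(
    n_native: int = 8,
    n_eau: int = 8,
    n_wau: int = 5,
) -> Tuple[Dict[str, ScenarioSpec], PriorSet]:
    """The three competing introduction scenarios and their shared priors.

    Sample sizes are diploid individuals per sampled deme (NAT = the
    native source group, EAU, WAU).  Returns ({label: spec}, priors).
    """
    nat = Deme("NAT", "ne_native", samples=n_native)
    eau = Deme("EAU", "ne_eau", samples=n_eau)
    wau = Deme("WAU", "ne_wau", samples=n_wau)
    ghost = Deme("GHOST", "ne_ghost", samples=0, ghost=True)

    eau_bottleneck = SizeChange("t_eau - db_eau", "EAU", "nf_eau")
    wau_bottleneck = SizeChange("t_wau - db_wau", "WAU", "nf_wau")

    direct = ScenarioSpec(
        label="direct",
        demes=[nat, eau, wau],
        events=[
            wau_bottleneck,
            Merge("t_wau", "WAU", "EAU"),
            eau_bottleneck,
            Merge("t_eau", "EAU", "NAT"),
        ],
    )
    ghost_src = ScenarioSpec(
        label="ghost",
        demes=[nat, eau, wau, ghost],
        events=[
            wau_bottleneck,
            Merge("t_wau", "WAU", "EAU"),
            eau_bottleneck,
            Merge("t_eau", "EAU", "GHOST"),
            Merge("t_ghost", "GHOST", "NAT"),
        ],
    )
    admixed = ScenarioSpec(
        label="admixed",
        demes=[nat, eau, wau, ghost],
        events=[
            wau_bottleneck,
            Admixture("t_wau", "WAU", "GHOST", "ra_wau"),
            Merge("t_wau + 0.5", "WAU", "EAU"),
            eau_bottleneck,
            Merge("t_eau", "EAU", "GHOST"),
            Merge("t_ghost", "GHOST", "NAT"),
        ],
    )
    return (
        {"direct": direct, "ghost": ghost_src, "admixed": admixed},
        study_priors(),
    )


def study_priors() -> PriorSet:
    """Record-anchored priors where available, defaults elsewhere.

    From the historical record: t_eau ~ U{38..45}, t_wau ~ U{8..10}
    generations; founder sizes bounded below by 5.  Defaults: founder
    sizes U{5..100}, bottleneck durations U{1..5}, effective sizes
    log-uniform [10, 1e4], admixture rate U[0.1, 0.9].
    """
    return PriorSet(
        priors={
            "t_eau": Prior("uniform", 38, 45, integer=True),
            "t_wau": Prior("uniform", 8, 10, integer=True),
            "t_ghost": Prior("uniform", 50, 500, integer=True),
            "nf_eau": Prior("uniform", 5, 100, integer=True),
            "nf_wau": Prior("uniform", 5, 100, integer=True),
            "db_eau": Prior("uniform", 1, 5, integer=True),
            "db_wau": Prior("uniform", 1, 5, integer=True),
            "ne_native": Prior("loguniform", 10, 1e4),
            "ne_eau": Prior("loguniform", 10, 1e4),
            "ne_wau": Prior("loguniform", 10, 1e4),
            "ne_ghost": Prior("loguniform", 10, 1e4),
            "ra_wau": Prior("uniform", 0.1, 0.9),
        },
        constraints=[
            "t_eau > t_wau",
            "db_eau < t_eau",
            "db_wau < t_wau",
            "t_ghost > t_eau",
        ],
    )


def separated_priors() -> PriorSet:
    """A well-separated parameterization for recovery studies.

    Identical to :func:`study_priors` except that long-term effective
    sizes are narrowed to log-uniform [1e3, 4e3], founder sizes to
    U{5..30}, ghost divergence to U{300..800} generations and the
    admixture rate to U[0.3, 0.7].  Native-range differentiation then
    sits in the FST ~ 0.1-0.3 regime typical of structured plant
    populations, and scenario differences are driven by topology and
    founder drift rather than swamped by extreme size draws.
    """
    base = study_priors()
    pri = dict(base.priors)
    for k in ("ne_native", "ne_eau", "ne_wau", "ne_ghost"):
        pri[k] = Prior("loguniform", 1e3, 4e3)
    for k in ("nf_eau", "nf_wau"):
        pri[k] = Prior("uniform", 5, 30, integer=True)
    pri["t_ghost"] = Prior("uniform", 300, 800, integer=True)
    pri["ra_wau"] = Prior("uniform", 0.3, 0.7)
    return PriorSet(priors=pri, constraints=list(base.constraints))


def trio_schema() -> SummaryStatSchema:
    return SummaryStatSchema(groups=("NAT", "EAU", "WAU"))


def estimation_scenario(
    n_native: int = 8, n_eau: int = 8
) -> Tuple[ScenarioSpec, PriorSet, SummaryStatSchema]:
    """Ghost-source EAU introduction used for parameter estimation.

    Two sampled demes (NAT, EAU) plus the ghost source; parameters are
    the eastern introduction time, founder size, bottleneck duration,
    ghost divergence time and a shared long-term effective size.
    """
    spec = ScenarioSpec(
        label="ghost_eau",
        demes=[
            Deme("NAT", "ne_anc", samples=n_native),
            Deme("EAU", "ne_eau", samples=n_eau),
            Deme("GHOST", "ne_anc", samples=0, ghost=True),
        ],
        events=[
            SizeChange("t_eau - db_eau", "EAU", "nf_eau"),
            Merge("t_eau", "EAU", "GHOST"),
            Merge("t_ghost", "GHOST", "NAT"),
        ],
    )
    priors = PriorSet(
        priors={
            "t_eau": Prior("uniform", 38, 45, integer=True),
            "nf_eau": Prior("uniform", 5, 30, integer=True),
            "db_eau": Prior("uniform", 1, 5, integer=True),
            "t_ghost": Prior("uniform", 50, 500, integer=True),
            "ne_anc": Prior("loguniform", 2e3, 1e4),
            "ne_eau": Prior("loguniform", 2e3, 1e4),
        },
        constraints=["t_ghost > t_eau"],
    )
    schema = SummaryStatSchema(groups=("NAT", "EAU"))
    return spec, priors, schema


# ----------------------------------------------------------------------
# synthetic ddRADseq fixture
# ----------------------------------------------------------------------

def study_system_scenario(
    n_per_native: int = 6, n_eau: int = 8, n_wau: int = 4
) -> ScenarioSpec:
    """Five-group system (NRS/NRC/NRN native, EAU, WAU) mirroring the
    inferred history: EAU founded from a ghost source that diverged from
    the southern native group, WAU an admixed bridgehead from EAU."""
    return ScenarioSpec(
        label="study_system",
        demes=[
            Deme("NRS", 5000, samples=n_per_native),
            Deme("NRC", 5000, samples=n_per_native),
            Deme("NRN", 5000, samples=n_per_native),
            Deme("EAU", 2000, samples=n_eau),
            Deme("WAU", 1000, samples=n_wau),
            Deme("GHOST", 5000, samples=0, ghost=True),
        ],
        events=[
            SizeChange(6, "WAU", 9),
            Admixture(9, "WAU", "GHOST", 0.5),
            Merge(9.5, "WAU", "EAU"),
            SizeChange(37, "EAU", 8),
            Merge(40, "EAU", "GHOST"),
            Merge(300, "GHOST", "NRS"),
            Merge(800, "NRC", "NRS"),
            Merge(1200, "NRN", "NRS"),
        ],
    )


def synthetic_radseq_dataset(
    n_loci: int = 500,
    seed: int = 1,
    depth_mean: float = 22.0,
    depth_overdispersion: float = 7.0,
    missing_rate: float = 0.05,
    n_extra_snps_per_locus: int = 2,
    **scenario_kwargs,
) -> Tuple[GenotypeMatrix, PopulationMap]:
    """A realistic synthetic ddRADseq dataset with its population map.

    Simulates the five-group study system and layers on sequencing
    depth (~22x mean, overdispersed), allele depths, missingness and
    extra linked SNPs per RAD locus, so the full filter cascade and all
    statistics can be exercised end to end without any real data.
    """
    spec = study_system_scenario(**scenario_kwargs)
    gm = simulate_snps(spec, n_loci=n_loci, maf_min=0.05, seed=seed)
    gm = add_sequencing_layer(
        gm,
        depth_mean=depth_mean,
        depth_overdispersion=depth_overdispersion,
        missing_rate=missing_rate,
        n_extra_snps_per_locus=n_extra_snps_per_locus,
        seed=seed + 1,
    )
    grouping = {
        "NRS": "native",
        "NRC": "native",
        "NRN": "native",
        "EAU": "EAU",
        "WAU": "WAU",
    }
    popmap = spec.population_map(grouping=grouping)
    return gm, popmap
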