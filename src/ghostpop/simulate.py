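"""Coalescent simulation of unlinked biallelic SNP loci.

Each RAD locus is an independent genealogy of all sampled lineages under
the scenario, simulated with msprime, with exactly one mutation placed
uniformly on the genealogy's total branch length (the classic
single-SNP-per-locus convention of simulation-based introduction-history
inference).  A locus is rejected and redrawn whenever its overall-sample
minor allele frequency falls below ``maf_min``, mirroring the MAF filter
applied to the real data.

Diploid genotypes pair the two lineages of each simulated individual.
:func:`add_sequencing_layer` then decorates a simulated matrix with
RADseq-like read depths, allele depths, missingness and (optionally)
extra perfectly linked SNPs per locus, so the full filter cascade can be
exercised on synthetic data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import GhostpopError
from .genotypes import MISSING, GenotypeMatrix, PopulationMap
from .scenarios import (
    PriorSet,
    ScenarioSpec,
    to_demography,
    validate_scenario,
)
from .sumstats import SummaryStatSchema, summary_vector

MAX_REDRAWS_PER_LOCUS = 10_000

try:
    from numba import njit

    @njit(cache=True)
    def _mutate_tree(child, parent, times, n_samples, u):  # pragma: no cover
        m = child.shape[0]
        total = 0.0
        for e in range(m):
            total += times[parent[e]] - times[child[e]]
        target = u * total
        pick = m - 1
        acc = 0.0
        for e in range(m):
            acc += times[parent[e]] - times[child[e]]
            if acc >= target:
                pick = e
                break
        mask = np.zeros(times.shape[0], np.bool_)
        mask[child[pick]] = True
        # edges are sorted by parent time; a reverse sweep propagates the
        # derived state down the tree in one pass
        for i in range(m - 1, -1, -1):
            if mask[parent[i]]:
                mask[child[i]] = True
        g = np.empty(n_samples // 2, np.int8)
        ac = 0
        for j in range(n_samples // 2):
            g[j] = np.int8(mask[2 * j]) + np.int8(mask[2 * j + 1])
            ac += g[j]
        return g, ac

except ImportError:  # pragma: no cover - numba is a hard dependency

    def _mutate_tree(child, parent, times, n_samples, u):
        bl = times[parent] - times[child]
        cs = np.cumsum(bl)
        pick = int(np.searchsorted(cs, u * cs[-1]))
        mask = np.zeros(times.shape[0], bool)
        mask[child[pick]] = True
        for i in range(len(child) - 1, -1, -1):
            if mask[parent[i]]:
                mask[child[i]] = True
        g = (mask[: n_samples].reshape(-1, 2).sum(axis=1)).astype(np.int8)
        return g, int(mask[:n_samples].sum())


def simulate_snps(
    spec: ScenarioSpec,
    draw: Optional[Dict[str, float]] = None,
    n_loci: int = 500,
    maf_min: float = 0.05,
    seed: Optional[int] = None,
) -> GenotypeMatrix:
    """Simulate ``n_loci`` unlinked biallelic SNPs under a scenario.

    ``draw`` binds any symbolic parameters of the scenario.  Sample columns
    are named ``<deme>_<i>`` in deme order, matching
    :meth:`ScenarioSpec.population_map`.
    """
    import msprime

    if n_loci < 1:
        raise GhostpopError("n_loci must be >= 1")
    concrete = spec.bind(draw or {})
    validate_scenario(concrete)
    dem = to_demography(concrete)
    sample_conf = {d.name: d.samples for d in concrete.demes if d.samples > 0}
    if not sample_conf:
        raise GhostpopError(f"scenario {spec.label!r} samples no deme")
    rng = np.random.default_rng(seed)

    n_dip = sum(sample_conf.values())
    n_hap = 2 * n_dip
    G = np.empty((n_loci, n_dip), dtype=np.int8)
    got = 0
    attempts = 0
    while got < n_loci:
        need = n_loci - got
        batch = need + int(0.5 * need) + 8
        reps = msprime.sim_ancestry(
            samples=sample_conf,
            demography=dem,
            ploidy=2,
            num_replicates=batch,
            random_seed=int(rng.integers(1, 2**31)),
        )
        for ts in reps:
            attempts += 1
            g, ac = _mutate_tree(
                ts.edges_child,
                ts.edges_parent,
                ts.nodes_time,
                n_hap,
                float(rng.random()),
            )
            if min(ac, n_hap - ac) >= maf_min * n_hap:
                G[got] = g
                got += 1
                if got == n_loci:
                    break
            elif attempts - got > MAX_REDRAWS_PER_LOCUS:
                raise GhostpopError(
                    f"locus rejected {MAX_REDRAWS_PER_LOCUS} times at "
                    f"maf_min={maf_min}; the sample may be too small for "
                    "this threshold"
                )

    samples = [
        f"{name}_{i}" for name in sample_conf for i in range(sample_conf[name])
    ]
    return GenotypeMatrix(
        samples=samples,
        locus_ids=np.array([str(i) for i in range(n_loci)], dtype=object),
        positions=np.arange(1, n_loci + 1),
        ref=np.array(["A"] * n_loci, dtype=object),
        alt=np.array(["T"] * n_loci, dtype=object),
        genotypes=G,
    )


def add_sequencing_layer(
    gm: GenotypeMatrix,
    depth_mean: float = 22.0,
    depth_overdispersion: float = 7.0,
    missing_rate: float = 0.0,
    n_extra_snps_per_locus: int = 0,
    seed: Optional[int] = None,
) -> GenotypeMatrix:
    """Decorate simulated genotypes with RADseq-like sequencing noise.

    Per-call depth is negative-binomial with the given mean and shape
    (``depth_overdispersion`` is the NB size parameter k; variance is
    ``m + m^2/k``, matching the large spread of RAD locus coverage).
    Allele depths split heterozygote reads Binomial(DP, 1/2).  Missing
    calls (locus dropout) get DP = AD = 0.  ``n_extra_snps_per_locus``
    appends perfectly linked copies of each site within its RAD locus so
    that per-locus thinning has work to do.
    """
    if not 0.0 <= missing_rate <= 1.0:
        raise GhostpopError("missing_rate outside [0, 1]")
    if depth_mean <= 0 or depth_overdispersion <= 0:
        raise GhostpopError("depth parameters must be positive")
    rng = np.random.default_rng(seed)
    out = gm.copy()
    if n_extra_snps_per_locus > 0:
        order = np.repeat(
            np.arange(gm.n_sites), 1 + n_extra_snps_per_locus
        )
        out = out.take_sites(order)
        reps = 1 + n_extra_snps_per_locus
        out.positions = np.concatenate(
            [gm.positions[i] * 100 + np.arange(reps) for i in range(gm.n_sites)]
        )
    S, N = out.genotypes.shape
    k = depth_overdispersion
    p = k / (k + depth_mean)
    dp = rng.negative_binomial(k, p, size=(S, N)).astype(np.int32)
    alt_reads = np.zeros_like(dp)
    het = out.genotypes == 1
    alt_reads[het] = rng.binomial(dp[het], 0.5)
    alt_reads[out.genotypes == 2] = dp[out.genotypes == 2]
    if missing_rate > 0:
        drop = rng.random(size=(S, N)) < missing_rate
        out.genotypes[drop] = MISSING
        dp[drop] = 0
        alt_reads[drop] = 0
    ref_reads = dp - alt_reads
    out.depth = dp
    out.allele_depth = np.stack([ref_reads, alt_reads], axis=-1)
    return out


# ----------------------------------------------------------------------
# reference tables
# ----------------------------------------------------------------------

@dataclass
class ReferenceTable:
    """Simulated (scenario label, parameter draw, summary statistics) rows.

    ``params`` is a DataFrame with one column per parameter (NaN where a
    parameter does not occur in a scenario) plus the scenario label;
    ``stats`` is the (rows x statistics) matrix in schema order.
    """

    labels: np.ndarray
    params: pd.DataFrame
    stats: np.ndarray
    stat_names: List[str]
    schema: SummaryStatSchema
    provenance: dict = field(default_factory=dict)

    @property
    def n_rows(self) -> int:
        return len(self.labels)

    def restrict(self, scenario_labels: Sequence[str]) -> "ReferenceTable":
        mask = np.isin(self.labels, list(scenario_labels))
        return ReferenceTable(
            labels=self.labels[mask],
            params=self.params.iloc[mask].reset_index(drop=True),
            stats=self.stats[mask],
            stat_names=self.stat_names,
            schema=self.schema,
            provenance=dict(self.provenance),
        )

    def to_tsv(self, path, sidecar: Optional[str] = None) -> None:
        df = self.params.copy()
        df.insert(0, "scenario", self.labels)
        for j, name in enumerate(self.stat_names):
            df[name] = self.stats[:, j]
        df.to_csv(path, sep="\t", index=False)
        if sidecar:
            with open(sidecar, "w") as fh:
                json.dump(
                    {
                        "schema_version": self.schema.version,
                        "groups": list(self.schema.groups),
                        "stat_names": self.stat_names,
                        **self.provenance,
                    },
                    fh,
                    indent=2,
                )

    @classmethod
    def from_tsv(cls, path, sidecar) -> "ReferenceTable":
        with open(sidecar) as fh:
            meta = json.load(fh)
        df = pd.read_csv(path, sep="\t")
        stat_names = meta["stat_names"]
        schema = SummaryStatSchema(
            groups=tuple(meta["groups"]), version=meta["schema_version"]
        )
        param_cols = [
            c for c in df.columns if c != "scenario" and c not in stat_names
        ]
        return cls(
            labels=df["scenario"].to_numpy(),
            params=df[param_cols],
            stats=df[stat_names].to_numpy(),
            stat_names=stat_names,
            schema=schema,
            provenance={
                k: v
                for k, v in meta.items()
                if k not in ("schema_version", "groups", "stat_names")
            },
        )


def build_reference_table(
    scenarios: Sequence[ScenarioSpec],
    priors: PriorSet,
    n_per_scenario: int,
    schema: SummaryStatSchema,
    seed: Optional[int] = None,
    n_loci: int = 500,
    maf_min: float = 0.05,
    popmap: Optional[PopulationMap] = None,
    grouping: Optional[Dict[str, str]] = None,
) -> ReferenceTable:
    """Simulate ``n_per_scenario`` parameter draws and statistic vectors
    per scenario under shared priors.

    All scenarios must sample the same demes (so one statistic schema
    applies); ``grouping`` optionally rolls demes up into the schema's
    groups.
    """
    rng = np.random.default_rng(seed)
    ref_popmap = popmap or scenarios[0].population_map(grouping)
    missing = [g for g in schema.groups if g not in ref_popmap.groups]
    if missing:
        raise GhostpopError(
            f"schema groups {missing} not present in the scenario popmap"
        )
    labels: List[str] = []
    draws: List[Dict[str, float]] = []
    stats = np.empty((len(scenarios) * n_per_scenario, len(schema)))
    row = 0
    for spec in scenarios:
        for _ in range(n_per_scenario):
            draw = priors.sample(rng)
            gm = simulate_snps(
                spec,
                draw,
                n_loci=n_loci,
                maf_min=maf_min,
                seed=int(rng.integers(1, 2**31)),
            )
            vec = summary_vector(gm, ref_popmap, schema)
            stats[row] = vec.values
            labels.append(spec.label)
            draws.append(draw)
            row += 1
    return ReferenceTable(
        labels=np.array(labels, dtype=object),
        params=pd.DataFrame(draws),
        stats=stats,
        stat_names=schema.stat_names(),
        schema=schema,
        provenance={
            "seed": seed,
            "n_per_scenario": n_per_scenario,
            "n_loci": n_loci,
            "maf_min": maf_min,
            "scenarios": [s.label for s in scenarios],
        },
    )
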