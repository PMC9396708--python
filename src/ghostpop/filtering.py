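"""Post-calling SNP filter cascade for RADseq genotype matrices.

The cascade runs five stages in a fixed order:

1. drop samples with more than 90% missing genotypes;
2. set genotype calls with read depth below 5 to missing;
3. keep biallelic sites with less than 20% missing genotypes and minor
   allele frequency above 0.05 (computed over non-missing calls, after
   the depth masking of stage 2);
4. thin to a single randomly chosen SNP per RAD locus (seeded);
5. drop samples with more than 50% missing genotypes.

All inequalities are strict, exactly as written above.  Stage 5 can in
principle re-break the per-site missingness bound of stage 3 (removing a
sample changes the denominators); any such sites are recorded in the
report rather than silently re-filtered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .errors import EmptyFilterError, GhostpopError
from .genotypes import MISSING, GenotypeMatrix


@dataclass
class FilterParams:
    """Stage thresholds; defaults follow the cascade described above."""

    max_missing_sample_pre: float = 0.90   # stage 1, strict >
    min_depth: int = 5                     # stage 2, calls with depth < 5
    max_missing_site: float = 0.20         # stage 3, strict <
    maf_min: float = 0.05                  # stage 3, strict >
    max_missing_sample_post: float = 0.50  # stage 5, strict >


@dataclass
class StageRecord:
    stage: int
    name: str
    params: dict
    sites_in: int
    sites_out: int
    samples_in: int
    samples_out: int
    detail: dict = field(default_factory=dict)


@dataclass
class FilterReport:
    """Per-stage bookkeeping; with the input and the seed it fully
    determines the cascade output."""

    stages: List[StageRecord] = field(default_factory=list)
    seed: Optional[int] = None
    rebroken_sites: int = 0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "stage": s.stage,
                    "name": s.name,
                    "sites_in": s.sites_in,
                    "sites_out": s.sites_out,
                    "samples_in": s.samples_in,
                    "samples_out": s.samples_out,
                    "params": ";".join(f"{k}={v}" for k, v in s.params.items()),
                }
                for s in self.stages
            ]
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def __str__(self) -> str:
        lines = [f"filter cascade (thinning seed {self.seed})"]
        for s in self.stages:
            lines.append(
                f"  stage {s.stage} {s.name}: sites {s.sites_in}->{s.sites_out}"
                f", samples {s.samples_in}->{s.samples_out}"
            )
        if self.rebroken_sites:
            lines.append(
                f"  note: {self.rebroken_sites} site(s) exceed the stage-3 "
                "missingness bound after stage-5 sample removal"
            )
        return "\n".join(lines)


def _sample_missing_fraction(gm: GenotypeMatrix) -> np.ndarray:
    return (gm.genotypes == MISSING).mean(axis=0)


def exclude_loci(gm: GenotypeMatrix, locus_ids) -> GenotypeMatrix:
    """Drop every site on the given RAD loci.

    Hook for caller-supplied exclusion lists (e.g. loci flagged as
    selection outliers by an upstream scan) applied before the cascade;
    the method producing such a list is outside this package's scope.
    """
    excluded = {str(x) for x in locus_ids}
    keep = np.array(
        [str(lid) not in excluded for lid in gm.locus_ids], dtype=bool
    )
    return gm.take_sites(np.nonzero(keep)[0])


def thin_one_per_locus(gm: GenotypeMatrix, seed: int = 1) -> GenotypeMatrix:
    """Keep exactly one SNP per RAD locus, chosen uniformly at random.

    Locus order of first appearance is preserved so the operation is
    deterministic given the seed.
    """
    if gm.n_sites and all(
        lid is None or str(lid) == "" for lid in gm.locus_ids
    ):
        raise GhostpopError(
            "no RAD-locus identifiers present; re-read the VCF with an "
            "appropriate locus_id_rule"
        )
    rng = np.random.default_rng(seed)
    keep = []
    order: dict = {}
    for i, lid in enumerate(gm.locus_ids):
        order.setdefault(lid, []).append(i)
    for lid, idx in order.items():
        keep.append(idx[rng.integers(len(idx))])
    return gm.take_sites(np.array(sorted(keep), dtype=np.intp))


def filter_cascade(
    gm: GenotypeMatrix,
    params: FilterParams = FilterParams(),
    seed: int = 1,
):
    """Run the five-stage cascade; returns (filtered matrix, report).

    Raises :class:`EmptyFilterError` if any stage leaves no sites or no
    samples, rather than silently returning an empty matrix.
    """
    report = FilterReport(seed=seed)
    gm = gm.copy()

    # stage 1: samples with >90% missing
    frac = _sample_missing_fraction(gm)
    keep = np.nonzero(~(frac > params.max_missing_sample_pre))[0]
    rec = StageRecord(
        1,
        "drop_high_missing_samples",
        {"max_missing": params.max_missing_sample_pre},
        gm.n_sites,
        gm.n_sites,
        gm.n_samples,
        len(keep),
        detail={"removed": [gm.samples[i] for i in range(gm.n_samples) if i not in set(keep)]},
    )
    gm = gm.take_samples(keep)
    report.stages.append(rec)
    if gm.n_samples == 0:
        raise EmptyFilterError(1, "samples")

    # stage 2: mask genotype calls with depth < 5 (unknown depth is kept)
    n_masked = 0
    if gm.depth is not None:
        low = (gm.depth >= 0) & (gm.depth < params.min_depth)
        low &= gm.genotypes != MISSING
        n_masked = int(low.sum())
        gm.genotypes[low] = MISSING
    report.stages.append(
        StageRecord(
            2,
            "mask_low_depth_calls",
            {"min_depth": params.min_depth},
            gm.n_sites,
            gm.n_sites,
            gm.n_samples,
            gm.n_samples,
            detail={"calls_masked": n_masked},
        )
    )

    # stage 3: biallelic sites, <20% missing, MAF > 0.05
    biallelic = ~gm.multiallelic
    site_missing = (gm.genotypes == MISSING).mean(axis=1)
    n, alt = gm.allele_counts()
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, alt / (2.0 * n), np.nan)
    maf = np.minimum(p, 1.0 - p)
    keep_sites = (
        biallelic
        & (site_missing < params.max_missing_site)
        & (n > 0)
        & (maf > params.maf_min)
    )
    rec = StageRecord(
        3,
        "site_filters",
        {
            "max_missing": params.max_missing_site,
            "maf_min": params.maf_min,
            "biallelic": True,
        },
        len(keep_sites),
        int(keep_sites.sum()),
        gm.n_samples,
        gm.n_samples,
        detail={
            "removed_multiallelic": int((~biallelic).sum()),
            "removed_missing": int(
                (biallelic & ~(site_missing < params.max_missing_site)).sum()
            ),
            "removed_maf": int(
                (
                    biallelic
                    & (site_missing < params.max_missing_site)
                    & ~((n > 0) & (maf > params.maf_min))
                ).sum()
            ),
        },
    )
    gm = gm.take_sites(np.nonzero(keep_sites)[0])
    report.stages.append(rec)
    if gm.n_sites == 0:
        raise EmptyFilterError(3, "sites")

    # stage 4: one SNP per RAD locus
    sites_in = gm.n_sites
    gm = thin_one_per_locus(gm, seed=seed)
    report.stages.append(
        StageRecord(
            4,
            "thin_one_per_locus",
            {"seed": seed},
            sites_in,
            gm.n_sites,
            gm.n_samples,
            gm.n_samples,
        )
    )

    # stage 5: samples with >50% missing
    frac = _sample_missing_fraction(gm)
    keep = np.nonzero(~(frac > params.max_missing_sample_post))[0]
    rec = StageRecord(
        5,
        "drop_high_missing_samples_post",
        {"max_missing": params.max_missing_sample_post},
        gm.n_sites,
        gm.n_sites,
        gm.n_samples,
        len(keep),
        detail={"removed": [gm.samples[i] for i in range(gm.n_samples) if i not in set(keep)]},
    )
    gm = gm.take_samples(keep)
    report.stages.append(rec)
    if gm.n_samples == 0:
        raise EmptyFilterError(5, "samples")

    # stage 5 can re-break the stage-3 site predicate; record, don't refilter
    site_missing = (gm.genotypes == MISSING).mean(axis=1)
    report.rebroken_sites = int((site_missing >= params.max_missing_site).sum())
    return gm, report
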