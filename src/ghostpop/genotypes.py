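"""Genotype containers and VCF input/output.

The central container is :class:`GenotypeMatrix`: biallelic (or flagged
multi-allelic) SNP genotypes for diploid samples, together with per-call
read depth and per-allele read depth, and the RAD-locus identifier of each
site.  Genotypes are coded as the number of alternate alleles (0, 1, 2)
with ``-1`` for missing; unknown depths are coded ``-1``.

RAD loci are short assembled fragments that may carry several linked SNPs.
How the locus identifier is recovered from a VCF differs between callers,
so :func:`read_vcf` exposes a ``locus_id_rule``:

``"ID"``
    the VCF ID column holds ``<locus>_<site>`` (stacks convention),
``"CHROM"``
    the CHROM column is the locus identifier,
``"INFO:<key>"``
    the locus identifier is an INFO field.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np

from .errors import ConfigError, VCFParseError

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Sites x samples diploid SNP genotypes with depths and locus ids.

    Attributes
    ----------
    samples
        Ordered unique sample identifiers (columns).
    locus_ids
        Per-site RAD-locus identifier (rows), as strings.
    positions
        Per-site position within the locus (or chromosome position).
    ref, alt
        Reference / alternate allele strings.  ``alt`` may contain commas
        for multi-allelic records, which are flagged in ``multiallelic``.
    genotypes
        ``(n_sites, n_samples)`` int8 array of alternate-allele counts,
        ``-1`` for missing.
    depth
        ``(n_sites, n_samples)`` int32 total read depth, ``-1`` unknown;
        may be None.
    allele_depth
        ``(n_sites, n_samples, 2)`` int32 (ref_reads, alt_reads), ``-1``
        unknown; may be None.
    multiallelic
        Per-site bool flag, True for records with >1 alternate allele.
    """

    samples: List[str]
    locus_ids: np.ndarray
    positions: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    genotypes: np.ndarray
    depth: Optional[np.ndarray] = None
    allele_depth: Optional[np.ndarray] = None
    multiallelic: Optional[np.ndarray] = None
    ploidy: int = 2

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.locus_ids = np.asarray(self.locus_ids, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        if self.multiallelic is None:
            self.multiallelic = np.array(
                ["," in str(a) for a in self.alt], dtype=bool
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample identifiers are not unique")
        n_sites, n_samples = self.genotypes.shape
        if len(self.samples) != n_samples or len(self.locus_ids) != n_sites:
            raise ValueError("genotype matrix shape does not match labels")

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[1]

    def missing_mask(self) -> np.ndarray:
        """Boolean (sites x samples) mask of missing genotype calls."""
        return self.genotypes == MISSING

    def take_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            locus_ids=self.locus_ids[idx],
            positions=self.positions[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            genotypes=self.genotypes[idx],
            depth=None if self.depth is None else self.depth[idx],
            allele_depth=(
                None if self.allele_depth is None else self.allele_depth[idx]
            ),
            multiallelic=self.multiallelic[idx],
        )

    def take_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            samples=[self.samples[i] for i in idx],
            genotypes=self.genotypes[:, idx],
            depth=None if self.depth is None else self.depth[:, idx],
            allele_depth=(
                None
                if self.allele_depth is None
                else self.allele_depth[:, idx]
            ),
        )

    def copy(self) -> "GenotypeMatrix":
        return replace(
            self,
            samples=list(self.samples),
            genotypes=self.genotypes.copy(),
            depth=None if self.depth is None else self.depth.copy(),
            allele_depth=(
                None if self.allele_depth is None else self.allele_depth.copy()
            ),
            multiallelic=self.multiallelic.copy(),
        )

    # -- frequency helpers used throughout the statistics layer ---------

    def allele_counts(self, sample_idx: Optional[np.ndarray] = None):
        """Per-site (n_called_genotypes, alt_allele_count) over a sample set."""
        g = self.genotypes if sample_idx is None else self.genotypes[:, sample_idx]
        called = g != MISSING
        n = called.sum(axis=1)
        alt = np.where(called, g, 0).sum(axis=1)
        return n, alt


@dataclass
class PopulationMap:
    """Sample -> population assignment plus population -> group rollup.

    ``grouping`` maps each population label to a coarser region group
    (for instance native-range south/central/north and the two introduced
    regions).  When no grouping is given each population is its own group.
    """

    assignment: Dict[str, str]
    grouping: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if not self.grouping:
            self.grouping = {p: p for p in set(self.assignment.values())}
        missing = set(self.assignment.values()) - set(self.grouping)
        if missing:
            raise ValueError(
                f"populations without a group: {sorted(missing)}"
            )

    @property
    def groups(self) -> List[str]:
        seen: Dict[str, None] = {}
        for pop in self.assignment.values():
            seen.setdefault(self.grouping[pop], None)
        return list(seen)

    def group_of(self, sample: str) -> str:
        return self.grouping[self.assignment[sample]]

    def group_indices(
        self, samples: Sequence[str], groups: Optional[Sequence[str]] = None
    ) -> Dict[str, np.ndarray]:
        """Column indices of each group within an ordered sample list."""
        unassigned = [s for s in samples if s not in self.assignment]
        if unassigned:
            raise ValueError(f"samples without population: {unassigned}")
        if groups is None:
            groups = self.groups
        out = {}
        for grp in groups:
            idx = [
                i for i, s in enumerate(samples) if self.group_of(s) == grp
            ]
            out[grp] = np.array(idx, dtype=np.intp)
        return out

    @classmethod
    def from_files(cls, popmap_path, grouping_path=None) -> "PopulationMap":
        """Read a two-column tab-separated sample->population map and an
        optional two-column population->group map."""
        assignment = _read_two_column(popmap_path)
        grouping = _read_two_column(grouping_path) if grouping_path else {}
        return cls(assignment=assignment, grouping=grouping)

    def to_file(self, popmap_path, grouping_path=None) -> None:
        with open(popmap_path, "w") as fh:
            for s, p in self.assignment.items():
                fh.write(f"{s}\t{p}\n")
        if grouping_path:
            with open(grouping_path, "w") as fh:
                for p, g in self.grouping.items():
                    fh.write(f"{p}\t{g}\n")


def _read_two_column(path) -> Dict[str, str]:
    out: Dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected two tab-separated columns"
                )
            out[parts[0]] = parts[1]
    return out


# ----------------------------------------------------------------------
# VCF input / output
# ----------------------------------------------------------------------

def _locus_from_record(variant, rule: str, lineno: int) -> str:
    if rule == "ID":
        vid = variant.ID
        if vid in (None, "", "."):
            raise VCFParseError(
                f"line {lineno}: ID field empty but locus_id_rule='ID'"
            )
        return str(vid).rsplit("_", 1)[0]
    if rule == "CHROM":
        chrom = str(variant.CHROM)
        # accept both a bare id and a "locus_<n>" style CHROM
        return chrom[len("locus_"):] if chrom.startswith("locus_") else chrom
    if rule.startswith("INFO:"):
        key = rule.split(":", 1)[1]
        val = variant.INFO.get(key)
        if val is None:
            raise VCFParseError(
                f"line {lineno}: INFO field '{key}' absent"
            )
        return str(val)
    raise ConfigError(
        f"unknown locus_id_rule {rule!r}; use 'ID', 'CHROM' or 'INFO:<key>'"
    )


def read_vcf(path, locus_id_rule: str = "ID") -> GenotypeMatrix:
    """Read a VCF 4.x file into a :class:`GenotypeMatrix`.

    GT is required; DP and AD are used when present.  ``/`` and ``|``
    genotype separators are both accepted (cyvcf2 normalises them).  When
    DP is absent but AD is present, depth is taken as the sum of AD.
    Multi-allelic records are retained but flagged.
    """
    if not str(locus_id_rule) in ("ID", "CHROM") and not str(
        locus_id_rule
    ).startswith("INFO:"):
        raise ConfigError(
            f"unknown locus_id_rule {locus_id_rule!r}; "
            "use 'ID', 'CHROM' or 'INFO:<key>'"
        )
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("cyvcf2 is required to read VCF files") from exc

    try:
        vcf = VCF(str(path))
    except Exception as exc:
        raise VCFParseError(f"{path}: cannot open as VCF ({exc})") from exc

    samples = list(vcf.samples)
    loci, positions, refs, alts = [], [], [], []
    gts, dps, ads = [], [], []
    # header lines precede records; cyvcf2 does not expose line numbers, so
    # we count records and report the 1-based record index instead.
    for rec_no, variant in enumerate(vcf, 1):
        try:
            loci.append(_locus_from_record(variant, locus_id_rule, rec_no))
            positions.append(variant.POS)
            refs.append(variant.REF)
            alts.append(",".join(variant.ALT) if variant.ALT else ".")
            gt = np.asarray(variant.genotype.array())[:, :2]
            missing = (gt < 0).any(axis=1)
            code = np.clip(gt, 0, None).astype(np.int16)
            # count non-reference alleles; allele indices >1 only occur in
            # flagged multi-allelic records
            g = (code > 0).sum(axis=1).astype(np.int8)
            g[missing] = MISSING
            gts.append(g)

            try:
                dp = variant.format("DP")
            except KeyError:
                dp = None
            try:
                ad = variant.format("AD")
            except KeyError:
                ad = None
            if ad is not None:
                ad = np.asarray(ad, dtype=np.int64)[:, :2]
                ad = np.where(ad < 0, -1, ad)
            if dp is not None:
                dp = np.asarray(dp, dtype=np.int64).reshape(-1)
                dp = np.where(dp < 0, -1, dp)
            elif ad is not None:
                known = (ad >= 0).all(axis=1)
                dp = np.where(known, ad.clip(0).sum(axis=1), -1)
            else:
                dp = np.full(len(samples), -1, dtype=np.int64)
            dps.append(dp)
            ads.append(
                ad
                if ad is not None
                else np.full((len(samples), 2), -1, dtype=np.int64)
            )
        except (VCFParseError, ConfigError):
            raise
        except Exception as exc:
            raise VCFParseError(
                f"{path}: malformed record {rec_no} "
                f"({variant.CHROM}:{variant.POS}): {exc}"
            ) from exc

    if not gts:
        raise VCFParseError(f"{path}: no variant records found")
    return GenotypeMatrix(
        samples=samples,
        locus_ids=np.array(loci, dtype=object),
        positions=np.array(positions),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        genotypes=np.vstack(gts),
        depth=np.vstack(dps).astype(np.int32),
        allele_depth=np.stack(ads).astype(np.int32),
    )


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=ghostpop
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele read depths">
"""

_GT_STR = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a :class:`GenotypeMatrix` as an uncompressed VCF 4.2 file.

    CHROM holds ``locus_<id>`` and ID holds ``<locus>_<position>`` so the
    file round-trips under either locus-id rule.
    """
    have_dp = gm.depth is not None
    have_ad = gm.allele_depth is not None
    fmt = "GT" + (":DP" if have_dp else "") + (":AD" if have_ad else "")
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        chroms = []
        for lid in gm.locus_ids:
            name = f"locus_{lid}"
            if name not in chroms:
                chroms.append(name)
        for name in chroms:
            fh.write(f"##contig=<ID={name}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for i in range(gm.n_sites):
            cols = [
                f"locus_{gm.locus_ids[i]}",
                str(int(gm.positions[i])),
                f"{gm.locus_ids[i]}_{int(gm.positions[i])}",
                str(gm.ref[i]),
                str(gm.alt[i]),
                ".",
                "PASS",
                ".",
                fmt,
            ]
            for j in range(gm.n_samples):
                parts = [_GT_STR[int(gm.genotypes[i, j])]]
                if have_dp:
                    d = int(gm.depth[i, j])
                    parts.append("." if d < 0 else str(d))
                if have_ad:
                    a = gm.allele_depth[i, j]
                    parts.append(
                        "."
                        if (a < 0).any()
                        else f"{int(a[0])},{int(a[1])}"
                    )
                cols.append(":".join(parts))
            fh.write("\t".join(cols) + "\n")
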