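"""Population diversity and differentiation statistics for SNP data.

All statistics operate on a :class:`~ghostpop.genotypes.GenotypeMatrix`
and a :class:`~ghostpop.genotypes.PopulationMap`, at the level of region
*groups*.  Genotypes are unphased diploid alternate-allele counts, so
every statistic is a function of per-group per-site allele counts and
heterozygote counts.

Notation: at a site, a group with ``n`` called genotypes has ``2n``
allele copies, alternate-allele frequency ``p``, and observed
heterozygosity ``Ho`` (fraction of called genotypes that are
heterozygous).  Expected heterozygosity is the naive gene diversity
``He = 2p(1-p)``; an unbiased small-sample variant ``He * 2n/(2n-1)``
is available behind a flag.

The module also defines the fixed-order summary-statistic vector used
for simulation-based inference (schema ``v1``): for each group
{mean He, variance of He across sites, proportion of monomorphic sites,
mean Ho}; for each unordered pair {Weir-Cockerham FST, Nei's D}; for
each choice of a target group out of an unordered trio {f3 admixture
statistic}.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import DegenerateStatisticWarning, GhostpopError
from .genotypes import MISSING, GenotypeMatrix, PopulationMap

# Nei's D is +inf when two groups share no allelic identity; the summary
# vector needs finite entries, so it is capped there (flagged elsewhere).
NEI_D_CAP = 10.0


# ----------------------------------------------------------------------
# per-group per-site building blocks
# ----------------------------------------------------------------------

def _group_site_counts(gm: GenotypeMatrix, idx: np.ndarray):
    """Return (n_called, alt_count, het_count) per site for one group."""
    g = gm.genotypes[:, idx]
    called = g != MISSING
    n = called.sum(axis=1)
    alt = np.where(called, g, 0).sum(axis=1)
    het = np.where(called, g == 1, False).sum(axis=1)
    return n, alt, het


def _freqs(n, alt):
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(n > 0, alt / (2.0 * n), np.nan)


def _resolve_groups(gm, popmap, groups=None) -> Dict[str, np.ndarray]:
    gi = popmap.group_indices(gm.samples, groups)
    empty = [g for g, idx in gi.items() if len(idx) == 0]
    if empty:
        raise GhostpopError(f"groups with zero samples: {empty}")
    return gi


# ----------------------------------------------------------------------
# diversity table
# ----------------------------------------------------------------------

def diversity(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    groups: Optional[Sequence[str]] = None,
    unbiased_he: bool = False,
    fis_per_site: bool = False,
) -> pd.DataFrame:
    """Per-group diversity summary.

    Columns: ``private_alleles``, ``polymorphic_fraction``, ``Ho``,
    ``He``, ``FIS``, ``pi`` plus a ``_se`` column for each mean (standard
    error over sites).  ``FIS`` defaults to the ratio-of-means estimator
    ``1 - mean(Ho)/mean(He)``; ``fis_per_site`` switches to the mean of
    per-site ``1 - Ho/He``.

    ``pi`` is the average pairwise difference per SNP site,
    ``2pq * 2n/(2n-1)``; invariant sites are not represented in a SNP
    matrix, so this is nucleotide diversity *at SNP sites*, not per
    locus.
    """
    gi = _resolve_groups(gm, popmap, groups)
    priv = private_alleles(gm, popmap, groups=list(gi)) if len(gi) > 1 else None
    rows = {}
    for grp, idx in gi.items():
        n, alt, het = _group_site_counts(gm, idx)
        ok = n > 0
        if not ok.any():
            raise GhostpopError(f"group {grp!r} has no called genotypes")
        p = _freqs(n, alt)[ok]
        nn = n[ok].astype(float)
        ho = het[ok] / nn
        he = 2.0 * p * (1.0 - p)
        if unbiased_he:
            he = he * (2 * nn) / (2 * nn - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            pi = np.where(2 * nn > 1, 2.0 * p * (1 - p) * (2 * nn) / (2 * nn - 1), 0.0)
        poly = (alt[ok] > 0) & (alt[ok] < 2 * n[ok])
        m = ok.sum()
        if fis_per_site:
            with np.errstate(divide="ignore", invalid="ignore"):
                fis_sites = 1.0 - np.where(he > 0, ho / he, np.nan)
            fis = float(np.nanmean(fis_sites))
            fis_se = float(np.nanstd(fis_sites, ddof=1) / np.sqrt(np.sum(~np.isnan(fis_sites))))
        else:
            mean_he = he.mean()
            fis = float(1.0 - ho.mean() / mean_he) if mean_he > 0 else np.nan
            # delta-method SE from the site-wise (Ho, He) covariance
            if m > 1 and mean_he > 0:
                cov = np.cov(ho, he, ddof=1)
                r = ho.mean() / mean_he
                var = (
                    cov[0, 0]
                    - 2 * r * cov[0, 1]
                    + r * r * cov[1, 1]
                ) / (mean_he ** 2 * m)
                fis_se = float(np.sqrt(max(var, 0.0)))
            else:
                fis_se = np.nan
        rows[grp] = {
            "private_alleles": np.nan if priv is None else priv[grp],
            "polymorphic_fraction": float(poly.mean()),
            "Ho": float(ho.mean()),
            "Ho_se": float(ho.std(ddof=1) / np.sqrt(m)) if m > 1 else np.nan,
            "He": float(he.mean()),
            "He_se": float(he.std(ddof=1) / np.sqrt(m)) if m > 1 else np.nan,
            "FIS": fis,
            "FIS_se": fis_se,
            "pi": float(pi.mean()),
            "pi_se": float(pi.std(ddof=1) / np.sqrt(m)) if m > 1 else np.nan,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def private_alleles(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    groups: Optional[Sequence[str]] = None,
) -> Dict[str, int]:
    """Count alleles observed in exactly one group.

    Both the reference and the alternate allele of every site are
    candidates; an allele missing from a group because all its genotypes
    are missing does not count as observed there.
    """
    gi = _resolve_groups(gm, popmap, groups)
    if len(gi) < 2:
        raise GhostpopError("private alleles need at least two groups")
    names = list(gi)
    seen_ref = np.zeros((len(names), gm.n_sites), dtype=bool)
    seen_alt = np.zeros_like(seen_ref)
    for k, grp in enumerate(names):
        n, alt, _ = _group_site_counts(gm, gi[grp])
        seen_alt[k] = alt > 0
        seen_ref[k] = (2 * n - alt) > 0
    counts = {}
    for k, grp in enumerate(names):
        others = np.ones(len(names), dtype=bool)
        others[k] = False
        priv_ref = seen_ref[k] & ~seen_ref[others].any(axis=0)
        priv_alt = seen_alt[k] & ~seen_alt[others].any(axis=0)
        counts[grp] = int(priv_ref.sum() + priv_alt.sum())
    return counts


# ----------------------------------------------------------------------
# differentiation
# ----------------------------------------------------------------------

def _wc84_components(n_list, p_list, h_list):
    """Weir-Cockerham (1984) per-site variance components a, b, c.

    ``n_list``: called genotype counts per population; ``p_list``: allele
    frequencies; ``h_list``: observed heterozygote proportions.  Returns
    arrays over sites; sites where any population has no data yield NaN.
    """
    n = np.array(n_list, dtype=float)  # (r, sites)
    p = np.array(p_list, dtype=float)
    h = np.array(h_list, dtype=float)
    r = n.shape[0]
    valid = (n > 0).all(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        nbar = n.mean(axis=0)
        nc = (r * nbar - (n ** 2).sum(axis=0) / (r * nbar)) / (r - 1)
        pbar = (n * p).sum(axis=0) / (r * nbar)
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n * h).sum(axis=0) / (r * nbar)
        a = (nbar / nc) * (
            s2
            - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
    a = np.where(valid & (nbar > 1) & (nc > 0), a, np.nan)
    b = np.where(valid & (nbar > 1), b, np.nan)
    c = np.where(valid, c, np.nan)
    return a, b, c


def _fst_wc(gm, idx_list) -> float:
    """Weir-Cockerham theta for k groups, ratio of summed components."""
    ns, ps, hs = [], [], []
    for idx in idx_list:
        n, alt, het = _group_site_counts(gm, idx)
        ns.append(n)
        ps.append(_freqs(n, alt))
        with np.errstate(divide="ignore", invalid="ignore"):
            hs.append(np.where(n > 0, het / n, np.nan))
    a, b, c = _wc84_components(ns, ps, hs)
    ok = ~np.isnan(a) & ~np.isnan(b) & ~np.isnan(c)
    denom = np.nansum(a[ok] + b[ok] + c[ok])
    if not ok.any() or denom == 0:
        warnings.warn(
            "Weir-Cockerham FST undefined (no variation)",
            DegenerateStatisticWarning,
        )
        return np.nan
    return float(np.nansum(a[ok]) / denom)


def _fst_wc_pair(gm, idx1, idx2) -> float:
    return _fst_wc(gm, [idx1, idx2])


def _phist(gm, idx_list) -> float:
    """AMOVA Phi-ST on squared differences of alternate-allele counts,
    summed over sites with per-site complete cases, k groups."""
    k = len(idx_list)
    gs, ns = [], []
    for idx in idx_list:
        g = gm.genotypes[:, idx].astype(float)
        g[gm.genotypes[:, idx] == MISSING] = np.nan
        gs.append(g)
        ns.append((~np.isnan(g)).sum(axis=1))
    ns_arr = np.array(ns)  # (k, sites)
    N = ns_arr.sum(axis=0)
    ok = (ns_arr > 0).all(axis=0) & (N > k)
    if not ok.any():
        warnings.warn("Phi-ST undefined", DegenerateStatisticWarning)
        return np.nan
    with np.errstate(invalid="ignore"):
        means = np.array([np.nanmean(g, axis=1) for g in gs])
        sums = np.array([np.nan_to_num(np.nansum(g, axis=1)) for g in gs])
        mt = sums.sum(axis=0) / N
        ssw = sum(
            np.nansum((g - m[:, None]) ** 2, axis=1)
            for g, m in zip(gs, means)
        )
        ssa = (ns_arr * (means - mt[None, :]) ** 2).sum(axis=0)
    ssd_w = float(ssw[ok].sum())
    ssd_a = float(ssa[ok].sum())
    df_w = float((N[ok] - k).sum())
    df_a = float(ok.sum() * (k - 1))
    nprime = (N[ok] - (ns_arr[:, ok] ** 2).sum(axis=0) / N[ok]) / (k - 1)
    nprime_wsum = float((nprime * (k - 1)).sum())
    if df_w == 0 or df_a == 0:
        warnings.warn("Phi-ST undefined", DegenerateStatisticWarning)
        return np.nan
    sigma_w = ssd_w / df_w
    nprime_bar = nprime_wsum / df_a
    msa = ssd_a / df_a
    sigma_a = (msa - sigma_w) / nprime_bar
    tot = sigma_a + sigma_w
    if tot == 0:
        warnings.warn("Phi-ST undefined (no variation)", DegenerateStatisticWarning)
        return np.nan
    return float(sigma_a / tot)


def _phist_pair(gm, idx1, idx2) -> float:
    return _phist(gm, [idx1, idx2])


def global_fst(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    estimator: str = "WC84",
    groups: Optional[Sequence[str]] = None,
) -> float:
    """Single multi-group differentiation value over all groups at once
    (WC84 theta or AMOVA Phi-ST)."""
    gi = _resolve_groups(gm, popmap, groups)
    idx_list = list(gi.values())
    if len(idx_list) < 2:
        raise GhostpopError("need at least two groups")
    if estimator == "WC84":
        return _fst_wc(gm, idx_list)
    if estimator == "PhiST":
        return _phist(gm, idx_list)
    raise GhostpopError(
        f"global estimator must be WC84 or PhiST, not {estimator!r}"
    )


def _fst_std_pair(gm, idx1, idx2) -> float:
    """Standardized FST: Nei G_ST divided by its maximum given the
    within-group gene diversity (Hedrick-style G'_ST), k = 2 groups."""
    n1, alt1, _ = _group_site_counts(gm, idx1)
    n2, alt2, _ = _group_site_counts(gm, idx2)
    p1, p2 = _freqs(n1, alt1), _freqs(n2, alt2)
    ok = (n1 > 0) & (n2 > 0)
    if not ok.any():
        warnings.warn("FST' undefined", DegenerateStatisticWarning)
        return np.nan
    p1, p2 = p1[ok], p2[ok]
    hs_site = 0.5 * (2 * p1 * (1 - p1) + 2 * p2 * (1 - p2))
    pbar = 0.5 * (p1 + p2)
    ht_site = 2 * pbar * (1 - pbar)
    hs, ht = hs_site.mean(), ht_site.mean()
    if ht == 0:
        warnings.warn("FST' undefined (no variation)", DegenerateStatisticWarning)
        return np.nan
    gst = (ht - hs) / ht
    if hs >= 1.0:
        warnings.warn("FST' undefined (HS=1)", DegenerateStatisticWarning)
        return np.nan
    gst_max = (2 - 1) * (1 - hs) / (2 - 1 + hs)
    if gst_max == 0:
        return np.nan
    return float(min(gst / gst_max, 1.0))


def _nei_d_pair(gm, idx1, idx2) -> float:
    n1, alt1, _ = _group_site_counts(gm, idx1)
    n2, alt2, _ = _group_site_counts(gm, idx2)
    p1, p2 = _freqs(n1, alt1), _freqs(n2, alt2)
    ok = (n1 > 0) & (n2 > 0)
    p1, p2 = p1[ok], p2[ok]
    jx = (p1 ** 2 + (1 - p1) ** 2).mean()
    jy = (p2 ** 2 + (1 - p2) ** 2).mean()
    jxy = (p1 * p2 + (1 - p1) * (1 - p2)).mean()
    if jxy == 0:
        warnings.warn(
            "Nei's D infinite (no shared identity)", DegenerateStatisticWarning
        )
        return np.inf
    return float(-np.log(jxy / np.sqrt(jx * jy)))


_PAIR_ESTIMATORS = {
    "WC84": _fst_wc_pair,
    "PhiST": _phist_pair,
    "FST_std": _fst_std_pair,
    "Nei_D": _nei_d_pair,
}


def pairwise_fst(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    estimator: str = "WC84",
    groups: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Symmetric group-by-group differentiation matrix.

    ``estimator`` is one of ``WC84`` (Weir-Cockerham theta as a
    multi-site ratio of summed variance components), ``PhiST`` (AMOVA
    among-group fraction of molecular variance on allele-count
    distances), ``FST_std`` (G_ST divided by its maximum given within-
    group diversity) or ``Nei_D``.  Undefined values (no variation) are
    NaN, never silently 0.
    """
    if estimator not in _PAIR_ESTIMATORS:
        raise GhostpopError(
            f"unknown estimator {estimator!r}; options: {sorted(_PAIR_ESTIMATORS)}"
        )
    gi = _resolve_groups(gm, popmap, groups)
    names = list(gi)
    if len(names) < 2:
        raise GhostpopError("need at least two groups")
    fn = _PAIR_ESTIMATORS[estimator]
    mat = pd.DataFrame(0.0, index=names, columns=names)
    for a, b in itertools.combinations(names, 2):
        v = fn(gm, gi[a], gi[b])
        mat.loc[a, b] = mat.loc[b, a] = v
    return mat


def nei_distance(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    groups: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Nei's standard genetic distance D = -ln(Jxy / sqrt(Jx Jy)),
    identities averaged over sites."""
    return pairwise_fst(gm, popmap, estimator="Nei_D", groups=groups)


def f3_admixture(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    target: str,
    src1: str,
    src2: str,
) -> float:
    """f3(target; src1, src2) = mean over sites of
    (pT - p1)(pT - p2) - pT(1-pT)/(2nT - 1).

    The correction term removes the sampling-noise bias of the squared
    target frequency.  Clearly negative values indicate that the target
    is a mixture of sources related to src1 and src2.
    """
    if len({target, src1, src2}) != 3:
        raise GhostpopError("target and sources must be three distinct groups")
    gi = _resolve_groups(gm, popmap, groups=[target, src1, src2])
    nT, altT, _ = _group_site_counts(gm, gi[target])
    n1, alt1, _ = _group_site_counts(gm, gi[src1])
    n2, alt2, _ = _group_site_counts(gm, gi[src2])
    ok = (nT > 0) & (n1 > 0) & (n2 > 0) & (2 * nT > 1)
    if not ok.any():
        raise GhostpopError("no sites with data in all three groups")
    pT = _freqs(nT, altT)[ok]
    p1 = _freqs(n1, alt1)[ok]
    p2 = _freqs(n2, alt2)[ok]
    corr = pT * (1 - pT) / (2 * nT[ok] - 1)
    return float(np.mean((pT - p1) * (pT - p2) - corr))


# ----------------------------------------------------------------------
# fixed-order summary vector
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class SummaryStatSchema:
    """Names the group list and fixes the statistic order (version v1)."""

    groups: Tuple[str, ...]
    version: str = "v1"

    def stat_names(self) -> List[str]:
        names = []
        for g in self.groups:
            names += [f"He_mean:{g}", f"He_var:{g}", f"mono_frac:{g}", f"Ho_mean:{g}"]
        for a, b in itertools.combinations(self.groups, 2):
            names.append(f"FST_WC:{a}|{b}")
            names.append(f"Nei_D:{a}|{b}")
        for trio in itertools.combinations(self.groups, 3):
            for t in trio:
                s1, s2 = [g for g in trio if g != t]
                names.append(f"f3:{t};{s1},{s2}")
        return names

    def __len__(self) -> int:
        g = len(self.groups)
        from math import comb

        return 4 * g + 2 * comb(g, 2) + 3 * comb(g, 3)


@dataclass
class SummaryStatVector:
    values: np.ndarray
    names: List[str]
    schema: SummaryStatSchema

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names)


def summary_vector(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    schema: SummaryStatSchema,
) -> SummaryStatVector:
    """Compute the schema's statistics in their fixed order.

    Deterministic: identical inputs give identical vectors, and the
    result is invariant to sample and site order.  Undefined pairwise
    values are mapped to 0 and infinite Nei distances are capped so the
    vector is always finite (reference tables must be numeric).
    """
    missing = [g for g in schema.groups if g not in popmap.groups]
    if missing:
        raise GhostpopError(f"schema groups absent from popmap: {missing}")
    gi = _resolve_groups(gm, popmap, groups=list(schema.groups))
    vals: List[float] = []
    freqs = {}
    for g in schema.groups:
        n, alt, het = _group_site_counts(gm, gi[g])
        ok = n > 0
        p = _freqs(n, alt)[ok]
        he = 2 * p * (1 - p)
        ho = het[ok] / n[ok]
        mono = (p == 0) | (p == 1)
        vals += [
            float(he.mean()),
            float(he.var(ddof=0)),
            float(mono.mean()),
            float(ho.mean()),
        ]
        freqs[g] = (n, alt)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateStatisticWarning)
        for a, b in itertools.combinations(schema.groups, 2):
            fst = _fst_wc_pair(gm, gi[a], gi[b])
            nd = _nei_d_pair(gm, gi[a], gi[b])
            vals.append(0.0 if np.isnan(fst) else fst)
            vals.append(min(nd, NEI_D_CAP) if np.isfinite(nd) or nd > 0 else 0.0)
        for trio in itertools.combinations(schema.groups, 3):
            for t in trio:
                s1, s2 = [g for g in trio if g != t]
                vals.append(f3_admixture(gm, popmap, t, s1, s2))
    return SummaryStatVector(
        values=np.array(vals, dtype=float),
        names=schema.stat_names(),
        schema=schema,
    )
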