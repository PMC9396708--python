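"""Ploidy inference from within-individual allele balance.

At a heterozygous biallelic site the fraction of reads carrying the
alternate allele clusters around d/m for a dosage d in an m-ploid
individual: diploids show one mode at 1/2, triploids modes at 1/3 and
2/3, tetraploids at 1/4, 1/2 and 3/4.  Per individual, the balances at
well-covered, clearly biallelic sites are fitted by Gaussian mixtures
with *fixed* component means for each candidate ploidy and free
weights, against a *free* mixture whose means are also optimised; all
models share a single free variance so the comparison is about where
the modes sit.

Because balances only survive extraction inside the window
``[maf_min, 1 - maf_min]``, every mixture component is a Gaussian
*truncated to that window* (renormalised by its mass on it).  Without
this, the clipped lower tail of a tetraploid's 1/4 component shifts its
apparent mode and the fixed models systematically mis-fit.

The call is the fixed model whose log-likelihood gap to the free
model, normalised by |lnL_free|, is smallest; models whose normalised
gaps are within 0.01 of the best are tied, the call is the lowest tied
ploidy (a unimodal 1/2 distribution is fitted equally well by the
tetraploid model with all weight on its 1/2 component, so parsimony
breaks that tie) and the fit is flagged ambiguous.

A denoising step removes balances better explained by a uniform
background (mismapping, paralogy) than by any mixture component before
the ploidy models are compared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import norm

from .errors import GhostpopError
from .genotypes import GenotypeMatrix

FIXED_MEANS = {
    "diploid": np.array([1 / 2]),
    "triploid": np.array([1 / 3, 2 / 3]),
    "tetraploid": np.array([1 / 4, 1 / 2, 3 / 4]),
}
AMBIGUITY_GAP = 0.01  # normalised log-likelihood gap treated as a tie
_PLOIDY_LEVEL = {"diploid": 2, "triploid": 3, "tetraploid": 4}
_SIGMA_BOUNDS = (1e-3, 0.5)


@dataclass
class AlleleBalanceSet:
    """Per-individual allele balances passing the coverage and
    within-individual minor-fraction thresholds."""

    balances: Dict[str, np.ndarray]
    min_cov: int
    maf_min: float

    @property
    def window(self) -> Tuple[float, float]:
        return (self.maf_min, 1.0 - self.maf_min)


def extract_allele_balance(
    gm: GenotypeMatrix, min_cov: int = 10, maf_min: float = 0.2
) -> AlleleBalanceSet:
    """Collect b = alt/(ref+alt) at sites with total allele coverage of
    at least ``min_cov`` and within-individual minor read fraction of at
    least ``maf_min``."""
    if gm.allele_depth is None:
        raise GhostpopError("allele depths (AD) are required")
    ad = gm.allele_depth
    known = (ad >= 0).all(axis=2)
    tot = ad[..., 0] + ad[..., 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        b = np.where(tot > 0, ad[..., 1] / tot, np.nan)
        minor = np.minimum(b, 1 - b)
    ok = known & (tot >= min_cov) & (minor >= maf_min)
    out = {
        s: b[ok[:, j], j].astype(float)
        for j, s in enumerate(gm.samples)
    }
    return AlleleBalanceSet(balances=out, min_cov=min_cov, maf_min=maf_min)


# ----------------------------------------------------------------------
# truncated Gaussian mixture likelihood and fits
# ----------------------------------------------------------------------

def _component_logdens(b, means, sigma, lo, hi):
    """(n, k) log density of window-truncated Gaussian components."""
    z = (b[:, None] - means[None, :]) / sigma
    logpdf = -0.5 * z**2 - np.log(sigma) - 0.5 * np.log(2 * np.pi)
    mass = norm.cdf((hi - means) / sigma) - norm.cdf((lo - means) / sigma)
    return logpdf - np.log(np.clip(mass, 1e-300, None))[None, :]


def _mixture_loglik(b, means, weights, sigma, lo, hi, uniform_weight=0.0):
    comp = _component_logdens(b, means, sigma, lo, hi) + np.log(
        np.clip(weights, 1e-300, None)
    )[None, :]
    if uniform_weight > 0.0:
        u = np.full(
            (len(b), 1), np.log(uniform_weight) - np.log(hi - lo)
        )
        comp = np.hstack([comp, u])
    return float(logsumexp(comp, axis=1).sum())


def _softmax(a):
    e = np.exp(a - a.max())
    return e / e.sum()


def _fit_mixture(
    b,
    fixed_means: Optional[np.ndarray],
    k: int,
    lo: float,
    hi: float,
    with_uniform: bool = False,
    mean_starts: Optional[Sequence[np.ndarray]] = None,
    weight_starts: Optional[Sequence[np.ndarray]] = None,
):
    """Maximum-likelihood fit of a shared-variance truncated mixture.

    ``fixed_means`` pins the component means (weights and sigma free);
    otherwise ``k`` free means are optimised too.  ``with_uniform`` adds
    a uniform background component with a free weight.  Returns
    (loglik, means, weights incl. uniform last, sigma).
    """
    free_means = fixed_means is None
    n_means = k if free_means else len(fixed_means)
    n_weights = n_means + (1 if with_uniform else 0)

    def unpack(theta):
        i = 0
        if free_means:
            raw = theta[:n_means]
            means = lo + (hi - lo) / (1 + np.exp(-raw))
            i = n_means
        else:
            means = fixed_means
        w = _softmax(np.concatenate([theta[i:i + n_weights - 1], [0.0]]))
        sigma = float(np.clip(np.exp(theta[-1]), *_SIGMA_BOUNDS))
        return means, w, sigma

    def negloglik(theta):
        means, w, sigma = unpack(theta)
        if with_uniform:
            return -_mixture_loglik(
                b, means, w[:-1], sigma, lo, hi, uniform_weight=w[-1]
            )
        return -_mixture_loglik(b, means, w, sigma, lo, hi)

    starts = []
    # two sigma starts: the empirical per-component spread and the
    # read-sampling scale typical of ~30x coverage
    sigs = [
        np.log(np.clip(np.std(b) / max(1, n_means), 0.02, 0.4)),
        np.log(0.08),
    ]
    if free_means:
        qs = np.quantile(b, np.linspace(0.15, 0.85, n_means))
        mean_inits = [qs] + [
            np.clip(np.asarray(m), lo + 1e-4, hi - 1e-4)
            for m in (mean_starts or [])
        ]
        if with_uniform:
            w0 = np.array([0.95 / k] * k + [0.05])
            wlog = np.log(w0 / w0[-1])[:-1]
        else:
            wlog = np.zeros(n_weights - 1)
        for m in mean_inits:
            raw = -np.log((hi - lo) / np.clip(m - lo, 1e-6, None) - 1)
            for s0 in sigs:
                starts.append(np.concatenate([raw, wlog, [s0]]))
    else:
        # hard-assignment weights: fraction of points nearest each mean
        near = np.argmin(np.abs(b[:, None] - fixed_means[None, :]), axis=1)
        w_hard = np.bincount(near, minlength=n_means).astype(float)
        w_hard = np.clip(w_hard / w_hard.sum(), 1e-3, None)
        if with_uniform:
            w_hard = np.concatenate([0.95 * w_hard, [0.05]])
        weight_inits = [np.full(n_weights, 1.0 / n_weights), w_hard] + [
            np.clip(np.asarray(w0, dtype=float), 1e-6, None)
            for w0 in (weight_starts or [])
        ]
        for w0 in weight_inits:
            a = np.log(w0 / w0[-1])[:-1]
            for s0 in sigs:
                starts.append(np.concatenate([a, [s0]]))

    n_par = len(starts[0])
    bounds = [(-9.0, 9.0)] * n_par
    bounds[-1] = (np.log(_SIGMA_BOUNDS[0]), np.log(_SIGMA_BOUNDS[1]))
    lo_b = np.array([b_[0] for b_ in bounds])
    hi_b = np.array([b_[1] for b_ in bounds])
    starts = [np.clip(x0, lo_b, hi_b) for x0 in starts]
    # screen the candidate starts with one objective evaluation each and
    # run the optimiser only from the most promising ones
    scored = sorted(starts, key=negloglik)
    best = None
    for x0 in scored[: min(3, len(scored))]:
        res = minimize(
            negloglik,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 200},
        )
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise GhostpopError("mixture fit failed to converge")
    means, w, sigma = unpack(best.x)
    return -float(best.fun), np.asarray(means, dtype=float), w, sigma


def denoise(
    balances: np.ndarray, window: Tuple[float, float] = (0.2, 0.8)
):
    """Remove balances best explained by uniform background noise.

    Fits a free 3-component truncated-Gaussian mixture plus a uniform
    component over the balance window and drops points whose largest
    posterior responsibility is the uniform one.  Returns (filtered
    balances, retained fraction, success flag).
    """
    b = np.asarray(balances, dtype=float)
    if len(b) < 50:
        raise GhostpopError("denoising needs at least 50 balances")
    lo, hi = window
    ll, means, w, sigma = _fit_mixture(
        b, None, k=3, lo=lo, hi=hi, with_uniform=True,
        mean_starts=[
            np.array([1 / 3, 1 / 2, 2 / 3]),
            np.array([1 / 4, 1 / 2, 3 / 4]),
        ],
    )
    logdens = _component_logdens(b, means, sigma, lo, hi) + np.log(
        np.clip(w[:-1], 1e-300, None)
    )
    logu = np.full((len(b), 1), np.log(max(w[-1], 1e-300)) - np.log(hi - lo))
    resp = np.hstack([logdens, logu])
    noisy = resp.argmax(axis=1) == resp.shape[1] - 1
    kept = b[~noisy]
    if len(kept) < 0.5 * len(b):
        # a background component absorbing most of the data means the
        # mixture fit failed, not that the data are mostly noise
        warnings.warn(
            "denoise would remove most balances; returning input unchanged"
        )
        return b, 1.0, False
    return kept, float(len(kept) / len(b)), True


@dataclass
class PloidyFit:
    """Fixed- and free-model fits and the resulting ploidy call."""

    logliks: Dict[str, float]
    gaps: Dict[str, float]             # (lnL_free - lnL_fixed)/|lnL_free|
    call: str
    ambiguous: bool
    denoised_fraction: float = 1.0
    n_balances: int = 0
    details: dict = field(default_factory=dict)


def call_ploidy(
    balances: np.ndarray,
    run_denoise: bool = True,
    window: Tuple[float, float] = (0.2, 0.8),
) -> PloidyFit:
    """Maximum-likelihood fixed-ploidy call against a free mixture.

    The free model is additionally started from each fitted fixed
    model's solution, so its log-likelihood is never below any fixed
    model's (the fixed models are nested in it).
    """
    b = np.asarray(balances, dtype=float)
    retained = 1.0
    if run_denoise:
        b, retained, _ = denoise(b, window=window)
    if len(b) < 100:
        raise GhostpopError(
            f"only {len(b)} balances after denoising; need at least 100"
        )
    lo, hi = window
    logliks: Dict[str, float] = {}
    free_starts = [np.array([1 / 3, 1 / 2, 2 / 3])]
    for name, mu in FIXED_MEANS.items():
        ws = None
        if name == "diploid":
            ws = [np.array([1.0])]
        ll, mu_f, w, sigma = _fit_mixture(
            b, mu, k=len(mu), lo=lo, hi=hi, weight_starts=ws
        )
        logliks[name] = ll
        pad = np.linspace(0.35, 0.65, 3 - len(mu_f))
        free_starts.append(np.concatenate([mu_f, pad]))
    best_free, free_means, _, _ = _fit_mixture(
        b, None, k=3, lo=lo, hi=hi, mean_starts=free_starts
    )
    # nesting guard: the free optimum dominates every fixed optimum
    best_free = max(best_free, max(logliks.values()))
    logliks["free"] = best_free
    denom = max(abs(best_free), 1e-12)
    gaps = {
        name: max((best_free - logliks[name]) / denom, 0.0)
        for name in FIXED_MEANS
    }
    gmin = min(gaps.values())
    tied = [name for name, g in gaps.items() if g - gmin < AMBIGUITY_GAP]
    call = min(tied, key=lambda name: _PLOIDY_LEVEL[name])
    return PloidyFit(
        logliks=logliks,
        gaps=gaps,
        call=call,
        ambiguous=len(tied) > 1,
        denoised_fraction=retained,
        n_balances=len(b),
        details={"free_means": free_means},
    )


def simulate_allele_balances(
    ploidy: int,
    n_sites: int = 2000,
    mean_coverage: float = 30.0,
    seed: Optional[int] = None,
    min_cov: int = 10,
    maf_min: float = 0.2,
    noise_fraction: float = 0.0,
) -> np.ndarray:
    """Synthetic allele balances for one individual of known ploidy.

    Per site: a heterozygous dosage d is drawn uniformly from 1..m-1,
    coverage from Poisson(mean), alternate reads Binomial(cov, d/m);
    optional uniform contamination emulates mismapping noise.  The same
    coverage and minor-fraction thresholds as the extraction step are
    applied.
    """
    if ploidy < 2:
        raise GhostpopError("ploidy must be >= 2")
    rng = np.random.default_rng(seed)
    cov = rng.poisson(mean_coverage, size=n_sites)
    dosage = rng.integers(1, ploidy, size=n_sites)
    frac = dosage / ploidy
    noisy = rng.random(n_sites) < noise_fraction
    frac = np.where(noisy, rng.random(n_sites), frac)
    alt = rng.binomial(cov, frac)
    with np.errstate(divide="ignore", invalid="ignore"):
        b = np.where(cov > 0, alt / cov, np.nan)
        minor = np.minimum(b, 1 - b)
    ok = (cov >= min_cov) & (minor >= maf_min)
    return b[ok]
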