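# Methods

This note records the models, estimators, defaults and numerical
choices behind `ghostpop`, and what the synthetic-data studies do and
do not demonstrate.

## The inference problem

An invasive plant is sampled in its native range (three structured
regional groups) and in two introduced regions: an eastern population
(EAU) first recorded roughly 120 years before sampling and a western
one (WAU) roughly 25 years before sampling. With a generation time of
3 years those records translate into narrow introduction-time priors of
38–45 and 8–10 generations. The questions are which source each
introduction came from (including the possibility that the true source
was never sampled — a *ghost* population), whether WAU is a secondary
*bridgehead* invasion out of EAU, how small the founding groups were,
and whether the invader is diploid. Inference is simulation-based:
competing demographic scenarios are simulated from priors, summarised,
and compared to the observed summary statistics with random forests
(scenario choice) and local-linear regression (parameter estimation).

## Genotype model and filtering

Genotypes are unphased diploid alternate-allele counts at biallelic
SNPs on short RAD loci; per-call total depth (DP) and per-allele depth
(AD) accompany each call. The filter cascade runs in a fixed order:

1. drop samples with >90% missing genotypes;
2. set calls with depth <5 to missing (calls with unknown depth kept);
3. keep biallelic sites with <20% missing calls and MAF >0.05,
   computed over non-missing calls *after* stage 2;
4. keep one uniformly chosen SNP per RAD locus (explicit seed,
   default 1, recorded in the report);
5. drop samples with >50% missing genotypes.

All inequalities are strict. Stage 5 changes per-site missingness
denominators and can in principle re-break the stage-3 bound; such
sites are counted in the report rather than silently re-filtered, so
the report plus the seed fully determines the output. The cascade is
idempotent once thinning has been done.

## Statistics

For a group with `n` called genotypes at a site, `p` the alternate
frequency: Ho is the called heterozygote fraction; He is the naive gene
diversity `2p(1-p)` (an unbiased `2n/(2n-1)` variant sits behind a
flag); π at SNP sites is `2p(1-p)·2n/(2n-1)`, i.e. mean pairwise
difference per site — without invariant sites this is *not* comparable
to per-locus π from an assembly, a deliberate and documented
divergence. F_IS defaults to the ratio-of-means `1 − mean(Ho)/mean(He)`
(per-site mean behind a flag); its standard error uses the delta method
on the site-wise (Ho, He) covariance. Standard errors elsewhere are
site-wise SEs of the mean; with linked or filtered data they understate
uncertainty relative to locus bootstraps.

Differentiation: Weir–Cockerham θ (1984 variance components, ratio of
sums over sites, any number of groups); AMOVA Φ_ST on squared
differences of allele counts (per-site complete cases, summed SSDs; for
complete data this equals the classical distance-matrix AMOVA, verified
against a brute-force oracle to 1e-10); F'_ST as G_ST divided by its
Hedrick-style maximum given within-group diversity; Nei's standard D
with +inf flagged when no identity is shared. θ between two identical
finite samples is *not* zero — the estimator carries an O(1/n)
finite-sample term (it is exactly zero in the all-heterozygote case);
tests assert the expectation-level behaviour. The f3 statistic
`mean[(pT−p1)(pT−p2) − pT(1−pT)/(2nT−1)]` carries the usual
sample-size bias correction for the target frequency.

The summary-statistic schema `v1` is a versioned, fixed-order vector:
per group {mean He, variance of He over sites, monomorphic fraction,
mean Ho}; per pair {θ, Nei D (capped at 10 so vectors stay finite)};
per trio orientation {f3} — length `4G + 2·C(G,2) + 3·C(G,3)`. It is a
reconstruction of the diversity/differentiation/admixture families a
SNP ABC analysis uses; versioning lets alternative sets coexist without
breaking stored reference tables.

## Coalescent scenario model

A scenario is a set of demes with diploid effective sizes and diploid
sample counts (ghost demes sample zero) plus backwards-time events:
`merge` (all lineages move child→parent; forwards, a founding),
`admixture` (lineages move recipient→donor with probability `ra`), and
`size_change`. Founder bottlenecks are a `size_change` to founder size
Nf at `t − db` followed by the founding merge at `t`, so the new deme
spends its first `db` generations at size Nf. Validation checks causal
ordering against deme activity and that everything funnels into one
ancestral deme. In msprime the events are expressed as mass lineage
movements (not population-split events) so a sampled deme can also be
the ancestor of a later split.

Each locus is an independent genealogy with exactly one mutation placed
uniformly on total branch length (the single-SNP-per-locus convention
of SNP-based ABC); a locus is redrawn whenever overall-sample MAF falls
below `maf_min` (default 0.05, matching the data filter; 10^4 redraws
raise an error). Diploids pair the two lineages of each simulated
individual. There is no recombination within a locus and no selection.
Mutation placement uses a single reverse sweep over the edge table
(edges are sorted by parent time), JIT-compiled with numba.

The sequencing layer draws per-call depth from a negative binomial with
mean 22 and shape k=7 — chosen to reproduce a ~22× mean with SD ≈ 9.6×,
the overdispersion typical of ddRADseq coverage — splits heterozygote
reads Binomial(DP, 1/2), zeroes depth at injected missing calls (locus
dropout), and can append perfectly linked SNP copies within a locus so
that thinning has work to do. It does not model genotyping *error*
(miscalls), allele-specific bias, or paralog collapse; filter tests on
synthetic data therefore demonstrate bookkeeping correctness, not
robustness to miscalling.

### Priors

Anchored by the historical record: t_EAU ~ U{38..45}, t_WAU ~ U{8..10}
generations (integer), founder sizes bounded below by 5, generation
time 3 years.  Package defaults elsewhere: founder sizes
U{5..100}, bottleneck durations U{1..5} generations, effective sizes
log-uniform [10, 10^4], admixture rate U[0.1, 0.9]; cross-parameter
constraints (e.g. `t_eau > t_wau`, `db < t`) are enforced by rejection.
The *separated* parameterization used by the recovery studies narrows
effective sizes to log-uniform [1e3, 4e3], founder sizes to U{5..30},
ghost divergence to U{300..800} generations and admixture to
U[0.3, 0.7]: native-range differentiation then sits in the
F_ST ≈ 0.1–0.3 regime typical of structured plant populations, and the
three scenario classes differ by topology rather than by extreme size
draws. Under the wide default priors the classes overlap heavily (a
ghost that diverged 50 generations ago at Ne 10^4 is operationally the
sampled source) and no classifier can separate them; the recovery
studies are statements about the separated regime.

## Scenario choice

The classifier is a random forest (default 1000 trees, √d features per
split, unlimited depth, 500 trees in the scaled studies) on the summary
statistics, optionally augmented with the LDA axes fit to the reference
table's scenario labels (default on). Constant statistic columns are
dropped with a warning (detected by an exact range test — floating-point
`std` of a constant column can be spuriously non-zero). The prior error
rate is the out-of-bag misclassification rate. For an observed vector,
votes are per-tree predictions; the posterior probability of the
selected scenario is a regression forest trained on the out-of-bag
classification-success indicator, evaluated at the observed point and
clipped to [0, 1] — a reconstruction of the ABC-RF construction.

The sequential tournament compares scenario subsets per round; a
scenario advances only with strictly more than `n_trees/k` votes (ties
do not advance); if nobody clears the bar the top-voted scenario
advances with a prominent warning, keeping noisy small-table
tournaments runnable; advancers meet in a final round. Forests are
memoised per scenario subset so classifying many observed datasets
against one reference table does not retrain.

## Parameter estimation

Distances are Euclidean on statistics standardized by median absolute
deviation (robust to the heavy tails of simulated F_ST columns);
zero-variance statistics are dropped with a warning. The closest
`tolerance` fraction (default 1%) is kept with Epanechnikov weights
`1 − (d/d_max)²`. Each parameter is logit-transformed to its prior
bounds (integer priors use bounds widened by 0.5 so the grid interior
maps to finite logits), adjusted by weighted local-linear regression on
the statistic discrepancies, and back-transformed — so adjusted draws
always respect the prior bounds. Singular regressions fall back to
rejection-only with a warning. Point estimates and quantiles are
weighted.

Calibration: regression-adjusted ABC intervals are known to narrow
faster than the true posterior when the accepted sample is small
relative to the number of regressors — in a linear-Gaussian testbed the
uncorrected 90% interval covers ~83% at 60 accepted rows. Two choices
keep the intervals honest. First, the adjustment's residuals are
inflated by `sqrt(n_eff/(n_eff − p))`, with Kish's effective sample
size `(Σw)²/Σw²` and `p` regression parameters — the standard
degrees-of-freedom correction for residual spread, which moves the toy
testbed to ~92% at 100 accepted rows. Second, the calibration study
uses a 10,000-row reference table (100 accepted rows at 1% tolerance)
with 80-locus datasets and 6+6 sampled diploids; measured 90% coverage
there sits in the mid-80s to low-90s. Rejection-only posteriors remain
available (`raw_draws`) and cover near nominal by themselves.

## Model checking

Datasets are simulated at parameter draws resampled from the posterior;
each observed statistic gets a two-tailed empirical p-value
`2·min(F, 1−F)` with mid-rank `F = (#less + ties/2 + 0.5)/(n+1)`, which
is uniform under exchangeability. No multiple-testing correction is
applied (the count of significant statistics is itself the diagnostic);
a held-out statistic subset can be reported separately. Posterior
predictive p-values are mildly conservative, so under the truth the
flagged fraction tends to sit at or below α.

## Ploidy from allele balance

Balances `b = alt/(ref+alt)` are kept at sites with total allele
coverage ≥10 and within-individual minor fraction ≥0.2. Because only
the window [0.2, 0.8] is observable, every mixture component is a
Gaussian *truncated to the window* (renormalised by its window mass) —
without this the clipped lower tail of a tetraploid's 1/4 component
shifts its apparent mode and fixed models systematically mis-fit.
Fixed models pin means at {1/2}, {1/3, 2/3}, {1/4, 1/2, 3/4} with free
weights; the free model has three free means; all share one variance so
the comparison is about mode positions. Fits maximise the likelihood
directly (bounded L-BFGS-B on softmax weights / logit means / log
sigma), with candidate starts — data quantiles, hard-assignment
weights, a read-sampling-scale sigma of 0.08 — screened by one
objective evaluation each. The free model is additionally started from
each fixed optimum, so nesting (free ≥ fixed) holds by construction.

The call minimises the normalised gap `(lnL_free − lnL_fixed)/|lnL_free|`;
models within 0.01 of the best gap are tied, the *lowest* tied ploidy
is called, and the fit is flagged ambiguous. The parsimony tie-break
matters: a diploid's unimodal data is fitted exactly as well by the
tetraploid model with all weight on its 1/2 component, so diploids are
frequently "ambiguous but diploid" — the behaviour real diploid RADseq
samples show under this test. Denoising fits three free truncated
components plus a uniform background and removes points whose largest
responsibility is the background; if that would remove most of the data
the fit is deemed failed and the input is returned with a warning. The
simulated validation (dosage uniform in 1..m−1, Poisson(30) coverage,
binomial reads, same thresholds) recovers 60/60 individuals in the
acceptance study; it does not model mapping bias or paralogy, so real
ambiguity rates will be higher.

## Cytometry

Events are gated at FSC-H ≥ 80,000 and FL2-H ≥ 600 (debris exclusion).
The G1 peak is the mode of a Silverman-bandwidth Gaussian KDE of gated
FL2-H on a 2048-point grid; the peak is summarised by the geometric
mean and CV of events within ±20% of the mode. 2C follows from the
sample/reference ratio times the reference 2C (tomato 1.96 pg default);
peaks within 1.1× of each other trigger a resolvability warning.
Genome size is `(2C/2) × 978` Mbp. The estimate is invariant to joint
rescaling of all fluorescence values (the KDE bandwidth scales with the
data). A single G1 peak is assumed — no cell-cycle modelling — and the
synthetic generator (lognormal peak, uniform sub-gate debris) shares
the sample/reference log-spread, which is what makes the window
geometric means cancel exactly in the ratio.

## Problem sizes used in the automated studies

Scenario recovery: 1000 reference simulations per scenario of 500 SNP
loci, 4/4/4 sampled diploids, 500 trees, 50 pseudo-observed datasets
per scenario through a two-round tournament. Calibration: 10,000
reference rows of 80 loci (6+6 diploids), tolerance 1%, 100
pseudo-observed replicates. Bottleneck signature: 200 replicates of 100
loci with founder size 8 and duration U{1..5}. Ploidy: 60 individuals,
2000 sites, 30× coverage. The real study behind these conditions used
10,000 simulations per scenario, ~20,000 SNPs and 138 samples; the
scaled sizes keep every study inside a few CPU-minutes while leaving
the estimators in their working regime.

## Known limitations

- No within-locus recombination, no selection, no mutation model beyond
  one biallelic site per locus; reference tables built under one schema
  cannot be mixed with another.
- The summary-statistic schema is a reconstruction, not the exact
  statistic set of any particular ABC package.
- Regression-adjusted credible intervals under-cover at small accepted
  counts (see above).
- AMOVA operates on unphased genotype allele counts; haplotype-level
  Φ_ST is not computable from unphased SNPs.
- Outlier-locus exclusion is supported only as a hook
  (`filtering.exclude_loci`) taking a caller-supplied locus list; no
  outlier-detection method is implemented.
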