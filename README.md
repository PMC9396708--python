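# ghostpop

Inference of invasion history from reduced-representation (ddRADseq) SNP
data, built around the question a biosecurity geneticist actually asks:
*where did an introduced population come from, was the true source even
sampled, how severe was the founding bottleneck, and is the invader the
ploidy we think it is?*

The package models a two-step plant invasion — a native range split into
structured regional groups, an eastern introduced population (EAU)
founded roughly 38–45 generations before sampling, and a western
population (WAU) founded 8–10 generations ago, possibly with the eastern
one acting as a bridgehead — but every component is generic and driven by
a scenario configuration.

## What it does

- **SNP filtering** (`ghostpop.filtering`): the standard post-calling
  cascade for RADseq data — drop samples >90% missing, mask genotype
  calls with depth <5, keep biallelic sites with <20% missing and minor
  allele frequency >0.05, thin to one SNP per RAD locus (seeded), drop
  samples >50% missing — with a full per-stage report. VCF 4.2 in/out via
  `ghostpop.genotypes`.
- **Population statistics** (`ghostpop.sumstats`): private alleles,
  polymorphic fraction, observed/expected heterozygosity, F_IS,
  nucleotide diversity at SNP sites; pairwise and multi-group
  Weir–Cockerham θ, AMOVA Φ_ST, standardized F'_ST, Nei's D; the f3
  admixture statistic; and a fixed-order summary-statistic vector
  (schema `v1`: per group {mean He, var He, monomorphic fraction, mean
  Ho}, per pair {θ, Nei D}, per trio orientation {f3}).
- **Coalescent scenario simulation** (`ghostpop.scenarios`,
  `ghostpop.simulate`): a small demographic DSL (demes, merges,
  admixture pulses, size changes, ghost demes, founder bottlenecks;
  symbolic parameters bound from priors) compiled to msprime; each RAD
  locus is an independent genealogy carrying exactly one mutation placed
  uniformly on its branches, rejected below a MAF floor. A sequencing
  layer adds negative-binomial depth (~22× mean), allele depths,
  missingness and linked SNPs so the filter cascade can be exercised on
  synthetic data.
- **ABC random-forest model choice** (`ghostpop.modelchoice`): reference
  tables of (scenario, parameters, statistics); a random-forest
  classifier (optionally with LDA axes appended), out-of-bag prior error,
  per-tree votes for an observed dataset, a Pudlo-style posterior
  probability from a regression forest on out-of-bag success, and a
  sequential tournament in which scenarios advance only with strictly
  more than `trees/k` votes.
- **Parameter estimation and model checking** (`ghostpop.estimate`):
  rejection to the closest 1% of reference rows, weighted local-linear
  regression adjustment on a logit scale (draws always respect prior
  bounds), weighted quantiles; posterior-predictive checks with
  two-tailed empirical p-values per summary statistic.
- **Ploidy and genome size** (`ghostpop.ploidy`, `ghostpop.cytometry`):
  allele-balance extraction (coverage ≥10, minor fraction ≥0.2),
  uniform-background denoising, maximum-likelihood comparison of fixed
  diploid/triploid/tetraploid truncated-Gaussian mixtures against a free
  mixture; flow-cytometry gating (FSC-H ≥ 80,000, FL2-H ≥ 600), KDE G1
  peak detection, 2C DNA content against an internal standard (tomato,
  2C = 1.96 pg) and the 1 pg = 978 Mbp genome-size conversion.

## A worked example

`examples/03_scenario_choice.py` simulates 200 reference datasets per
scenario (300 SNP loci each) for three competing histories of the
introduction — direct from the sampled native source, from an unsampled
ghost population, or an admixed bridgehead — trains a 300-tree forest,
and classifies pseudo-observed data generated under the admixed
scenario:

```
out-of-bag prior error rate: 0.108
votes (of 300): {'admixed': 235, 'direct': 4, 'ghost': 61}
selected scenario: admixed (posterior probability 0.78)
round ['direct', 'ghost']: votes {'direct': 10, 'ghost': 290} -> advanced ['ghost']
round ['ghost', 'admixed']: votes {'admixed': 232, 'ghost': 68} -> advanced ['admixed']
tournament winner: admixed
```

The out-of-bag error is the prior probability of picking the wrong
scenario; the vote share measures how decisively the forest separates
the histories; and the tournament reproduces the sequential
subset-then-final comparison used for real analyses. The other examples
cover filtering (`01`), diversity tables (`02`), parameter posteriors
and model checking (`04`), ploidy calls (`05`) and cytometry (`06`).

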