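"""Independent brute-force oracles for differentiation statistics.

These are deliberately naive reimplementations from the original
definitions — explicit per-site loops for the Weir-Cockerham (1984)
variance components, and a literal sums-of-squares AMOVA on the full
pairwise distance matrix — used only to validate the vectorised
implementations on small random instances.
"""

import itertools
import math

import numpy as np


def wc84_theta_bruteforce(pops):
    """Weir-Cockerham theta over sites as a ratio of summed components.

    ``pops``: list of (n_sites x n_individuals) genotype arrays coded
    0/1/2, no missing data.
    """
    r = len(pops)
    n_sites = pops[0].shape[0]
    sum_a = sum_b = sum_c = 0.0
    for s in range(n_sites):
        ns, ps, hs = [], [], []
        for pop in pops:
            g = pop[s]
            ns.append(len(g))
            ps.append(sum(g) / (2 * len(g)))
            hs.append(sum(1 for x in g if x == 1) / len(g))
        nbar = sum(ns) / r
        if nbar <= 1:
            continue
        nc = (r * nbar - sum(n * n for n in ns) / (r * nbar)) / (r - 1)
        if nc <= 0:
            continue
        pbar = sum(n * p for n, p in zip(ns, ps)) / (r * nbar)
        s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
        hbar = sum(n * h for n, h in zip(ns, hs)) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        sum_a += a
        sum_b += b
        sum_c += c
    denom = sum_a + sum_b + sum_c
    return math.nan if denom == 0 else sum_a / denom


def amova_phist_bruteforce(pops):
    """Phi-ST from literal AMOVA sums of squares on the pairwise
    squared-difference distance matrix of alternate-allele counts.

    ``pops``: list of (n_sites x n_individuals) genotype arrays, no
    missing data.
    """
    X = np.hstack(pops).T.astype(float)  # individuals x sites
    sizes = [p.shape[1] for p in pops]
    N = X.shape[0]
    k = len(pops)
    D = np.zeros((N, N))
    for i, j in itertools.combinations(range(N), 2):
        D[i, j] = D[j, i] = ((X[i] - X[j]) ** 2).sum()
    ssd_total = D[np.triu_indices(N, 1)].sum() / N
    ssd_within = 0.0
    start = 0
    for n_p in sizes:
        idx = range(start, start + n_p)
        sub = [D[i, j] for i, j in itertools.combinations(idx, 2)]
        ssd_within += sum(sub) / n_p
        start += n_p
    ssd_among = ssd_total - ssd_within
    df_among = k - 1
    df_within = N - k
    sigma_w = ssd_within / df_within
    n_prime = (N - sum(n * n for n in sizes) / N) / (k - 1)
    sigma_a = (ssd_among / df_among - sigma_w) / n_prime
    tot = sigma_a + sigma_w
    return math.nan if tot == 0 else sigma_a / tot


def random_instance(rng, n_groups=2, max_samples=8, max_sites=10):
    """Random small genotype instance guaranteed to carry variation."""
    while True:
        n_sites = rng.integers(2, max_sites + 1)
        pops = [
            rng.integers(0, 3, size=(n_sites, rng.integers(2, max_samples + 1)))
            for _ in range(n_groups)
        ]
        flat = np.hstack(pops)
        if (flat.std(axis=1) > 0).any():
            return pops
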