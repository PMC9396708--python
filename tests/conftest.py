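import numpy as np
import pytest

from ghostpop import GenotypeMatrix, PopulationMap


def make_gm(
    genotypes,
    loci=None,
    samples=None,
    depth=None,
    allele_depth=None,
    alt=None,
):
    """Build a small GenotypeMatrix from nested lists (sites x samples)."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_samples = g.shape
    if samples is None:
        samples = [f"s{j}" for j in range(n_samples)]
    if loci is None:
        loci = [str(i) for i in range(n_sites)]
    return GenotypeMatrix(
        samples=list(samples),
        locus_ids=np.array([str(x) for x in loci], dtype=object),
        positions=np.arange(1, n_sites + 1),
        ref=np.array(["A"] * n_sites, dtype=object),
        alt=np.array(alt if alt is not None else ["T"] * n_sites, dtype=object),
        genotypes=g,
        depth=None if depth is None else np.asarray(depth, dtype=np.int32),
        allele_depth=(
            None
            if allele_depth is None
            else np.asarray(allele_depth, dtype=np.int32)
        ),
    )


def make_popmap(sample_pops, grouping=None):
    return PopulationMap(assignment=dict(sample_pops), grouping=grouping or {})


@pytest.fixture
def gm_factory():
    return make_gm


@pytest.fixture
def popmap_factory():
    return make_popmap
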