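"""Diversity and differentiation statistics for a five-group system.

Simulates the study system (native range split into south/central/
north groups; an eastern introduced population founded from a ghost
source through a strong bottleneck; a western population founded from
the eastern one with ghost admixture), then prints the per-group
diversity table and pairwise differentiation matrices.
"""

import pandas as pd

from ghostpop import diversity, nei_distance, pairwise_fst
from ghostpop.presets import study_system_scenario
from ghostpop.genotypes import PopulationMap
from ghostpop.simulate import simulate_snps

pd.set_option("display.width", 120)
pd.set_option("display.float_format", lambda v: f"{v:.4f}")

spec = study_system_scenario()
gm = simulate_snps(spec, n_loci=2000, seed=7)
popmap = spec.population_map(
    grouping={
        "NRS": "native",
        "NRC": "native",
        "NRN": "native",
        "EAU": "EAU",
        "WAU": "WAU",
    }
)

div = diversity(gm, popmap)
print("per-group diversity (native = pooled native range):")
print(div[["private_alleles", "polymorphic_fraction", "Ho", "He", "FIS", "pi"]])
print(
    "\nexpect: far fewer private alleles and lower polymorphic fraction in "
    "the introduced groups (founder bottlenecks), Ho largely preserved, "
    "and positive FIS in the pooled native range (Wahlund effect of "
    "pooling three structured groups)"
)

for est in ("WC84", "PhiST", "FST_std"):
    print(f"\npairwise {est}:")
    print(pairwise_fst(gm, popmap, estimator=est))
print("\nNei's standard genetic distance:")
print(nei_distance(gm, popmap))
print(
    "\nall pairs involving an introduced group show strong differentiation "
    "- founder drift during the bottlenecks dominates; WAU, founded "
    "through two sequential bottlenecks, is the most diverged from the "
    "native range"
)
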