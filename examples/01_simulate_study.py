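"""Simulate the default synthetic F2 study and inspect its structure.

Generates 115 F2 animals plus one "average" animal per parental strain on a
384-marker genome-wide panel, with an epistatic phenotype: only animals
homozygous for the A-strain allele at two unlinked loci (chromosomes 11 and
18) have roughly doubled airway responsiveness.
"""

import numpy as np

from qtlspan import simulate_scenario
from qtlspan.cross import AA

scenario = simulate_scenario(seed=1)
cross = scenario.cross
print(f"animals: {cross.n_mice} ({cross.origins.count('F2')} F2 + 2 parental averages)")
print(f"markers: {cross.gmap.n_markers} over {len(cross.gmap.chromosomes)} autosomes")
print(f"planted loci: {scenario.model.locus_a} (chr 11) x {scenario.model.locus_b} (chr 18)")

# segregation at the first planted locus: F2 expectation is 1 AA : 2 AB : 1 BB
g = cross.genotype_at(scenario.model.locus_a)[:115]
counts = np.bincount(g, minlength=3)
print(f"AA/AB/BB at {scenario.model.locus_a}: {counts[0]}/{counts[1]}/{counts[2]}")

ga = cross.genotype_at(scenario.model.locus_a)
gb = cross.genotype_at(scenario.model.locus_b)
both = (ga == AA) & (gb == AA)
ratio = cross.phenotype[both].mean() / cross.phenotype[~both].mean()
print(f"double-homozygous animals: {both.sum()}; responsiveness ratio vs rest: {ratio:.2f}")
print("(the ratio should be about 2: the planted epistatic effect)")
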