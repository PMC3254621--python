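"""Delimit the linked haplotype windows and list their candidate genes.

High responders are the animals homozygous for the A-strain allele at both
peak markers. Each locus extends over the run of markers where none of
those animals shows a crossover, plus a 1 Mb flank for distal regulatory
elements; genes overlapping the window by at least 1 bp are candidates.
"""

from qtlspan import (
    extend_interval,
    genes_in_interval,
    nonrecombinant_span,
    select_high_responders,
    simulate_scenario,
)

scenario = simulate_scenario(seed=1)
cross = scenario.cross
locus_a, locus_b = scenario.model.locus_a, scenario.model.locus_b

responders = select_high_responders(cross, locus_a, locus_b)
print(f"high responders (AA at both {locus_a} and {locus_b}): {len(responders)}")

for locus in (locus_a, locus_b):
    chrom = cross.gmap.chrom_of(locus)
    span = nonrecombinant_span(cross, responders, chrom, locus)
    interval = extend_interval(cross.gmap, span, flank_bp=1_000_000)
    genes = genes_in_interval(scenario.annotation, interval)
    print(f"chr {chrom}: non-recombinant span {span[0]}..{span[1]}, "
          f"window {interval.start_bp / 1e6:.1f}-{interval.end_bp / 1e6:.1f} Mb, "
          f"{len(genes)} candidate genes")
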