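"""Simulate a two-parent haploid cross and inspect its recombination.

Builds the default desk-scale genome (two chromosomes, 200 genes, 500
SNP/indel sites, a recombination-suppressed pericentric inversion), crosses
the parents into 44 F1 segregants and prints the breakpoint statistics.
"""

from segqtl import SimConfig, make_genome, simulate_cross

genome = make_genome(SimConfig(), seed=1)
truth = simulate_cross(genome, n_segregants=44, generation="F1", seed=1)

counts = truth.breakpoint_counts()
inv = genome.inversion
inside = sum(
    1
    for bps in truth.breakpoints.values()
    for chrom, pos in bps
    if chrom == inv.chrom and inv.start <= pos <= inv.end
)
total = int(counts.sum())

print(f"genome: {len(genome.genes)} genes, {len(genome.variants)} variant sites")
print(f"segregants: {len(truth.strains)}")
print(f"breakpoints: {total} total, {counts.mean():.1f} per strain")
print(f"breakpoints inside the inversion: {inside} "
      f"({inv.chrom}:{inv.start}-{inv.end}, suppression 0.1)")

# Per strain the genome is a mosaic of large parental blocks; the inversion
# contributes almost no breakpoints because crossovers there are suppressed,
# so markers inside it segregate as one giant linked block.
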