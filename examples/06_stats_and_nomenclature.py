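"""Assembly statistics and chromosome-name translation.

N50 is the contig length at which half of all assembled bases sit in
contigs at least that long — the standard single-number contiguity
summary.  The nomenclature table translates chromosome labels between
human/great-ape numbering and the macaque systems.
"""

from scaftier import (SimConfig, compute_assembly_stats, map_chromosome_name,
                      simulate_world)

world = simulate_world(SimConfig(seed=7, n_chromosomes=2, chrom_length=300_000,
                                 n_genes=24, n_scaffold_fragments=10, n_chimeras=2))
stats = compute_assembly_stats(world.scaffolds)
print(f"contigs        : {stats.n_contigs}")
print(f"total bp       : {stats.total_bp:,}")
print(f"max contig     : {stats.max_contig:,} bp")
print(f"contig N50     : {stats.contig_n50:,} bp")
print(f"scaffold N50   : {stats.scaffold_n50:,} bp")
# Chimeric scaffolds contain 100-N junction gaps, so there are slightly
# more contigs than scaffolds and contig N50 < scaffold N50.

print("\nchromosome-name translations (human -> macaque):")
for label in ("1", "2p+", "2q-", "7/21", "X"):
    print(f"  {label:>5}  ->  {map_chromosome_name(label, 'H', 'M')}")
# Human 2p+/2q- map to macaque 2a/2b: human chromosome 2 arose from a
# fusion after the macaque lineage diverged, so the macaque keeps two
# separate chromosomes.
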