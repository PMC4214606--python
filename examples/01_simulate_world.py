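"""Generate a small truth-annotated world and look at what it contains.

The simulator builds a reference genome with known genes, derives a
diverged target genome from it by shuffling synteny blocks and applying
substitutions, and fragments the target into draft scaffolds — some of
them deliberately chimeric.  Everything downstream examples consume comes
from here.
"""

from scaftier import SimConfig, simulate_world, write_world

config = SimConfig(seed=7, n_chromosomes=2, chrom_length=300_000, n_genes=24,
                   n_scaffold_fragments=10, n_chimeras=2)
world = simulate_world(config)

print(f"reference chromosomes : {[r.id for r in world.reference]}")
print(f"target chromosomes    : {[r.id for r in world.target_chromosomes]}")
print(f"scaffolds emitted     : {len(world.scaffolds)}")
print(f"genes planted         : {len(world.genes)}")
print(f"markers on the map    : {len(world.markers)}")
print(f"synteny blocks        : {len(world.synteny)}")
print("planted chimeric joins:")
print(world.truth.junctions.to_string(index=False))

write_world(world, "scratch/example_world")
print("\nworld written to scratch/example_world/ (truth tables under truth/)")
# The junction table is the ground truth the curation example must rediscover:
# each row is an N-gap inside one scaffold that wrongly fuses two chromosomes.
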