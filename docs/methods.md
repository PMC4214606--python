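# Methods

This note documents the models, rules and numerical choices behind
`scaftier`, what the bundled simulator does and does not emulate, and the
design decisions taken where the design was genuinely open.

## Coordinate conventions

Internally every coordinate is 0-based half-open.  External formats keep
their native conventions — GTF, AGP and 12-column (outfmt-6 dialect)
alignment tables are 1-based inclusive, with `t_start > t_end` encoding a
minus-strand hit — and conversion happens only inside readers/writers.
This confines off-by-one risk to the I/O boundary, where round-trip tests
pin it down.

## The internal mapper

`mapping.build_index` / `map_sequence` implement an exact-k-mer
seed-and-extend mapper used to place reference exons, markers, tiling
segments and reads on scaffolds.  Choices:

* **k = 15, index stride configurable (1 by default, 2 in the pipeline).**
  At ~1% nucleotide divergence the chance that a 15-mer is substitution
  free is ≈ 0.86, so even a 120-bp exon yields dozens of candidate seeds;
  striding the index halves memory at a modest seed-density cost.
* **Ungapped extension.**  Seeds sharing a (scaffold, strand, diagonal) are
  chained; the dominant diagonal is scored by direct string comparison
  over the full query/scaffold overlap.  Placement needs loci and
  orientation, not base-perfect alignments; inputs with indels are served
  by importing an external alignment table (`map_exons(external_table=…)`),
  which is also the production path when a dedicated aligner was run.
* **≥ 2 colinear seeds per chain** (1 for queries shorter than 2k, where
  two disjoint seeds cannot fit) suppresses spurious single-seed hits.
* **Defaults**: min_identity 95% for exons (reflecting primate coding
  divergence), 90% for tiling segments and reads; min coverage 0.5 of the
  query (0.9 for read-mappability assessment).  All configurable.
* **Best-hit policy**: a single best alignment per query — highest score
  (match count), ties broken by identity, then alignment length, then
  lexicographically smallest target id, so results are deterministic.

## Contiguity rule and chimera breaking

Per gene with ≥ 2 placed exons: `split_gene` if exons land on ≥ 2
scaffolds, `orientation_violation` for mixed strands, `order_violation`
when exon starts are not strictly monotonic in transcript order
(increasing on `+`, decreasing on `−`).

Chimera detection positions each gene on its scaffold (midpoint of its
exon hits), assigns each gene a chromosome vote by locating its reference
coordinates in the synteny blocks, and scans for maximal runs of equal
votes.  Two or more runs ⇒ chimeric scaffold.  Two guards:

* **min_run_genes = 2**: a single interleaved foreign gene is reported for
  curation but never triggers an automatic break — single-gene evidence is
  exactly the case manual curation existed for, and breaking on it is
  fragile.
* **Inversions are reported, not broken**: order/orientation violations
  within one scaffold do not change which chromosome a segment belongs to,
  and breaking is only needed for placement.  (Small inversions may
  therefore survive into the chromosome build — a documented limitation of
  reference-guided ordering.)

Break coordinates: the midpoint of the longest N-run strictly between two
adjacent clusters, else the midpoint of the inter-cluster interval.
Assembly gaps are where scaffolding joins were made, so the longest gap is
the best available estimate of the join point; the exact choice within the
gap is arbitrary and the midpoint is deterministic.  `apply_breaks` names
parts `<id>.1 … <id>.n` left-to-right and emits a provenance table;
concatenating the parts reproduces the parent byte-exactly.

## Tiered placement and the merge

Tier 1 (markers): a scaffold inherits its markers' chromosome; its rank is
the median marker order; orientation is the sign of the correlation
between marker rank and scaffold position, falling back to the majority
hit strand for single-marker scaffolds.  Markers disagreeing on the
chromosome leave the scaffold unplaced with a recorded conflict.

Tier 2 (synteny): each gene's reference position selects a synteny block;
the scaffold follows the majority chromosome/block, ordered within the
block by the median reference position of its genes — negated when the
block is inverted, so larger keys always mean further along the target
chromosome.  Orientation = block orientation × majority exon-hit strand
(the two flips cancel when an inverted block rides a forward scaffold).

Tier 3 (tiling): reference chromosomes are cut into 10-kb segments (the
terminal stub still votes); each segment's best hit votes
(ref_chrom, segment index, strand); the scaffold is placed at the synteny
position of its median voting segment.

**Merge.**  Marker ranks and reference coordinates are not on a common
scale, so a single lexicographic sort key cannot interleave tiers.  The
merge instead sorts marker-bearing scaffolds by median marker order (a
total order along the chromosome — the "backbone") and inserts
synteny/tiling placements by bisection among backbone members that carry
both keys.  Scaffolds with both kinds of evidence use markers for
chromosome and orientation and record a conflict when synteny disagrees —
marker maps are assembly-independent, so they win.  An override table
(manual curation) is applied last and always wins.  Ties in orientation
evidence (exact 50/50) default to `+` with a conflict note, keeping output
deterministic.

AGP output uses 100-N inter-scaffold gaps (`gap_type scaffold`,
`linkage no`); the gap length is a convention, not an estimate, and is
configurable.  Chromosome FASTA headers are `chr<label>` using the macaque
(M-column) labels of the bundled nomenclature table, including `2a`/`2b`.

## Annotation QC

`extract_cds` splices CDS intervals 5′→3′ (reverse-complemented,
right-to-left on `−`), trimming the translation-first interval's phase.
`translate` uses the standard code and returns diagnostic flags
(`internal_stop` — protein truncated at the stop, `no_start`,
`incomplete_codon`) instead of raising, because broken models are data,
not errors.

`global_align` is Needleman–Wunsch with affine gaps via Biopython's
`PairwiseAligner`: BLOSUM62, gap open 10, extend 0.5, **free end gaps**
(the `needle` default; the end-gap setting changes gap counts for
length-discrepant pairs, so it is stated here explicitly).  A gap of
length L costs `open + (L−1)·extend`.  Identity and similarity are
percentages of alignment columns (gap columns in the denominator);
similarity counts columns with a positive substitution score, identities
included; `gap_positions` counts gap characters over both rows (a count,
not a percentage — matching the summary-table convention this mirrors).

Acceptance: `accept` iff |Δlen| < 5 aa and similarity > 92% (both strict)
and no internal stop; otherwise `flag_for_review`.  The toolkit never
auto-rejects: borderline values are exactly the manual-inspection cases,
and a configurable `fast_evolving` class (defaults Δlen < 10, similarity
> 80%; artifact defaults, since no published numbers exist for the
relaxation) covers gene families that legitimately score low.

Terminal-exon repair: when the two 3′-most exons are non-coding past the
CDS and within 1 kb of each other, they merge (with the intervening
sequence) into one terminal exon; CDS is untouched.  The optional 3′-UTR
extension projects the reference terminal-exon length onto the model when
the downstream sequence is gap-free — projection by length, not by
alignment, which keeps the module alignment-free at the cost of ignoring
local indels (documented limitation).  Missed-exon rescue and paralog
resolution are served by `map_sequence` plus the override/report files
rather than bespoke operations.

`validate_gtf` checks CDS⊆exon containment, exon overlap and strand
sanity, and removes duplicate transcripts (identical chromosome, strand,
exon set and CDS set), keeping the lexicographically smallest transcript
id.  Validation is idempotent.

## Read filter

Keep a read iff best alignment length > threshold(read length), with the
two literal thresholds 76→70 and 100→90 and a floor(0.9·length) fallback
for unlisted lengths (70/76 ≈ 0.921 and 90/100 = 0.90; the fallback is an
interpolation choice).  "Alignment length" is the alignment column count
as reported in outfmt-6 column 4.  In paired mode a pair survives iff both
mates survive; unpaired ids in paired mode are an error, and output files
stay synchronized.

## The simulator

`sim.simulate_world` emulates the study design: a well-annotated reference
species guiding a diverged draft.  Defaults are the simulated study
conditions used throughout the tests: 3 chromosomes × 2 Mb, 150 multi-exon
genes (3–8 exons of 120–300 bp, introns 300–2000 bp), 2 synteny blocks per
chromosome shuffled across target chromosomes with random orientation, 1%
per-site substitutions, 40 emitted scaffolds of which 5 are chimeric
fusions of gene-rich fragments from different chromosomes joined by a
100-N gap, ≥ 2 markers per scaffold part (plus a 20/Mb density component),
and scaffolds randomly reverse-complemented at emission.

Deliberate simplifications, and what they mean for the tests:

* **Substitutions only** in the default divergence model, with coding
  repair (start codon, internal stops and the terminal stop are reverted
  to the reference base).  This conserves exon order and protein lengths,
  isolating the curation/QC logic under test; an intergenic indel mode
  exists for stressing the mappers but invalidates gene-coordinate truth.
  Real data adds indels, so real protein comparisons have nonzero gap
  counts where the simulated ones are ~0.
* **Chimeras join fragments that each carry ≥ 2 genes.**  The detector's
  min_run_genes guard needs two genes per cluster; a chimera inside a
  gene desert is undetectable by annotation evidence by construction, in
  the simulator and in reality alike.
* **Fragment cuts and block boundaries are intergenic**, so no gene is
  split between scaffolds and truth tables stay internally consistent;
  real assemblies do split genes, which surfaces as `split_gene`
  violations rather than chimera calls.
* Gene models have no UTR exons (exons = CDS); the terminal-exon
  operations are exercised on hand-built models in the unit tests.
* No repeat landscape, no sequencing-error model, no GC bias.  Passing
  tests therefore demonstrate the logic under near-ideal evidence, not
  robustness to repeat-induced ambiguous mappings.

Reads: error-free uniform sampling from spliced transcripts with a
configurable fraction drawn from intergenic sequence (truth-labelled);
paired mode samples a 2·read_length+50 insert.

Determinism: one `numpy` Generator seeded from `SimConfig.seed` drives
everything; identical seeds give byte-identical emitted files, and the
seed is recorded in FASTA headers and `config.json`.

## Problem sizes used by the tests and acceptance script

Unit tests run on 2–3 chromosome worlds of 150–300 kb (seconds); the
end-to-end and acceptance checks run the default 6-Mb world once per
session (tens of seconds, shared via session fixtures).  The acceptance
script simulates one default world per run; these sizes keep a full run on
one CPU under a minute while leaving every rule's decision boundary
exercised at realistic gene/marker densities.

## Known limitations

* The merge's backbone-plus-bisection interleave is exact when marker
  order is consistent with synteny; with grossly wrong marker maps it
  degrades to marker order plus conflict notes rather than attempting a
  global reconciliation.
* Tier-3 placements follow reference order inside blocks, so small
  inversions and translocations below tiling resolution are represented in
  reference order.
* The internal mapper is not quality-aware and does not do spliced or
  gapped alignment; it is a placement tool, not an aligner replacement.
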