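"""Truth-annotated synthetic worlds.

The simulator emulates the study design the toolkit exists for: a
well-annotated reference species guides the curation of a diverged,
fragmented draft of a related species.  It builds

* a reference genome with multi-exon protein-coding genes (exon order,
  CDS phases and proteins all known),
* a target genome derived from the reference by rearranging synteny
  blocks (with inversions of whole blocks) and applying per-site
  substitutions — coding sequence is repaired so that substitutions never
  destroy the start codon, create premature stops, or remove the terminal
  stop, keeping protein lengths conserved by construction,
* draft scaffolds cut from the target chromosomes at intergenic sites,
  some of which are chimeric fusions of fragments from different
  chromosomes joined across a 100-N gap, and some of which are emitted
  reverse complemented,
* an ordered marker map, the synteny-block table, reference exon/protein
  sequences with gene metadata, true gene models in scaffold coordinates,
  and read sets with known transcriptomic/genomic origin.

Every quantity the pipeline is supposed to recover is recorded in a
:class:`TruthSet`.  All randomness flows from the single configured seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .gtf import GeneModel, write_gtf
from .mapping import ExonMeta, write_exon_metadata
from .seqio import SeqRecord, revcomp, write_fasta, write_fastq
from .tables import Marker, SyntenyBlock, write_markers, write_synteny

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = ("TAA", "TAG", "TGA")
_M_LABELS = ("1", "2a", "2b", "3", "4", "5", "6", "7", "8", "9", "10")


@dataclass
class SimConfig:
    """Study-design knobs; defaults are the simulated study conditions
    (3 chromosomes of 2 Mb, 150 genes, 40 scaffolds of which 5 chimeric,
    1% nucleotide divergence)."""

    seed: int
    n_chromosomes: int = 3
    chrom_length: int = 2_000_000
    n_genes: int = 150
    exons_per_gene: tuple[int, int] = (3, 8)
    exon_length: tuple[int, int] = (120, 300)
    intron_length: tuple[int, int] = (300, 2000)
    substitution_rate: float = 0.01
    indel_rate: float = 0.0  # intergenic single-base indels (stress mode)
    n_scaffold_fragments: int = 40  # emitted scaffolds, chimeras included
    n_chimeras: int = 5
    n_inversions: int = 0
    blocks_per_chromosome: int = 2
    marker_density: float = 20.0  # per Mb, on top of the per-scaffold floor
    marker_min_per_scaffold: int = 2
    marker_length: int = 300
    chimera_gap_len: int = 100
    read_length: int = 76
    n_reads: int = 2000
    contamination_fraction: float = 0.1

    def validate(self) -> None:
        if not (0 <= self.substitution_rate < 1):
            raise ConfigError("substitution_rate must be in [0, 1)")
        if not (0 <= self.contamination_fraction <= 1):
            raise ConfigError("contamination_fraction must be in [0, 1]")
        for name in ("n_chromosomes", "chrom_length", "n_genes",
                     "n_scaffold_fragments", "read_length", "n_reads"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.n_chimeras * 2 > self.n_scaffold_fragments + self.n_chimeras:
            raise ConfigError("more chimeras than fragment pairs available")


@dataclass
class RefGene:
    gene_id: str
    ref_chrom: str
    exons: list[tuple[int, int]]  # 0-based half-open on the reference chromosome
    cds_seq: str  # reference coding sequence (spliced)
    # filled when the target genome is built:
    target_chrom: str = ""
    target_exons: list[tuple[int, int]] = field(default_factory=list)
    target_strand: str = "+"


@dataclass
class TruthSet:
    """Everything the pipeline should recover.

    scaffold_parts: one row per true genomic segment of each emitted
    scaffold (non-chimeric scaffolds have one part) with target-chromosome
    span, orientation of the emitted sequence relative to the chromosome,
    and the part's extent in scaffold coordinates.
    junctions: planted chimeric joins, with the N-gap extent in scaffold
    coordinates.  gene_chrom: true target chromosome per gene.
    """

    scaffold_parts: pd.DataFrame
    junctions: pd.DataFrame
    inversions: pd.DataFrame
    gene_chrom: dict[str, str]


@dataclass
class SimWorld:
    config: SimConfig
    reference: list[SeqRecord]
    target_chromosomes: list[SeqRecord]
    scaffolds: list[SeqRecord]
    genes: list[RefGene]
    exon_records: list[SeqRecord]
    exon_metadata: dict[str, ExonMeta]
    markers: list[Marker]
    synteny: list[SyntenyBlock]
    ref_proteome: list[SeqRecord]
    ortholog_pairs: list[tuple[str, str]]  # (gene_id, reference protein id)
    true_models: list[GeneModel]
    truth: TruthSet


def _random_dna(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, n)]


def _codons(rng: np.random.Generator, n: int) -> str:
    """n random non-stop codons."""
    sense = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
             if a + b + c not in _STOPS]
    idx = rng.integers(0, len(sense), n)
    return "".join(sense[i] for i in idx)


def _translate_simple(cds: str) -> str:
    from Bio.Seq import Seq

    protein = str(Seq(cds).translate())
    return protein[:-1] if protein.endswith("*") else protein


def _plan_genes(cfg: SimConfig, rng: np.random.Generator,
                chrom_names: list[str]) -> dict[str, list[RefGene]]:
    """Lay genes along each reference chromosome with scaled intergenic gaps
    so they span the whole chromosome."""
    per_chrom = {c: [] for c in chrom_names}
    counts = [cfg.n_genes // cfg.n_chromosomes] * cfg.n_chromosomes
    for i in range(cfg.n_genes % cfg.n_chromosomes):
        counts[i] += 1
    gid = 0
    margin = 10_000
    for chrom, count in zip(chrom_names, counts):
        structures = []
        total_span = 0
        for _ in range(count):
            n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
            ex_lens = rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1, n_ex)
            ex_lens[-1] += (3 - int(ex_lens.sum()) % 3) % 3  # whole codons overall
            in_lens = rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1,
                                   max(n_ex - 1, 0))
            structures.append((ex_lens.tolist(), in_lens.tolist()))
            total_span += int(ex_lens.sum() + sum(in_lens))
        free = cfg.chrom_length - 2 * margin - total_span
        if free < count + 1:
            raise ConfigError("chromosome too short for the requested genes: infeasible config")
        gaps = rng.random(count + 1)
        gaps = np.floor(gaps / gaps.sum() * free).astype(int)
        pos = margin
        for (ex_lens, in_lens), gap in zip(structures, gaps):
            pos += int(gap)
            exons = []
            p = pos
            for i, el in enumerate(ex_lens):
                exons.append((p, p + int(el)))
                p += int(el)
                if i < len(in_lens):
                    p += int(in_lens[i])
            coding_len = sum(e - s for s, e in exons)
            cds = "ATG" + _codons(rng, coding_len // 3 - 2) + _STOPS[int(rng.integers(0, 3))]
            gene = RefGene(f"g{gid:04d}", chrom, exons, cds)
            per_chrom[chrom].append(gene)
            gid += 1
            pos = p
    return per_chrom


def _mutate_block(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Per-site substitutions (always to a different base)."""
    out = seq.copy()
    if rate <= 0:
        return out
    hit = np.nonzero(rng.random(len(seq)) < rate)[0]
    if hit.size:
        shift = rng.integers(1, 4, hit.size)
        base_idx = np.searchsorted(_BASES, out[hit])
        out[hit] = _BASES[(base_idx + shift) % 4]
    return out


def _repair_cds(mut: np.ndarray, ref: np.ndarray, exons_rel: list[tuple[int, int]]) -> None:
    """Revert substitutions that break the reading frame of one gene
    (in block-relative, reference-orientation coordinates): keep the start
    codon, keep the terminal stop, remove premature stops."""
    spliced_pos = np.concatenate([np.arange(s, e) for s, e in exons_rel])
    cds = mut[spliced_pos].tobytes().decode()
    n_codons = len(cds) // 3
    for j in range(n_codons):
        codon = cds[3 * j : 3 * j + 3]
        bad = (
            (j == 0 and codon != "ATG")
            or (j < n_codons - 1 and codon in _STOPS)
            or (j == n_codons - 1 and codon not in _STOPS)
        )
        if bad:
            pos = spliced_pos[3 * j : 3 * j + 3]
            mut[pos] = ref[pos]


def _phases(exon_lengths: Sequence[int]) -> list[int]:
    """GTF frame per CDS interval in translation order."""
    phases = []
    cum = 0
    for length in exon_lengths:
        phases.append((3 - cum % 3) % 3)
        cum += length
    return phases


def simulate_world(config: SimConfig) -> SimWorld:
    """Build a complete world; deterministic given ``config.seed``."""
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    ref_names = [f"ref{i + 1}" for i in range(cfg.n_chromosomes)]
    target_names = list(_M_LABELS[: cfg.n_chromosomes])
    if cfg.n_chromosomes > len(_M_LABELS):
        target_names = [str(i + 1) for i in range(cfg.n_chromosomes)]

    # --- reference genome with genes written in ---------------------------
    genes_by_chrom = _plan_genes(cfg, rng, ref_names)
    ref_arrays: dict[str, np.ndarray] = {}
    for chrom in ref_names:
        arr = _random_dna(rng, cfg.chrom_length)
        for gene in genes_by_chrom[chrom]:
            offset = 0
            for s, e in gene.exons:
                arr[s:e] = np.frombuffer(
                    gene.cds_seq[offset : offset + (e - s)].encode(), dtype=np.uint8
                )
                offset += e - s
        ref_arrays[chrom] = arr
    reference = [SeqRecord(c, ref_arrays[c].tobytes().decode(),
                           f"seed={cfg.seed}") for c in ref_names]
    genes = [g for c in ref_names for g in genes_by_chrom[c]]

    # --- synteny blocks: split each ref chromosome intergenically ---------
    blocks_raw: list[dict] = []
    for chrom in ref_names:
        chrom_genes = genes_by_chrom[chrom]
        n_blocks = cfg.blocks_per_chromosome
        bounds = [0]
        for b in range(1, n_blocks):
            want = round(cfg.chrom_length * b / n_blocks)
            # snap to the nearest intergenic midpoint
            gaps = []
            prev_end = 0
            for g in chrom_genes:
                gaps.append(((prev_end + g.exons[0][0]) // 2, prev_end, g.exons[0][0]))
                prev_end = g.exons[-1][1]
            gaps.append(((prev_end + cfg.chrom_length) // 2, prev_end, cfg.chrom_length))
            usable = [mid for mid, lo, hi in gaps if hi - lo > 2000 and bounds[-1] < mid]
            if not usable:
                raise ConfigError("no intergenic space for a block boundary: infeasible config")
            bounds.append(min(usable, key=lambda m: abs(m - want)))
        bounds.append(cfg.chrom_length)
        for i, (lo, hi) in enumerate(zip(bounds, bounds[1:])):
            blocks_raw.append({"ref_chrom": chrom, "ref_start": lo, "ref_end": hi})

    # --- assign blocks to target chromosomes, orient, mutate --------------
    order = rng.permutation(len(blocks_raw))
    per_target: dict[str, list[dict]] = {c: [] for c in target_names}
    for rank, bidx in enumerate(order):
        per_target[target_names[rank % cfg.n_chromosomes]].append(blocks_raw[bidx])

    synteny: list[SyntenyBlock] = []
    target_seqs: dict[str, str] = {}
    for tchrom in target_names:
        pieces = []
        offset = 0
        for border, block in enumerate(per_target[tchrom], 1):
            orient = "+" if rng.random() < 0.5 else "-"
            lo, hi = block["ref_start"], block["ref_end"]
            ref_arr = ref_arrays[block["ref_chrom"]][lo:hi]
            mut = _mutate_block(ref_arr, cfg.substitution_rate, rng)
            in_block = [
                g for g in genes_by_chrom[block["ref_chrom"]]
                if lo <= g.exons[0][0] and g.exons[-1][1] <= hi
            ]
            for g in in_block:
                _repair_cds(mut, ref_arr, [(s - lo, e - lo) for s, e in g.exons])
            block_len = hi - lo
            block_seq = mut.tobytes().decode()
            if orient == "-":
                block_seq = revcomp(block_seq)
            for g in in_block:
                g.target_chrom = tchrom
                if orient == "+":
                    g.target_exons = [(offset + s - lo, offset + e - lo) for s, e in g.exons]
                    g.target_strand = "+"
                else:
                    g.target_exons = [
                        (offset + block_len - (e - lo), offset + block_len - (s - lo))
                        for s, e in reversed(g.exons)
                    ]
                    g.target_strand = "-"
            synteny.append(
                SyntenyBlock(block["ref_chrom"], lo + 1, hi, tchrom, orient, border)
            )
            pieces.append(block_seq)
            offset += block_len
        target_seqs[tchrom] = "".join(pieces)
    target_chromosomes = [SeqRecord(c, target_seqs[c], f"seed={cfg.seed}")
                          for c in target_names]

    # --- optional intergenic indels (stress mode) -------------------------
    if cfg.indel_rate > 0:
        for tchrom in target_names:
            seq = target_seqs[tchrom]
            gene_spans = sorted(
                (g.target_exons[0][0], g.target_exons[-1][1])
                for g in genes if g.target_chrom == tchrom
            )
            out = []
            cursor = 0
            for span_lo, span_hi in gene_spans + [(len(seq), len(seq))]:
                inter = seq[cursor:span_lo]
                keep = np.nonzero(np.random.default_rng(
                    cfg.seed ^ hash((tchrom, cursor)) & 0x7FFFFFFF
                ).random(len(inter)) >= cfg.indel_rate)[0]
                out.append("".join(inter[i] for i in keep))
                out.append(seq[span_lo:span_hi])
                cursor = span_hi
            # NOTE: stress mode invalidates downstream gene coordinates;
            # it exists to exercise the mappers, not the truth tables.
            target_seqs[tchrom] = "".join(out)

    # --- fragmentation at intergenic sites --------------------------------
    total_len = sum(len(target_seqs[c]) for c in target_names)
    n_fragments = cfg.n_scaffold_fragments + cfg.n_chimeras
    frag_counts = {
        c: max(1, round(n_fragments * len(target_seqs[c]) / total_len))
        for c in target_names
    }
    while sum(frag_counts.values()) != n_fragments:
        key = max(frag_counts) if sum(frag_counts.values()) > n_fragments else min(frag_counts)
        frag_counts[key] += -1 if sum(frag_counts.values()) > n_fragments else 1

    fragments: list[dict] = []  # chrom, start, end (0-based half-open)
    for tchrom in target_names:
        length = len(target_seqs[tchrom])
        gene_spans = sorted(
            (g.target_exons[0][0], g.target_exons[-1][1])
            for g in genes if g.target_chrom == tchrom
        )
        allowed: list[tuple[int, int]] = []  # intergenic cut windows
        prev = 0
        margin = 500
        for lo, hi in gene_spans + [(length, length)]:
            if lo - prev > 2 * margin:
                allowed.append((prev + margin, lo - margin))
            prev = max(prev, hi)
        k = frag_counts[tchrom] - 1
        cuts: list[int] = []
        for i in range(1, k + 1):
            want = round(length * i / (k + 1)) + int(rng.integers(-5000, 5000))
            candidates = [
                (max(lo, min(hi - 1, want)), lo, hi) for lo, hi in allowed
            ]
            snap = min(candidates, key=lambda t: abs(t[0] - want))[0]
            if snap not in cuts:
                cuts.append(snap)
        cuts = sorted(set(cuts))
        bounds = [0, *cuts, length]
        for lo, hi in zip(bounds, bounds[1:]):
            fragments.append({"chrom": tchrom, "start": lo, "end": hi})

    # --- chimeras and scaffold emission -----------------------------------
    def frag_genes(frag: dict) -> list[RefGene]:
        return [
            g for g in genes
            if g.target_chrom == frag["chrom"]
            and frag["start"] <= g.target_exons[0][0]
            and g.target_exons[-1][1] <= frag["end"]
        ]

    frag_idx = list(range(len(fragments)))
    rich = [i for i in frag_idx if len(frag_genes(fragments[i])) >= 2]
    chimera_pairs: list[tuple[int, int]] = []
    used: set[int] = set()
    shuffled = list(rng.permutation(rich))
    for i in shuffled:
        if len(chimera_pairs) == cfg.n_chimeras:
            break
        if i in used:
            continue
        partner = next(
            (j for j in shuffled
             if j not in used and j != i
             and fragments[j]["chrom"] != fragments[i]["chrom"]),
            None,
        )
        if partner is None:
            continue
        used.update((i, int(partner)))
        chimera_pairs.append((int(i), int(partner)))
    if len(chimera_pairs) < cfg.n_chimeras:
        raise ConfigError(
            "could not plant the requested chimeras (too few gene-rich fragments "
            "on distinct chromosomes): infeasible config"
        )

    emit_order = [i for i in frag_idx if i not in used]
    rng.shuffle(emit_order)

    scaffolds: list[SeqRecord] = []
    part_rows: list[dict] = []
    junction_rows: list[dict] = []
    sid = 0

    def next_id() -> str:
        nonlocal sid
        sid += 1
        return f"s{sid:04d}"

    for a, b in chimera_pairs:
        fa, fb = fragments[a], fragments[b]
        seq_a = target_seqs[fa["chrom"]][fa["start"] : fa["end"]]
        seq_b = target_seqs[fb["chrom"]][fb["start"] : fb["end"]]
        scaffold_id = next_id()
        gap = "N" * cfg.chimera_gap_len
        scaffolds.append(SeqRecord(scaffold_id, seq_a + gap + seq_b,
                                   f"seed={cfg.seed} planted_chimera"))
        part_rows.append(dict(scaffold_id=scaffold_id, part_index=1,
                              chrom=fa["chrom"], chrom_start=fa["start"],
                              chrom_end=fa["end"], orientation="+",
                              scaffold_start=0, scaffold_end=len(seq_a)))
        part_rows.append(dict(scaffold_id=scaffold_id, part_index=2,
                              chrom=fb["chrom"], chrom_start=fb["start"],
                              chrom_end=fb["end"], orientation="+",
                              scaffold_start=len(seq_a) + cfg.chimera_gap_len,
                              scaffold_end=len(seq_a) + cfg.chimera_gap_len + len(seq_b)))
        junction_rows.append(dict(scaffold_id=scaffold_id,
                                  gap_start=len(seq_a),
                                  gap_end=len(seq_a) + cfg.chimera_gap_len,
                                  left_chrom=fa["chrom"], right_chrom=fb["chrom"]))

    for i in emit_order:
        frag = fragments[i]
        seq = target_seqs[frag["chrom"]][frag["start"] : frag["end"]]
        orient = "+" if rng.random() < 0.5 else "-"
        if orient == "-":
            seq = revcomp(seq)
        scaffold_id = next_id()
        scaffolds.append(SeqRecord(scaffold_id, seq, f"seed={cfg.seed}"))
        part_rows.append(dict(scaffold_id=scaffold_id, part_index=1,
                              chrom=frag["chrom"], chrom_start=frag["start"],
                              chrom_end=frag["end"], orientation=orient,
                              scaffold_start=0, scaffold_end=len(seq)))

    parts_df = pd.DataFrame(part_rows)

    # --- planted within-scaffold inversions (reported, never broken) ------
    inversion_rows: list[dict] = []
    if cfg.n_inversions > 0:
        forward_parts = parts_df[(parts_df.orientation == "+")
                                 & (parts_df.part_index == 1)]
        candidates = []
        scaffold_by_id = {r.id: r for r in scaffolds}
        for _, row in forward_parts.iterrows():
            for g in genes:
                if (g.target_chrom == row.chrom
                        and row.chrom_start <= g.target_exons[0][0]
                        and g.target_exons[-1][1] <= row.chrom_end
                        and len(g.target_exons) >= 3):
                    candidates.append((row.scaffold_id, row.chrom_start, g))
        rng.shuffle(candidates)
        seen_scaffolds: set[str] = set()
        for scaffold_id, chrom_start, g in candidates:
            if len(inversion_rows) == cfg.n_inversions:
                break
            if scaffold_id in seen_scaffolds:
                continue
            seen_scaffolds.add(scaffold_id)
            # invert from the gene's start through its middle exon
            mid = len(g.target_exons) // 2
            lo = g.target_exons[0][0] - chrom_start
            hi = g.target_exons[mid][1] - chrom_start
            rec = scaffold_by_id[scaffold_id]
            rec.sequence = rec.sequence[:lo] + revcomp(rec.sequence[lo:hi]) + rec.sequence[hi:]
            inversion_rows.append(dict(scaffold_id=scaffold_id, start=lo, end=hi,
                                       gene_id=g.gene_id))
        if len(inversion_rows) < cfg.n_inversions:
            raise ConfigError("not enough eligible genes for requested inversions")

    # --- reference exon records, metadata, proteome -----------------------
    exon_records: list[SeqRecord] = []
    exon_metadata: dict[str, ExonMeta] = {}
    ref_proteome: list[SeqRecord] = []
    ortholog_pairs: list[tuple[str, str]] = []
    for g in genes:
        chrom_seq = ref_arrays[g.ref_chrom]
        for i, (s, e) in enumerate(g.exons, 1):
            exon_id = f"{g.gene_id}.e{i}"
            exon_records.append(SeqRecord(exon_id, chrom_seq[s:e].tobytes().decode(),
                                          f"seed={cfg.seed}"))
            exon_metadata[exon_id] = ExonMeta(exon_id, g.gene_id, i,
                                              g.ref_chrom, s + 1, e)
        protein_id = f"{g.gene_id}.ref_protein"
        ref_proteome.append(SeqRecord(protein_id, _translate_simple(g.cds_seq),
                                      f"seed={cfg.seed}"))
        ortholog_pairs.append((g.gene_id, protein_id))

    # --- true gene models in scaffold coordinates -------------------------
    true_models: list[GeneModel] = []
    for _, part in parts_df.iterrows():
        in_part = [
            g for g in genes
            if g.target_chrom == part.chrom
            and part.chrom_start <= g.target_exons[0][0]
            and g.target_exons[-1][1] <= part.chrom_end
        ]
        scaffold_len = len(next(s for s in scaffolds if s.id == part.scaffold_id).sequence)
        for g in in_part:
            if part.orientation == "+":
                exons0 = [
                    (part.scaffold_start + (s - part.chrom_start),
                     part.scaffold_start + (e - part.chrom_start))
                    for s, e in g.target_exons
                ]
                strand = g.target_strand
            else:
                part_len = part.chrom_end - part.chrom_start
                exons0 = sorted(
                    (part.scaffold_start + part_len - (e - part.chrom_start),
                     part.scaffold_start + part_len - (s - part.chrom_start))
                    for s, e in g.target_exons
                )
                strand = "-" if g.target_strand == "+" else "+"
            exons1 = [(s + 1, e) for s, e in exons0]
            translation_order = exons1 if strand == "+" else list(reversed(exons1))
            phases = _phases([e - s + 1 for s, e in translation_order])
            cds = [
                (s, e, ph) for (s, e), ph in zip(translation_order, phases)
            ]
            cds.sort()
            true_models.append(
                GeneModel(
                    transcript_id=f"{g.gene_id}.t1", gene_id=g.gene_id,
                    gene_name=g.gene_id.upper(),
                    gene_description=f"simulated gene {g.gene_id}",
                    chrom=part.scaffold_id, strand=strand,
                    exons=exons1, cds=cds,
                )
            )

    # --- markers ----------------------------------------------------------
    marker_positions: dict[str, list[tuple[int, str]]] = {c: [] for c in target_names}
    mlen = cfg.marker_length
    for _, part in parts_df.iterrows():
        span = part.chrom_end - part.chrom_start
        n_extra = int(cfg.marker_density * span / 1e6)
        count = max(cfg.marker_min_per_scaffold, n_extra)
        lo = part.chrom_start + 200
        hi = part.chrom_end - 200 - mlen
        if hi <= lo:
            lo, hi = part.chrom_start, max(part.chrom_start + 1, part.chrom_end - mlen)
        pos = sorted(set(int(p) for p in rng.integers(lo, hi, count)))
        for p in pos:
            marker_positions[part.chrom].append((p, part.scaffold_id))
    markers: list[Marker] = []
    for tchrom in target_names:
        entries = sorted(set(marker_positions[tchrom]))
        for rank, (p, _sid) in enumerate(entries, 1):
            markers.append(
                Marker(f"m_{tchrom}_{rank:04d}", tchrom, rank,
                       target_seqs[tchrom][p : p + mlen])
            )

    truth = TruthSet(
        scaffold_parts=parts_df,
        junctions=pd.DataFrame(junction_rows,
                               columns=["scaffold_id", "gap_start", "gap_end",
                                        "left_chrom", "right_chrom"]),
        inversions=pd.DataFrame(inversion_rows,
                                columns=["scaffold_id", "start", "end", "gene_id"]),
        gene_chrom={g.gene_id: g.target_chrom for g in genes},
    )
    world = SimWorld(
        config=cfg,
        reference=reference,
        target_chromosomes=target_chromosomes,
        scaffolds=scaffolds,
        genes=genes,
        exon_records=exon_records,
        exon_metadata=exon_metadata,
        markers=markers,
        synteny=synteny,
        ref_proteome=ref_proteome,
        ortholog_pairs=ortholog_pairs,
        true_models=true_models,
        truth=truth,
    )
    return world


def transcript_records(world: SimWorld) -> list[SeqRecord]:
    """Spliced target coding sequences, one per gene (read-source and
    contamination-filter transcript set)."""
    out = []
    seq_by_chrom = {r.id: r.sequence for r in world.target_chromosomes}
    for g in world.genes:
        chrom_seq = seq_by_chrom[g.target_chrom]
        spliced = "".join(chrom_seq[s:e] for s, e in g.target_exons)
        if g.target_strand == "-":
            spliced = revcomp(spliced)
        out.append(SeqRecord(f"{g.gene_id}.t1", spliced, f"seed={world.config.seed}"))
    return out


def simulate_reads(
    world: SimWorld,
    n_reads: int | None = None,
    read_length: int | None = None,
    contamination_fraction: float | None = None,
    paired: bool = False,
    seed: int | None = None,
) -> tuple[list[SeqRecord], list[SeqRecord], pd.DataFrame]:
    """Error-free reads from transcripts, with a contaminating fraction
    drawn from intergenic genomic sequence.

    Returns (mate1 reads, mate2 reads (empty when single-end), truth table
    with read core id and origin 'transcriptomic'/'genomic').
    """
    cfg = world.config
    n_reads = n_reads if n_reads is not None else cfg.n_reads
    read_length = read_length if read_length is not None else cfg.read_length
    frac = (contamination_fraction if contamination_fraction is not None
            else cfg.contamination_fraction)
    rng = np.random.default_rng(cfg.seed + 7919 if seed is None else seed)

    transcripts = [t for t in transcript_records(world)
                   if len(t.sequence) >= (2 * read_length + 50 if paired else read_length)]
    if not transcripts:
        raise ConfigError("read_length exceeds every transcript length")

    intergenic: list[str] = []
    for rec in world.target_chromosomes:
        spans = sorted((g.target_exons[0][0], g.target_exons[-1][1])
                       for g in world.genes if g.target_chrom == rec.id)
        prev = 0
        for lo, hi in spans + [(len(rec.sequence), len(rec.sequence))]:
            if lo - prev >= 2 * read_length + 50:
                intergenic.append(rec.sequence[prev:lo])
            prev = max(prev, hi)

    mate1, mate2, rows = [], [], []
    insert = 2 * read_length + 50
    for i in range(n_reads):
        genomic = bool(rng.random() < frac)
        pool = intergenic if genomic and intergenic else [t.sequence for t in transcripts]
        src = pool[int(rng.integers(0, len(pool)))]
        span = insert if paired else read_length
        start = int(rng.integers(0, max(1, len(src) - span + 1)))
        core = f"r{i:06d}"
        origin = "genomic" if genomic and intergenic else "transcriptomic"
        rows.append({"read_id": core, "origin": origin})
        if paired:
            frag = src[start : start + insert]
            mate1.append(SeqRecord(f"{core}/1", frag[:read_length]))
            mate2.append(SeqRecord(f"{core}/2", revcomp(frag[-read_length:])))
        else:
            mate1.append(SeqRecord(core, src[start : start + read_length]))
    return mate1, mate2, pd.DataFrame(rows)


def write_world(world: SimWorld, outdir: str | Path) -> None:
    """Emit the world in the exact formats the pipeline consumes, plus
    truth tables under ``truth/``."""
    outdir = Path(outdir)
    (outdir / "truth").mkdir(parents=True, exist_ok=True)
    write_fasta(world.scaffolds, outdir / "scaffolds.fasta")
    write_fasta(world.reference, outdir / "reference.fasta")
    write_fasta(world.exon_records, outdir / "ref_exons.fasta")
    write_fasta(world.ref_proteome, outdir / "ref_proteome.fasta", line_width=80)
    write_exon_metadata(world.exon_metadata.values(), outdir / "exon_metadata.tsv")
    write_markers(world.markers, outdir / "markers.tsv")
    write_synteny(world.synteny, outdir / "synteny.tsv")
    write_gtf(world.true_models, outdir / "true_models.gtf")
    pd.DataFrame(world.ortholog_pairs,
                 columns=["gene_id", "protein_id"]).to_csv(
        outdir / "ortholog_pairs.tsv", sep="\t", index=False)
    world.truth.scaffold_parts.to_csv(outdir / "truth" / "scaffold_parts.tsv",
                                      sep="\t", index=False)
    world.truth.junctions.to_csv(outdir / "truth" / "junctions.tsv", sep="\t", index=False)
    world.truth.inversions.to_csv(outdir / "truth" / "inversions.tsv", sep="\t", index=False)
    pd.DataFrame(sorted(world.truth.gene_chrom.items()),
                 columns=["gene_id", "chrom"]).to_csv(
        outdir / "truth" / "gene_chrom.tsv", sep="\t", index=False)
    with open(outdir / "config.json", "w") as fh:
        json.dump(asdict(world.config), fh, indent=2, default=list)
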