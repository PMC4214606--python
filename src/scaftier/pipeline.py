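"""End-to-end orchestration: curation -> placement -> chromosome build,
plus truth-based evaluation helpers for simulated worlds.

The functions here wire the per-module operations together in the order a
production run uses them: map reference exons onto the draft scaffolds,
apply the gene-contiguity rule, break chimeric scaffolds at assembly gaps,
re-map onto the curated scaffold set, place scaffolds on chromosomes by
the three evidence tiers, and emit AGP + chromosome FASTA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import kendalltau

from . import contiguity as ct
from . import placement as pl
from .mapping import (ExonEvidence, ExonMeta, KmerIndex, build_index, map_exons,
                      map_sequence)
from .seqio import SeqRecord
from .tables import Marker, SyntenyBlock, locate_in_blocks


def gene_chromosome_votes(
    evidence: Sequence[ExonEvidence], blocks: Sequence[SyntenyBlock]
) -> dict[str, str]:
    """Each gene's target-chromosome vote: locate its exons' reference
    positions in the synteny blocks and take the majority chromosome."""
    votes: dict[str, list[str]] = {}
    for ev in evidence:
        block = locate_in_blocks(list(blocks), ev.ref_chrom, ev.ref_pos)
        if block is not None:
            votes.setdefault(ev.gene_id, []).append(block.target_chrom)
    out = {}
    for gene_id, chroms in votes.items():
        winner, _ = pl._majority(chroms)
        out[gene_id] = str(winner)
    return out


@dataclass
class CurationResult:
    scaffolds: list[SeqRecord]
    violations: list[ct.Violation]
    breakpoints: list[ct.Breakpoint]
    provenance: list[dict]
    chimeras: dict[str, list[ct.GeneCluster]] = field(default_factory=dict)


def curate_scaffolds(
    scaffolds: Sequence[SeqRecord],
    exon_records: Sequence[SeqRecord],
    exon_metadata: dict[str, ExonMeta],
    blocks: Sequence[SyntenyBlock],
    k: int = 15,
    stride: int = 2,
    min_identity: float = 95.0,
) -> CurationResult:
    """Contiguity-rule curation: detect violations and chimeric scaffolds
    from ortholog exon evidence, and break chimeras at assembly gaps."""
    index = build_index(scaffolds, k=k, stride=stride)
    evidence = map_exons(exon_records, exon_metadata, index, min_identity=min_identity)
    violations = ct.detect_violations(evidence)
    votes = gene_chromosome_votes(evidence, blocks)
    chimeras, chimera_violations = ct.detect_chimeras(evidence, votes)
    breakpoints = ct.propose_breakpoints(chimeras, {s.id: s for s in scaffolds})
    new_scaffolds, provenance = ct.apply_breaks(scaffolds, breakpoints)
    return CurationResult(
        scaffolds=new_scaffolds,
        violations=violations + chimera_violations,
        breakpoints=breakpoints,
        provenance=provenance,
        chimeras=chimeras,
    )


@dataclass
class PlacementResult:
    table: pd.DataFrame
    tier1: list[pl.PlacementDecision]
    tier2: list[pl.PlacementDecision]
    tier3: list[pl.PlacementDecision]
    evidence: list[ExonEvidence]


def place_scaffolds(
    scaffolds: Sequence[SeqRecord],
    exon_records: Sequence[SeqRecord],
    exon_metadata: dict[str, ExonMeta],
    markers: Sequence[Marker],
    blocks: Sequence[SyntenyBlock],
    reference: Sequence[SeqRecord],
    tiling_segment_bp: int = 10000,
    k: int = 15,
    stride: int = 2,
    min_identity: float = 95.0,
    override: pd.DataFrame | None = None,
) -> PlacementResult:
    """Three-tier placement of (curated) scaffolds onto chromosomes."""
    index = build_index(scaffolds, k=k, stride=stride)
    evidence = map_exons(exon_records, exon_metadata, index, min_identity=min_identity)

    tier1 = pl.place_by_markers(scaffolds, markers, index=index,
                                min_identity=min_identity) if markers else []
    placed1 = {d.scaffold_id for d in tier1 if d.tier == pl.TIER_MARKER}
    conflicted1 = {d.scaffold_id for d in tier1 if d.tier == pl.TIER_UNPLACED}

    # enrich tier-1 decisions with synteny keys so tiers interleave
    ev_by_scaffold: dict[str, list[ExonEvidence]] = {}
    for ev in evidence:
        if ev.hit is not None:
            ev_by_scaffold.setdefault(ev.hit.target_id, []).append(ev)
    for dec in tier1:
        if dec.tier != pl.TIER_MARKER:
            continue
        evs = ev_by_scaffold.get(dec.scaffold_id, [])
        genes: dict[str, list[ExonEvidence]] = {}
        for ev in evs:
            genes.setdefault(ev.gene_id, []).append(ev)
        entries = [
            (g_evs[0].ref_chrom, int(np.median([e.ref_pos for e in g_evs])))
            for g_evs in genes.values()
        ]
        keyed = pl.synteny_key_for_genes(entries, blocks)
        if keyed is not None:
            chrom, synteny_key, _orient, _unanimous = keyed
            if chrom == dec.chrom:
                dec.synteny_key = synteny_key
            else:
                dec.conflicts.append(
                    f"synteny evidence favours {chrom}, markers say {dec.chrom}; markers kept"
                )

    remaining_ids = [s.id for s in scaffolds if s.id not in placed1 | conflicted1]
    tier2 = pl.place_by_synteny(remaining_ids, evidence, blocks)
    placed2 = {d.scaffold_id for d in tier2 if d.tier == pl.TIER_SYNTENY}

    still = [s for s in scaffolds if s.id not in placed1 | conflicted1 | placed2]
    tier3 = pl.place_by_tiling(still, reference, blocks, tiling_segment_bp,
                               min_identity=90.0) if still else []

    table = pl.merge_placements([tier1, tier2, tier3], [s.id for s in scaffolds],
                                override=override)
    return PlacementResult(table=table, tier1=tier1, tier2=tier2, tier3=tier3,
                           evidence=evidence)


def build_assembly(
    table: pd.DataFrame,
    scaffolds: Sequence[SeqRecord],
    gap_length: int = 100,
) -> tuple[list, list[SeqRecord], list[SeqRecord]]:
    """AGP rows, chromosome FASTA records and the unplaced scaffold set."""
    by_id = {s.id: s for s in scaffolds}
    lengths = {sid: len(rec.sequence) for sid, rec in by_id.items()}
    agp_rows = pl.build_agp(table, lengths, gap_length=gap_length)
    chroms = pl.build_chromosomes(agp_rows, by_id)
    unplaced_ids = table.loc[table["chrom"].isna(), "scaffold_id"]
    unplaced = [by_id[sid] for sid in unplaced_ids]
    return agp_rows, chroms, unplaced


# ---------------------------------------------------------------------------
# Truth-based evaluation (simulated worlds)
# ---------------------------------------------------------------------------

def _truth_units(truth_parts: pd.DataFrame, placed_ids: Sequence[str]) -> pd.DataFrame:
    """Match placed scaffold ids (possibly post-break parts '<id>.<i>')
    to truth rows; returns one row per matched unit with true chromosome,
    start and orientation."""
    rows = []
    for sid in placed_ids:
        if "." in sid:
            parent, part = sid.rsplit(".", 1)
            match = truth_parts[(truth_parts.scaffold_id == parent)
                                & (truth_parts.part_index == int(part))]
        else:
            match = truth_parts[truth_parts.scaffold_id == sid]
            if len(match) > 1:  # unbroken chimera: no single truth
                continue
        if len(match) == 1:
            m = match.iloc[0]
            rows.append({"scaffold_id": sid, "true_chrom": m.chrom,
                         "true_start": m.chrom_start, "true_orientation": m.orientation})
    return pd.DataFrame(rows)


def evaluate_placement(table: pd.DataFrame, truth_parts: pd.DataFrame) -> dict:
    """Compare a chromosome table with simulator truth.

    Returns per-chromosome Kendall tau between recovered and true order,
    counts of orientation errors and wrong-chromosome placements, the
    fraction of placed scaffolds on their true chromosome, and the
    fraction of true adjacencies (consecutive units per chromosome)
    recovered as consecutive.
    """
    placed = table[table["chrom"].notna()].copy()
    matched = _truth_units(truth_parts, placed["scaffold_id"].tolist())
    merged = placed.merge(matched, on="scaffold_id", how="inner")

    correct = merged[merged["chrom"] == merged["true_chrom"]]
    chrom_accuracy = 100.0 * len(correct) / len(merged) if len(merged) else 0.0

    taus = {}
    orientation_errors = 0
    recovered_adjacencies = 0
    true_adjacencies = 0
    for chrom, group in correct.groupby("true_chrom"):
        group = group.sort_values("position")
        if len(group) >= 2:
            tau, _ = kendalltau(group["position"], group["true_start"])
            taus[str(chrom)] = float(round(tau, 12))  # shed float noise at exact concordance
        orientation_errors += int((group["orientation"] != group["true_orientation"]).sum())
        true_order = group.sort_values("true_start")["scaffold_id"].tolist()
        rec_order = group["scaffold_id"].tolist()
        rec_pairs = set(zip(rec_order, rec_order[1:]))
        for pair in zip(true_order, true_order[1:]):
            true_adjacencies += 1
            if pair in rec_pairs:
                recovered_adjacencies += 1
    return {
        "per_chrom_tau": taus,
        "min_tau": min(taus.values()) if taus else float("nan"),
        "orientation_errors": orientation_errors,
        "chrom_accuracy_pct": chrom_accuracy,
        "adjacency_recovery_pct": (
            100.0 * recovered_adjacencies / true_adjacencies if true_adjacencies else 0.0
        ),
        "n_evaluated": len(merged),
    }


def evaluate_chimera_detection(
    chimeras: dict[str, list[ct.GeneCluster]],
    breakpoints: Sequence[ct.Breakpoint],
    truth_junctions: pd.DataFrame,
) -> dict:
    """Recall/false positives of chimera flagging and whether each proposed
    break falls inside its planted junction gap."""
    planted = set(truth_junctions["scaffold_id"]) if len(truth_junctions) else set()
    flagged = set(chimeras)
    breaks_in_gap = 0
    for bp in breakpoints:
        rows = truth_junctions[truth_junctions.scaffold_id == bp.scaffold_id]
        if any(r.gap_start <= bp.coordinate <= r.gap_end for r in rows.itertuples()):
            breaks_in_gap += 1
    return {
        "n_planted": len(planted),
        "n_detected": len(planted & flagged),
        "false_positives": len(flagged - planted),
        "n_breaks": len(breakpoints),
        "breaks_in_gap": breaks_in_gap,
    }
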