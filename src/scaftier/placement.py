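"""Tiered scaffold-to-chromosome placement and chromosome building.

Three evidence tiers place curated scaffolds on chromosomes:

1. ordered mapping markers (e.g. radiation-hybrid maps) — chromosome,
   rank along it, and orientation from the marker order/position trend;
2. ortholog gene evidence located inside published synteny blocks —
   chromosome and block from the block table, within-block position from
   reference gene coordinates;
3. fixed-size tiling segments of the reference chromosomes aligned to the
   still-unplaced scaffolds — a coarse synteny vote for gene-poor regions.

A tier never re-places a scaffold claimed by an earlier tier.  The merge
orders each chromosome by the marker backbone where markers exist and
inserts synteny/tiling placements by their reference-coordinate keys; an
override table (manual curation) is applied last and wins.
"""

from __future__ import annotations

import bisect
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .agp import AgpRow, validate_agp
from .errors import InputError
from .mapping import AlnHit, ExonEvidence, KmerIndex, best_hit, map_sequence
from .seqio import SeqRecord, revcomp
from .tables import Marker, SyntenyBlock, locate_in_blocks

TIER_MARKER = 1
TIER_SYNTENY = 2
TIER_TILING = 3
TIER_UNPLACED = 0


@dataclass
class PlacementDecision:
    scaffold_id: str
    chrom: str | None  # None <=> unplaced
    orientation: str = "+"
    tier: int = TIER_UNPLACED
    # ordering keys; either may be missing depending on the evidence tier
    marker_key: float | None = None  # median marker order_index
    synteny_key: tuple[int, float] | None = None  # (block_order, signed ref pos)
    conflicts: list[str] = field(default_factory=list)


@dataclass
class TilingSegment:
    ref_chrom: str
    segment_index: int
    ref_start: int  # 0-based offset on the reference chromosome
    hit: AlnHit | None = None


def _orientation_from_trend(orders: Sequence[int], positions: Sequence[int],
                            strands: Sequence[str]) -> tuple[str, str | None]:
    """Orientation of a scaffold from its markers.

    Sign of the correlation between marker rank and scaffold position; a
    single marker (or a flat trend) falls back to the majority hit strand.
    Returns (orientation, conflict note or None).
    """
    if len(orders) >= 2:
        trend = np.corrcoef(np.asarray(orders, float), np.asarray(positions, float))[0, 1]
        if np.isfinite(trend) and trend != 0:
            return ("+" if trend > 0 else "-"), None
    counts = Counter(strands)
    if counts["+"] == counts["-"]:
        return "+", "orientation tie (50/50 strand evidence), defaulted to +"
    return counts.most_common(1)[0][0], None


def place_by_markers(
    scaffolds: Sequence[SeqRecord],
    markers: Sequence[Marker],
    index: KmerIndex | None = None,
    marker_hits: Sequence[AlnHit] | None = None,
    min_identity: float = 95.0,
) -> list[PlacementDecision]:
    """Tier-1 placement from ordered markers.

    Markers are located on scaffolds (internal mapper or a precomputed hit
    table); each scaffold inherits its markers' chromosome, a rank equal to
    the median marker order, and an orientation from the rank/position
    trend.  Scaffolds whose markers disagree on the chromosome are left
    unplaced with a recorded conflict (a curation case).
    """
    marker_by_id = {m.marker_id: m for m in markers}
    hits_by_marker: dict[str, AlnHit | None] = {}
    if marker_hits is not None:
        grouped: dict[str, list[AlnHit]] = defaultdict(list)
        for h in marker_hits:
            grouped[h.query_id].append(h)
        for mid, hs in grouped.items():
            hits_by_marker[mid] = best_hit(hs)
    else:
        if index is None:
            raise InputError("place_by_markers needs an index or a marker hit table")
        for m in markers:
            if m.sequence is None:
                continue
            hits_by_marker[m.marker_id] = best_hit(
                map_sequence(SeqRecord(m.marker_id, m.sequence), index, min_identity)
            )

    per_scaffold: dict[str, list[tuple[Marker, AlnHit]]] = defaultdict(list)
    for mid, hit in hits_by_marker.items():
        if hit is not None and mid in marker_by_id:
            per_scaffold[hit.target_id].append((marker_by_id[mid], hit))

    decisions = []
    for scaffold_id, pairs in sorted(per_scaffold.items()):
        chroms = {m.chrom for m, _ in pairs}
        if len(chroms) > 1:
            decisions.append(
                PlacementDecision(
                    scaffold_id,
                    chrom=None,
                    tier=TIER_UNPLACED,
                    conflicts=[f"markers disagree on chromosome: {sorted(chroms)}"],
                )
            )
            continue
        pairs.sort(key=lambda p: p[1].t_lo)
        orders = [m.order_index for m, _ in pairs]
        positions = [h.t_lo for _, h in pairs]
        strands = [h.strand for _, h in pairs]
        orientation, note = _orientation_from_trend(orders, positions, strands)
        dec = PlacementDecision(
            scaffold_id,
            chrom=chroms.pop(),
            orientation=orientation,
            tier=TIER_MARKER,
            marker_key=float(np.median(orders)),
        )
        if note:
            dec.conflicts.append(note)
        decisions.append(dec)
    return decisions


def _majority(items: Iterable) -> tuple[object, bool]:
    """(winner, unanimous) of a non-empty vote; deterministic tie-break by
    count then string order."""
    counts = Counter(items)
    winner = sorted(counts.items(), key=lambda kv: (-kv[1], str(kv[0])))[0][0]
    return winner, len(counts) == 1


def synteny_key_for_genes(
    gene_entries: Sequence[tuple[str, int]], blocks: Sequence[SyntenyBlock]
) -> tuple[str, tuple[int, float], str, bool] | None:
    """Locate genes (ref_chrom, ref_pos) in blocks and derive the scaffold's
    (target_chrom, (block_order, signed pos), block_orientation, unanimous).

    The within-block position is the median reference position of the genes
    in the majority block, negated when the block is inverted on the target
    (so that larger keys always mean further along the target chromosome).
    """
    located = []
    for ref_chrom, ref_pos in gene_entries:
        block = locate_in_blocks(list(blocks), ref_chrom, ref_pos)
        if block is not None:
            located.append((block, ref_pos))
    if not located:
        return None
    chrom, chrom_unanimous = _majority(b.target_chrom for b, _ in located)
    in_chrom = [(b, p) for b, p in located if b.target_chrom == chrom]
    block_order, block_unanimous = _majority(b.block_order for b, _ in in_chrom)
    in_block = [(b, p) for b, p in in_chrom if b.block_order == block_order]
    block_orient = in_block[0][0].block_orientation
    med = float(np.median([p for _, p in in_block]))
    pos_key = med if block_orient == "+" else -med
    return str(chrom), (int(block_order), pos_key), block_orient, chrom_unanimous and block_unanimous


def place_by_synteny(
    unplaced: Sequence[str],
    evidence: Sequence[ExonEvidence],
    blocks: Sequence[SyntenyBlock],
) -> list[PlacementDecision]:
    """Tier-2 placement: ortholog genes located inside synteny blocks.

    Each placed gene votes with its block; the scaffold follows the
    majority chromosome/block.  Orientation is the block orientation times
    the majority exon-hit strand (an inverted block carried by a forward
    scaffold shows minus-strand exon hits, and the two flips cancel).
    """
    unplaced_set = set(unplaced)
    per_scaffold: dict[str, list[ExonEvidence]] = defaultdict(list)
    for ev in evidence:
        if ev.hit is not None and ev.hit.target_id in unplaced_set:
            per_scaffold[ev.hit.target_id].append(ev)

    decisions = []
    for scaffold_id, evs in sorted(per_scaffold.items()):
        # one vote per gene: representative ref position and majority strand
        genes: dict[str, list[ExonEvidence]] = defaultdict(list)
        for ev in evs:
            genes[ev.gene_id].append(ev)
        gene_entries = []
        strands = []
        for gid, g_evs in genes.items():
            gene_entries.append((g_evs[0].ref_chrom, int(np.median([e.ref_pos for e in g_evs]))))
            strand, _ = _majority(e.hit.strand for e in g_evs)
            strands.append(strand)
        keyed = synteny_key_for_genes(gene_entries, blocks)
        if keyed is None:
            continue
        chrom, synteny_key, block_orient, unanimous = keyed
        hit_strand, _ = _majority(strands)
        orientation = "+" if block_orient == hit_strand else "-"
        dec = PlacementDecision(
            scaffold_id,
            chrom=chrom,
            orientation=orientation,
            tier=TIER_SYNTENY,
            synteny_key=synteny_key,
        )
        if not unanimous:
            dec.conflicts.append("gene evidence spans multiple blocks; placed by majority")
        decisions.append(dec)
    return decisions


def tile_reference(reference: Sequence[SeqRecord], tiling_segment_bp: int = 10000) -> list[SeqRecord]:
    """Cut reference chromosomes into consecutive fixed-size segments.

    Segment ids encode origin as ``<chrom>|seg<i>``; the terminal segment
    may be shorter but still votes.
    """
    segments = []
    for rec in reference:
        for i, off in enumerate(range(0, len(rec.sequence), tiling_segment_bp)):
            seg = rec.sequence[off : off + tiling_segment_bp]
            segments.append(SeqRecord(f"{rec.id}|seg{i}", seg))
    return segments


def place_by_tiling(
    unplaced: Sequence[SeqRecord],
    reference: Sequence[SeqRecord],
    blocks: Sequence[SyntenyBlock],
    tiling_segment_bp: int = 10000,
    min_identity: float = 90.0,
    index: KmerIndex | None = None,
) -> list[PlacementDecision]:
    """Tier-3 placement: reference-chromosome tiling segments vote.

    Each segment's best hit on an unplaced scaffold casts a vote
    (ref_chrom, segment_index, strand); a scaffold is placed at the synteny
    position of its median voting segment.  Scaffolds with no votes remain
    unplaced (tier 0).
    """
    from .mapping import build_index  # local import to avoid cycle at module load

    if index is None:
        index = build_index(unplaced)
    votes: dict[str, list[tuple[str, int, str]]] = defaultdict(list)
    for seg in tile_reference(reference, tiling_segment_bp):
        hit = best_hit(map_sequence(seg, index, min_identity, min_cov=0.5))
        if hit is None:
            continue
        chrom, seg_idx = seg.id.rsplit("|seg", 1)
        votes[hit.target_id].append((chrom, int(seg_idx), hit.strand))

    decisions = []
    placed_ids = set()
    for scaffold_id, vts in sorted(votes.items()):
        ref_chrom, _ = _majority(v[0] for v in vts)
        in_chrom = [v for v in vts if v[0] == ref_chrom]
        med_seg = float(np.median([v[1] for v in in_chrom]))
        ref_pos = int((med_seg + 0.5) * tiling_segment_bp)
        block = locate_in_blocks(list(blocks), str(ref_chrom), ref_pos)
        if block is None:
            # clamp into the nearest block of that reference chromosome
            cands = [b for b in blocks if b.ref_chrom == ref_chrom]
            if not cands:
                continue
            block = min(cands, key=lambda b: min(abs(ref_pos - b.ref_start), abs(ref_pos - b.ref_end)))
            ref_pos = min(max(ref_pos, block.ref_start), block.ref_end)
        strand, _ = _majority(v[2] for v in in_chrom)
        orientation = "+" if block.block_orientation == strand else "-"
        pos_key = float(ref_pos) if block.block_orientation == "+" else -float(ref_pos)
        decisions.append(
            PlacementDecision(
                scaffold_id,
                chrom=block.target_chrom,
                orientation=orientation,
                tier=TIER_TILING,
                synteny_key=(block.block_order, pos_key),
            )
        )
        placed_ids.add(scaffold_id)
    for rec in unplaced:
        if rec.id not in placed_ids:
            decisions.append(PlacementDecision(rec.id, chrom=None, tier=TIER_UNPLACED))
    return decisions


def read_override(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"scaffold_id": str, "chrom": str,
                                              "position": int, "orientation": str})


def merge_placements(
    tier_lists: Sequence[Sequence[PlacementDecision]],
    all_scaffold_ids: Sequence[str],
    override: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Deterministic merge of the tier placements into one chromosome table.

    Earlier tiers win (a scaffold placed at tier t is never re-placed at a
    later tier).  Per chromosome, scaffolds carrying marker keys form an
    ordered backbone; scaffolds with only a synteny key are inserted by
    bisection among backbone members that carry both keys.  A manual
    override table (scaffold -> chrom, position, orientation) is applied
    last and wins.  Returns a table with one row per input scaffold
    (unplaced rows have chrom ``NA`` and position 0).
    """
    chosen: dict[str, PlacementDecision] = {}
    for tier_list in tier_lists:
        for dec in tier_list:
            if dec.scaffold_id in chosen:
                continue  # tier monotonicity
            if dec.chrom is None and dec.tier == TIER_UNPLACED and not dec.conflicts:
                continue  # later tiers may still claim it
            chosen[dec.scaffold_id] = dec

    by_chrom: dict[str, list[PlacementDecision]] = defaultdict(list)
    for dec in chosen.values():
        if dec.chrom is not None:
            by_chrom[dec.chrom].append(dec)

    rows: list[dict] = []
    for chrom in sorted(by_chrom):
        decs = by_chrom[chrom]
        backbone = sorted(
            (d for d in decs if d.marker_key is not None),
            key=lambda d: (d.marker_key, d.scaffold_id),
        )
        rest = sorted(
            (d for d in decs if d.marker_key is None),
            key=lambda d: (d.synteny_key if d.synteny_key is not None else (0, 0.0),
                           d.tier, d.scaffold_id),
        )
        if backbone:
            # bridge: backbone members with a synteny key anchor the bisection
            anchors = [(i, d.synteny_key) for i, d in enumerate(backbone)
                       if d.synteny_key is not None]
            ordered = list(backbone)
            inserts: dict[int, list[PlacementDecision]] = defaultdict(list)
            for d in rest:
                if d.synteny_key is None or not anchors:
                    inserts[len(backbone)].append(d)
                    continue
                keys = [a[1] for a in anchors]
                j = bisect.bisect_left(keys, d.synteny_key)
                pos = anchors[j][0] if j < len(anchors) else anchors[-1][0] + 1
                inserts[pos].append(d)
            merged: list[PlacementDecision] = []
            for i in range(len(backbone) + 1):
                merged.extend(inserts.get(i, []))
                if i < len(backbone):
                    merged.append(backbone[i])
            ordered = merged
        else:
            ordered = rest
        for pos, dec in enumerate(ordered, 1):
            rows.append(
                {
                    "scaffold_id": dec.scaffold_id,
                    "chrom": chrom,
                    "position": pos,
                    "orientation": dec.orientation,
                    "tier": dec.tier,
                    "conflicts": "; ".join(dec.conflicts),
                }
            )

    placed_ids = {r["scaffold_id"] for r in rows}
    for sid in all_scaffold_ids:
        if sid not in placed_ids:
            dec = chosen.get(sid)
            rows.append(
                {
                    "scaffold_id": sid,
                    "chrom": pd.NA,
                    "position": 0,
                    "orientation": "+",
                    "tier": TIER_UNPLACED,
                    "conflicts": "; ".join(dec.conflicts) if dec else "",
                }
            )

    table = pd.DataFrame(rows)
    if override is not None and len(override):
        known = set(all_scaffold_ids)
        for _, orow in override.iterrows():
            sid = orow["scaffold_id"]
            if sid not in known:
                raise InputError(f"override references unknown scaffold '{sid}'")
            mask = table["scaffold_id"] == sid
            table.loc[mask, ["chrom", "position", "orientation"]] = [
                orow["chrom"], int(orow["position"]), orow["orientation"]
            ]
            table.loc[mask, "conflicts"] = (
                table.loc[mask, "conflicts"].str.cat(["manual override applied"], sep="; ")
                .str.lstrip("; ")
            )
        # re-rank each chromosome after overrides, stable on (position, id)
        placed = table[table["chrom"].notna()].sort_values(
            ["chrom", "position", "scaffold_id"], kind="stable"
        )
        table.loc[placed.index, "position"] = placed.groupby("chrom").cumcount() + 1
    return table.reset_index(drop=True)


def build_agp(
    chromosome_table: pd.DataFrame,
    scaffold_lengths: dict[str, int],
    gap_length: int = 100,
    chrom_prefix: str = "chr",
) -> list[AgpRow]:
    """Encode the chromosome table as AGP v2.0: W rows for scaffolds
    alternating with fixed-length N gap rows (gap_type scaffold, linkage no)."""
    rows: list[AgpRow] = []
    placed = chromosome_table[chromosome_table["chrom"].notna()]
    for chrom, group in placed.groupby("chrom", sort=True):
        group = group.sort_values("position")
        obj = f"{chrom_prefix}{chrom}"
        beg, part = 1, 1
        for i, (_, row) in enumerate(group.iterrows()):
            sid = row["scaffold_id"]
            if sid not in scaffold_lengths:
                raise InputError(f"no sequence length for scaffold '{sid}'")
            if i > 0:
                rows.append(
                    AgpRow(obj, beg, beg + gap_length - 1, part, "N", gap_length=gap_length)
                )
                beg += gap_length
                part += 1
            length = scaffold_lengths[sid]
            rows.append(
                AgpRow(obj, beg, beg + length - 1, part, "W",
                       component_id=sid, component_beg=1, component_end=length,
                       orientation=row["orientation"])
            )
            beg += length
            part += 1
    validate_agp(rows)
    return rows


def build_chromosomes(agp_rows: Sequence[AgpRow], scaffolds: dict[str, SeqRecord]) -> list[SeqRecord]:
    """Materialise chromosome FASTA records from AGP rows; minus-orientation
    components are reverse complemented."""
    by_object: dict[str, list[AgpRow]] = defaultdict(list)
    for r in agp_rows:
        by_object[r.object].append(r)
    out = []
    for obj in sorted(by_object):
        parts = []
        for r in sorted(by_object[obj], key=lambda r: r.part_number):
            if r.component_type == "N":
                parts.append("N" * r.gap_length)
            else:
                if r.component_id not in scaffolds:
                    raise InputError(f"missing scaffold sequence '{r.component_id}'")
                seq = scaffolds[r.component_id].sequence[r.component_beg - 1 : r.component_end]
                parts.append(revcomp(seq) if r.orientation == "-" else seq)
        out.append(SeqRecord(obj, "".join(parts)))
    return out
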