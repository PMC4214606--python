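"""Tiered placement, the chromosome-table merge, and AGP/FASTA building."""

import numpy as np
import pandas as pd
import pytest

from scaftier.errors import InputError
from scaftier.mapping import ExonEvidence
from scaftier.placement import (PlacementDecision, TIER_MARKER, TIER_SYNTENY,
                                TIER_TILING, TIER_UNPLACED, build_agp,
                                build_chromosomes, merge_placements,
                                place_by_markers, place_by_synteny,
                                place_by_tiling, tile_reference)
from scaftier.seqio import SeqRecord, revcomp
from scaftier.tables import AlnHit, Marker, SyntenyBlock


def _marker_hit(marker_id, scaffold, pos, strand="+", length=300):
    ts, te = (pos, pos + length - 1) if strand == "+" else (pos + length - 1, pos)
    return AlnHit(marker_id, scaffold, 1, length, ts, te, length, length,
                  100.0, float(length))


class TestPlaceByMarkers:
    def test_increasing_markers_forward(self):
        markers = [Marker(f"m{i}", "chr2", i) for i in (5, 6, 7)]
        hits = [_marker_hit("m5", "sA", 1000), _marker_hit("m6", "sA", 5000),
                _marker_hit("m7", "sA", 9000)]
        (dec,) = place_by_markers([SeqRecord("sA", "A" * 10_000)], markers,
                                  marker_hits=hits)
        assert (dec.chrom, dec.orientation, dec.marker_key) == ("chr2", "+", 6.0)
        assert dec.tier == TIER_MARKER

    def test_decreasing_markers_reverse(self):
        markers = [Marker(f"m{i}", "chr2", i) for i in (5, 6, 7)]
        hits = [_marker_hit("m5", "sA", 9000, "-"), _marker_hit("m6", "sA", 5000, "-"),
                _marker_hit("m7", "sA", 1000, "-")]
        (dec,) = place_by_markers([SeqRecord("sA", "A" * 10_000)], markers,
                                  marker_hits=hits)
        assert dec.orientation == "-"

    def test_chromosome_conflict_left_unplaced(self):
        markers = [Marker("m1", "chr1", 4), Marker("m2", "chr3", 9)]
        hits = [_marker_hit("m1", "sA", 1000), _marker_hit("m2", "sA", 5000)]
        (dec,) = place_by_markers([SeqRecord("sA", "A" * 10_000)], markers,
                                  marker_hits=hits)
        assert dec.tier == TIER_UNPLACED and dec.chrom is None
        assert "disagree" in dec.conflicts[0]

    def test_single_marker_uses_hit_strand(self):
        markers = [Marker("m1", "chr1", 4)]
        (dec,) = place_by_markers([SeqRecord("sA", "A" * 10_000)], markers,
                                  marker_hits=[_marker_hit("m1", "sA", 1000, "-")])
        assert dec.orientation == "-"


def _gene_ev(gene, scaffold, ref_chrom, ref_pos, strand="+", exon_index=1):
    t_start = 100 * exon_index
    ts, te = (t_start, t_start + 99) if strand == "+" else (t_start + 99, t_start)
    hit = AlnHit(f"{gene}.e{exon_index}", scaffold, 1, 100, ts, te, 100, 100,
                 100.0, 100.0)
    return ExonEvidence(gene, exon_index, hit, ref_chrom, ref_pos)


BLOCKS = [
    SyntenyBlock("ref3", 1, 500_000, "2", "+", 1),
    SyntenyBlock("ref3", 500_001, 1_000_000, "2", "-", 2),
    SyntenyBlock("ref1", 1, 1_000_000, "1", "+", 1),
]


class TestPlaceBySynteny:
    def test_forward_block(self):
        evs = [_gene_ev(f"g{i}", "sB", "ref3", 100_000 * i) for i in (1, 2, 3)]
        (dec,) = place_by_synteny(["sB"], evs, BLOCKS)
        assert (dec.chrom, dec.tier) == ("2", TIER_SYNTENY)
        assert dec.synteny_key == (1, 200_000.0)
        assert dec.orientation == "+"

    def test_inverted_block_reflects_order_and_flips(self):
        """In a '-' block, larger reference positions come earlier on the
        target, so the position key is the negated median; the orientation
        flip combines block and hit strands."""
        evs = [_gene_ev(f"g{i}", "sB", "ref3", 500_000 + 100_000 * i) for i in (1, 2)]
        (dec,) = place_by_synteny(["sB"], evs, BLOCKS)
        assert dec.synteny_key == (2, -650_000.0)
        assert dec.orientation == "-"  # block '-', hits '+'
        evs_neg = [_gene_ev(f"g{i}", "sB", "ref3", 500_000 + 100_000 * i, "-")
                   for i in (1, 2)]
        (dec2,) = place_by_synteny(["sB"], evs_neg, BLOCKS)
        assert dec2.orientation == "+"  # both flips cancel

    def test_two_blocks_majority_with_conflict(self):
        evs = [_gene_ev("g1", "sB", "ref3", 100_000),
               _gene_ev("g2", "sB", "ref3", 200_000),
               _gene_ev("g3", "sB", "ref3", 700_000)]
        (dec,) = place_by_synteny(["sB"], evs, BLOCKS)
        assert dec.synteny_key[0] == 1  # majority block
        assert any("majority" in c for c in dec.conflicts)

    def test_only_unplaced_considered(self):
        evs = [_gene_ev("g1", "sB", "ref3", 100_000)]
        assert place_by_synteny([], evs, BLOCKS) == []


class TestPlaceByTiling:
    def test_segments_and_terminal_stub(self):
        ref = [SeqRecord("ref1", "A" * 25_000)]
        segs = tile_reference(ref, 10_000)
        assert [len(s.sequence) for s in segs] == [10_000, 10_000, 5_000]
        assert segs[2].id == "ref1|seg2"

    def test_votes_place_scaffold(self):
        rng = np.random.default_rng(1)
        ref_seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 60_000))
        ref = [SeqRecord("ref1", ref_seq)]
        blocks = [SyntenyBlock("ref1", 1, 60_000, "1", "+", 1)]
        scaffold = SeqRecord("sT", ref_seq[20_000:50_000])
        decs = place_by_tiling([scaffold], ref, blocks, 10_000)
        (dec,) = [d for d in decs if d.scaffold_id == "sT"]
        assert (dec.chrom, dec.tier, dec.orientation) == ("1", TIER_TILING, "+")
        # median voting segment (segments 2..4 hit) sits inside the scaffold span
        assert 20_000 <= dec.synteny_key[1] <= 50_000

    def test_no_hits_unplaced(self):
        rng = np.random.default_rng(2)
        ref = [SeqRecord("ref1", "".join("ACGT"[i] for i in rng.integers(0, 4, 20_000)))]
        blocks = [SyntenyBlock("ref1", 1, 20_000, "1", "+", 1)]
        alien = SeqRecord("sX", "".join("ACGT"[i] for i in rng.integers(0, 4, 15_000)))
        decs = place_by_tiling([alien], ref, blocks, 10_000)
        (dec,) = decs
        assert dec.tier == TIER_UNPLACED and dec.chrom is None


class TestMergePlacements:
    def test_tiers_interleave_by_keys(self):
        t1 = [PlacementDecision("sA", "1", "+", TIER_MARKER, marker_key=2.0,
                                synteny_key=(1, 100.0)),
              PlacementDecision("sC", "1", "+", TIER_MARKER, marker_key=8.0,
                                synteny_key=(1, 900.0))]
        t2 = [PlacementDecision("sB", "1", "+", TIER_SYNTENY,
                                synteny_key=(1, 500.0))]
        table = merge_placements([t1, t2], ["sA", "sB", "sC"])
        assert table.sort_values("position")["scaffold_id"].tolist() == ["sA", "sB", "sC"]

    def test_override_wins(self):
        t1 = [PlacementDecision("sA", "1", "+", TIER_MARKER, marker_key=1.0),
              PlacementDecision("sB", "1", "+", TIER_MARKER, marker_key=2.0)]
        override = pd.DataFrame([{"scaffold_id": "sB", "chrom": "2",
                                  "position": 1, "orientation": "-"}])
        table = merge_placements([t1], ["sA", "sB"], override=override)
        row = table[table.scaffold_id == "sB"].iloc[0]
        assert (row.chrom, row.orientation) == ("2", "-")
        assert "override" in row.conflicts

    def test_override_unknown_scaffold_rejected(self):
        override = pd.DataFrame([{"scaffold_id": "ghost", "chrom": "1",
                                  "position": 1, "orientation": "+"}])
        with pytest.raises(InputError, match="ghost"):
            merge_placements([[]], ["sA"], override=override)

    def test_empty_evidence_all_unplaced(self):
        table = merge_placements([[]], ["sA", "sB"])
        assert table["chrom"].isna().all()
        assert set(table["scaffold_id"]) == {"sA", "sB"}

    def test_every_scaffold_exactly_once(self):
        t1 = [PlacementDecision("sA", "1", "+", TIER_MARKER, marker_key=1.0)]
        table = merge_placements([t1], ["sA", "sB", "sC"])
        assert sorted(table["scaffold_id"]) == ["sA", "sB", "sC"]
        assert table["scaffold_id"].is_unique


class TestAgpBuild:
    def _table(self):
        return pd.DataFrame([
            {"scaffold_id": "s1", "chrom": "1", "position": 1, "orientation": "+",
             "tier": 1, "conflicts": ""},
            {"scaffold_id": "s2", "chrom": "1", "position": 2, "orientation": "-",
             "tier": 2, "conflicts": ""},
        ])

    def test_rows_and_length(self):
        rows = build_agp(self._table(), {"s1": 1000, "s2": 1000}, gap_length=100)
        assert len(rows) == 3
        assert rows[-1].object_end == 2100
        assert [r.component_type for r in rows] == ["W", "N", "W"]

    def test_minus_component_revcomped(self):
        rng = np.random.default_rng(3)
        seqs = {sid: SeqRecord(sid, "".join("ACGT"[i] for i in rng.integers(0, 4, 1000)))
                for sid in ("s1", "s2")}
        rows = build_agp(self._table(), {"s1": 1000, "s2": 1000})
        (chrom,) = build_chromosomes(rows, seqs)
        assert chrom.sequence[:1000] == seqs["s1"].sequence
        assert chrom.sequence[1100:] == revcomp(seqs["s2"].sequence)

    def test_agp_fasta_coordinate_round_trip(self):
        """Extracting a W row's object range reproduces the oriented scaffold."""
        rng = np.random.default_rng(4)
        seqs = {sid: SeqRecord(sid, "".join("ACGT"[i] for i in rng.integers(0, 4, 1000)))
                for sid in ("s1", "s2")}
        rows = build_agp(self._table(), {"s1": 1000, "s2": 1000})
        (chrom,) = build_chromosomes(rows, seqs)
        for r in rows:
            if r.component_type != "W":
                continue
            segment = chrom.sequence[r.object_beg - 1 : r.object_end]
            source = seqs[r.component_id].sequence[r.component_beg - 1 : r.component_end]
            assert segment == (revcomp(source) if r.orientation == "-" else source)

    def test_missing_sequence_rejected(self):
        with pytest.raises(InputError, match="no sequence length"):
            build_agp(self._table(), {"s1": 1000})


class TestWorldRecovery:
    """Placement on the simulated world recovers the true arrangement."""

    def test_full_markers_exact_order(self, small_world):
        from scaftier.pipeline import curate_scaffolds, evaluate_placement, place_scaffolds

        w = small_world
        cur = curate_scaffolds(w.scaffolds, w.exon_records, w.exon_metadata, w.synteny)
        res = place_scaffolds(cur.scaffolds, w.exon_records, w.exon_metadata,
                              w.markers, w.synteny, w.reference)
        ev = evaluate_placement(res.table, w.truth.scaffold_parts)
        assert ev["min_tau"] == 1.0
        assert ev["orientation_errors"] == 0
        assert ev["chrom_accuracy_pct"] == 100.0

    def test_tier_monotonicity_and_partition(self, small_world):
        from scaftier.pipeline import curate_scaffolds, place_scaffolds

        w = small_world
        cur = curate_scaffolds(w.scaffolds, w.exon_records, w.exon_metadata, w.synteny)
        res = place_scaffolds(cur.scaffolds, w.exon_records, w.exon_metadata,
                              w.markers, w.synteny, w.reference)
        tiers = {}
        for tier_list in (res.tier1, res.tier2, res.tier3):
            for dec in tier_list:
                if dec.tier != TIER_UNPLACED:
                    assert dec.scaffold_id not in tiers  # never re-placed
                    tiers[dec.scaffold_id] = dec.tier
        # every curated scaffold appears exactly once in the final table
        assert sorted(res.table["scaffold_id"]) == sorted(s.id for s in cur.scaffolds)
        assert res.table["scaffold_id"].is_unique
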