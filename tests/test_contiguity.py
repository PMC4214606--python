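"""The gene-contiguity rule, chimera detection and scaffold breaking."""

import numpy as np
import pytest

from scaftier.contiguity import (apply_breaks, detect_chimeras, detect_violations,
                                 propose_breakpoints)
from scaftier.errors import ValidationError
from scaftier.mapping import ExonEvidence
from scaftier.pipeline import gene_chromosome_votes
from scaftier.seqio import SeqRecord
from scaftier.tables import AlnHit

from .oracles import maximal_runs


def _ev(gene, idx, scaffold, t_start, strand="+", length=100):
    """Exon evidence with a synthetic hit at t_start (1-based)."""
    if strand == "+":
        ts, te = t_start, t_start + length - 1
    else:
        ts, te = t_start + length - 1, t_start
    hit = AlnHit(f"{gene}.e{idx}", scaffold, 1, length, ts, te,
                 length, length, 100.0, float(length))
    return ExonEvidence(gene, idx, hit, "ref1", 1000 * idx)


class TestDetectViolations:
    def test_ordered_gene_clean(self):
        evs = [_ev("g1", i, "s1", pos) for i, pos in enumerate((100, 500, 900), 1)]
        assert detect_violations(evs) == []

    def test_minus_strand_decreasing_clean(self):
        evs = [_ev("g1", i, "s1", pos, "-") for i, pos in enumerate((900, 500, 100), 1)]
        assert detect_violations(evs) == []

    def test_order_violation(self):
        evs = [_ev("g1", i, "s1", pos) for i, pos in enumerate((100, 900, 500), 1)]
        (v,) = detect_violations(evs)
        assert v.kind == "order_violation"
        assert v.scaffolds == ["s1"]

    def test_split_gene_lists_both_scaffolds(self):
        # exons 1-2 on one scaffold, exon 3 assigned elsewhere: the classic
        # misassembly signature the rule exists to flag
        evs = [_ev("g1", 1, "s1", 100), _ev("g1", 2, "s1", 500),
               _ev("g1", 3, "s2", 40)]
        (v,) = detect_violations(evs)
        assert v.kind == "split_gene"
        assert v.scaffolds == ["s1", "s2"]

    def test_mixed_strands_flagged(self):
        evs = [_ev("g1", 1, "s1", 100, "+"), _ev("g1", 2, "s1", 500, "-")]
        (v,) = detect_violations(evs)
        assert v.kind == "orientation_violation"

    def test_permutation_invariant(self):
        rng = np.random.default_rng(0)
        evs = [_ev("g1", i, "s1", p) for i, p in enumerate((100, 900, 500), 1)]
        evs += [_ev("g2", 1, "s1", 2000), _ev("g2", 2, "s2", 10)]
        base = [(v.gene_id, v.kind) for v in detect_violations(evs)]
        for _ in range(5):
            perm = [evs[i] for i in rng.permutation(len(evs))]
            assert [(v.gene_id, v.kind) for v in detect_violations(perm)] == base

    def test_single_placed_exon_ignored(self):
        evs = [_ev("g1", 1, "s1", 100),
               ExonEvidence("g1", 2, None, "ref1", 2000)]
        assert detect_violations(evs) == []


class TestDetectChimeras:
    def _world(self, votes_layout):
        """votes_layout: list of (gene, chrom, kb offset); two exons each."""
        evidence, votes = [], {}
        for gene, chrom, kb in votes_layout:
            evidence.append(_ev(gene, 1, "sC", kb * 1000 + 1))
            evidence.append(_ev(gene, 2, "sC", kb * 1000 + 301))
            votes[gene] = chrom
        return evidence, votes

    def test_two_camps_flagged(self):
        evidence, votes = self._world(
            [("g1", "chr1", 0), ("g2", "chr1", 5), ("g3", "chr2", 20), ("g4", "chr2", 25)]
        )
        flagged, _ = detect_chimeras(evidence, votes)
        assert list(flagged) == ["sC"]
        clusters = flagged["sC"]
        assert [c.chrom for c in clusters] == ["chr1", "chr2"]

    def test_unanimous_not_flagged(self):
        evidence, votes = self._world([("g1", "chr1", 0), ("g2", "chr1", 10)])
        flagged, violations = detect_chimeras(evidence, votes)
        assert flagged == {} and violations == []

    def test_three_runs_two_breaks(self):
        layout = [("g1", "chr1", 0), ("g2", "chr1", 4), ("g3", "chr2", 10),
                  ("g4", "chr2", 14), ("g5", "chr1", 20), ("g6", "chr1", 24)]
        evidence, votes = self._world(layout)
        flagged, _ = detect_chimeras(evidence, votes)
        clusters = flagged["sC"]
        # cross-check run structure against a brute-force run finder
        runs = maximal_runs([chrom for _, chrom, _ in layout])
        assert len(clusters) == len(runs) == 3
        assert [c.chrom for c in clusters] == ["chr1", "chr2", "chr1"]

    def test_single_interleaved_gene_not_broken(self):
        evidence, votes = self._world(
            [("g1", "chr1", 0), ("g2", "chr1", 5), ("g3", "chr2", 10),
             ("g4", "chr1", 15), ("g5", "chr1", 20)]
        )
        flagged, violations = detect_chimeras(evidence, votes)
        assert flagged == {}  # run of length 1 is a curation case
        assert [v.kind for v in violations] == ["chimeric_scaffold"]
        assert violations[0].gene_id == "g3"


class TestProposeBreakpoints:
    def _clusters(self, evidence, votes):
        flagged, _ = detect_chimeras(evidence, votes)
        return flagged

    def test_break_at_n_run_midpoint(self):
        seq = "A" * 14_000 + "N" * 100 + "C" * 15_900
        evidence, votes = TestDetectChimeras()._world(
            [("g1", "chr1", 0), ("g2", "chr1", 5), ("g3", "chr2", 20), ("g4", "chr2", 25)]
        )
        flagged = self._clusters(evidence, votes)
        (bp,) = propose_breakpoints(flagged, {"sC": SeqRecord("sC", seq)})
        assert bp.coordinate == 14_050
        assert (bp.evidence_left, bp.evidence_right) == ("chr1", "chr2")

    def test_fallback_midpoint_without_n(self):
        seq = "A" * 30_000
        evidence, votes = TestDetectChimeras()._world(
            [("g1", "chr1", 0), ("g2", "chr1", 5), ("g3", "chr2", 20), ("g4", "chr2", 25)]
        )
        flagged = self._clusters(evidence, votes)
        (bp,) = propose_breakpoints(flagged, {"sC": SeqRecord("sC", seq)})
        # clusters end at g2's last exon, next starts at g3's first exon
        clusters = flagged["sC"]
        assert bp.coordinate == (clusters[0].end + clusters[1].start) // 2

    def test_longest_n_run_wins(self):
        seq = ("A" * 8_000 + "N" * 50 + "A" * 2_000 + "N" * 200 + "A" * 2_000
               + "C" * 17_750)
        evidence, votes = TestDetectChimeras()._world(
            [("g1", "chr1", 0), ("g2", "chr1", 5), ("g3", "chr2", 20), ("g4", "chr2", 25)]
        )
        flagged = self._clusters(evidence, votes)
        (bp,) = propose_breakpoints(flagged, {"sC": SeqRecord("sC", seq)})
        assert 10_050 <= bp.coordinate <= 10_250  # inside the 200-N run


class TestApplyBreaks:
    def test_parts_and_provenance(self):
        rec = SeqRecord("s1", "A" * 14_050 + "C" * 15_950)
        from scaftier.contiguity import Breakpoint
        parts, prov = apply_breaks([rec], [Breakpoint("s1", 14_050, "", "chr1", "chr2")])
        assert [p.id for p in parts] == ["s1.1", "s1.2"]
        assert [len(p.sequence) for p in parts] == [14_050, 15_950]
        assert prov == [
            {"part": "s1.1", "parent": "s1", "parent_start": 1, "parent_end": 14_050},
            {"part": "s1.2", "parent": "s1", "parent_start": 14_051, "parent_end": 30_000},
        ]
        assert "".join(p.sequence for p in parts) == rec.sequence

    def test_no_breaks_identity(self):
        rec = SeqRecord("s1", "ACGT" * 100)
        parts, prov = apply_breaks([rec], [])
        assert parts == [rec] and prov == []

    def test_two_breaks_three_parts_conserve_sequence(self):
        from scaftier.contiguity import Breakpoint
        rec = SeqRecord("s1", "ACGTN" * 2000)
        bps = [Breakpoint("s1", 3000, "", "a", "b"), Breakpoint("s1", 7000, "", "b", "c")]
        parts, _ = apply_breaks([rec], bps)
        assert len(parts) == 3
        assert "".join(p.sequence for p in parts) == rec.sequence
        assert sum(len(p.sequence) for p in parts) == len(rec.sequence)

    def test_out_of_range_rejected(self):
        from scaftier.contiguity import Breakpoint
        rec = SeqRecord("s1", "ACGT")
        with pytest.raises(ValidationError, match="out of range"):
            apply_breaks([rec], [Breakpoint("s1", 10, "", "a", "b")])


def test_planted_chimeras_recovered(small_world):
    """Every planted chimeric join is flagged, nothing else, and each break
    falls inside the planted junction's N-gap."""
    from scaftier.mapping import build_index, map_exons

    w = small_world
    idx = build_index(w.scaffolds, stride=2)
    evidence = map_exons(w.exon_records, w.exon_metadata, idx)
    votes = gene_chromosome_votes(evidence, w.synteny)
    flagged, _ = detect_chimeras(evidence, votes)
    assert set(flagged) == set(w.truth.junctions["scaffold_id"])
    bps = propose_breakpoints(flagged, {s.id: s for s in w.scaffolds})
    for bp in bps:
        rows = w.truth.junctions[w.truth.junctions.scaffold_id == bp.scaffold_id]
        assert any(r.gap_start <= bp.coordinate <= r.gap_end for r in rows.itertuples())
    # total sequence is conserved by breaking
    parts, _ = apply_breaks(w.scaffolds, bps)
    assert (sum(len(p.sequence) for p in parts)
            == sum(len(s.sequence) for s in w.scaffolds))
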