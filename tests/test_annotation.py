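"""Protein reconstruction, global alignment and the model-acceptance rule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scaftier.annotation import (ProteinComparison, QcThresholds, TranslationFlags,
                                 compare_proteins, evaluate_model, extract_cds,
                                 global_align, merge_terminal_exons,
                                 summarize_comparisons, translate, validate_gtf)
from scaftier.errors import InputError, ValidationError
from scaftier.gtf import GeneModel
from scaftier.seqio import SeqRecord, revcomp

from .oracles import nw_affine_score

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestExtractCds:
    GENOME = {"c": SeqRecord("c", "ATGNNNGAATAGCCC")}

    def test_plus_strand_concatenation(self):
        m = GeneModel("t", "g", chrom="c", strand="+",
                      exons=[(1, 3), (7, 12)], cds=[(1, 3, 0), (7, 9, 0)])
        assert extract_cds(m, self.GENOME) == "ATGGAA"

    def test_minus_strand_reverse_complement(self):
        m = GeneModel("t", "g", chrom="c", strand="-",
                      exons=[(1, 3), (7, 12)], cds=[(1, 3, 0), (7, 9, 0)])
        assert extract_cds(m, self.GENOME) == revcomp("ATG" + "GAA")

    def test_phase_trims_leading_bases(self):
        # 7-bp toy CDS with phase 1: the first base is skipped so the
        # remaining 6 bases form two codons
        genome = {"c": SeqRecord("c", "TATGGAA")}
        m = GeneModel("t", "g", chrom="c", strand="+",
                      exons=[(1, 7)], cds=[(1, 7, 1)])
        assert extract_cds(m, genome) == "ATGGAA"

    def test_out_of_bounds_rejected(self):
        m = GeneModel("t", "g", chrom="c", strand="+",
                      exons=[(1, 99)], cds=[(1, 99, 0)])
        with pytest.raises(ValidationError, match="outside"):
            extract_cds(m, self.GENOME)


class TestTranslate:
    def test_clean_orf(self):
        protein, flags = translate("ATGGAATAA")
        assert protein == "ME"
        assert not flags.any()

    def test_internal_stop_flagged_and_truncated(self):
        protein, flags = translate("ATGTAAGAA")
        assert flags.internal_stop
        assert protein == "M"

    def test_incomplete_codon(self):
        protein, flags = translate("ATGGAAGGAT")  # 10 bp
        assert flags.incomplete_codon
        assert len(protein) == 3

    def test_no_start(self):
        _, flags = translate("GCGGAATAA")
        assert flags.no_start


class TestGlobalAlign:
    def test_identical_sequences(self):
        identity, similarity, gaps, _, _ = global_align("MKVLAW", "MKVLAW")
        assert (identity, similarity, gaps) == (100.0, 100.0, 0)

    def test_conservative_substitution(self):
        # K/R scores +2 in BLOSUM62: identity drops, similarity does not
        identity, similarity, gaps, _, _ = global_align("MKV", "MRV")
        assert round(identity, 2) == 66.67
        assert similarity == 100.0
        assert gaps == 0

    def test_gap_positions_count_both_rows(self):
        _, _, gaps, (row_a, row_b), _ = global_align("MKVAW", "MKW")
        assert gaps == row_a.count("-") + row_b.count("-")
        assert gaps >= 2  # length difference forces at least that many

    def test_non_amino_acid_rejected(self):
        with pytest.raises(InputError, match="non-amino-acid"):
            global_align("MK1", "MKV")

    def test_score_matches_bruteforce_oracle(self):
        """Needleman-Wunsch score equals a memoized-recursion oracle on 200
        random pairs of length <= 12."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            a = "".join(AA[i] for i in rng.integers(0, 20, rng.integers(1, 13)))
            b = "".join(AA[i] for i in rng.integers(0, 20, rng.integers(1, 13)))
            *_, score = global_align(a, b)
            assert score == nw_affine_score(a, b), (a, b)


class TestEvaluateModel:
    def _comp(self, dlen, sim, internal_stop=False):
        return ProteinComparison("g", 100 + dlen, 100, 90.0, sim, abs(dlen),
                                 flags=TranslationFlags(internal_stop=internal_stop))

    @pytest.mark.parametrize(
        "dlen, sim, expected",
        [
            (4, 93.0, "accept"),
            (5, 99.0, "flag_for_review"),   # strict "less than 5"
            (0, 92.0, "flag_for_review"),   # strict "greater than 92"
            (-4, 92.01, "accept"),
            (0, 100.0, "accept"),
        ],
    )
    def test_rule_boundaries(self, dlen, sim, expected):
        assert evaluate_model(self._comp(dlen, sim)) == expected

    def test_internal_stop_never_accepted(self):
        assert evaluate_model(self._comp(0, 100.0, internal_stop=True)) == "flag_for_review"

    def test_fast_evolving_class_relaxed(self):
        comp = self._comp(7, 85.0)
        assert evaluate_model(comp) == "flag_for_review"
        assert evaluate_model(comp, "fast_evolving") == "accept"

    @settings(derandomize=True, max_examples=60)
    @given(dlen=st.integers(0, 10), sim=st.floats(80, 100),
           d_dlen=st.integers(0, 5), d_sim=st.floats(0, 10))
    def test_monotone(self, dlen, sim, d_dlen, d_sim):
        """Raising similarity or shrinking the length difference never turns
        an accept into a flag."""
        base = evaluate_model(self._comp(dlen, sim))
        better = evaluate_model(self._comp(max(dlen - d_dlen, 0), min(sim + d_sim, 100)))
        assert not (base == "accept" and better != "accept")


class TestMergeTerminalExons:
    def _model(self, gap, cds_end=1000):
        # + strand: CDS ends inside exon 2; exons 3 (penultimate) and 4
        # (terminal) are non-coding
        return GeneModel("t", "g", chrom="c", strand="+",
                         exons=[(1, 500), (600, 1100), (1200, 1400),
                                (1400 + gap + 1, 1400 + gap + 200)],
                         cds=[(10, 500, 0), (600, cds_end, 0)])

    def test_close_noncoding_exons_merged(self):
        m = merge_terminal_exons(self._model(900))
        assert len(m.exons) == 3
        assert m.exons[-1] == (1200, 2500)
        assert m.cds == self._model(900).cds  # CDS untouched

    def test_distant_exons_unchanged(self):
        m = merge_terminal_exons(self._model(1100))
        assert m.exons == self._model(1100).exons

    def test_coding_penultimate_guard(self):
        model = GeneModel("t", "g", chrom="c", strand="+",
                          exons=[(1, 500), (600, 1100)],
                          cds=[(10, 500, 0), (600, 1100, 0)])
        assert merge_terminal_exons(model).exons == model.exons

    def test_minus_strand_merge(self):
        # '-' strand: terminal exon is leftmost
        model = GeneModel("t", "g", chrom="c", strand="-",
                          exons=[(100, 300), (800, 1000), (1100, 2000)],
                          cds=[(1200, 1900, 0)])
        m = merge_terminal_exons(model)
        assert m.exons == [(100, 1000), (1100, 2000)]

    def test_utr_projection_extends_terminal(self):
        genome = {"c": SeqRecord("c", "A" * 5000)}
        model = GeneModel("t", "g", chrom="c", strand="+",
                          exons=[(1, 500), (600, 800)], cds=[(10, 500, 0)])
        m = merge_terminal_exons(model, genome, ref_terminal_exon_len=600)
        assert m.exons[-1] == (600, 1199)

    def test_utr_projection_blocked_by_gap(self):
        genome = {"c": SeqRecord("c", "A" * 900 + "N" * 50 + "A" * 4050)}
        model = GeneModel("t", "g", chrom="c", strand="+",
                          exons=[(1, 500), (600, 800)], cds=[(10, 500, 0)])
        m = merge_terminal_exons(model, genome, ref_terminal_exon_len=600)
        assert m.exons[-1] == (600, 800)


class TestValidateGtf:
    def test_cds_containment_issue(self):
        m = GeneModel("t", "g", chrom="c", exons=[(1, 40), (70, 100)],
                      cds=[(50, 60, 0)])
        clean, issues = validate_gtf([m])
        assert clean == []
        assert issues[0].kind == "cds_without_exon"

    def test_duplicates_keep_smallest_id(self):
        def mk(tid):
            return GeneModel(tid, "g", chrom="c", exons=[(1, 40)], cds=[(1, 39, 0)])
        clean, issues = validate_gtf([mk("tB"), mk("tA")])
        assert [m.transcript_id for m in clean] == ["tA"]
        assert issues[0].transcript_id == "tB"
        assert issues[0].kind == "duplicate_transcript"

    def test_clean_input_identity_and_idempotent(self):
        m1 = GeneModel("t1", "g1", chrom="c", exons=[(1, 40)], cds=[(1, 39, 0)])
        m2 = GeneModel("t2", "g2", chrom="c", exons=[(50, 90)], cds=[(50, 88, 0)])
        clean, issues = validate_gtf([m1, m2])
        assert issues == []
        clean2, issues2 = validate_gtf(clean)
        assert issues2 == []
        assert [m.transcript_id for m in clean2] == [m.transcript_id for m in clean]

    def test_overlapping_exons_flagged(self):
        m = GeneModel("t", "g", chrom="c", exons=[(1, 40), (30, 80)], cds=[])
        _, issues = validate_gtf([m])
        assert issues[0].kind == "overlapping_exons"


class TestSummarize:
    def _comp(self, identity, similarity=98.0, gaps=0):
        return ProteinComparison("g", 100, 100, identity, similarity, gaps)

    def test_mean_of_two(self):
        mean_id, mean_sim, mean_gaps, n = summarize_comparisons(
            [self._comp(90.0), self._comp(100.0)])
        assert (mean_id, n) == (95.0, 2)

    def test_single_comparison(self):
        mean_id, mean_sim, mean_gaps, n = summarize_comparisons([self._comp(91.5, 93.0, 4)])
        assert (mean_id, mean_sim, mean_gaps, n) == (91.5, 93.0, 4.0, 1)

    def test_matches_independent_recomputation(self):
        rng = np.random.default_rng(9)
        comps = [self._comp(float(rng.uniform(80, 100)), float(rng.uniform(85, 100)),
                            int(rng.integers(0, 30))) for _ in range(50)]
        mean_id, mean_sim, mean_gaps, n = summarize_comparisons(comps)
        assert mean_id == pytest.approx(sum(c.identity for c in comps) / 50)
        assert mean_sim == pytest.approx(sum(c.similarity for c in comps) / 50)
        assert mean_gaps == pytest.approx(sum(c.gap_positions for c in comps) / 50)

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            summarize_comparisons([])


def test_true_models_accepted_on_world(small_world):
    """Substitution-only divergence conserves protein length, so the world's
    true models all pass the conservation rule."""
    w = small_world
    genome = {s.id: s for s in w.scaffolds}
    proteome = {p.id: p.sequence for p in w.ref_proteome}
    pairs = dict(w.ortholog_pairs)
    accepted = 0
    for m in w.true_models:
        protein, flags = translate(extract_cds(m, genome))
        comp = compare_proteins(m.gene_id, protein, proteome[pairs[m.gene_id]],
                                flags=flags)
        accepted += evaluate_model(comp) == "accept"
    assert accepted == len(w.true_models)


def test_frameshift_never_accepted(small_world):
    """A 1-bp deletion inside the CDS destroys the reading frame: the model
    must not be accepted regardless of where the shift lands."""
    w = small_world
    genome = {s.id: s for s in w.scaffolds}
    proteome = {p.id: p.sequence for p in w.ref_proteome}
    pairs = dict(w.ortholog_pairs)
    rng = np.random.default_rng(1)
    for m in w.true_models[:10]:
        s, e, _ = m.cds[0]
        cut = int(rng.integers(s + 3, e - 3))
        rec = genome[m.chrom]
        mutated = dict(genome)
        mutated[m.chrom] = SeqRecord(rec.id, rec.sequence[:cut] + rec.sequence[cut + 1:])
        protein, flags = translate(extract_cds(m, mutated))
        if not protein:
            continue
        comp = compare_proteins(m.gene_id, protein, proteome[pairs[m.gene_id]],
                                flags=flags)
        assert evaluate_model(comp) != "accept"
        assert flags.internal_stop or abs(comp.len_test - comp.len_ref) >= 5
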