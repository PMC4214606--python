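"""Annotation quality control.

Proteins are rebuilt from the GTF gene models and the genome sequence,
globally aligned against their ortholog proteins (Needleman-Wunsch, affine
gaps, BLOSUM62, free end gaps — the needle defaults), and judged by the
conservation rule: a model is accepted when the protein length difference
is below 5 amino acids and the similarity exceeds 92%.  Everything else is
flagged for review — borderline models are a manual-inspection case, never
a silent rejection, because gene families evolve at very different rates
(immune and reproductive genes legitimately fall below thresholds that
would be alarming for a synapse gene).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .errors import InputError, ValidationError
from .gtf import GeneModel
from .seqio import SeqRecord, revcomp

_PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYBZX*")


@dataclass
class QcThresholds:
    """Acceptance-rule and alignment parameters.

    max_len_diff: amino acids; a model passes when |len_test - len_ref| is
    strictly below this.  min_similarity: percent; strictly above passes.
    terminal_merge_max: bp between two non-coding 3' exons that may be
    merged into one terminal exon.  Gap penalties and matrix follow the
    EMBOSS needle defaults.
    """

    max_len_diff: int = 5
    min_similarity: float = 92.0
    terminal_merge_max: int = 1000
    gap_open: float = 10.0
    gap_extend: float = 0.5
    matrix: str = "BLOSUM62"


#: per-gene-class thresholds; the fast_evolving relaxation is configurable
GENE_CLASS_THRESHOLDS: dict[str, QcThresholds] = {
    "default": QcThresholds(),
    "fast_evolving": QcThresholds(max_len_diff=10, min_similarity=80.0),
}


@dataclass
class TranslationFlags:
    internal_stop: bool = False
    no_start: bool = False
    incomplete_codon: bool = False

    def any(self) -> bool:
        return self.internal_stop or self.no_start or self.incomplete_codon


@dataclass
class ProteinComparison:
    gene_id: str
    len_test: int
    len_ref: int
    identity: float
    similarity: float
    gap_positions: int
    decision: str = ""  # accept | flag_for_review | reject
    flags: TranslationFlags = field(default_factory=TranslationFlags)


def extract_cds(model: GeneModel, genome: dict[str, SeqRecord]) -> str:
    """Concatenate a model's CDS intervals 5'->3' into the coding DNA.

    On '-' strand the intervals are read right to left and reverse
    complemented.  Leading bases of the translation-first interval are
    trimmed according to its phase (phase = bases to skip before the first
    complete codon).
    """
    if not model.cds:
        raise InputError(f"{model.transcript_id}: no CDS intervals")
    if model.chrom not in genome:
        raise InputError(f"{model.transcript_id}: chromosome '{model.chrom}' not in genome")
    chrom_seq = genome[model.chrom].sequence
    pieces = []
    intervals = sorted(model.cds)
    for s, e, _phase in intervals:
        if not (1 <= s <= e <= len(chrom_seq)):
            raise ValidationError(
                f"{model.transcript_id}: CDS {s}-{e} outside {model.chrom} (1-{len(chrom_seq)})"
            )
        pieces.append(chrom_seq[s - 1 : e])
    if model.strand == "-":
        cds = "".join(revcomp(p) for p in reversed(pieces))
        first_phase = intervals[-1][2]
    else:
        cds = "".join(pieces)
        first_phase = intervals[0][2]
    return cds[first_phase:]


def translate(cds: str) -> tuple[str, TranslationFlags]:
    """Standard-code translation with diagnostic flags instead of errors.

    The terminal stop is removed; a stop before the end sets internal_stop
    and truncates the returned protein there; a first residue other than M
    sets no_start; a length not divisible by 3 sets incomplete_codon and
    trailing bases are ignored.
    """
    flags = TranslationFlags()
    if len(cds) % 3 != 0:
        flags.incomplete_codon = True
        cds = cds[: len(cds) - len(cds) % 3]
    if len(cds) < 3:
        return "", flags
    protein = str(Seq(cds).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        flags.internal_stop = True
        protein = protein[: protein.index("*")]
    if not protein.startswith("M"):
        flags.no_start = True
    return protein, flags


def _aligner(thresholds: QcThresholds) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(thresholds.matrix)
    aligner.open_gap_score = -thresholds.gap_open
    aligner.extend_gap_score = -thresholds.gap_extend
    # free end gaps (needle's default endweight=false)
    aligner.end_gap_score = 0.0
    return aligner


def global_align(
    a: str, b: str, thresholds: QcThresholds | None = None
) -> tuple[float, float, int, tuple[str, str], float]:
    """Global protein alignment in the needle style.

    Returns (identity %, similarity %, gap characters over both rows,
    (aligned_a, aligned_b), score).  Identity counts identical columns over
    the alignment length; similarity counts columns whose substitution
    score is positive (identities included); both are percentages of the
    alignment length including gap columns.
    """
    thresholds = thresholds or QcThresholds()
    if not a or not b:
        raise InputError("global_align requires non-empty sequences")
    for name, seq in (("first", a), ("second", b)):
        bad = set(seq) - _PROTEIN_ALPHABET
        if bad:
            raise InputError(f"{name} sequence contains non-amino-acid symbols {sorted(bad)}")
    aligner = _aligner(thresholds)
    alignment = aligner.align(a, b)[0]  # first co-optimal alignment; deterministic
    row_a, row_b = str(alignment[0]), str(alignment[1])
    matrix = aligner.substitution_matrix
    length = len(row_a)
    identical = similar = gaps = 0
    for ca, cb in zip(row_a, row_b):
        if ca == "-" or cb == "-":
            gaps += 1
            continue
        if ca == cb:
            identical += 1
        if matrix[ca, cb] > 0:
            similar += 1
    identity = 100.0 * identical / length
    similarity = 100.0 * similar / length
    return identity, similarity, gaps, (row_a, row_b), float(alignment.score)


def compare_proteins(
    gene_id: str,
    test_protein: str,
    ref_protein: str,
    thresholds: QcThresholds | None = None,
    flags: TranslationFlags | None = None,
) -> ProteinComparison:
    identity, similarity, gaps, _, _ = global_align(test_protein, ref_protein, thresholds)
    return ProteinComparison(
        gene_id=gene_id,
        len_test=len(test_protein),
        len_ref=len(ref_protein),
        identity=identity,
        similarity=similarity,
        gap_positions=gaps,
        flags=flags or TranslationFlags(),
    )


def evaluate_model(
    comparison: ProteinComparison, gene_class: str = "default"
) -> str:
    """Accept/flag decision for one model.

    accept iff the length difference is strictly below max_len_diff AND the
    similarity is strictly above min_similarity AND translation raised no
    internal-stop flag; everything else is flag_for_review (manual
    inspection), never a silent rejection.
    """
    thr = GENE_CLASS_THRESHOLDS.get(gene_class)
    if thr is None:
        raise InputError(f"unknown gene class '{gene_class}'")
    ok = (
        abs(comparison.len_test - comparison.len_ref) < thr.max_len_diff
        and comparison.similarity > thr.min_similarity
        and not comparison.flags.internal_stop
    )
    comparison.decision = "accept" if ok else "flag_for_review"
    return comparison.decision


def _exon_cds_overlap(model: GeneModel, exon: tuple[int, int]) -> bool:
    s, e = exon
    return any(cs <= e and ce >= s for cs, ce, _ in model.cds)


def merge_terminal_exons(
    model: GeneModel,
    genome: dict[str, SeqRecord] | None = None,
    ref_terminal_exon_len: int | None = None,
    thresholds: QcThresholds | None = None,
) -> GeneModel:
    """3'-end repair for models whose terminal exon was annotated short.

    When the two 3'-most exons are non-coding past the CDS and lie within
    ``terminal_merge_max`` bp of each other, they and the intervening
    sequence become one terminal exon (automated spliced aligners often
    fragment the poorly conserved 3' UTR).  CDS intervals are untouched.
    Optionally, with a reference terminal-exon length, the terminal exon is
    extended by length projection to cover the reference 3' UTR when the
    downstream genomic sequence is gap-free.
    """
    thresholds = thresholds or QcThresholds()
    m = GeneModel(
        transcript_id=model.transcript_id, gene_id=model.gene_id,
        gene_name=model.gene_name, gene_description=model.gene_description,
        chrom=model.chrom, strand=model.strand,
        exons=list(model.exons), cds=list(model.cds),
    )
    if len(m.exons) >= 2:
        if m.strand == "+":
            penult, term = m.exons[-2], m.exons[-1]
            penult_3p_noncoding = not m.cds or max(e for _, e, _ in m.cds) < penult[1]
            gap = term[0] - penult[1] - 1
            terminal_noncoding = not _exon_cds_overlap(m, term)
            if penult_3p_noncoding and terminal_noncoding and 0 <= gap <= thresholds.terminal_merge_max:
                m.exons = m.exons[:-2] + [(penult[0], term[1])]
        else:
            term, penult = m.exons[0], m.exons[1]
            penult_3p_noncoding = not m.cds or min(s for s, _, _ in m.cds) > penult[0]
            gap = penult[0] - term[1] - 1
            terminal_noncoding = not _exon_cds_overlap(m, term)
            if penult_3p_noncoding and terminal_noncoding and 0 <= gap <= thresholds.terminal_merge_max:
                m.exons = [(term[0], penult[1])] + m.exons[2:]
    if ref_terminal_exon_len is not None and genome is not None:
        chrom_len = len(genome[m.chrom].sequence)
        if m.strand == "+":
            s, e = m.exons[-1]
            want = s + ref_terminal_exon_len - 1
            if want > e:
                new_e = min(want, chrom_len)
                if "N" not in genome[m.chrom].sequence[e:new_e]:
                    m.exons[-1] = (s, new_e)
        else:
            s, e = m.exons[0]
            want = e - ref_terminal_exon_len + 1
            if want < s:
                new_s = max(want, 1)
                if "N" not in genome[m.chrom].sequence[new_s - 1 : s - 1]:
                    m.exons[0] = (new_s, e)
    return m


@dataclass
class GtfIssue:
    transcript_id: str
    kind: str  # cds_without_exon | overlapping_exons | strand_inconsistent | duplicate_transcript
    detail: str = ""


def validate_gtf(models: Sequence[GeneModel]) -> tuple[list[GeneModel], list[GtfIssue]]:
    """Structural GTF checks: every CDS contained in an exon, no overlapping
    exons, and duplicate transcripts (identical chrom/strand/exons/CDS)
    collapsed to the lexicographically smallest transcript id."""
    issues: list[GtfIssue] = []
    clean: list[GeneModel] = []
    for m in models:
        ok = True
        for s, e, _ in m.cds:
            if not any(xs <= s and e <= xe for xs, xe in m.exons):
                issues.append(GtfIssue(m.transcript_id, "cds_without_exon",
                                       f"CDS {s}-{e} not contained in any exon"))
                ok = False
        ex = sorted(m.exons)
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if s2 <= e1:
                issues.append(GtfIssue(m.transcript_id, "overlapping_exons",
                                       f"exons {s1}-{e1} and {s2}-{e2} overlap"))
                ok = False
        if m.strand not in ("+", "-"):
            issues.append(GtfIssue(m.transcript_id, "strand_inconsistent",
                                   f"strand '{m.strand}'"))
            ok = False
        if ok:
            clean.append(m)
    # duplicate removal among structurally clean models
    by_structure: dict[tuple, list[GeneModel]] = {}
    for m in clean:
        by_structure.setdefault(m.structure_key(), []).append(m)
    kept: list[GeneModel] = []
    for group in by_structure.values():
        group.sort(key=lambda m: m.transcript_id)
        kept.append(group[0])
        for dup in group[1:]:
            issues.append(GtfIssue(dup.transcript_id, "duplicate_transcript",
                                   f"duplicate of {group[0].transcript_id}; removed"))
    kept.sort(key=lambda m: (m.chrom, m.span()[0], m.transcript_id))
    return kept, issues


def summarize_comparisons(
    comparisons: Sequence[ProteinComparison],
) -> tuple[float, float, float, int]:
    """Arithmetic means of identity, similarity and gap count, plus n —
    the summary-table semantics (gaps is a mean count of gap characters,
    not a percentage)."""
    if not comparisons:
        raise InputError("cannot summarize zero comparisons")
    return (
        float(np.mean([c.identity for c in comparisons])),
        float(np.mean([c.similarity for c in comparisons])),
        float(np.mean([c.gap_positions for c in comparisons])),
        len(comparisons),
    )
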