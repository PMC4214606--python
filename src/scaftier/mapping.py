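"""Seed-and-extend DNA mapping.

A light ungapped mapper that places query sequences (reference-species
exons, mapping markers, reference-chromosome tiling segments, mRNA reads)
onto scaffolds.  Exact k-mer seeds are looked up in a scaffold index,
chained per (scaffold, strand, diagonal), and the dominant diagonal is
scored by direct string comparison over the full overlap of the query with
the scaffold.  The mapper is deliberately ungapped: its job is to recover
loci and orientation for ordering decisions, not base-perfect alignments;
indel-containing use cases are served by importing an external alignment
table instead.

Best-hit policy mirrors single-target alignment reporting: one best
alignment per query, ties broken deterministically.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ConfigError, InputError
from .seqio import SeqRecord, revcomp
from .tables import AlnHit

MIN_K = 8


@dataclass
class KmerIndex:
    """Exact-match k-mer index over scaffold forward strands.

    Postings map a k-mer string to ``[(scaffold_idx, offset), ...]`` with
    0-based offsets.  Only forward-strand k-mers are stored; minus-strand
    hits are found by querying the reverse complement of the query, so both
    strands are covered without doubling the index.  ``stride`` subsamples
    indexed positions (every ``stride``-th offset) to bound memory on large
    scaffold sets; queries still probe every position.
    """

    k: int
    stride: int
    ids: list[str]
    seqs: list[str]
    postings: dict[str, list[tuple[int, int]]]
    _id_to_idx: dict[str, int] = field(default_factory=dict)

    def scaffold(self, scaffold_id: str) -> str:
        return self.seqs[self._id_to_idx[scaffold_id]]

    def scaffold_length(self, scaffold_id: str) -> int:
        return len(self.scaffold(scaffold_id))


def build_index(scaffolds: Sequence[SeqRecord], k: int = 15, stride: int = 1) -> KmerIndex:
    """Index every ``stride``-th k-mer of each scaffold's forward strand."""
    if k < MIN_K:
        raise ConfigError(f"k={k} too small (minimum {MIN_K})")
    if stride < 1:
        raise ConfigError("stride must be >= 1")
    postings: dict[str, list[tuple[int, int]]] = defaultdict(list)
    ids, seqs = [], []
    for idx, rec in enumerate(scaffolds):
        ids.append(rec.id)
        seqs.append(rec.sequence)
        seq = rec.sequence
        for off in range(0, len(seq) - k + 1, stride):
            kmer = seq[off : off + k]
            if "N" not in kmer:
                postings[kmer].append((idx, off))
    return KmerIndex(
        k=k,
        stride=stride,
        ids=ids,
        seqs=seqs,
        postings=dict(postings),
        _id_to_idx={rid: i for i, rid in enumerate(ids)},
    )


def _seed_diagonals(query: str, index: KmerIndex) -> dict[tuple[int, int], list[int]]:
    """Collect seed counts per (scaffold_idx, diagonal) for one orientation.

    The diagonal is ``scaffold_offset - query_offset``: all seeds of a
    gap-free co-linear match share it.
    """
    k = index.k
    postings = index.postings
    diags: dict[tuple[int, int], list[int]] = defaultdict(list)
    for qoff in range(0, len(query) - k + 1):
        hits = postings.get(query[qoff : qoff + k])
        if hits:
            for sidx, soff in hits:
                diags[(sidx, soff - qoff)].append(qoff)
    return diags


def _score_diagonal(query: str, scaffold: str, diag: int) -> tuple[int, int, int, int] | None:
    """Compare query to scaffold along one diagonal.

    Returns (q_lo, q_hi, matches, length) in 0-based half-open query
    coordinates over the part of the query that overlaps the scaffold, or
    None if the overlap is empty.
    """
    q_lo = max(0, -diag)
    q_hi = min(len(query), len(scaffold) - diag)
    if q_hi <= q_lo:
        return None
    qseg = query[q_lo:q_hi]
    sseg = scaffold[q_lo + diag : q_hi + diag]
    matches = sum(a == b for a, b in zip(qseg, sseg))
    return q_lo, q_hi, matches, q_hi - q_lo


def map_sequence(
    query: SeqRecord,
    index: KmerIndex,
    min_identity: float = 95.0,
    min_cov: float = 0.5,
    min_chain_seeds: int = 2,
) -> list[AlnHit]:
    """Map one DNA query against the index; hits sorted by score descending.

    Seeds are grouped per (scaffold, strand, diagonal); a diagonal needs at
    least ``min_chain_seeds`` seeds (1 when the query is shorter than 2k,
    where two disjoint seeds cannot fit) and is then scored ungapped over
    the full query/scaffold overlap.  Hits below ``min_identity`` percent
    or covering less than ``min_cov`` of the query are dropped.  The score
    is the number of matching bases.
    """
    qseq = query.sequence
    need = min_chain_seeds if len(qseq) >= 2 * index.k else 1
    hits: list[AlnHit] = []
    best_per_scaffold: dict[tuple[int, str], tuple] = {}
    for strand, seq in (("+", qseq), ("-", revcomp(qseq))):
        for (sidx, diag), qoffs in _seed_diagonals(seq, index).items():
            if len(qoffs) < need:
                continue
            scored = _score_diagonal(seq, index.seqs[sidx], diag)
            if scored is None:
                continue
            q_lo, q_hi, matches, length = scored
            key = (sidx, strand)
            prev = best_per_scaffold.get(key)
            if prev is None or matches > prev[2]:
                best_per_scaffold[key] = (q_lo, q_hi, matches, length, diag)
    for (sidx, strand), (q_lo, q_hi, matches, length, diag) in best_per_scaffold.items():
        identity = 100.0 * matches / length
        if identity < min_identity or length < min_cov * len(qseq):
            continue
        s_lo, s_hi = q_lo + diag, q_hi + diag  # 0-based half-open on scaffold
        if strand == "+":
            hit = AlnHit(
                query_id=query.id,
                target_id=index.ids[sidx],
                q_start=q_lo + 1,
                q_end=q_hi,
                t_start=s_lo + 1,
                t_end=s_hi,
                aln_len=length,
                matches=matches,
                identity=round(identity, 2),
                score=float(matches),
            )
        else:
            # coordinates were computed on revcomp(query); mirror back:
            # query range maps to [len-q_hi, len-q_lo) on the original query,
            # and the scaffold range is reported descending (minus strand).
            n = len(qseq)
            hit = AlnHit(
                query_id=query.id,
                target_id=index.ids[sidx],
                q_start=n - q_hi + 1,
                q_end=n - q_lo,
                t_start=s_hi,
                t_end=s_lo + 1,
                aln_len=length,
                matches=matches,
                identity=round(identity, 2),
                score=float(matches),
            )
        hits.append(hit)
    hits.sort(key=lambda h: (-h.score, -h.identity, -h.aln_len, h.target_id))
    return hits


def best_hit(hits: Sequence[AlnHit]) -> AlnHit | None:
    """Single best alignment: highest score, ties broken by higher identity,
    longer alignment, then lexicographically smallest target id."""
    if not hits:
        return None
    return min(hits, key=lambda h: (-h.score, -h.identity, -h.aln_len, h.target_id))


# ---------------------------------------------------------------------------
# Exon evidence
# ---------------------------------------------------------------------------

@dataclass
class ExonMeta:
    """One reference exon's bookkeeping from the metadata TSV."""

    exon_id: str
    gene_id: str
    exon_index: int  # 1-based order along the reference transcript
    ref_chrom: str
    ref_start: int  # 1-based inclusive on the reference chromosome
    ref_end: int


@dataclass
class ExonEvidence:
    """Best placement of one reference exon on the scaffold set — the
    currency of the gene-contiguity rule."""

    gene_id: str
    exon_index: int
    hit: AlnHit | None
    ref_chrom: str
    ref_pos: int  # representative bp on the reference chromosome


def read_exon_metadata(path: str | Path) -> dict[str, ExonMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    metas: dict[str, ExonMeta] = {}
    for _, row in df.iterrows():
        metas[row["exon_id"]] = ExonMeta(
            exon_id=row["exon_id"],
            gene_id=row["gene_id"],
            exon_index=int(row["exon_index"]),
            ref_chrom=row["ref_chrom"],
            ref_start=int(row["ref_start"]),
            ref_end=int(row["ref_end"]),
        )
    return metas


def write_exon_metadata(metas: Iterable[ExonMeta], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "exon_id": m.exon_id,
                "gene_id": m.gene_id,
                "exon_index": m.exon_index,
                "ref_chrom": m.ref_chrom,
                "ref_start": m.ref_start,
                "ref_end": m.ref_end,
            }
            for m in metas
        ]
    ).to_csv(path, sep="\t", index=False)


def map_exons(
    exon_records: Sequence[SeqRecord] | None,
    gene_metadata: dict[str, ExonMeta],
    index: KmerIndex | None = None,
    external_table: Sequence[AlnHit] | None = None,
    min_identity: float = 95.0,
    min_cov: float = 0.5,
) -> list[ExonEvidence]:
    """One :class:`ExonEvidence` per exon in the metadata.

    Either maps ``exon_records`` with the internal mapper, or consumes a
    precomputed alignment table (the production path when an external
    aligner was run); in both cases the best hit per exon is kept.
    """
    by_exon: dict[str, list[AlnHit]] = defaultdict(list)
    if external_table is not None:
        for hit in external_table:
            if hit.query_id not in gene_metadata:
                raise InputError(f"alignment query '{hit.query_id}' not in exon metadata")
            by_exon[hit.query_id].append(hit)
    else:
        if index is None or exon_records is None:
            raise InputError("map_exons needs either an index plus exon records, or an external table")
        for rec in exon_records:
            if rec.id not in gene_metadata:
                raise InputError(f"exon record '{rec.id}' not in exon metadata")
            by_exon[rec.id] = map_sequence(rec, index, min_identity, min_cov)
    evidence = []
    for exon_id, meta in gene_metadata.items():
        evidence.append(
            ExonEvidence(
                gene_id=meta.gene_id,
                exon_index=meta.exon_index,
                hit=best_hit(by_exon.get(exon_id, [])),
                ref_chrom=meta.ref_chrom,
                ref_pos=(meta.ref_start + meta.ref_end) // 2,
            )
        )
    return evidence


def assess_mappability(
    reads: Sequence[SeqRecord],
    index: KmerIndex,
    min_identity: float = 90.0,
    min_cov: float = 0.9,
) -> float:
    """Percent of reads with at least one passing hit (assembly completeness
    proxy: reads drawn from sequence absent from the assembly cannot map)."""
    if not reads:
        raise InputError("cannot compute a mapping rate over zero reads")
    mapped = sum(
        1 for r in reads if map_sequence(r, index, min_identity, min_cov)
    )
    return 100.0 * mapped / len(reads)
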