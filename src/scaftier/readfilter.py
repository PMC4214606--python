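"""Genomic-contamination filter for mRNA reads.

mRNA libraries contain a fraction of genomic (intronic/intergenic) reads.
Aligning reads against a curated transcript set separates the two: a true
transcriptomic read aligns over almost its whole length, while a genomic
read aligns partially or not at all.  The filter keeps a read only when
its best alignment length exceeds a per-read-length threshold — 70 bp for
76-bp reads and 90 bp for 100-bp reads ("an alignment length of 70 bp or
less" is filtered out; likewise 90 bp for 100-bp reads).  In paired-end
mode a read is also removed when its mate is removed, keeping the two
files synchronized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import InputError, ValidationError
from .mapping import best_hit
from .seqio import SeqRecord
from .tables import AlnHit


@dataclass
class FilterPolicy:
    """Keep a read iff best alignment length > threshold(read length).

    Lengths without an explicit threshold fall back to
    ``floor(fallback_fraction * read_length)`` — an interpolation of the
    two literal defaults (76->70 is 0.921, 100->90 is 0.90).
    """

    thresholds: dict[int, int] = field(default_factory=lambda: {76: 70, 100: 90})
    fallback_fraction: float = 0.90
    paired: bool = False

    def __post_init__(self) -> None:
        for read_len, thr in self.thresholds.items():
            if thr >= read_len:
                raise ValidationError(
                    f"threshold {thr} must be below its read length {read_len}"
                )
        if not (0 < self.fallback_fraction < 1):
            raise ValidationError("fallback_fraction must be in (0, 1)")

    def threshold(self, read_length: int) -> int:
        if read_length in self.thresholds:
            return self.thresholds[read_length]
        return int(self.fallback_fraction * read_length)


@dataclass
class FilterSummary:
    n_input: int
    n_kept: int
    n_removed: int
    n_mate_removed: int = 0  # removed only because the mate failed


def best_alignment_lengths(hits: Iterable[AlnHit]) -> dict[str, int]:
    """Best-hit alignment length per read id from an alignment table."""
    grouped: dict[str, list[AlnHit]] = {}
    for h in hits:
        grouped.setdefault(h.query_id, []).append(h)
    return {rid: best_hit(hs).aln_len for rid, hs in grouped.items()}


def _core_id(read_id: str) -> str:
    """Mate-pair key: strip a trailing /1 or /2."""
    if len(read_id) > 2 and read_id[-2] == "/" and read_id[-1] in "12":
        return read_id[:-2]
    return read_id


def decide_reads(
    reads: Sequence[SeqRecord],
    aln_lengths: Mapping[str, int],
    policy: FilterPolicy,
) -> dict[str, bool]:
    """Per-read keep/remove decision (True = keep); a missing alignment
    counts as length 0."""
    decisions = {}
    for r in reads:
        length = aln_lengths.get(r.id, 0)
        decisions[r.id] = length > policy.threshold(len(r.sequence))
    return decisions


def synchronize_pairs(
    decisions: Mapping[str, bool], policy: FilterPolicy
) -> tuple[dict[str, bool], int]:
    """In paired mode a pair survives only if both mates survive.

    Pairing is derived from read ids (``/1``/``/2`` suffixes, or identical
    core ids across the two input files).  Returns (adjusted decisions,
    number of reads removed solely because of their mate).  Unpaired ids in
    paired mode are an error.
    """
    if not policy.paired:
        return dict(decisions), 0
    by_core: dict[str, list[str]] = {}
    for rid in decisions:
        by_core.setdefault(_core_id(rid), []).append(rid)
    orphans = sorted(core for core, rids in by_core.items() if len(rids) != 2)
    if orphans:
        raise InputError(f"unpaired read ids in paired mode: {orphans[:10]}")
    adjusted = dict(decisions)
    mate_removed = 0
    for rids in by_core.values():
        keep = all(decisions[r] for r in rids)
        for r in rids:
            if decisions[r] and not keep:
                mate_removed += 1
            adjusted[r] = keep
    return adjusted, mate_removed


def filter_reads(
    reads: Sequence[SeqRecord],
    aln_lengths: Mapping[str, int],
    policy: FilterPolicy | None = None,
) -> tuple[list[SeqRecord], list[str], FilterSummary]:
    """Apply the contamination filter.

    ``aln_lengths`` maps read id -> best alignment length against the
    transcript set (absent = 0).  Alignment ids that match no read are an
    error (orphan alignments point at an id mismatch between the FASTQ and
    the table).  Returns (kept reads in input order, removed ids, summary).
    """
    policy = policy or FilterPolicy()
    read_ids = {r.id for r in reads}
    orphans = sorted(set(aln_lengths) - read_ids)
    if orphans:
        raise InputError(f"alignment ids with no matching read: {orphans[:10]}")
    decisions = decide_reads(reads, aln_lengths, policy)
    decisions, mate_removed = synchronize_pairs(decisions, policy)
    kept = [r for r in reads if decisions[r.id]]
    removed = [r.id for r in reads if not decisions[r.id]]
    summary = FilterSummary(
        n_input=len(reads),
        n_kept=len(kept),
        n_removed=len(removed),
        n_mate_removed=mate_removed,
    )
    return kept, removed, summary
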