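"""Assembly statistics: contig decomposition and N50.

A contig is a maximal run of non-N sequence; scaffolds are contigs joined
by N-gaps.  N50 is the length L such that contigs of length >= L together
contain at least half of the total contig bases.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .errors import InputError
from .seqio import SeqRecord


@dataclass
class AssemblyStats:
    n_contigs: int
    total_bp: int
    max_contig: int
    mean_contig: float
    contig_n50: int
    scaffold_n50: int


def n50(lengths: Iterable[int]) -> int:
    arr = np.sort(np.fromiter(lengths, dtype=np.int64))[::-1]
    if arr.size == 0:
        return 0
    total = int(arr.sum())
    cum = np.cumsum(arr)
    idx = int(np.searchsorted(cum, total / 2))
    return int(arr[idx])


def contig_lengths(record: SeqRecord, gap_min_n: int = 1) -> list[int]:
    """Lengths of maximal non-gap runs; a gap is a run of >= ``gap_min_n`` Ns."""
    if gap_min_n < 1:
        raise InputError("gap_min_n must be >= 1")
    gap_re = re.compile("N{%d,}" % gap_min_n)
    return [len(part) for part in gap_re.split(record.sequence) if part]


def compute_assembly_stats(records: Iterable[SeqRecord], gap_min_n: int = 1) -> AssemblyStats:
    scaffold_lens: list[int] = []
    contigs: list[int] = []
    for rec in records:
        scaffold_lens.append(len(rec.sequence))
        contigs.extend(contig_lengths(rec, gap_min_n))
    if not contigs:
        raise InputError("no contigs: empty record set or all-N sequences")
    total = sum(contigs)
    return AssemblyStats(
        n_contigs=len(contigs),
        total_bp=total,
        max_contig=max(contigs),
        mean_contig=total / len(contigs),
        contig_n50=n50(contigs),
        scaffold_n50=n50(scaffold_lens),
    )
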