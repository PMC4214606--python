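"""The gene-contiguity rule and chimeric-scaffold breaking.

A correctly assembled scaffold carries each gene's exons on one scaffold,
in transcript order, on one strand.  Evidence that violates this points at
a misassembly.  Scaffolds whose genes vote for different chromosomes along
their length are chimeric joins and are broken apart; single-gene
disagreements and within-scaffold inversions are reported for curation but
not auto-broken, since breaking is only needed to place genomic segments
on the right chromosome.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import ScaftierError, ValidationError
from .mapping import ExonEvidence
from .seqio import SeqRecord


@dataclass
class Violation:
    gene_id: str
    kind: str  # split_gene | order_violation | orientation_violation | chimeric_scaffold
    scaffolds: list[str]
    detail: str = ""


@dataclass
class Breakpoint:
    scaffold_id: str
    coordinate: int  # 0-based; the break occurs before this base
    reason: str
    evidence_left: str
    evidence_right: str


@dataclass
class GeneCluster:
    """A maximal run of same-chromosome gene evidence along a scaffold."""

    chrom: str
    start: int  # 0-based half-open extent on the scaffold
    end: int
    genes: list[str] = field(default_factory=list)


def _group_by_gene(evidence: Iterable[ExonEvidence]) -> dict[str, list[ExonEvidence]]:
    by_gene: dict[str, list[ExonEvidence]] = defaultdict(list)
    for ev in evidence:
        by_gene[ev.gene_id].append(ev)
    return by_gene


def detect_violations(evidence: Iterable[ExonEvidence]) -> list[Violation]:
    """Check each gene with >= 2 placed exons against the contiguity rule.

    split_gene: exons hit >= 2 scaffolds.  orientation_violation: mixed
    strands on one scaffold.  order_violation: exon start positions are not
    strictly monotonic in transcript order (increasing on '+', decreasing
    on '-').  Input order is irrelevant; output is sorted by gene id.
    """
    violations: list[Violation] = []
    for gene_id, evs in sorted(_group_by_gene(evidence).items()):
        placed = sorted((e for e in evs if e.hit is not None), key=lambda e: e.exon_index)
        if len(placed) < 2:
            continue
        scaffolds = sorted({e.hit.target_id for e in placed})
        if len(scaffolds) > 1:
            violations.append(
                Violation(gene_id, "split_gene", scaffolds,
                          f"exons on {len(scaffolds)} scaffolds")
            )
            continue
        strands = {e.hit.strand for e in placed}
        if len(strands) > 1:
            violations.append(
                Violation(gene_id, "orientation_violation", scaffolds, "mixed exon strands")
            )
            continue
        starts = [e.hit.t_start for e in placed]
        strand = strands.pop()
        ordered = (
            all(a < b for a, b in zip(starts, starts[1:]))
            if strand == "+"
            else all(a > b for a, b in zip(starts, starts[1:]))
        )
        if not ordered:
            violations.append(
                Violation(gene_id, "order_violation", scaffolds,
                          f"exon starts {starts} not monotonic on strand {strand}")
            )
    return violations


def detect_chimeras(
    evidence: Iterable[ExonEvidence],
    gene_chrom_votes: dict[str, str],
    min_run_genes: int = 2,
) -> tuple[dict[str, list[GeneCluster]], list[Violation]]:
    """Find scaffolds whose gene evidence clusters into runs voting for
    different chromosomes.

    Genes are positioned on their scaffold by the midpoint of their exon
    hits and scanned in scaffold order; maximal runs of equal chromosome
    vote become clusters.  Runs shorter than ``min_run_genes`` do not
    trigger a break on their own (single interleaved foreign genes are a
    curation case, not an automatic break) — they are reported as
    chimeric_scaffold violations and absorbed into their neighbourhood.
    Returns (flagged scaffold -> ordered clusters, violations).
    """
    per_scaffold: dict[str, dict[str, list[int]]] = defaultdict(lambda: defaultdict(list))
    for ev in evidence:
        if ev.hit is None or ev.gene_id not in gene_chrom_votes:
            continue
        per_scaffold[ev.hit.target_id][ev.gene_id].append(ev.hit.t_lo - 1)
        per_scaffold[ev.hit.target_id][ev.gene_id].append(ev.hit.t_hi)

    flagged: dict[str, list[GeneCluster]] = {}
    violations: list[Violation] = []
    for scaffold_id, genes in sorted(per_scaffold.items()):
        placed = sorted(
            ((min(pos), max(pos), gid, gene_chrom_votes[gid]) for gid, pos in genes.items()),
            key=lambda t: (t[0] + t[1]) / 2,
        )
        # maximal runs of equal chromosome vote
        runs: list[GeneCluster] = []
        for lo, hi, gid, chrom in placed:
            if runs and runs[-1].chrom == chrom:
                runs[-1].end = max(runs[-1].end, hi)
                runs[-1].genes.append(gid)
            else:
                runs.append(GeneCluster(chrom, lo, hi, [gid]))
        if len(runs) < 2:
            continue
        # short runs: report, then absorb so they cannot trigger a break
        kept: list[GeneCluster] = []
        for run in runs:
            if len(run.genes) < min_run_genes:
                violations.append(
                    Violation(
                        run.genes[0],
                        "chimeric_scaffold",
                        [scaffold_id],
                        f"single-gene {run.chrom} evidence inside {scaffold_id}; "
                        "not auto-broken, flagged for curation",
                    )
                )
                continue
            if kept and kept[-1].chrom == run.chrom:
                kept[-1].end = max(kept[-1].end, run.end)
                kept[-1].genes.extend(run.genes)
            else:
                kept.append(run)
        if len(kept) >= 2:
            flagged[scaffold_id] = kept
    return flagged, violations


def _longest_n_run(seq: str, lo: int, hi: int) -> tuple[int, int] | None:
    """Longest run of Ns strictly inside [lo, hi); ties broken leftmost."""
    best = None
    for m in re.finditer("N+", seq[lo:hi]):
        if best is None or (m.end() - m.start()) > (best[1] - best[0]):
            best = (lo + m.start(), lo + m.end())
    return best


def propose_breakpoints(
    clusters_by_scaffold: dict[str, list[GeneCluster]],
    scaffolds: dict[str, SeqRecord],
) -> list[Breakpoint]:
    """One break between each adjacent cluster pair.

    The break coordinate is the midpoint of the longest N-run strictly
    between the clusters (assembly gaps are where joins were made), falling
    back to the midpoint of the inter-cluster interval when the gap is
    gap-free.
    """
    breakpoints: list[Breakpoint] = []
    for scaffold_id, clusters in sorted(clusters_by_scaffold.items()):
        seq = scaffolds[scaffold_id].sequence
        for left, right in zip(clusters, clusters[1:]):
            if right.start < left.end:
                raise ScaftierError(
                    f"{scaffold_id}: overlapping evidence clusters "
                    f"({left.chrom} ends {left.end}, {right.chrom} starts {right.start})"
                )
            n_run = _longest_n_run(seq, left.end, right.start)
            if n_run is not None:
                coord = (n_run[0] + n_run[1]) // 2
                reason = f"midpoint of longest N-run {n_run[0]}-{n_run[1]}"
            else:
                coord = (left.end + right.start) // 2
                reason = "midpoint of inter-cluster interval (no N-run)"
            breakpoints.append(
                Breakpoint(scaffold_id, coord, reason, left.chrom, right.chrom)
            )
    return breakpoints


def apply_breaks(
    scaffolds: Sequence[SeqRecord], breakpoints: Sequence[Breakpoint]
) -> tuple[list[SeqRecord], list[dict]]:
    """Split scaffolds at the given coordinates.

    Parts are named ``<id>.1``, ``<id>.2``, ... left to right; the
    provenance table maps each part to its parent interval (1-based
    inclusive) so that concatenating the parts reproduces the parent
    byte-exactly.  Unbroken scaffolds pass through unchanged.
    """
    by_scaffold: dict[str, list[int]] = defaultdict(list)
    for bp in breakpoints:
        by_scaffold[bp.scaffold_id].append(bp.coordinate)
    out: list[SeqRecord] = []
    provenance: list[dict] = []
    for rec in scaffolds:
        coords = sorted(set(by_scaffold.get(rec.id, [])))
        if not coords:
            out.append(rec)
            continue
        for c in coords:
            if not (0 < c < len(rec.sequence)):
                raise ValidationError(
                    f"break coordinate {c} out of range for {rec.id} (length {len(rec.sequence)})"
                )
        bounds = [0, *coords, len(rec.sequence)]
        for i, (lo, hi) in enumerate(zip(bounds, bounds[1:]), 1):
            part_id = f"{rec.id}.{i}"
            out.append(SeqRecord(part_id, rec.sequence[lo:hi], f"part of {rec.id}"))
            provenance.append(
                {"part": part_id, "parent": rec.id, "parent_start": lo + 1, "parent_end": hi}
            )
    return out, provenance
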