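"""Tabular inputs: alignment tables, marker maps, synteny blocks, and the
macaque chromosome-nomenclature table.

Alignment hits use the 12-column tab-separated dialect produced by
``blastn -outfmt 6``: query, target, percent identity, alignment length,
mismatches, gap opens, q_start, q_end, t_start, t_end, e-value, bit score.
Target coordinates with ``t_start > t_end`` encode a minus-strand hit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import InputError, ParseError, ValidationError


@dataclass
class AlnHit:
    """One pairwise alignment, coordinates 1-based inclusive (external
    convention, kept as-is because hits are pass-through currency)."""

    query_id: str
    target_id: str
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    aln_len: int
    matches: int
    identity: float
    score: float

    @property
    def strand(self) -> str:
        return "-" if self.t_start > self.t_end else "+"

    @property
    def t_lo(self) -> int:
        """Smaller target coordinate regardless of strand."""
        return min(self.t_start, self.t_end)

    @property
    def t_hi(self) -> int:
        return max(self.t_start, self.t_end)

    def to_outfmt6_row(self) -> str:
        mism = self.aln_len - self.matches
        return "\t".join(
            [
                self.query_id,
                self.target_id,
                f"{self.identity:.2f}",
                str(self.aln_len),
                str(mism),
                "0",
                str(self.q_start),
                str(self.q_end),
                str(self.t_start),
                str(self.t_end),
                "1e-30",
                f"{self.score:g}",
            ]
        )


def read_aln_table(path: str | Path, dialect: str = "outfmt6") -> list[AlnHit]:
    """Read a 12-column tabular alignment file into :class:`AlnHit` objects."""
    if dialect != "outfmt6":
        raise InputError(f"unknown alignment-table dialect '{dialect}'")
    spath = str(path)
    hits: list[AlnHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise ParseError(f"expected 12 columns, found {len(cols)}", spath, lineno)
            try:
                identity = float(cols[2])
                aln_len = int(cols[3])
                mismatches = int(cols[4])
                q_start, q_end = int(cols[6]), int(cols[7])
                t_start, t_end = int(cols[8]), int(cols[9])
                score = float(cols[11])
            except ValueError as exc:
                raise ParseError(f"non-numeric field: {exc}", spath, lineno) from None
            if not (1 <= q_start <= q_end):
                raise ParseError(f"bad query range {q_start}..{q_end}", spath, lineno)
            hits.append(
                AlnHit(
                    query_id=cols[0],
                    target_id=cols[1],
                    q_start=q_start,
                    q_end=q_end,
                    t_start=t_start,
                    t_end=t_end,
                    aln_len=aln_len,
                    matches=aln_len - mismatches,
                    identity=identity,
                    score=score,
                )
            )
    return hits


def write_aln_table(hits: Iterable[AlnHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(h.to_outfmt6_row() + "\n")


# ---------------------------------------------------------------------------
# Marker maps and synteny blocks
# ---------------------------------------------------------------------------

@dataclass
class Marker:
    """An ordered mapping marker (e.g. from a radiation-hybrid map):
    chromosome plus an integer rank along it; sequence optional when a
    precomputed alignment table is supplied instead."""

    marker_id: str
    chrom: str
    order_index: int
    sequence: str | None = None


@dataclass
class SyntenyBlock:
    """A conserved block: a reference-species interval mapped to a target
    chromosome with an orientation and a rank along that chromosome."""

    ref_chrom: str
    ref_start: int  # 1-based inclusive on the reference
    ref_end: int
    target_chrom: str
    block_orientation: str  # '+' or '-'
    block_order: int

    def contains(self, ref_chrom: str, ref_pos: int) -> bool:
        return self.ref_chrom == ref_chrom and self.ref_start <= ref_pos <= self.ref_end


def read_markers(path: str | Path) -> list[Marker]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"marker_id", "chrom", "order_index"}
    if not required <= set(df.columns):
        raise ParseError(f"marker TSV needs columns {sorted(required)}", str(path))
    markers = []
    seen: set[tuple[str, int]] = set()
    for _, row in df.iterrows():
        order = int(row["order_index"])
        if order < 1:
            raise ValidationError(f"marker {row['marker_id']}: order_index must be >= 1")
        key = (row["chrom"], order)
        if key in seen:
            raise ValidationError(f"duplicate (chrom, order_index) {key}")
        seen.add(key)
        seq = row.get("sequence")
        markers.append(
            Marker(row["marker_id"], row["chrom"], order, None if pd.isna(seq) else seq)
        )
    return markers


def write_markers(markers: Iterable[Marker], path: str | Path) -> None:
    rows = [
        {
            "marker_id": m.marker_id,
            "chrom": m.chrom,
            "order_index": m.order_index,
            "sequence": m.sequence if m.sequence is not None else "",
        }
        for m in markers
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_synteny(path: str | Path) -> list[SyntenyBlock]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    blocks = []
    seen: set[tuple[str, int]] = set()
    for _, row in df.iterrows():
        b = SyntenyBlock(
            ref_chrom=row["ref_chrom"],
            ref_start=int(row["ref_start"]),
            ref_end=int(row["ref_end"]),
            target_chrom=row["target_chrom"],
            block_orientation=row["block_orientation"],
            block_order=int(row["block_order"]),
        )
        if b.ref_start > b.ref_end:
            raise ValidationError(f"synteny block on {b.ref_chrom}: ref_start > ref_end")
        key = (b.target_chrom, b.block_order)
        if key in seen:
            raise ValidationError(f"duplicate block_order {key}")
        seen.add(key)
        blocks.append(b)
    return blocks


def write_synteny(blocks: Iterable[SyntenyBlock], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "ref_chrom": b.ref_chrom,
                "ref_start": b.ref_start,
                "ref_end": b.ref_end,
                "target_chrom": b.target_chrom,
                "block_orientation": b.block_orientation,
                "block_order": b.block_order,
            }
            for b in blocks
        ]
    ).to_csv(path, sep="\t", index=False)


def locate_in_blocks(blocks: list[SyntenyBlock], ref_chrom: str, ref_pos: int) -> SyntenyBlock | None:
    """Find the block containing a reference-chromosome position."""
    for b in blocks:
        if b.contains(ref_chrom, ref_pos):
            return b
    return None


# ---------------------------------------------------------------------------
# Chromosome nomenclature
# ---------------------------------------------------------------------------

NOMENCLATURE_COLUMNS = ("H", "C", "G", "O", "M", "W", "R")


class NomenclatureTable:
    """Cross-species chromosome label table.

    Columns: H human, C chimpanzee, G gorilla, O orangutan, M macaque,
    W an earlier macaque cytogenetic numbering, R an alternative macaque
    numbering.  Each row names the same ancestral chromosome in the seven
    systems; human labels are unique and serve as the natural join key.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in NOMENCLATURE_COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"nomenclature table missing columns {missing}")
        if frame["H"].duplicated().any():
            raise ValidationError("nomenclature H labels must be unique")
        if frame[list(NOMENCLATURE_COLUMNS)].isna().any().any():
            raise ValidationError("nomenclature table has empty cells")
        self.frame = frame.reset_index(drop=True)

    @classmethod
    def bundled(cls) -> "NomenclatureTable":
        """The packaged rhesus-macaque nomenclature table."""
        with resources.files("scaftier.data").joinpath("chromosome_nomenclature.tsv").open() as fh:
            return cls(pd.read_csv(fh, sep="\t", dtype=str))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "NomenclatureTable":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def map(self, label: str, from_col: str, to_col: str) -> str:
        if from_col not in NOMENCLATURE_COLUMNS or to_col not in NOMENCLATURE_COLUMNS:
            raise InputError(f"unknown nomenclature column: {from_col!r} or {to_col!r}")
        rows = self.frame[self.frame[from_col] == label]
        if rows.empty:
            raise InputError(f"label '{label}' not found in column {from_col}")
        return str(rows.iloc[0][to_col])


def map_chromosome_name(
    label: str, from_col: str, to_col: str, table: NomenclatureTable | None = None
) -> str:
    """Translate a chromosome label between naming systems (bundled table by
    default)."""
    if table is None:
        table = NomenclatureTable.bundled()
    return table.map(label, from_col, to_col)
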