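"""AGP v2.0 reading/writing.

An AGP file describes how components (scaffolds and gaps) tile an assembled
object (a chromosome).  Only the two component types the pipeline emits are
supported: ``W`` (WGS component) and ``N`` (gap of known length, type
``scaffold``, ``linkage no``).  The tiling invariant — consecutive rows
abut exactly, part numbers run 1..n — is enforced on read.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .errors import ParseError, ValidationError


@dataclass
class AgpRow:
    object: str
    object_beg: int  # 1-based inclusive
    object_end: int
    part_number: int
    component_type: str  # 'W' or 'N'
    # W fields
    component_id: str | None = None
    component_beg: int | None = None
    component_end: int | None = None
    orientation: str | None = None  # '+' or '-'
    # N fields
    gap_length: int | None = None
    gap_type: str = "scaffold"
    linkage: str = "no"

    def span(self) -> int:
        return self.object_end - self.object_beg + 1


def validate_agp(rows: list[AgpRow]) -> None:
    """Check the tiling invariant per object."""
    by_object: dict[str, list[AgpRow]] = {}
    for r in rows:
        by_object.setdefault(r.object, []).append(r)
    for obj, obj_rows in by_object.items():
        obj_rows.sort(key=lambda r: r.part_number)
        expected_beg = 1
        for i, r in enumerate(obj_rows, 1):
            if r.part_number != i:
                raise ValidationError(f"{obj}: part_numbers not consecutive at part {r.part_number}")
            if r.object_beg != expected_beg:
                kind = "hole" if r.object_beg > expected_beg else "overlap"
                raise ValidationError(
                    f"{obj}: {kind} at object coordinate {expected_beg} (row begins {r.object_beg})"
                )
            if r.component_type == "W":
                comp_span = r.component_end - r.component_beg + 1
                if comp_span != r.span():
                    raise ValidationError(
                        f"{obj} part {i}: component span {comp_span} != object span {r.span()}"
                    )
            elif r.component_type == "N":
                if r.gap_length != r.span():
                    raise ValidationError(
                        f"{obj} part {i}: gap_length {r.gap_length} != object span {r.span()}"
                    )
            else:
                raise ValidationError(f"{obj} part {i}: unsupported component type {r.component_type}")
            expected_beg = r.object_end + 1


def read_agp(path: str | Path) -> list[AgpRow]:
    spath = str(path)
    rows: list[AgpRow] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"expected 9 AGP columns, found {len(cols)}", spath, lineno)
            try:
                base = dict(
                    object=cols[0],
                    object_beg=int(cols[1]),
                    object_end=int(cols[2]),
                    part_number=int(cols[3]),
                    component_type=cols[4],
                )
                if cols[4] == "W":
                    row = AgpRow(
                        **base,
                        component_id=cols[5],
                        component_beg=int(cols[6]),
                        component_end=int(cols[7]),
                        orientation=cols[8],
                    )
                    if row.orientation not in ("+", "-"):
                        raise ParseError(f"bad orientation '{cols[8]}'", spath, lineno)
                elif cols[4] == "N":
                    row = AgpRow(**base, gap_length=int(cols[5]), gap_type=cols[6], linkage=cols[7])
                else:
                    raise ParseError(f"unsupported component type '{cols[4]}'", spath, lineno)
            except ValueError as exc:
                raise ParseError(f"non-numeric AGP field: {exc}", spath, lineno) from None
            rows.append(row)
    validate_agp(rows)
    return rows


def write_agp(rows: Iterable[AgpRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.0\n")
        for r in rows:
            if r.component_type == "W":
                tail = [r.component_id, str(r.component_beg), str(r.component_end), r.orientation]
            else:
                tail = [str(r.gap_length), r.gap_type, r.linkage, "na"]
            fh.write(
                "\t".join(
                    [r.object, str(r.object_beg), str(r.object_end), str(r.part_number),
                     r.component_type, *tail]
                )
                + "\n"
            )
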