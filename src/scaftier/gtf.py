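"""GTF gene models.

A :class:`GeneModel` is one transcript: ordered exon intervals plus CDS
intervals with phase.  External GTF coordinates are 1-based inclusive and
stay that way inside the model (gene models are pass-through currency whose
coordinates are compared against other GTF-derived quantities); sequence
extraction converts at the point of slicing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .errors import ParseError, ValidationError

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


@dataclass
class GeneModel:
    transcript_id: str
    gene_id: str
    gene_name: str = ""
    gene_description: str = ""
    chrom: str = ""
    strand: str = "+"
    exons: list[tuple[int, int]] = field(default_factory=list)  # 1-based inclusive, sorted
    cds: list[tuple[int, int, int]] = field(default_factory=list)  # (start, end, phase)

    def validate(self) -> None:
        """Raise :class:`ValidationError` on structural inconsistency."""
        ex = sorted(self.exons)
        if ex != self.exons:
            raise ValidationError(f"{self.transcript_id}: exons not sorted by start")
        for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
            if s2 <= e1:
                raise ValidationError(f"{self.transcript_id}: overlapping exons")
        for s, e, _ in self.cds:
            if not any(xs <= s and e <= xe for xs, xe in self.exons):
                raise ValidationError(
                    f"{self.transcript_id}: CDS {s}-{e} not contained in any exon"
                )
        if self.cds and self.cds_length() < 3:
            raise ValidationError(f"{self.transcript_id}: total CDS shorter than one codon")

    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e, _ in self.cds)

    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def structure_key(self) -> tuple:
        """Identity of the transcript's shape; used for duplicate removal."""
        return (
            self.chrom,
            self.strand,
            tuple(self.exons),
            tuple((s, e) for s, e, _ in self.cds),
        )


def _parse_attributes(raw: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(raw))


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Parse exon and CDS features of a GTF2.2 file into gene models.

    Features are grouped by ``transcript_id``; attribute order inside the
    ninth column is irrelevant.  Models are returned with exons and CDS
    sorted by start, in order of first appearance of each transcript.
    """
    spath = str(path)
    models: dict[str, GeneModel] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"expected 9 GTF columns, found {len(cols)}", spath, lineno)
            chrom, _source, feature, start, end, _score, strand, frame, attrs_raw = cols
            if feature not in ("exon", "CDS"):
                continue
            attrs = _parse_attributes(attrs_raw)
            tid = attrs.get("transcript_id")
            if not tid:
                raise ParseError(f"{feature} line without transcript_id", spath, lineno)
            gid = attrs.get("gene_id", tid)
            model = models.get(tid)
            if model is None:
                model = GeneModel(
                    transcript_id=tid,
                    gene_id=gid,
                    gene_name=attrs.get("gene_name", ""),
                    gene_description=attrs.get("gene_description", ""),
                    chrom=chrom,
                    strand=strand,
                )
                models[tid] = model
            if model.chrom != chrom or model.strand != strand:
                raise ParseError(
                    f"transcript {tid} spans chrom/strand combinations", spath, lineno
                )
            s, e = int(start), int(end)
            if feature == "exon":
                model.exons.append((s, e))
            else:
                phase = int(frame) if frame in ("0", "1", "2") else 0
                model.cds.append((s, e, phase))
    out = list(models.values())
    for m in out:
        m.exons.sort()
        m.cds.sort()
    return out


def write_gtf(models: Iterable[GeneModel], path: str | Path, source: str = "scaftier") -> None:
    """Write exon and CDS lines, sorted by chromosome then start."""
    lines: list[tuple[str, int, str]] = []
    for m in models:
        attrs = (
            f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}"; '
            f'gene_name "{m.gene_name}"; gene_description "{m.gene_description}";'
        )
        for s, e in m.exons:
            lines.append(
                (m.chrom, s, f"{m.chrom}\t{source}\texon\t{s}\t{e}\t.\t{m.strand}\t.\t{attrs}")
            )
        for s, e, phase in m.cds:
            lines.append(
                (m.chrom, s, f"{m.chrom}\t{source}\tCDS\t{s}\t{e}\t.\t{m.strand}\t{phase}\t{attrs}")
            )
    lines.sort(key=lambda t: (t[0], t[1]))
    with open(path, "w") as fh:
        for _, _, text in lines:
            fh.write(text + "\n")
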