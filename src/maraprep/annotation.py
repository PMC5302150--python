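"""Promoter/transcript annotation: the quantification targets.

The pre-processing pipelines quantify signal per *promoter*. A promoter is a
genomic anchor point (the transcription start site region's center) on a
chromosome; transcripts are exon chains associated many-to-one with promoters.
All coordinates are 0-based half-open (BED convention).

File formats (all tab-separated, ``#`` comment lines allowed):

* promoters — BED4/BED6: ``chrom start end name [score] [strand]``; the
  promoter anchor is ``floor((start+end)/2)``.
* transcripts — one exon per row with header
  ``transcript_id chrom start end strand``.
* associations — header ``transcript_id promoter_id``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)

SUPPORTED_ASSEMBLIES = ("hg18", "hg19", "mm9")


@dataclass(frozen=True)
class Promoter:
    """A promoter anchor: the center of the TSS region, with strand."""

    promoter_id: str
    chrom: str
    anchor: int
    strand: str = "+"

    def __post_init__(self):
        if self.anchor < 0:
            raise ValidationError(f"promoter {self.promoter_id}: negative anchor")
        if not self.chrom:
            raise ValidationError(f"promoter {self.promoter_id}: empty chrom")
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"promoter {self.promoter_id}: bad strand {self.strand!r}"
            )


@dataclass(frozen=True)
class Transcript:
    """A transcript as a sorted chain of non-overlapping exon intervals.

    ``length`` is the summed exon length in bp (mature transcript length),
    the denominator of length-normalized expression (RPKM).
    """

    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    length: int = field(init=False)

    def __post_init__(self):
        prev_end = None
        total = 0
        for start, end in self.exons:
            if start >= end:
                raise ValidationError(
                    f"transcript {self.transcript_id}: empty exon [{start},{end})"
                )
            if prev_end is not None and start < prev_end:
                raise ValidationError(
                    f"transcript {self.transcript_id}: overlapping exons"
                )
            prev_end = end
            total += end - start
        if total == 0:
            raise ValidationError(f"transcript {self.transcript_id}: no exons")
        object.__setattr__(self, "length", total)


@dataclass
class PromoterSet:
    """Ordered promoters; the order defines summary-matrix row order."""

    promoters: list[Promoter]
    assembly: str = "hg19"

    def __post_init__(self):
        if self.assembly not in SUPPORTED_ASSEMBLIES:
            raise ValidationError(
                f"unsupported assembly {self.assembly!r}; "
                f"expected one of {SUPPORTED_ASSEMBLIES}"
            )
        seen = set()
        for p in self.promoters:
            if p.promoter_id in seen:
                raise ValidationError(f"duplicate promoter_id {p.promoter_id!r}")
            seen.add(p.promoter_id)

    def __len__(self):
        return len(self.promoters)

    def __iter__(self):
        return iter(self.promoters)

    @property
    def ids(self) -> list[str]:
        return [p.promoter_id for p in self.promoters]


@dataclass
class AssociationTable:
    """Many-to-one transcript -> promoter mapping."""

    pairs: dict[str, str]

    def promoter_of(self, transcript_id: str) -> str | None:
        return self.pairs.get(transcript_id)

    def transcripts_of(self, promoter_id: str) -> list[str]:
        return [t for t, p in self.pairs.items() if p == promoter_id]

    def validate(self, promoters: PromoterSet, transcripts=None) -> None:
        known = set(promoters.ids)
        for t, p in self.pairs.items():
            if p not in known:
                raise ValidationError(
                    f"association {t} -> {p}: unknown promoter_id {p!r}"
                )
        if transcripts is not None:
            tids = {tr.transcript_id for tr in transcripts}
            missing = set(self.pairs) - tids
            if missing:
                raise ValidationError(
                    f"associations reference unknown transcripts: {sorted(missing)[:5]}"
                )


def _data_lines(path):
    """Yield (line_number, stripped_line) skipping comments and blanks."""
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield i, line


def read_promoters(path, assembly: str = "hg19") -> PromoterSet:
    """Read a promoter BED file; anchor = floor of the interval midpoint.

    Row order is preserved and becomes the summary row order. Strand defaults
    to ``+`` when the file has fewer than 6 columns.
    """
    promoters = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 4:
            raise ParseError(
                f"expected >=4 tab-separated columns, got {len(fields)}",
                path=path, line=lineno,
            )
        chrom, start_s, end_s, name = fields[:4]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise ParseError("non-integer coordinates", path=path, line=lineno)
        if start < 0 or start >= end:
            raise ParseError(
                f"invalid interval [{start},{end})", path=path, line=lineno
            )
        strand = fields[5] if len(fields) >= 6 else "+"
        if strand not in ("+", "-"):
            raise ParseError(f"bad strand {strand!r}", path=path, line=lineno)
        promoters.append(Promoter(name, chrom, (start + end) // 2, strand))
    return PromoterSet(promoters, assembly=assembly)


def write_promoters(pset: PromoterSet, path, half_width: int = 500) -> None:
    """Write promoters as BED6, each as a ``2*half_width`` interval on its anchor."""
    with open(path, "w") as fh:
        for p in pset:
            start = max(0, p.anchor - half_width)
            end = p.anchor + half_width
            fh.write(f"{p.chrom}\t{start}\t{end}\t{p.promoter_id}\t0\t{p.strand}\n")


def read_transcripts(path) -> list[Transcript]:
    """Read the one-exon-per-row transcript table.

    Exons of a transcript are grouped, sorted by start, and abutting exons
    merged; overlapping exons raise. Returns transcripts in first-seen order.
    """
    rows: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}
    order: list[str] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if fields[0] == "transcript_id":  # header
            continue
        if len(fields) < 5:
            raise ParseError(
                f"expected 5 columns, got {len(fields)}", path=path, line=lineno
            )
        tid, chrom, start_s, end_s, strand = fields[:5]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise ParseError("non-integer coordinates", path=path, line=lineno)
        if start >= end:
            raise ParseError(f"exon start {start} >= end {end}", path=path, line=lineno)
        if strand not in ("+", "-"):
            raise ParseError(f"bad strand {strand!r}", path=path, line=lineno)
        if tid not in rows:
            rows[tid] = []
            meta[tid] = (chrom, strand)
            order.append(tid)
        elif meta[tid] != (chrom, strand):
            raise ValidationError(
                f"transcript {tid}: exons on multiple chroms/strands"
            )
        rows[tid].append((start, end))

    out = []
    for tid in order:
        exons = sorted(rows[tid])
        merged: list[list[int]] = []
        for start, end in exons:
            if merged and start < merged[-1][1]:
                raise ValidationError(f"transcript {tid}: overlapping exons")
            if merged and start == merged[-1][1]:  # abutting: merge
                merged[-1][1] = end
            else:
                merged.append([start, end])
        chrom, strand = meta[tid]
        out.append(Transcript(tid, chrom, strand, tuple(tuple(e) for e in merged)))
    return out


def write_transcripts(transcripts, path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tchrom\tstart\tend\tstrand\n")
        for t in transcripts:
            for start, end in t.exons:
                fh.write(f"{t.transcript_id}\t{t.chrom}\t{start}\t{end}\t{t.strand}\n")


def read_associations(path) -> AssociationTable:
    """Read the transcript -> promoter association table."""
    pairs: dict[str, str] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if fields[0] == "transcript_id":  # header
            continue
        if len(fields) < 2:
            raise ParseError("expected 2 columns", path=path, line=lineno)
        tid, pid = fields[:2]
        if tid in pairs and pairs[tid] != pid:
            raise ValidationError(
                f"transcript {tid} associated with both {pairs[tid]} and {pid}"
            )
        pairs[tid] = pid
    return AssociationTable(pairs)


def write_associations(assoc: AssociationTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tpromoter_id\n")
        for tid, pid in assoc.pairs.items():
            fh.write(f"{tid}\t{pid}\n")
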