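"""Genome-aligned read input: BED/BAM reading, sorting and indexing.

Reads are stored column-wise in numpy arrays sorted by
``(chrom lexicographic, start, end)``; "indexing" is an in-memory
per-chromosome offset table over the sorted arrays, which is what downstream
region counting needs. Coordinates are 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd

from .errors import ParseError

logger = logging.getLogger(__name__)


class AlignedRead(NamedTuple):
    chrom: str
    start: int
    end: int
    strand: str


@dataclass
class AlignmentSet:
    """One sample's aligned reads, sorted and chromosome-indexed.

    ``total_reads`` counts the records retained after input filtering
    (for BAM: primary mapped alignments only) and is the library size used
    as the normalization denominator.
    """

    sample_id: str
    chroms: np.ndarray  # object/str array, len n
    starts: np.ndarray  # int64
    ends: np.ndarray  # int64
    strands: np.ndarray  # '+'/'-'
    total_reads: int = -1
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if self.total_reads < 0:
            self.total_reads = len(self.starts)
        self._build_index()

    def _build_index(self):
        """chrom -> (lo, hi) slice bounds into the sorted arrays."""
        self._index = {}
        n = len(self.chroms)
        lo = 0
        while lo < n:
            chrom = self.chroms[lo]
            hi = lo
            while hi < n and self.chroms[hi] == chrom:
                hi += 1
            self._index[chrom] = (lo, hi)
            lo = hi

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def reads(self) -> Iterator[AlignedRead]:
        for i in range(len(self.starts)):
            yield AlignedRead(
                str(self.chroms[i]), int(self.starts[i]), int(self.ends[i]),
                str(self.strands[i]),
            )

    @property
    def chrom_names(self) -> set:
        return set(self._index)

    def chrom_slice(self, chrom: str) -> tuple[int, int]:
        """Slice bounds of ``chrom`` in the sorted arrays; (0, 0) if absent."""
        return self._index.get(chrom, (0, 0))

    def is_sorted(self) -> bool:
        order = np.lexsort((self.ends, self.starts, self.chroms))
        return bool(np.array_equal(order, np.arange(len(order))))


def _make_set(sample_id, chroms, starts, ends, strands, total_reads=None) -> AlignmentSet:
    chroms = np.asarray(chroms, dtype=object)
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    strands = np.asarray(strands, dtype=object)
    order = np.lexsort((ends, starts, chroms))
    return AlignmentSet(
        sample_id=sample_id,
        chroms=chroms[order],
        starts=starts[order],
        ends=ends[order],
        strands=strands[order],
        total_reads=len(starts) if total_reads is None else total_reads,
    )


def read_alignments_bed(path, sample_id: str | None = None) -> AlignmentSet:
    """Read a BED3+ file into a sorted :class:`AlignmentSet`.

    Unknown strand symbols (including the BED '.') are treated as '+' with a
    logged warning; ``start >= end`` is a parse error naming the line.
    """
    if sample_id is None:
        sample_id = _sample_id_from_path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        empty = np.array([], dtype=object)
        return _make_set(sample_id, empty, [], [], empty, total_reads=0)
    if df.shape[1] < 3:
        _locate_bad_coordinates(path)
        raise ParseError("fewer than 3 BED columns", path=path)

    chroms = df.iloc[:, 0].to_numpy(dtype=object)
    try:
        starts = df.iloc[:, 1].to_numpy(dtype=np.int64)
        ends = df.iloc[:, 2].to_numpy(dtype=np.int64)
    except (ValueError, TypeError):
        # slow path to report the offending line
        _locate_bad_coordinates(path)
        raise
    if (starts >= ends).any():
        _locate_bad_coordinates(path)
        raise ParseError("start >= end", path=path)
    if (starts < 0).any():
        raise ParseError("negative start coordinate", path=path)

    if df.shape[1] >= 6:
        strands = df.iloc[:, 5].to_numpy(dtype=object)
        missing = pd.isna(strands)
        known = np.isin(strands, ("+", "-"))
        if (~known & ~missing).any():
            logger.warning(
                "%s: %d records with unknown strand symbol treated as '+'",
                path, int((~known & ~missing).sum()),
            )
        strands = np.where(known, strands, "+")
    else:
        strands = np.full(len(chroms), "+", dtype=object)
    return _make_set(sample_id, chroms, starts, ends, strands)


def _locate_bad_coordinates(path):
    """Re-scan line by line to attach a line number to the first bad record."""
    lineno = 0
    with open(path) as fh:
        for raw in fh:
            lineno += 1
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError("fewer than 3 BED columns", path=path, line=lineno)
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError("non-integer coordinates", path=path, line=lineno)
            if start >= end:
                raise ParseError(
                    f"start {start} >= end {end}", path=path, line=lineno
                )


def read_alignments_bam(path, sample_id: str | None = None) -> AlignmentSet:
    """Read a BAM/SAM file; keep primary mapped alignments only.

    Unmapped, secondary and supplementary records are excluded and do not
    count toward ``total_reads``. The read interval is the reference span
    consumed by the alignment (CIGAR-aware), half-open.
    """
    import pysam

    if sample_id is None:
        sample_id = _sample_id_from_path(path)
    mode = "r" if str(path).endswith(".sam") else "rb"
    chroms, starts, ends, strands = [], [], [], []
    try:
        with pysam.AlignmentFile(str(path), mode, check_sq=False) as bam:
            for rec in bam.fetch(until_eof=True):
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                chroms.append(rec.reference_name)
                starts.append(rec.reference_start)
                ends.append(rec.reference_end)
                strands.append("-" if rec.is_reverse else "+")
    except ValueError as exc:
        raise ParseError(f"cannot read alignment file: {exc}", path=path)
    return _make_set(sample_id, chroms, starts, ends, strands)


def read_alignments(path, fmt: str | None = None, sample_id: str | None = None) -> AlignmentSet:
    """Dispatch on format; inferred from the extension when ``fmt`` is None."""
    if fmt is None:
        name = str(path)
        if name.endswith((".bam", ".sam")):
            fmt = "bam"
        elif name.endswith((".bed", ".bed.gz")):
            fmt = "bed"
        else:
            raise ParseError(f"cannot infer format from extension", path=path)
    if fmt == "bed":
        return read_alignments_bed(path, sample_id=sample_id)
    if fmt == "bam":
        return read_alignments_bam(path, sample_id=sample_id)
    raise ParseError(f"unknown alignment format {fmt!r}", path=path)


def sort_alignments(aset: AlignmentSet) -> AlignmentSet:
    """Re-sort by (chrom, start, end); idempotent, stable for equal keys."""
    return _make_set(
        aset.sample_id, aset.chroms, aset.starts, aset.ends, aset.strands,
        total_reads=aset.total_reads,
    )


def write_alignments_bed(aset: AlignmentSet, path) -> None:
    with open(path, "w") as fh:
        for i in range(len(aset)):
            fh.write(
                f"{aset.chroms[i]}\t{aset.starts[i]}\t{aset.ends[i]}"
                f"\tr{i}\t0\t{aset.strands[i]}\n"
            )


def warn_if_disjoint_chroms(aset: AlignmentSet, annotation_chroms: set) -> bool:
    """Log when alignment and annotation share no chromosome names.

    Exact string comparison ('chr1' != '1'): a disjoint name set silently
    yields all-zero counts, the classic failure mode, hence the warning.
    """
    if len(aset) and annotation_chroms and not (aset.chrom_names & annotation_chroms):
        logger.warning(
            "sample %s: no chromosome name overlap between alignments %s and "
            "annotation %s — all counts will be zero",
            aset.sample_id, sorted(aset.chrom_names)[:3],
            sorted(annotation_chroms)[:3],
        )
        return True
    return False


def _sample_id_from_path(path) -> str:
    import os

    base = os.path.basename(str(path))
    for suffix in (".gz", ".bed", ".bam", ".sam"):
        if base.endswith(suffix):
            base = base[: -len(suffix)]
    return base
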