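"""ChIP-seq chain: count reads in promoter windows, normalize, log-transform.

Each promoter contributes one fixed-width window (default 2 kb) centered on
its anchor; a read increments every window it overlaps by at least 1 bp.
Counts are scaled to counts-per-million of the sample's total included reads
and log2-transformed with a pseudocount.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignments import AlignmentSet
from .annotation import PromoterSet
from .errors import ProcessingError, ValidationError
from .summary import SummaryMatrix

DEFAULT_WINDOW_WIDTH = 2000
DEFAULT_PSEUDOCOUNT = 0.5

COUNT_MODES = ("overlap", "midpoint", "five_prime")


@dataclass(frozen=True)
class WindowSpec:
    """Width of the promoter-centered counting window, in bp; must be even."""

    width: int = DEFAULT_WINDOW_WIDTH

    def __post_init__(self):
        if self.width < 2 or self.width % 2 != 0:
            raise ValidationError(
                f"window width must be even and >= 2, got {self.width}"
            )


@dataclass
class CountMatrix:
    """Raw window counts: promoters x samples, with per-sample library sizes."""

    row_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # (n_promoters, n_samples)
    library_sizes: np.ndarray  # (n_samples,)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.library_sizes = np.asarray(self.library_sizes, dtype=np.int64)
        if self.values.shape != (len(self.row_ids), len(self.sample_ids)):
            raise ValidationError("count matrix shape mismatch")
        if (self.values < 0).any():
            raise ValidationError("negative counts")


def make_windows(
    promoters: PromoterSet, spec: WindowSpec = WindowSpec()
) -> list[tuple[str, int, int]]:
    """One ``[max(0, a - w/2), a + w/2)`` interval per promoter, in set order."""
    half = spec.width // 2
    return [
        (p.chrom, max(0, p.anchor - half), p.anchor + half) for p in promoters
    ]


def count_in_windows(
    reads: AlignmentSet,
    windows: list[tuple[str, int, int]],
    mode: str = "overlap",
) -> np.ndarray:
    """Count reads per window by a sorted sweep; windows may overlap.

    ``overlap`` (default): a read counts toward every window it overlaps by
    >= 1 bp. ``midpoint``: the read's floor-midpoint must fall in the window.
    ``five_prime``: the strand-aware 5' end must fall in the window.
    Exploits the sorted arrays: per chromosome, the number of reads
    overlapping [ws, we) is n - #(start >= we) - #(end <= ws), the two
    excluded sets being disjoint.
    """
    if mode not in COUNT_MODES:
        raise ValidationError(f"unknown count mode {mode!r}")
    counts = np.zeros(len(windows), dtype=np.int64)

    if mode == "overlap":
        # per-chrom: starts already sorted; ends need their own sort
        cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for i, (chrom, ws, we) in enumerate(windows):
            lo, hi = reads.chrom_slice(chrom)
            if lo == hi:
                continue
            if chrom not in cache:
                cache[chrom] = (
                    reads.starts[lo:hi],
                    np.sort(reads.ends[lo:hi]),
                )
            starts, ends_sorted = cache[chrom]
            n = hi - lo
            n_start_ge = n - np.searchsorted(starts, we, side="left")
            n_end_le = np.searchsorted(ends_sorted, ws, side="right")
            counts[i] = n - n_start_ge - n_end_le
        return counts

    # point modes: reduce each read to one genomic position, then bin
    cache_pts: dict[str, np.ndarray] = {}
    for i, (chrom, ws, we) in enumerate(windows):
        lo, hi = reads.chrom_slice(chrom)
        if lo == hi:
            continue
        if chrom not in cache_pts:
            if mode == "midpoint":
                pts = (reads.starts[lo:hi] + reads.ends[lo:hi]) // 2
            else:  # five_prime
                rev = reads.strands[lo:hi] == "-"
                pts = np.where(rev, reads.ends[lo:hi] - 1, reads.starts[lo:hi])
            cache_pts[chrom] = np.sort(pts)
        pts = cache_pts[chrom]
        counts[i] = np.searchsorted(pts, we, side="left") - np.searchsorted(
            pts, ws, side="left"
        )
    return counts


def count_samples(
    samples: list[AlignmentSet],
    promoters: PromoterSet,
    spec: WindowSpec = WindowSpec(),
    mode: str = "overlap",
) -> CountMatrix:
    """Count every sample into one promoters x samples matrix."""
    windows = make_windows(promoters, spec)
    cols = [count_in_windows(s, windows, mode=mode) for s in samples]
    return CountMatrix(
        row_ids=promoters.ids,
        sample_ids=[s.sample_id for s in samples],
        values=np.column_stack(cols) if cols else np.zeros((len(windows), 0)),
        library_sizes=np.array([s.total_reads for s in samples], dtype=np.int64),
    )


def normalize_log(
    counts: CountMatrix, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> SummaryMatrix:
    """log2(CPM + pseudocount) per cell.

    CPM = count * 1e6 / library_size, so doubling every count together with
    the library size leaves the output unchanged.
    """
    for sid, lib in zip(counts.sample_ids, counts.library_sizes):
        if lib == 0:
            raise ProcessingError(
                f"sample {sid}: library size is zero, cannot normalize"
            )
    cpm = counts.values * 1e6 / counts.library_sizes[np.newaxis, :]
    return SummaryMatrix(
        row_ids=list(counts.row_ids),
        sample_ids=list(counts.sample_ids),
        values=np.log2(cpm + pseudocount),
        meta={"data_type": "chipseq", "pseudocount": repr(pseudocount)},
    )
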