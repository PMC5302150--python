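"""RNA-seq chain: exon-overlap read assignment and promoter-level expression.

Inputs are already genome-aligned reads, so "mapping to the transcript set"
is exon-overlap assignment: a read is compatible with a transcript when it
overlaps any of its exons by >= 1 bp on the same chromosome (strand ignored
by default, since library strandedness is unknown to the tool). A read
compatible with k transcripts contributes 1/k to each, which conserves read
mass and is deterministic.

Per-promoter expression sums the length- and depth-normalized transcript
values (RPKM by default) over the promoter's associated transcripts, then
log2-transforms with a pseudocount.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree

from .alignments import AlignmentSet
from .annotation import AssociationTable, PromoterSet, Transcript
from .errors import ProcessingError, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_PSEUDOCOUNT = 0.5
RNA_NORMS = ("rpkm", "tpm")
STRANDED_MODES = ("none", "forward", "reverse")


@dataclass
class TranscriptCounts:
    """Fractional reads per transcript, plus the library size."""

    counts: dict[str, float]
    library_size: int
    assigned_reads: float = field(default=0.0)  # reads hitting >= 1 transcript


def _exon_trees(transcripts: list[Transcript]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for idx, t in enumerate(transcripts):
        tree = trees.setdefault(t.chrom, IntervalTree())
        for start, end in t.exons:
            tree.addi(start, end, idx)
    return trees


def assign_reads(
    reads: AlignmentSet,
    transcripts: list[Transcript],
    stranded: str = "none",
) -> TranscriptCounts:
    """Fractionally assign each read to its exon-compatible transcripts.

    Returns counts keyed by transcript_id; ``assigned_reads`` is the number
    of reads compatible with at least one transcript (the conserved mass:
    the fractional counts sum to it exactly, up to float rounding).
    """
    if stranded not in STRANDED_MODES:
        raise ValidationError(f"unknown strandedness mode {stranded!r}")
    trees = _exon_trees(transcripts)
    counts = np.zeros(len(transcripts), dtype=float)
    assigned = 0
    for chrom, tree in trees.items():
        lo, hi = reads.chrom_slice(chrom)
        for i in range(lo, hi):
            hits = tree.overlap(int(reads.starts[i]), int(reads.ends[i]))
            if not hits:
                continue
            idxs = {h.data for h in hits}
            if stranded != "none":
                read_strand = reads.strands[i]
                want = read_strand if stranded == "forward" else (
                    "-" if read_strand == "+" else "+"
                )
                idxs = {j for j in idxs if transcripts[j].strand == want}
                if not idxs:
                    continue
            w = 1.0 / len(idxs)
            for j in idxs:
                counts[j] += w
            assigned += 1
    return TranscriptCounts(
        counts={t.transcript_id: float(c) for t, c in zip(transcripts, counts)},
        library_size=reads.total_reads,
        assigned_reads=float(assigned),
    )


def promoter_expression(
    counts: TranscriptCounts,
    assoc: AssociationTable,
    transcripts: list[Transcript],
    promoters: PromoterSet,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    norm: str = "rpkm",
) -> np.ndarray:
    """Per-promoter log2 expression, one value per promoter in set order.

    rpkm_t = count_t * 1e9 / (length_t * library_size); a promoter's
    expression is the sum of its transcripts' values (total initiation at
    that promoter), log2(E_p + pseudocount). ``tpm`` rescales the per-kb
    rates to sum to 1e6 instead of dividing by the library size.
    """
    if norm not in RNA_NORMS:
        raise ValidationError(f"unknown rna normalization {norm!r}")
    if counts.library_size == 0:
        raise ProcessingError("library size is zero, cannot normalize")
    lengths = {t.transcript_id: t.length for t in transcripts}

    per_kb = {}
    dropped = 0
    for tid, c in counts.counts.items():
        if tid not in lengths:
            dropped += 1
            continue
        per_kb[tid] = c * 1e3 / lengths[tid]
    if dropped:
        logger.warning("%d counted transcripts missing from transcript set", dropped)

    if norm == "rpkm":
        scale = 1e6 / counts.library_size
    else:  # tpm
        total = sum(per_kb.values())
        scale = 1e6 / total if total > 0 else 0.0
    expr = {tid: v * scale for tid, v in per_kb.items()}

    unassociated = [tid for tid in expr if assoc.promoter_of(tid) is None]
    if unassociated:
        logger.warning(
            "%d transcripts have no promoter association and are dropped",
            len(unassociated),
        )

    per_promoter = dict.fromkeys(promoters.ids, 0.0)
    for tid, v in expr.items():
        pid = assoc.promoter_of(tid)
        if pid is not None and pid in per_promoter:
            per_promoter[pid] += v
    values = np.array([per_promoter[pid] for pid in promoters.ids])
    return np.log2(values + pseudocount)
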