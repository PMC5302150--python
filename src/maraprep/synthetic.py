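"""Synthetic fixtures: annotations, reads with known promoter rates, and
probe intensities drawn from the background model.

Every generator is a pure function of its spec and seed: the same inputs
produce byte-identical files. The synthetic chromosome is named ``chrS1`` so
that any accidental reliance on real chromosome names surfaces as an
all-zero count matrix (which the chromosome-name warning then flags).

Defaults encode the simulated study conditions used throughout the test
suite: promoters spaced 10 kb apart on one chromosome, 50 bp reads, ChIP
fragments centered on the promoter anchor with a 200 bp positional spread
(so a 2 kb window captures essentially all of a promoter's reads), and
probe intensities X = S + B with S ~ Exponential(theta) signal over
B ~ Normal(mu, sigma^2) optical background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotation import (
    AssociationTable,
    Promoter,
    PromoterSet,
    Transcript,
    write_associations,
    write_promoters,
    write_transcripts,
)
from .errors import ValidationError
from .microarray import ProbeMatrix, write_intensities

CHROM = "chrS1"
READ_LENGTH = 50  # bp, fixed
CHIP_SPREAD = 200.0  # bp sd of read start around the promoter anchor
PROMOTER_SPACING = 10_000  # bp between consecutive anchors
PROMOTER_MARGIN = 5_000  # first anchor offset from the chromosome start


@dataclass
class SimSpec:
    """Parameters of one synthetic study.

    ``promoter_rates`` are relative transcription-initiation rates; read
    counts are Poisson with expectations proportional to them (times
    transcript length for RNA-seq). Microarray parameters mirror the
    normal+exponential background model.
    """

    n_promoters: int = 100
    n_transcripts_per_promoter: int = 2
    n_reads: int = 100_000
    promoter_rates: np.ndarray | None = None
    assembly: str = "hg19"
    seed: int = 0
    # microarray block
    n_probes: int = 10_000
    n_samples: int = 4
    mu: float = 100.0
    sigma: float = 15.0
    theta: float = 200.0
    frac_background: float = 0.2

    def __post_init__(self):
        if min(self.n_promoters, self.n_transcripts_per_promoter,
               self.n_probes, self.n_samples) <= 0:
            raise ValidationError("all synthetic sizes must be positive")
        if self.n_reads < 0:
            raise ValidationError("n_reads must be >= 0")
        if self.promoter_rates is None:
            # log-normal spread of rates: realistic dynamic range of a few
            # hundred-fold across promoters
            rng = np.random.default_rng(self.seed + 101)
            self.promoter_rates = np.exp(rng.normal(0.0, 1.0, self.n_promoters))
        self.promoter_rates = np.asarray(self.promoter_rates, dtype=float)
        if len(self.promoter_rates) != self.n_promoters:
            raise ValidationError("promoter_rates length != n_promoters")
        if (self.promoter_rates <= 0).any():
            raise ValidationError("promoter rates must be positive")
        if not 0 <= self.frac_background <= 1:
            raise ValidationError("frac_background must be in [0, 1]")

    @property
    def chrom_length(self) -> int:
        return PROMOTER_MARGIN * 2 + self.n_promoters * PROMOTER_SPACING


def gen_annotation(
    spec: SimSpec,
) -> tuple[PromoterSet, list[Transcript], AssociationTable]:
    """Non-overlapping promoters on chrS1, each with its own transcripts.

    Anchors sit every 10 kb; each promoter's transcripts start at its anchor
    and extend downstream (upstream for '-' strands) with 1-3 exons and
    total exonic length between 500 and 4000 bp, always inside the
    promoter's 10 kb slot so transcripts of different promoters never
    overlap.
    """
    rng = np.random.default_rng(spec.seed)
    promoters: list[Promoter] = []
    transcripts: list[Transcript] = []
    pairs: dict[str, str] = {}

    for i in range(spec.n_promoters):
        anchor = PROMOTER_MARGIN + i * PROMOTER_SPACING
        strand = "+" if rng.random() < 0.5 else "-"
        pid = f"P{i + 1:05d}"
        promoters.append(Promoter(pid, CHROM, anchor, strand))
        for k in range(spec.n_transcripts_per_promoter):
            tid = f"T{i + 1:05d}.{k + 1}"
            n_exons = int(rng.integers(1, 4))
            exon_lens = rng.integers(150, 1200, n_exons)
            total = int(exon_lens.sum())
            if total > 4000:
                exon_lens = (exon_lens * 4000 / total).astype(int) + 1
            gap_lens = rng.integers(50, 400, n_exons - 1) if n_exons > 1 else []
            exons = []
            pos = anchor
            if strand == "+":
                for j in range(n_exons):
                    exons.append((pos, pos + int(exon_lens[j])))
                    pos += int(exon_lens[j])
                    if j < n_exons - 1:
                        pos += int(gap_lens[j])
            else:
                for j in range(n_exons):
                    exons.append((pos - int(exon_lens[j]), pos))
                    pos -= int(exon_lens[j])
                    if j < n_exons - 1:
                        pos -= int(gap_lens[j])
                exons = sorted(exons)
            transcripts.append(Transcript(tid, CHROM, strand, tuple(exons)))
            pairs[tid] = pid

    return (
        PromoterSet(promoters, assembly=spec.assembly),
        transcripts,
        AssociationTable(pairs),
    )


def write_annotation(spec: SimSpec, promoter_path, transcript_path, assoc_path):
    """Generate and serialize the annotation triple; returns the objects."""
    pset, transcripts, assoc = gen_annotation(spec)
    write_promoters(pset, promoter_path)
    write_transcripts(transcripts, transcript_path)
    write_associations(assoc, assoc_path)
    return pset, transcripts, assoc


def _write_bed(path, chroms, starts, ends, strands):
    import pandas as pd

    pd.DataFrame({
        "chrom": chroms,
        "start": starts,
        "end": ends,
        "name": [f"r{i}" for i in range(len(starts))],
        "score": 0,
        "strand": strands,
    }).to_csv(path, sep="\t", header=False, index=False, lineterminator="\n")


def gen_reads_chipseq(spec: SimSpec, out_path, seed_offset: int = 0) -> np.ndarray:
    """ChIP-seq reads: per-promoter Poisson counts, Gaussian positions.

    Promoter i receives Poisson(rate_i * n_reads / sum(rates)) reads whose
    start positions are Normal(anchor_i, 200 bp), truncated to the
    chromosome; read length is fixed at 50 bp. Returns the per-promoter
    true counts (before truncation clipping, which only moves positions).
    """
    rng = np.random.default_rng(spec.seed + 7919 * (seed_offset + 1))
    rates = spec.promoter_rates
    lam = rates * spec.n_reads / rates.sum()
    counts = rng.poisson(lam)
    anchors = PROMOTER_MARGIN + np.arange(spec.n_promoters) * PROMOTER_SPACING
    starts = np.concatenate([
        np.round(rng.normal(anchors[i], CHIP_SPREAD, counts[i])).astype(np.int64)
        for i in range(spec.n_promoters)
    ]) if counts.sum() else np.array([], dtype=np.int64)
    starts = np.clip(starts, 0, spec.chrom_length - READ_LENGTH - 1)
    order = np.argsort(starts, kind="stable")
    starts = starts[order]
    strands = np.where(
        rng.random(len(starts)) < 0.5, "+", "-"
    )
    _write_bed(
        out_path,
        np.full(len(starts), CHROM),
        starts,
        starts + READ_LENGTH,
        strands,
    )
    return counts


def gen_reads_rnaseq(
    spec: SimSpec,
    transcripts: list[Transcript],
    assoc: AssociationTable,
    out_path,
    seed_offset: int = 0,
) -> dict[str, int]:
    """RNA-seq reads: Poisson per transcript, uniform position within exons.

    Transcript t of promoter p gets expected count proportional to
    rate_p * length_t; each read starts at a uniformly chosen exonic base of
    its transcript (50 bp long, so it overlaps that exon by >= 1 bp).
    Returns the true per-transcript counts.
    """
    rng = np.random.default_rng(spec.seed + 104729 * (seed_offset + 1))
    rate_of = {
        f"P{i + 1:05d}": spec.promoter_rates[i] for i in range(spec.n_promoters)
    }
    weights = np.array([
        rate_of[assoc.promoter_of(t.transcript_id)] * t.length
        for t in transcripts
    ])
    lam = weights * spec.n_reads / weights.sum()
    counts = rng.poisson(lam)

    all_starts: list[np.ndarray] = []
    for t, c in zip(transcripts, counts):
        if c == 0:
            continue
        # uniform over exonic bases, mapped back to genomic coordinates
        offsets = rng.integers(0, t.length, c)
        starts = np.empty(c, dtype=np.int64)
        cum = 0
        for ex_start, ex_end in t.exons:
            ex_len = ex_end - ex_start
            in_exon = (offsets >= cum) & (offsets < cum + ex_len)
            starts[in_exon] = ex_start + (offsets[in_exon] - cum)
            cum += ex_len
        all_starts.append(starts)
    starts = (
        np.concatenate(all_starts) if all_starts else np.array([], dtype=np.int64)
    )
    starts = np.clip(starts, 0, spec.chrom_length - READ_LENGTH - 1)
    order = np.argsort(starts, kind="stable")
    starts = starts[order]
    strands = np.where(rng.random(len(starts)) < 0.5, "+", "-")
    _write_bed(
        out_path,
        np.full(len(starts), CHROM),
        starts,
        starts + READ_LENGTH,
        strands,
    )
    return {
        t.transcript_id: int(c) for t, c in zip(transcripts, counts)
    }


def gen_intensities(spec: SimSpec, out_path, labels_path=None) -> np.ndarray:
    """Probe intensities under the normal+exponential model.

    A fraction ``frac_background`` of probes are pure background
    B ~ N(mu, sigma^2) (clamped positive); the rest are X = S + B with
    S ~ Exponential(theta) drawn independently per sample. Returns the
    boolean planted-background labels (also written to ``labels_path`` as a
    two-column TSV when given, for filter benchmarking).
    """
    rng = np.random.default_rng(spec.seed + 65537)
    n_bg = int(round(spec.frac_background * spec.n_probes))
    is_background = np.zeros(spec.n_probes, dtype=bool)
    bg_idx = rng.choice(spec.n_probes, n_bg, replace=False)
    is_background[bg_idx] = True

    values = rng.normal(spec.mu, spec.sigma, (spec.n_probes, spec.n_samples))
    signal = rng.exponential(spec.theta, (spec.n_probes, spec.n_samples))
    signal[is_background] = 0.0
    values = values + signal
    values = np.maximum(values, 1e-3)  # intensities are positive scanner units

    probe_ids = [f"probe_{i + 1:06d}" for i in range(spec.n_probes)]
    sample_ids = [f"sample_{j + 1}" for j in range(spec.n_samples)]
    write_intensities(ProbeMatrix(probe_ids, sample_ids, values), out_path)
    if labels_path is not None:
        with open(labels_path, "w") as fh:
            fh.write("probe_id\tis_background\n")
            for pid, b in zip(probe_ids, is_background):
                fh.write(f"{pid}\t{int(b)}\n")
    return is_background
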