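# Methods

maraprep reduces raw gene-expression and chromatin datasets to small
promoter-level (or probe-level) summary matrices suitable for upload to a
motif activity response analysis (MARA) server, and manages the resulting
processing/submission jobs. This note documents the models, the defaults,
and the design decisions where the choice was genuinely open.

## Coordinate conventions

All genomic coordinates are 0-based half-open (BED convention). A promoter
is represented by a single anchor position — the floor of the midpoint of
its annotated interval — plus a strand. Using the floored midpoint removes
the ±1 ambiguity that otherwise arises for even-width intervals.
Chromosome names are compared as exact strings (`chr1` ≠ `1`); when an
alignment file and the annotation share no chromosome names at all, a
warning is logged, because the alternative failure mode is a silently
all-zero count matrix.

## Alignment input

BED (3+ columns) and BAM/SAM are accepted. For BAM, unmapped, secondary and
supplementary records are excluded and do not count toward the library
size; each remaining record becomes the reference span consumed by its
CIGAR. Duplicates are kept and paired-end mates are treated as independent
reads: with no information about the upstream protocol, counting each
primary alignment exactly once is the most predictable rule, and the
library size is the normalization denominator, so its definition must be
fixed. Unknown strand symbols (including BED's `.`) are coerced to `+` with
a warning. Reads are sorted by (chromosome, start, end); "indexing" is an
in-memory per-chromosome offset table over the sorted arrays, which is
exactly the structure region counting needs — no on-disk index file is
produced.

## ChIP-seq chain

Each promoter contributes one fixed-width window centered on its anchor,
`[max(0, a − w/2), a + w/2)`, with w = 2000 bp by default (widths must be
even). A read increments every window it overlaps by ≥ 1 bp; windows of
nearby promoters may overlap, in which case one read legitimately counts
toward several. Any-overlap is the default because it is the most inclusive
deterministic rule; `midpoint` and `five_prime` counting modes are
available behind the `count_mode` option. Strand is ignored: ChIP fragments
are strand-symmetric around binding sites.

Counting is done with a sorted sweep: within a chromosome holding n reads,
the number overlapping `[ws, we)` is `n − #(start ≥ we) − #(end ≤ ws)`,
each term a binary search in the sorted start (respectively end) arrays;
the two excluded sets are disjoint whenever the window is non-empty. The
test suite checks this against a brute-force all-pairs oracle on hundreds
of random instances; agreement is exact.

Counts are normalized to counts-per-million of the sample's library size
and transformed as `log2(CPM + c)` with pseudocount c = 0.5. CPM makes the
output invariant under duplicating every read, a property the tests assert;
the log base and pseudocount are fixed defaults so reruns are
byte-identical.

## RNA-seq chain

Inputs are already genome-aligned, so "mapping to the transcript set" is
exon-overlap assignment: a read is compatible with a transcript when it
overlaps any exon by ≥ 1 bp on the same chromosome. A read compatible with
k transcripts contributes 1/k to each — deterministic and mass-conserving
(the fractional counts sum exactly to the number of reads compatible with
at least one transcript; no EM rescue is attempted). Strandedness defaults
to `none` since the library protocol is unknown to the tool; `forward` and
`reverse` modes exist. Junction-spanning reads are treated by their genomic
span.

Per-transcript counts become RPKM (`count × 10^9 / (length × library)`),
and a promoter's expression is the **sum** of its associated transcripts'
RPKM — the promoter-level quantity is total transcription initiation, so
summation rather than averaging is the meaningful aggregate. The output is
`log2(E_p + 0.5)`. TPM is available via `rna_norm=tpm`. A transcript may
associate with exactly one promoter; ambiguous association tables are a
validation error rather than an undocumented weighting scheme.

On synthetic data with reads drawn Poisson with expectation ∝ promoter
rate × transcript length, the promoter log-expression rank-recovers the
planted rates with Spearman ρ ≈ 0.997 at 10^5 reads over 200 promoters.

## Microarray chain

The input is an open tab-delimited probe-intensity table (probe_id + one
column per sample); proprietary binary scanner formats and chip-definition
files are out of scope. The chain is: background correction → non-specific
binding (NSB) adjustment → expression filtering → quantile normalization →
log2.

**Background model.** Observed intensity is X = S + B with signal
S ~ Exponential(mean θ) and background B ~ Normal(μ, σ²) — the normexp
convolution. Correction replaces x with the posterior mean
E[S | X = x] = a + σ·φ(a/σ)/Φ(a/σ), a = x − μ − σ²/θ, evaluated through
log-space pdf/cdf so the Mills ratio stays accurate deep in the left tail.
The function is strictly positive and strictly increasing; tests verify it
against direct numerical quadrature of E[S|X=x] (agreement ~1e-12
relative) and against limma's `normexp.signal`.

**Parameter estimation** initializes μ at the mode of a Gaussian-KDE of the
intensities, σ at the RMS of the left-tail residuals and θ at the mean
right-tail excess, then refines by maximum likelihood on the closed-form
marginal density (L-BFGS-B over (μ, log σ, log θ)). The refinement is not
cosmetic: the mode of the convolution density sits at
μ + σ(z* + σ/θ) where φ(z*)/Φ(z*) = σ/θ, i.e. ≈ 29% above μ for
(μ, σ, θ) = (100, 15, 200), so the initializer alone is badly biased
whenever θ ≫ σ. The MLE recovers all three parameters within a few percent
at 50,000 probes. θ is bounded below (σ₀/100) to avoid the degenerate
θ → 0 likelihood ridge; for pure-background data the fit degrades
gracefully to μ ≈ sample mean with θ small.

**NSB adjustment** subtracts each sample's q-quantile (default q = 0.05) of
the corrected intensities and clamps at ε = 1.0 — a monotone within-sample
shift that also guarantees positivity for the final log. This quantile
floor is the minimal deterministic instantiation of an NSB correction; it
does not model GC-content or mismatch probes.

**Expression filter.** A probe is "expressed" in a sample when its
corrected (pre-adjustment) intensity exceeds μ̂ + 2σ̂ of that sample's
background fit; probes expressed in zero samples are removed
("consistently non-expressed" — one sample above background suffices to
keep a probe). On simulated data with 20% planted pure-background probes,
essentially all planted probes are removed and ~5% of signal probes are
lost.

**Quantile normalization** is the classic rank-mean procedure: sort each
column, average across columns at each rank, map every entry back to its
rank mean, with ties receiving the mean of their tied rank-means. After
normalization all columns carry the same multiset of values (exactly, for
tie-free input), the procedure is idempotent, and it matches limma's
`normalizeQuantiles` on random matrices.

Output rows are probes; mapping probes to promoters is a server-side
concern outside this package.

## Summary format

The upload payload is a plain TSV: leading `#key=value` metadata lines, a
header `id<TAB>sample…`, then one row per promoter/probe with values
printed at exactly six significant digits. The formatter goes through
scientific notation and a decimal expansion so six digits are always
emitted, making write → read → write reproduce the file byte for byte —
this is what lets the rerun and worker-count contracts be tested bitwise.
For 5,000 promoters × 3 samples the summary is ~155 KB regardless of how
many reads went in; at 10^6 reads per sample the raw-to-summary size ratio
is ~700.

## Job management

A job's states are created → processing → processed → uploading →
submitted, with `failed` reachable from anywhere. One retry edge,
failed → uploading, exists so that a failed *submission* (the summary is
still on disk) can be retried without reprocessing; reprocessing after a
processing failure requires a new job. `download_url` is non-empty exactly
when a job is submitted. The store is a single TSV rewritten atomically
(temp-file-then-rename) on every transition; a torn final line from a
crash is ignored on reload. Each input file is processed independently —
optionally in a process pool — and columns are assembled in input order,
so the summary bytes are identical for any worker count.

The server protocol is a deliberately minimal documented contract
(`POST /submit`, multipart form with data_type/assembly/project/email and
the summary file; 200 + a plain-text result URL on success), implemented
by an in-repo threaded mock server used in tests. The HTTP client uses the
Python standard library. Email addresses are validated only syntactically
(must contain `@`; empty allowed). A `--scratch DIR` option relocates
temporaries, e.g. to an external drive.

## Synthetic data

The generators define the simulated study conditions. Promoters sit every
10 kb on a synthetic chromosome `chrS1` (a deliberately unreal name, so
accidental dependence on real chromosome naming surfaces immediately);
each promoter carries 1–3-exon transcripts of 150–3600 exonic bp anchored
at its TSS, always within its 10 kb slot. Promoter rates default to
log-normal(0, 1) — a realistic few-hundred-fold dynamic range. Reads are
50 bp; ChIP read starts are Normal(anchor, 200 bp), so a 2 kb window
captures essentially all of a promoter's fragments and rate recovery is
sharp; RNA-seq reads are Poisson per transcript (∝ rate × length) and
uniform over exonic bases. Microarray intensities follow the normexp model
with defaults (μ, σ, θ) = (100, 15, 200) and a 20% planted pure-background
fraction. Every generator is a pure function of (spec, seed) and produces
byte-identical output on reruns.

What the synthetic data does **not** emulate: sequence content and
alignment artifacts (multi-mapping, soft-clipping), PCR duplicates,
strand-specific protocols, overlapping gene models across promoter slots,
batch effects, and probe-specific affinity differences. Passing tests
demonstrate the correctness of the pipeline's arithmetic and contracts
under the stated models, not robustness to those real-data complications.

## Problem sizes and numerics

The test suite and the acceptance script use 5,000 promoters × 10^6 reads
per sample for the size-reduction measurement, 10^5 reads / 200 promoters
for expression recovery, and 50,000 probes for background-model recovery —
sizes at which the stochastic checks have comfortable margins while the
whole suite runs in well under a minute of compute per pipeline. Counting
is exact integer arithmetic; read-mass conservation holds to < 1e-9;
quantile-normalization idempotence holds to ~1e-13 (float associativity);
the posterior-mean correction matches quadrature to ~1e-12 relative.
Degenerate inputs are handled explicitly: empty alignment files yield a
baseline log2(pseudocount) column with a logged warning rather than an
error; constant intensity vectors and sub-100-probe samples are estimation
errors; an all-filtered probe matrix is a processing error.
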