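# maraprep

Local pre-processing client for motif activity response analysis (MARA).

MARA-style analyses model genome-wide expression or chromatin state in
terms of predicted regulatory sites to infer transcription-factor and
miRNA activities. Their servers only need a small promoter × sample matrix
of normalized log-signal — but raw NGS inputs are tens of GB, so uploading
them is the bottleneck (and ships potentially sensitive raw data off-site).
`maraprep` performs the reduction locally: it turns RNA-seq or ChIP-seq
alignments (BED/BAM) and microarray probe-intensity tables into small
tab-delimited summary files, manages processing/submission jobs, and
uploads only the summary. For a million-read ChIP-seq sample the summary
is ~700× smaller than the input.

## What it computes

* **ChIP-seq** — reads overlapping the 2 kb window centered on each
  promoter are counted by a sorted sweep, scaled to counts-per-million and
  transformed as log2(CPM + 0.5).
* **RNA-seq** — genome-aligned reads are assigned to transcripts by exon
  overlap (a read hitting k transcripts contributes 1/k to each), converted
  to RPKM = count·10⁹/(length·library), summed over each promoter's
  associated transcripts, and log2-transformed:
  E_p = Σ_{t→p} RPKM_t, value = log2(E_p + 0.5).
* **Microarray** — normexp background correction (X = S + B,
  S ~ Exp(θ), B ~ N(μ, σ²); each intensity is replaced by the posterior
  mean E[S|X=x]), a quantile-floor non-specific-binding adjustment,
  removal of consistently non-expressed probes (never above μ̂ + 2σ̂ in any
  sample), rank-mean quantile normalization, log2.
* **Jobs** — created → processing → processed → uploading → submitted
  lifecycle with crash-safe persistence, per-job logs, parallel per-file
  processing whose output is byte-identical for any worker count, and
  multipart upload to a documented `POST /submit` endpoint (an in-repo mock
  server implements the contract for testing).

See `docs/methods.md` for models, defaults and design decisions.

## Worked example

Generate a synthetic ChIP-seq study (default spec: 100 promoters with
log-normal activity rates, 10^5 reads, 2 samples), process it, and submit
it to a local mock server:

```
$ maraprep synth annotation --seed 3 --out ann
$ maraprep synth reads --seed 3 --mode chipseq --samples 2 --out reads
$ maraprep --store store create --type chipseq --assembly mm9 \
    --promoters ann/promoters.bed --project demo \
    --email user@example.org reads/sample_1.bed reads/sample_2.bed
c0b6202f-825e-422d-b4d1-3d215bceeb1e
$ maraprep --store store run c0b6202f-825e-422d-b4d1-3d215bceeb1e --workers 2
c0b6202f-825e-422d-b4d1-3d215bceeb1e	processed	store/c0b6202f-....summary.tsv
```

The summary file is the upload payload — a plain promoter × sample TSV:

```
#assembly=mm9
#count_mode=overlap
#data_type=chipseq
#pseudocount=0.5
#window=2000
id	sample_1	sample_2
P00001	13.1667	13.1931
P00002	13.1776	13.2668
P00003	11.5192	11.4640
...
```

Each value is log2(CPM + 0.5) of the reads in that promoter's 2 kb window:
P00001 at ~13.17 holds about 2^13.17 ≈ 9,200 reads per million in both
samples; P00003, ~1.7 log2 units lower, about 3× fewer — the promoters'
relative activities, which is what the downstream motif-activity inference
consumes. With a
mock server running, `maraprep --store store submit <job-id> --server
http://127.0.0.1:<port>` uploads the file and stores the returned results
URL; `maraprep --store store jobs` lists every job with its state and
download URL.

One-shot processing without a job store:

```
maraprep process --type chipseq --assembly hg19 \
    --promoters ann/promoters.bed --out summary.tsv reads/*.bed
```

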