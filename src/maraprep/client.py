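"""Job lifecycle management: create, run, submit, list, inspect.

A job is one processing/submission request: a data type, an assembly (for
sequencing data), input files, and optional project/email metadata that the
analysis server uses for notification. Jobs move through the state machine

    created -> processing -> processed -> uploading -> submitted

with ``failed`` reachable from any state; a failed *submission* keeps the
processed summary on disk and may be retried (``failed -> uploading``).
``download_url`` is non-empty exactly when the state is ``submitted``.

The store is a single tab-separated file (one record per line) rewritten
atomically (write-temp-then-rename) on every transition, so a crash after
any persisted transition reloads to a consistent store. Per-job logs are
plain text files next to it.
"""

from __future__ import annotations

import json
import logging
import os
import time
import uuid
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field, replace

import numpy as np

from . import chipseq as chipseq_mod
from . import microarray as microarray_mod
from . import rnaseq as rnaseq_mod
from .alignments import read_alignments, warn_if_disjoint_chroms
from .annotation import (
    SUPPORTED_ASSEMBLIES,
    read_associations,
    read_promoters,
    read_transcripts,
)
from .errors import ConfigError, ProcessingError, SubmissionError, ValidationError
from .summary import SummaryMatrix, write_summary

logger = logging.getLogger(__name__)

DATA_TYPES = ("microarray", "rnaseq", "chipseq")
STATES = ("created", "processing", "processed", "uploading", "submitted", "failed")
_ALLOWED_EDGES = {
    ("created", "processing"),
    ("processing", "processed"),
    ("processed", "uploading"),
    ("uploading", "submitted"),
    ("failed", "uploading"),  # submission retry
} | {(s, "failed") for s in STATES if s != "failed"}

_STORE_COLUMNS = [
    "job_id", "project", "email", "data_type", "assembly", "input_paths",
    "state", "download_url", "created_at", "updated_at", "log_path",
    "summary_path", "config_json",
]


@dataclass
class JobConfig:
    """Everything needed to run one job."""

    data_type: str
    input_paths: list[str]
    assembly: str = ""
    project: str = ""
    email: str = ""
    promoters: str = ""
    transcripts: str = ""
    associations: str = ""
    window: int = chipseq_mod.DEFAULT_WINDOW_WIDTH
    pseudocount: float = chipseq_mod.DEFAULT_PSEUDOCOUNT
    count_mode: str = "overlap"
    rna_norm: str = "rpkm"
    stranded: str = "none"
    nsb_quantile: float = microarray_mod.DEFAULT_NSB_QUANTILE

    def validate(self) -> None:
        if self.data_type not in DATA_TYPES:
            raise ConfigError(f"unknown data type {self.data_type!r}")
        if self.data_type in ("rnaseq", "chipseq"):
            if not self.assembly:
                raise ConfigError(f"{self.data_type} requires an assembly")
            if self.assembly not in SUPPORTED_ASSEMBLIES:
                raise ConfigError(
                    f"unsupported assembly {self.assembly!r}; "
                    f"expected one of {SUPPORTED_ASSEMBLIES}"
                )
            if not self.promoters:
                raise ConfigError(f"{self.data_type} requires a promoter file")
        if self.data_type == "rnaseq" and not (
            self.transcripts and self.associations
        ):
            raise ConfigError("rnaseq requires transcript and association files")
        if self.email and "@" not in self.email:
            raise ConfigError(f"invalid email {self.email!r}")
        for text in (self.project, self.email):
            if "\t" in text or "\n" in text:
                raise ConfigError("project/email must not contain tabs or newlines")
        if not self.input_paths:
            raise ConfigError("no input files given")
        for p in self.input_paths:
            if not os.path.exists(p):
                raise ConfigError(f"input file does not exist: {p}")


@dataclass
class JobRecord:
    job_id: str
    project: str
    email: str
    data_type: str
    assembly: str
    input_paths: list[str]
    state: str = "created"
    download_url: str = ""
    created_at: float = 0.0
    updated_at: float = 0.0
    log_path: str = ""
    summary_path: str = ""
    config: JobConfig | None = field(default=None)

    def can_transition(self, new_state: str) -> bool:
        return (self.state, new_state) in _ALLOWED_EDGES

    def to_row(self) -> list[str]:
        cfg = json.dumps(self.config.__dict__) if self.config else ""
        return [
            self.job_id, self.project, self.email, self.data_type,
            self.assembly, json.dumps(self.input_paths), self.state,
            self.download_url, repr(self.created_at), repr(self.updated_at),
            self.log_path, self.summary_path, cfg,
        ]

    @classmethod
    def from_row(cls, row: list[str]) -> "JobRecord":
        cfg = JobConfig(**json.loads(row[12])) if row[12] else None
        return cls(
            job_id=row[0], project=row[1], email=row[2], data_type=row[3],
            assembly=row[4], input_paths=json.loads(row[5]), state=row[6],
            download_url=row[7], created_at=float(row[8]),
            updated_at=float(row[9]), log_path=row[10], summary_path=row[11],
            config=cfg,
        )


class JobStore:
    """Append-ordered persistent collection of jobs under one directory."""

    def __init__(self, root):
        self.root = str(root)
        os.makedirs(self.root, exist_ok=True)
        os.makedirs(os.path.join(self.root, "logs"), exist_ok=True)
        self.path = os.path.join(self.root, "jobs.tsv")
        self._jobs: dict[str, JobRecord] = {}
        if os.path.exists(self.path):
            self._load()

    def _load(self) -> None:
        with open(self.path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                row = line.split("\t")
                if len(row) != len(_STORE_COLUMNS):
                    continue  # tolerate a torn final line from a crash
                rec = JobRecord.from_row(row)
                self._jobs[rec.job_id] = rec

    def _persist(self) -> None:
        tmp = self.path + ".tmp"
        with open(tmp, "w") as fh:
            fh.write("#" + "\t".join(_STORE_COLUMNS) + "\n")
            for rec in self._jobs.values():
                fh.write("\t".join(rec.to_row()) + "\n")
        os.replace(tmp, self.path)

    def add(self, rec: JobRecord) -> None:
        if rec.job_id in self._jobs:
            raise ValidationError(f"duplicate job_id {rec.job_id}")
        self._jobs[rec.job_id] = rec
        self._persist()

    def update(self, rec: JobRecord) -> None:
        self._jobs[rec.job_id] = rec
        self._persist()

    def get(self, job_id: str) -> JobRecord:
        if job_id not in self._jobs:
            raise ValidationError(f"unknown job_id {job_id}")
        return self._jobs[job_id]

    def transition(self, job_id: str, new_state: str, note: str = "") -> JobRecord:
        rec = self.get(job_id)
        if not rec.can_transition(new_state):
            raise ValidationError(
                f"job {job_id}: illegal transition {rec.state} -> {new_state}"
            )
        rec = replace(rec, state=new_state, updated_at=time.time())
        self._jobs[job_id] = rec
        self._persist()
        self.log(job_id, f"state -> {new_state}" + (f" ({note})" if note else ""))
        return rec

    def log(self, job_id: str, message: str) -> None:
        rec = self.get(job_id)
        stamp = time.strftime("%Y-%m-%d %H:%M:%S", time.gmtime())
        with open(rec.log_path, "a") as fh:
            fh.write(f"[{stamp}] {message}\n")

    def job_log(self, job_id: str) -> str:
        rec = self.get(job_id)
        if not os.path.exists(rec.log_path):
            return ""
        with open(rec.log_path) as fh:
            return fh.read()

    def list_jobs(self) -> list[JobRecord]:
        return sorted(self._jobs.values(), key=lambda r: (r.created_at, r.job_id))


def create_job(store: JobStore, config: JobConfig) -> JobRecord:
    """Validate the configuration and persist a new job in state ``created``."""
    config.validate()
    job_id = str(uuid.uuid4())
    log_path = os.path.join(store.root, "logs", f"{job_id}.log")
    now = time.time()
    rec = JobRecord(
        job_id=job_id,
        project=config.project,
        email=config.email,
        data_type=config.data_type,
        assembly=config.assembly if config.data_type != "microarray" else "",
        input_paths=list(config.input_paths),
        state="created",
        created_at=now,
        updated_at=now,
        log_path=log_path,
        config=config,
    )
    store.add(rec)
    store.log(job_id, f"job created: type={config.data_type} "
                      f"inputs={len(config.input_paths)}")
    return rec


def _process_sequencing_sample(args) -> tuple[str, np.ndarray, int, list[str]]:
    """Process one BED/BAM file into one summary column (worker function).

    Module-level so it is picklable for process pools; annotation files are
    re-read in the worker, which keeps the task payload to plain paths.
    """
    (path, cfg_dict) = args
    cfg = JobConfig(**cfg_dict)
    warnings: list[str] = []
    aset = read_alignments(path)
    pset = read_promoters(cfg.promoters, assembly=cfg.assembly)
    if warn_if_disjoint_chroms(aset, {p.chrom for p in pset}):
        warnings.append(
            f"{path}: chromosome names disjoint from annotation; counts are zero"
        )
    if len(aset) == 0:
        warnings.append(f"{path}: empty alignment file; column is baseline only")

    if cfg.data_type == "chipseq":
        windows = chipseq_mod.make_windows(
            pset, chipseq_mod.WindowSpec(cfg.window)
        )
        counts = chipseq_mod.count_in_windows(aset, windows, mode=cfg.count_mode)
        lib = aset.total_reads
        if lib == 0:
            lib = 1  # empty sample: CPM column is all zero, value log2(pc)
        cpm = counts * 1e6 / lib
        column = np.log2(cpm + cfg.pseudocount)
    else:  # rnaseq
        transcripts = read_transcripts(cfg.transcripts)
        assoc = read_associations(cfg.associations)
        assoc.validate(pset, transcripts)
        if aset.total_reads == 0:
            column = np.full(len(pset), np.log2(cfg.pseudocount))
        else:
            tcounts = rnaseq_mod.assign_reads(aset, transcripts, stranded=cfg.stranded)
            column = rnaseq_mod.promoter_expression(
                tcounts, assoc, transcripts, pset,
                pseudocount=cfg.pseudocount, norm=cfg.rna_norm,
            )
    return aset.sample_id, column, aset.total_reads, warnings


def process_config(cfg: JobConfig, workers: int = 1, log_fn=None) -> SummaryMatrix:
    """Run the data-type pipeline described by ``cfg`` to a summary matrix.

    Input files are processed independently (in parallel when ``workers`` >
    1) and the columns assembled in input order, so the result is identical
    for any worker count.
    """
    log = log_fn or (lambda msg: logger.info(msg))
    for p in cfg.input_paths:
        if not os.path.exists(p):
            raise ProcessingError(f"input file missing at run time: {p}")
    if cfg.data_type == "microarray":
        if len(cfg.input_paths) != 1:
            raise ProcessingError("microarray expects exactly one intensity table")
        log(f"stage: read intensities {cfg.input_paths[0]}")
        matrix = microarray_mod.read_intensities(cfg.input_paths[0])
        log("stage: background/NSB/filter/quantile/log chain")
        return microarray_mod.process_intensities(
            matrix, nsb_quantile=cfg.nsb_quantile
        )
    tasks = [(p, dict(cfg.__dict__)) for p in cfg.input_paths]
    log(f"stage: processing {len(tasks)} sample file(s)")
    if workers == 1 or len(tasks) == 1:
        results = [_process_sequencing_sample(t) for t in tasks]
    else:
        with ProcessPoolExecutor(max_workers=workers) as pool:
            results = list(pool.map(_process_sequencing_sample, tasks))
    for _, _, _, warns in results:
        for w in warns:
            log(f"warning: {w}")
    sample_ids = [r[0] for r in results]
    if len(set(sample_ids)) != len(sample_ids):
        sample_ids = [f"{sid}_{i + 1}" for i, sid in enumerate(sample_ids)]
    pset = read_promoters(cfg.promoters, assembly=cfg.assembly)
    return SummaryMatrix(
        row_ids=pset.ids,
        sample_ids=sample_ids,
        values=np.column_stack([r[1] for r in results]),
        meta={
            "data_type": cfg.data_type,
            "assembly": cfg.assembly,
            "pseudocount": repr(cfg.pseudocount),
            **({"window": str(cfg.window), "count_mode": cfg.count_mode}
               if cfg.data_type == "chipseq"
               else {"rna_norm": cfg.rna_norm, "stranded": cfg.stranded}),
        },
    )


def run_job(store: JobStore, job_id: str, workers: int = 1) -> JobRecord:
    """Run the job's pipeline and persist the summary; state -> processed."""
    rec = store.get(job_id)
    if rec.state != "created":
        raise ProcessingError(f"job {job_id} is in state {rec.state}, not created")
    if workers < 1:
        raise ConfigError("workers must be >= 1")
    cfg = rec.config
    rec = store.transition(job_id, "processing", note=f"workers={workers}")
    try:
        summary = process_config(
            cfg, workers=workers, log_fn=lambda m: store.log(job_id, m)
        )
        summary_path = os.path.join(store.root, f"{job_id}.summary.tsv")
        store.log(job_id, f"stage: writing summary {summary_path}")
        write_summary(summary, summary_path)
        rec = replace(store.get(job_id), summary_path=summary_path)
        store.update(rec)
        return store.transition(job_id, "processed")
    except Exception as exc:
        store.log(job_id, f"error: {exc}")
        store.transition(job_id, "failed", note=str(exc)[:200])
        if isinstance(exc, (ProcessingError, ConfigError)):
            raise
        raise ProcessingError(str(exc)) from exc


def _multipart_post(url: str, fields: dict[str, str], file_field: str,
                    filename: str, payload: bytes, timeout: float = 30.0):
    """POST a multipart/form-data request with stdlib urllib."""
    import urllib.error
    import urllib.request

    boundary = uuid.uuid4().hex
    parts = []
    for key, value in fields.items():
        parts.append(
            f"--{boundary}\r\n"
            f'Content-Disposition: form-data; name="{key}"\r\n\r\n'
            f"{value}\r\n".encode()
        )
    parts.append(
        f"--{boundary}\r\n"
        f'Content-Disposition: form-data; name="{file_field}"; '
        f'filename="{filename}"\r\n'
        f"Content-Type: text/tab-separated-values\r\n\r\n".encode()
        + payload + b"\r\n"
    )
    parts.append(f"--{boundary}--\r\n".encode())
    body = b"".join(parts)
    req = urllib.request.Request(
        url, data=body,
        headers={"Content-Type": f"multipart/form-data; boundary={boundary}"},
        method="POST",
    )
    try:
        with urllib.request.urlopen(req, timeout=timeout) as resp:
            return resp.status, resp.read().decode("utf-8", "replace").strip()
    except urllib.error.HTTPError as err:
        return err.code, err.read().decode("utf-8", "replace").strip()
    except (urllib.error.URLError, OSError) as err:
        raise SubmissionError(f"cannot reach server at {url}: {err}") from err


def submit_job(store: JobStore, job_id: str, server_url: str) -> JobRecord:
    """Upload the processed summary; store the result URL on HTTP 200.

    The server contract is ``POST <server_url>/submit`` with multipart
    fields data_type, assembly, project, email and the summary file; a 200
    response whose body is a URL marks success. Any other outcome moves the
    job to ``failed`` but leaves the summary in place, so the submission can
    be retried.
    """
    rec = store.get(job_id)
    if rec.state not in ("processed", "failed"):
        raise SubmissionError(
            f"job {job_id} is in state {rec.state}; only processed jobs "
            f"(or failed submissions) can be submitted"
        )
    if not rec.summary_path or not os.path.exists(rec.summary_path):
        raise SubmissionError(f"job {job_id} has no summary file to submit")
    store.transition(job_id, "uploading", note=server_url)
    with open(rec.summary_path, "rb") as fh:
        payload = fh.read()
    try:
        status, body = _multipart_post(
            server_url.rstrip("/") + "/submit",
            fields={
                "data_type": rec.data_type,
                "assembly": rec.assembly,
                "project": rec.project,
                "email": rec.email,
            },
            file_field="summary",
            filename=os.path.basename(rec.summary_path),
            payload=payload,
        )
    except SubmissionError as exc:
        store.log(job_id, f"error: {exc}")
        store.transition(job_id, "failed", note=str(exc)[:200])
        raise
    if status == 200 and body.startswith(("http://", "https://")):
        # single atomic persist so download_url is set exactly when submitted
        rec = store.get(job_id)
        if not rec.can_transition("submitted"):
            raise SubmissionError(
                f"job {job_id}: illegal transition {rec.state} -> submitted"
            )
        rec = replace(rec, download_url=body, state="submitted",
                      updated_at=time.time())
        store.update(rec)
        store.log(job_id, f"state -> submitted ({body})")
        return rec
    store.log(job_id, f"error: server returned {status}: {body[:200]}")
    store.transition(job_id, "failed", note=f"HTTP {status}")
    raise SubmissionError(f"submission failed with HTTP {status}")
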