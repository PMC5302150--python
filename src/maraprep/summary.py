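"""The upload payload: a small tab-delimited matrix of normalized log-signal.

Dialect (fixed so reruns are byte-comparable):

* leading ``#key=value`` metadata lines;
* header ``id<TAB>sample1<TAB>...``;
* one row per id, values printed with 6 significant digits, ``.`` decimal
  separator, ``\\n`` line endings.

Writing is byte-deterministic for equal inputs, which is what makes the
worker-count and rerun determinism contracts testable bitwise.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ParseError, ValidationError


@dataclass
class SummaryMatrix:
    """row_ids x sample_ids matrix of finite normalized log-expression."""

    row_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.sample_ids)):
            raise ValidationError(
                f"summary shape {self.values.shape} does not match "
                f"{len(self.row_ids)} rows x {len(self.sample_ids)} samples"
            )
        if len(set(self.row_ids)) != len(self.row_ids):
            raise ValidationError("duplicate row ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids")
        if self.values.size and not np.isfinite(self.values).all():
            raise ValidationError("summary contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _format_value(x: float) -> str:
    """6 significant digits, trailing zeros kept (e.g. 4.3576 -> '4.35760').

    Goes through scientific notation and a Decimal expansion so exactly six
    significant digits are always emitted; this makes write -> read -> write
    reproduce the file byte for byte.
    """
    if x == 0:
        return "0.00000"
    from decimal import Decimal

    return format(Decimal(f"{x:.5e}"), "f")


def write_summary(matrix: SummaryMatrix, path, compress: bool = False) -> None:
    """Serialize to the tab-delimited dialect; optionally gzip."""
    opener = gzip.open if compress or str(path).endswith(".gz") else open
    with opener(path, "wt", newline="") as fh:
        for key in sorted(matrix.meta):
            fh.write(f"#{key}={matrix.meta[key]}\n")
        fh.write("id\t" + "\t".join(matrix.sample_ids) + "\n")
        for i, rid in enumerate(matrix.row_ids):
            row = "\t".join(_format_value(v) for v in matrix.values[i])
            fh.write(f"{rid}\t{row}\n")


def read_summary(path) -> SummaryMatrix:
    """Inverse of :func:`write_summary` up to 6-significant-digit precision."""
    opener = gzip.open if str(path).endswith(".gz") else open
    meta: dict = {}
    sample_ids: list[str] | None = None
    row_ids: list[str] = []
    rows: list[list[float]] = []
    seen: set = set()
    with opener(path, "rt") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    key, _, value = line[1:].partition("=")
                    meta[key] = value
                continue
            fields = line.split("\t")
            if sample_ids is None:
                if fields[0] != "id":
                    raise ParseError(
                        "header must start with 'id'", path=path, line=lineno
                    )
                sample_ids = fields[1:]
                continue
            if len(fields) != len(sample_ids) + 1:
                raise ParseError(
                    f"expected {len(sample_ids) + 1} columns, got {len(fields)}",
                    path=path, line=lineno,
                )
            rid = fields[0]
            if rid in seen:
                raise ParseError(f"duplicate id {rid!r}", path=path, line=lineno)
            seen.add(rid)
            try:
                values = [float(v) for v in fields[1:]]
            except ValueError:
                raise ParseError("non-numeric cell", path=path, line=lineno)
            if any(not math.isfinite(v) for v in values):
                raise ParseError("non-finite cell", path=path, line=lineno)
            row_ids.append(rid)
            rows.append(values)
    if sample_ids is None:
        raise ParseError("missing header line", path=path)
    values = (
        np.array(rows, dtype=float)
        if rows
        else np.zeros((0, len(sample_ids)))
    )
    return SummaryMatrix(row_ids, sample_ids, values, meta=meta)
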