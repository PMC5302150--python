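import numpy as np
import pytest

from maraprep.alignments import AlignmentSet
from maraprep.synthetic import SimSpec, gen_annotation, write_annotation


@pytest.fixture(scope="session")
def small_spec():
    """Session-wide small synthetic study: 30 promoters, 20k reads."""
    return SimSpec(n_promoters=30, n_reads=20_000, seed=11)


@pytest.fixture(scope="session")
def small_annotation(small_spec):
    return gen_annotation(small_spec)


@pytest.fixture()
def annotation_paths(tmp_path, small_spec):
    paths = (
        tmp_path / "promoters.bed",
        tmp_path / "transcripts.tsv",
        tmp_path / "associations.tsv",
    )
    write_annotation(small_spec, *paths)
    return paths


def make_alignment_set(chroms, starts, ends, strands=None, sample_id="s",
                       total_reads=None) -> AlignmentSet:
    """Build a sorted AlignmentSet from plain lists (test helper)."""
    from maraprep.alignments import _make_set

    n = len(starts)
    if strands is None:
        strands = ["+"] * n
    return _make_set(
        sample_id,
        np.asarray(chroms, dtype=object),
        np.asarray(starts, dtype=np.int64),
        np.asarray(ends, dtype=np.int64),
        np.asarray(strands, dtype=object),
        total_reads=total_reads,
    )


def brute_force_window_counts(aset: AlignmentSet, windows) -> np.ndarray:
    """All-pairs >=1 bp overlap counts; the independent counting oracle."""
    counts = np.zeros(len(windows), dtype=np.int64)
    for i, (chrom, ws, we) in enumerate(windows):
        on_chrom = aset.chroms == chrom
        counts[i] = int(
            np.sum(on_chrom & (aset.starts < we) & (aset.ends > ws))
        )
    return counts
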