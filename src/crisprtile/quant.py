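"""sgRNA cassette read counting into a sample-annotated count matrix.

A read is assigned to a guide when exactly one library protospacer (either
orientation) occurs as an exact substring of the read; reads matching zero
or more than one distinct guide are tallied as unassigned.  Counting is
therefore invariant to read order and quality strings, and exact by
construction (no mismatch tolerance by default).
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .library_io import Library, revcomp

CELL_LINES = ("CAS9", "PAR")


class CountError(ValueError):
    """Inconsistent count inputs."""


@dataclass(frozen=True)
class SampleMeta:
    """One screen sample: cell-line arm, day, treatment, replicate."""

    sample_id: str
    cell_line: str
    day: int
    treatment: str
    replicate: int

    def __post_init__(self) -> None:
        if self.cell_line not in CELL_LINES:
            raise CountError(
                f"{self.sample_id}: cell_line must be one of {CELL_LINES}"
            )
        if self.day < 0 or self.replicate < 1:
            raise CountError(f"{self.sample_id}: bad day/replicate")

    @property
    def condition(self) -> tuple:
        return (self.cell_line, self.day, self.treatment, self.replicate)


@dataclass
class CountMatrix:
    """Integer sgRNA x sample counts plus per-sample unassigned totals."""

    counts: pd.DataFrame  # index sgrna_id, columns sample_id
    samples: list[SampleMeta]
    unassigned: dict[str, int]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if list(self.counts.columns) != ids:
            raise CountError("count columns do not match the sample sheet order")
        conds = [s.condition for s in self.samples]
        if len(set(conds)) != len(conds):
            raise CountError("(cell_line, day, treatment, replicate) not unique")
        if (self.counts.to_numpy() < 0).any():
            raise CountError("negative counts")

    @property
    def sgrna_ids(self) -> list[str]:
        return list(self.counts.index)

    def sample(self, sample_id: str) -> SampleMeta:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def select(self, **selector) -> list[SampleMeta]:
        """Samples matching all given fields (cell_line, day, treatment...)."""
        out = []
        for s in self.samples:
            if all(getattr(s, k) == v for k, v in selector.items()):
                out.append(s)
        return out


def _open_maybe_gz(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _read_seqs(fastq_path: str | Path) -> Iterable[str]:
    with _open_maybe_gz(Path(fastq_path)) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield str(rec.seq).upper()


def count_reads(reads: Iterable[str], library: Library) -> tuple[pd.Series, int]:
    """Count an iterable of read sequences against the library.

    Returns (per-guide counts in library order, unassigned count).  Each
    20-mer of a read is looked up against the protospacers and their
    reverse complements; a read matching one guide several times counts
    once.
    """
    if len(library) == 0:
        raise CountError("empty library")
    lookup: dict[str, set[str]] = {}
    for g in library.sgrnas:
        lookup.setdefault(g.protospacer, set()).add(g.sgrna_id)
        lookup.setdefault(revcomp(g.protospacer), set()).add(g.sgrna_id)
    counts = {gid: 0 for gid in library.sgrna_ids}
    unassigned = 0
    k = 20
    for read in reads:
        matched: set[str] = set()
        for i in range(len(read) - k + 1):
            hit = lookup.get(read[i : i + k])
            if hit:
                matched |= hit
                if len(matched) > 1:
                    break
        if len(matched) == 1:
            counts[next(iter(matched))] += 1
        else:
            unassigned += 1
    return pd.Series(counts, name="count"), unassigned


def count_fastq(
    fastq_path: str | Path, library: Library, sample_meta: SampleMeta | None = None
) -> tuple[pd.Series, int]:
    """Count one FASTQ file (optionally gzipped) against the library."""
    try:
        return count_reads(_read_seqs(fastq_path), library)
    except ValueError as exc:  # malformed FASTQ record
        raise IOError(f"{fastq_path}: {exc}") from exc


def assemble_matrix(
    vectors: Sequence[pd.Series],
    metas: Sequence[SampleMeta],
    unassigned: Sequence[int] | None = None,
) -> CountMatrix:
    """Column-bind per-sample count vectors following the sample sheet."""
    if len(vectors) != len(metas):
        raise CountError("one count vector per sample required")
    ref_ids = list(vectors[0].index)
    for m, v in zip(metas, vectors):
        if list(v.index) != ref_ids:
            extra = set(v.index) ^ set(ref_ids)
            raise CountError(f"{m.sample_id}: sgrna_id set mismatch: {sorted(extra)}")
    counts = pd.DataFrame(
        {m.sample_id: v.to_numpy() for m, v in zip(metas, vectors)},
        index=pd.Index(ref_ids, name="sgrna_id"),
        dtype=np.int64,
    )
    ua = {m.sample_id: int(u) for m, u in zip(metas, unassigned or [0] * len(metas))}
    return CountMatrix(counts, list(metas), ua)


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    """Counts as TSV plus a JSON sidecar with sample metadata."""
    path = Path(path)
    matrix.counts.to_csv(path, sep="\t")
    sidecar = {
        "samples": [asdict(s) for s in matrix.samples],
        "unassigned": matrix.unassigned,
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(sidecar, indent=1))


def read_counts(path: str | Path) -> CountMatrix:
    path = Path(path)
    counts = pd.read_csv(path, sep="\t", index_col="sgrna_id")
    meta = json.loads(Path(str(path) + ".meta.json").read_text())
    samples = [SampleMeta(**s) for s in meta["samples"]]
    return CountMatrix(counts.astype(np.int64), samples, meta["unassigned"])


def write_fastq(reads: Sequence[str], path: str | Path, prefix: str = "read") -> None:
    """Write plain sequences as FASTQ with uniform quality."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@{prefix}{i}\n{seq}\n+\n{'I' * len(seq)}\n")
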