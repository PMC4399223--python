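"""Core records of a pooled hairpin screen.

A screen is described by three tables: the hairpin library (one row per
shRNA clone: id, target gene, 19-22 nt antisense sequence, pool), the
sample sheet (one row per sequenced sample: id, 5 bp multiplexing index,
pool, timepoint T2/T14, replicate), and the hairpin x sample count matrix
produced by amplicon counting.  All three round-trip through plain
tab-separated files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

_DNA = set("ACGT")

LIBRARY_COLUMNS = ["hairpin_id", "gene", "antisense", "pool_id"]
SAMPLE_COLUMNS = ["sample_id", "index_seq", "pool_id", "timepoint", "replicate"]
TIMEPOINTS = ("T2", "T14")


def _check_dna(seq: str, what: str) -> None:
    if not seq or set(seq) - _DNA:
        raise ValueError(f"{what} must be a non-empty string over ACGT, got {seq!r}")


@dataclass(frozen=True)
class HairpinRecord:
    """One library member: an shRNA clone targeting a gene."""

    hairpin_id: str
    gene: str
    antisense: str
    pool_id: str

    def __post_init__(self) -> None:
        _check_dna(self.antisense, f"antisense of {self.hairpin_id}")
        if not (19 <= len(self.antisense) <= 22):
            raise ValueError(
                f"antisense of {self.hairpin_id} has length {len(self.antisense)}, "
                "expected 19-22 nt"
            )
        if not self.gene:
            raise ValueError(f"hairpin {self.hairpin_id} has an empty gene symbol")


@dataclass(frozen=True)
class SampleRecord:
    """One sequenced sample: a (pool, timepoint, replicate) with a 5 bp index."""

    sample_id: str
    index_seq: str
    pool_id: str
    timepoint: str
    replicate: int

    def __post_init__(self) -> None:
        _check_dna(self.index_seq, f"index of {self.sample_id}")
        if len(self.index_seq) != 5:
            raise ValueError(
                f"index of {self.sample_id} has length {len(self.index_seq)}, expected 5"
            )
        if self.timepoint not in TIMEPOINTS:
            raise ValueError(
                f"timepoint of {self.sample_id} must be one of {TIMEPOINTS}, "
                f"got {self.timepoint!r}"
            )
        if self.replicate < 1:
            raise ValueError(f"replicate of {self.sample_id} must be >= 1")


@dataclass(frozen=True)
class ReadStructure:
    """Fixed positional layout of an amplicon read.

    Reads are ``[index][constant spacer][hairpin antisense][filler]``.  The
    default spacer is the common region of the reverse PCR primer that sits
    between the sample index and the hairpin in the sequenced product; the
    sequencer-facing orientation is a declared convention and every offset
    is configurable.
    """

    index_start: int = 0
    index_len: int = 5
    spacer: str = "GTAGCCCCTTGAATTCCGAG"
    hairpin_start: int = -1  # default: immediately after index + spacer
    read_len: int = 50

    def __post_init__(self) -> None:
        if self.spacer:
            _check_dna(self.spacer, "spacer")
        if self.hairpin_start < 0:
            object.__setattr__(
                self, "hairpin_start", self.index_start + self.index_len + len(self.spacer)
            )
        if self.index_start < 0 or self.index_len <= 0:
            raise ValueError("index span must be non-negative with positive length")
        if self.index_start + self.index_len > self.hairpin_start:
            raise ValueError("index span overlaps the hairpin span")
        if self.read_len <= self.hairpin_start:
            raise ValueError("read_len leaves no room for the hairpin")

    def hairpin_span(self, length: int) -> tuple[int, int]:
        end = self.hairpin_start + length
        if end > self.read_len:
            raise ValueError(
                f"hairpin of length {length} does not fit in a {self.read_len} nt read "
                f"starting at {self.hairpin_start}"
            )
        return self.hairpin_start, end


class CountMatrix:
    """Non-negative integer hairpin x sample counts with attached metadata.

    ``counts`` is a pandas DataFrame indexed by hairpin_id with sample_id
    columns.  ``hairpins`` and ``samples`` carry the library and sample-sheet
    rows in matrix order; ``samples`` may be None when a matrix is read back
    from a bare counts file.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        hairpins: Sequence[HairpinRecord] | None = None,
        samples: Sequence[SampleRecord] | None = None,
        genes: Sequence[str] | None = None,
    ):
        counts = counts.copy()
        arr = counts.to_numpy()
        if arr.size and (not np.issubdtype(arr.dtype, np.number) or np.any(arr < 0)):
            raise ValueError("counts must be non-negative")
        if arr.size and not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integers")
        counts = counts.astype(np.int64) if arr.size else counts.astype(np.int64)
        if counts.index.has_duplicates:
            raise ValueError("duplicate hairpin_ids in count matrix")
        if counts.columns.has_duplicates:
            raise ValueError("duplicate sample_ids in count matrix")
        self.counts = counts
        self.hairpins = list(hairpins) if hairpins is not None else None
        self.samples = list(samples) if samples is not None else None
        if self.hairpins is not None:
            if [h.hairpin_id for h in self.hairpins] != list(counts.index):
                raise ValueError("hairpin metadata does not match matrix rows")
            self._genes = pd.Series(
                [h.gene for h in self.hairpins], index=counts.index, name="gene"
            )
        elif genes is not None:
            if len(genes) != len(counts.index):
                raise ValueError("gene metadata does not match matrix rows")
            self._genes = pd.Series(list(genes), index=counts.index, name="gene")
        else:
            self._genes = pd.Series("", index=counts.index, name="gene")
        if self.samples is not None and [s.sample_id for s in self.samples] != list(
            counts.columns
        ):
            raise ValueError("sample metadata does not match matrix columns")

    @property
    def genes(self) -> pd.Series:
        return self._genes

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def pool_of_sample(self) -> pd.Series:
        if self.samples is None:
            raise ValueError("no sample metadata attached")
        return pd.Series(
            {s.sample_id: s.pool_id for s in self.samples}, name="pool_id"
        ).loc[list(self.counts.columns)]

    def timepoint_of_sample(self) -> pd.Series:
        if self.samples is None:
            raise ValueError("no sample metadata attached")
        return pd.Series(
            {s.sample_id: s.timepoint for s in self.samples}, name="timepoint"
        ).loc[list(self.counts.columns)]

    def pool_of_hairpin(self) -> pd.Series:
        if self.hairpins is None:
            raise ValueError("no hairpin metadata attached")
        return pd.Series(
            {h.hairpin_id: h.pool_id for h in self.hairpins}, name="pool_id"
        ).loc[list(self.counts.index)]

    def subset_pool(self, pool_id: str) -> "CountMatrix":
        """Rows and columns belonging to one pool (requires full metadata)."""
        hp = [h for h in self.hairpins or [] if h.pool_id == pool_id]
        sm = [s for s in self.samples or [] if s.pool_id == pool_id]
        if not hp or not sm:
            raise ValueError(f"pool {pool_id!r} not present in both axes")
        sub = self.counts.loc[[h.hairpin_id for h in hp], [s.sample_id for s in sm]]
        return CountMatrix(sub, hairpins=hp, samples=sm)

    def attach_samples(self, samples: Sequence[SampleRecord]) -> "CountMatrix":
        by_id = {s.sample_id: s for s in samples}
        missing = [c for c in self.counts.columns if c not in by_id]
        if missing:
            raise ValueError(f"sample sheet lacks samples: {missing}")
        return CountMatrix(
            self.counts,
            hairpins=self.hairpins,
            samples=[by_id[c] for c in self.counts.columns],
            genes=None if self.hairpins is not None else list(self._genes),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return self.counts.equals(other.counts)


# ---------------------------------------------------------------------------
# table IO


def read_library(path: str | Path) -> list[HairpinRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(LIBRARY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"library table {path} lacks columns {sorted(missing)}")
    recs = [
        HairpinRecord(r.hairpin_id, r.gene, r.antisense, r.pool_id)
        for r in df.itertuples()
    ]
    validate_library(recs)
    return recs


def write_library(library: Iterable[HairpinRecord], path: str | Path) -> None:
    pd.DataFrame([vars(h) for h in library], columns=LIBRARY_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def read_samples(path: str | Path) -> list[SampleRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"replicate": int}, keep_default_na=False)
    missing = set(SAMPLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet {path} lacks columns {sorted(missing)}")
    recs = [
        SampleRecord(str(r.sample_id), r.index_seq, str(r.pool_id), r.timepoint, int(r.replicate))
        for r in df.itertuples()
    ]
    validate_samples(recs)
    return recs


def write_samples(samples: Iterable[SampleRecord], path: str | Path) -> None:
    pd.DataFrame([vars(s) for s in samples], columns=SAMPLE_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def validate_library(library: Sequence[HairpinRecord]) -> None:
    """Reject libraries that could double-match a read.

    Beyond the basic within-pool uniqueness, counting at a fixed offset with
    variable 19-22 nt hairpin lengths is unambiguous only when no antisense
    sequence is a prefix of another; uniqueness and prefix-freeness are
    enforced library-wide.
    """
    ids = [h.hairpin_id for h in library]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate hairpin_ids in library")
    seqs = sorted(h.antisense for h in library)
    for a, b in zip(seqs, seqs[1:]):
        if b.startswith(a):
            reason = "duplicate" if a == b else "prefix of another"
            raise ValueError(
                f"ambiguous library: antisense {a} is a {reason} antisense sequence"
            )


def validate_samples(
    samples: Sequence[SampleRecord], library: Sequence[HairpinRecord] | None = None
) -> None:
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample_ids in sample sheet")
    idx = [s.index_seq for s in samples]
    if len(set(idx)) != len(idx):
        raise ValueError("index sequences are not unique across samples")
    if library is not None:
        pools = {h.pool_id for h in library}
        orphans = sorted({s.pool_id for s in samples} - pools)
        if orphans:
            raise ValueError(f"sample pools absent from library: {orphans}")
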