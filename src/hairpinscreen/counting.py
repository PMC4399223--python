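"""Exact-match hairpin-amplicon counting.

A read increments cell (hairpin, sample) iff the bases at the fixed index
span equal the sample's 5 bp index exactly AND the bases at the fixed
hairpin span equal a library antisense sequence exactly.  There is no
mismatch tolerance and qualities are ignored: counting is a tally of
perfect index-hairpin matches at known offsets, as appropriate for a
fixed-layout PCR product.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .records import (
    CountMatrix,
    HairpinRecord,
    SampleRecord,
    validate_library,
    validate_samples,
)

__all__ = ["CountingReport", "count_reads", "write_counts", "read_counts"]


@dataclass
class CountingReport:
    """Per-run tally of read fates; total is always the sum of the four fates."""

    total_reads: int = 0
    matched_reads: int = 0
    index_only: int = 0
    hairpin_only: int = 0
    unmatched: int = 0

    def __post_init__(self) -> None:
        parts = self.matched_reads + self.index_only + self.hairpin_only + self.unmatched
        if self.total_reads != parts:
            raise ValueError("report fates do not sum to total_reads")


def _open_fastq(fastq) -> IO[str]:
    if isinstance(fastq, (str, Path)):
        if str(fastq).endswith(".gz"):
            return gzip.open(fastq, "rt")
        return open(fastq, "rt")
    return fastq  # already a text handle / iterable of lines


def count_reads(
    fastq,
    library: Sequence[HairpinRecord],
    samples: Sequence[SampleRecord],
    structure,
) -> tuple[CountMatrix, CountingReport]:
    """Tally perfect index-hairpin matches into a CountMatrix.

    ``fastq`` may be a path (``.gz`` handled transparently) or an open text
    handle.  Reads too short for a span simply fail that match; a malformed
    FASTQ record raises with the offending record number.
    """
    validate_library(library)
    validate_samples(samples, library)
    hp_ids = [h.hairpin_id for h in library]
    sample_ids = [s.sample_id for s in samples]
    hp_pos = {h: i for i, h in enumerate(hp_ids)}
    sm_pos = {s: i for i, s in enumerate(sample_ids)}

    # per-length sequence -> hairpin lookup (lengths 19-22 may coexist)
    by_len: dict[int, dict[str, str]] = {}
    for h in library:
        by_len.setdefault(len(h.antisense), {})[h.antisense] = h.hairpin_id
    lengths = sorted(by_len)
    index_of = {s.index_seq: s.sample_id for s in samples}

    i0 = structure.index_start
    i1 = i0 + structure.index_len
    h0 = structure.hairpin_start

    mat = np.zeros((len(hp_ids), len(sample_ids)), dtype=np.int64)
    total = matched = index_only = hairpin_only = unmatched = 0

    handle = _open_fastq(fastq)
    records = FastqGeneralIterator(handle)
    while True:
        try:
            item = next(records, None)
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ record {total + 1}: {exc}") from exc
        if item is None:
            break
        _, seq, _ = item
        total += 1
        sample_id = index_of.get(seq[i0:i1]) if len(seq) >= i1 else None
        hairpin_id = None
        for L in lengths:
            if len(seq) >= h0 + L:
                hairpin_id = by_len[L].get(seq[h0 : h0 + L])
                if hairpin_id is not None:
                    break
        if sample_id is not None and hairpin_id is not None:
            mat[hp_pos[hairpin_id], sm_pos[sample_id]] += 1
            matched += 1
        elif sample_id is not None:
            index_only += 1
        elif hairpin_id is not None:
            hairpin_only += 1
        else:
            unmatched += 1
    if isinstance(fastq, (str, Path)):
        handle.close()

    counts = pd.DataFrame(mat, index=hp_ids, columns=sample_ids)
    report = CountingReport(total, matched, index_only, hairpin_only, unmatched)
    return CountMatrix(counts, hairpins=list(library), samples=list(samples)), report


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    """Write counts as TSV: hairpin_id, gene, then one column per sample."""
    out = matrix.counts.copy()
    out.insert(0, "gene", matrix.genes)
    out.index.name = "hairpin_id"
    out.to_csv(path, sep="\t")


def read_counts(path: str | Path) -> CountMatrix:
    """Read a counts TSV back; inverse of :func:`write_counts`.

    The file carries hairpin ids and genes but no sample metadata; use
    :meth:`CountMatrix.attach_samples` to restore it from a sample sheet.
    Non-integer or negative cells are rejected with their location.
    """
    df = pd.read_csv(path, sep="\t", index_col="hairpin_id")
    if "gene" not in df.columns:
        raise ValueError(f"counts file {path} lacks a gene column")
    genes = df.pop("gene")
    arr = df.to_numpy()
    if arr.size:
        bad = ~np.isfinite(arr) | (arr < 0) | (arr != np.round(arr))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"counts file {path}: invalid entry {arr[r, c]!r} at "
                f"hairpin {df.index[r]!r}, sample {df.columns[c]!r}"
            )
    return CountMatrix(df, genes=list(genes.fillna("")))
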