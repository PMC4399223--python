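"""Synthetic pooled-screen generator.

Emulates the data a dropout/enrichment screen produces: per-pool baseline
hairpin abundances, a planted minority of hairpins whose abundance is
multiplied by a fitness fold between the early (T2) and late (T14)
timepoints, negative-binomially dispersed counts at each sample's
sequencing depth, and finally raw FASTQ reads laid out as
``[index][spacer][antisense][filler]``.

The generative model matches the assumptions of the downstream exact test:
counts are NB with variance mu + phi*mu^2 (phi = 0 degenerates to Poisson),
and T14 proportions are renormalized after applying the folds because
sequencing is compositional — a fixed read budget is split among hairpins.
An optional Poisson "founder" bottleneck models the finite number of
sphere-forming transduced cells carrying each hairpin (expected 77 per
hairpin under the screen's design arithmetic).
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .records import (
    CountMatrix,
    HairpinRecord,
    ReadStructure,
    SampleRecord,
    validate_library,
    validate_samples,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_truth",
    "simulate_counts",
    "emit_fastq",
    "synthetic_library",
    "synthetic_samples",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generative model.

    hit_fraction
        Fraction of hairpins with a true fitness effect (fold != 1).
    fold_enriched, fold_depleted
        (low, high) ranges the fold of an enriched / depleted hit is drawn
        from, uniformly.  Defaults plant 3-fold enrichment and 3-fold
        depletion, split evenly between the two directions.
    phi
        Common NB dispersion of the counts; variance = mu + phi*mu^2.
    mean_libsize
        Expected reads per sample; actual depths are log-normal around it
        (sigma ``libsize_sigma`` on the log scale) to emulate uneven lanes.
    baseline_sigma
        Log-normal spread of baseline hairpin abundances within a pool.
    bottleneck_mean
        If set, each hairpin's baseline is additionally multiplied by a
        Poisson(bottleneck_mean) founder count (77 reproduces the screen's
        expected per-hairpin representation); None disables the bottleneck.
    """

    hit_fraction: float = 0.10
    fold_enriched: tuple[float, float] = (3.0, 3.0)
    fold_depleted: tuple[float, float] = (1 / 3, 1 / 3)
    phi: float = 0.1
    mean_libsize: float = 1e6
    libsize_sigma: float = 0.2
    baseline_sigma: float = 1.0
    bottleneck_mean: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.hit_fraction <= 1.0:
            raise ValueError(f"hit_fraction must be in [0,1], got {self.hit_fraction}")
        if self.phi < 0:
            raise ValueError(f"dispersion phi must be >= 0, got {self.phi}")
        for name, (lo, hi) in (
            ("fold_enriched", self.fold_enriched),
            ("fold_depleted", self.fold_depleted),
        ):
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be a positive (low, high) range")
        if self.mean_libsize <= 0:
            raise ValueError("mean_libsize must be positive")
        if self.bottleneck_mean is not None and self.bottleneck_mean < 0:
            raise ValueError("bottleneck_mean must be >= 0")


@dataclass
class GroundTruth:
    """Planted truth of one simulated screen.

    baseline_prop sums to 1 within each pool; fold is 1 for every non-hit
    hairpin; founders is None unless a bottleneck was simulated.
    """

    baseline_prop: pd.Series  # indexed by hairpin_id
    fold: pd.Series  # indexed by hairpin_id
    dispersion: float
    lib_sizes: pd.Series  # indexed by sample_id
    founders: pd.Series | None
    pool_of_hairpin: pd.Series

    @property
    def hits(self) -> pd.Index:
        return self.fold.index[self.fold != 1.0]


def simulate_truth(
    library: Sequence[HairpinRecord],
    samples: Sequence[SampleRecord],
    config: SimulationConfig = SimulationConfig(),
    seed: int = 0,
) -> GroundTruth:
    """Draw baseline abundances, planted folds and sequencing depths.

    All randomness flows from one ``numpy.random.default_rng(seed)``; the
    same (library, samples, config, seed) always yields the same truth.
    """
    validate_library(library)
    validate_samples(samples, library)
    rng = np.random.default_rng(seed)
    hp_ids = [h.hairpin_id for h in library]
    pools = pd.Series([h.pool_id for h in library], index=hp_ids, name="pool_id")

    raw = rng.lognormal(mean=0.0, sigma=config.baseline_sigma, size=len(library))
    founders = None
    if config.bottleneck_mean is not None:
        founders = pd.Series(
            rng.poisson(config.bottleneck_mean, size=len(library)), index=hp_ids
        )
        raw = raw * founders.to_numpy()
    baseline = pd.Series(raw, index=hp_ids, dtype=float)
    for pool, idx in baseline.groupby(pools).groups.items():
        total = baseline.loc[idx].sum()
        if total == 0:
            # bottleneck wiped the pool; fall back to uniform representation
            baseline.loc[idx] = 1.0 / len(idx)
        else:
            baseline.loc[idx] /= total

    is_hit = rng.random(len(library)) < config.hit_fraction
    up = rng.random(len(library)) < 0.5
    folds = np.ones(len(library))
    lo_e, hi_e = config.fold_enriched
    lo_d, hi_d = config.fold_depleted
    folds[is_hit & up] = rng.uniform(lo_e, hi_e, size=int((is_hit & up).sum()))
    folds[is_hit & ~up] = rng.uniform(lo_d, hi_d, size=int((is_hit & ~up).sum()))
    fold = pd.Series(folds, index=hp_ids)

    depths = rng.lognormal(
        mean=np.log(config.mean_libsize) - config.libsize_sigma**2 / 2,
        sigma=config.libsize_sigma,
        size=len(samples),
    )
    lib_sizes = pd.Series(
        np.round(depths).astype(np.int64), index=[s.sample_id for s in samples]
    )
    return GroundTruth(baseline, fold, config.phi, lib_sizes, founders, pools)


def simulate_counts(
    truth: GroundTruth,
    library: Sequence[HairpinRecord],
    samples: Sequence[SampleRecord],
    seed: int = 0,
) -> CountMatrix:
    """Draw the hairpin x sample count matrix implied by a GroundTruth.

    For a T2 sample of pool P the mean of hairpin h is
    ``lib_size * baseline_prop[h]``; for T14 the baseline is multiplied by
    the folds and renormalized within the pool before scaling.  Counts are
    NB(mean, phi) with variance mu + phi*mu^2; phi = 0 draws Poisson.
    """
    rng = np.random.default_rng(seed)
    phi = truth.dispersion
    cols = {}
    for s in samples:
        in_pool = truth.pool_of_hairpin == s.pool_id
        props = truth.baseline_prop.copy()
        pool_props = props[in_pool]
        if s.timepoint == "T14":
            pool_props = pool_props * truth.fold[in_pool]
            tot = pool_props.sum()
            if tot > 0:
                pool_props = pool_props / tot
        mu = np.zeros(len(props))
        mu[in_pool.to_numpy()] = truth.lib_sizes[s.sample_id] * pool_props.to_numpy()
        if phi == 0:
            draws = rng.poisson(mu)
        else:
            r = 1.0 / phi
            p = np.where(mu > 0, r / (r + mu), 1.0)
            draws = rng.negative_binomial(r, p)
        cols[s.sample_id] = draws
    counts = pd.DataFrame(cols, index=truth.baseline_prop.index)
    return CountMatrix(counts, hairpins=list(library), samples=list(samples))


_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_INDEX[b] for b in seq], dtype=np.uint8)


def emit_fastq(
    counts: CountMatrix,
    library: Sequence[HairpinRecord],
    samples: Sequence[SampleRecord],
    structure: ReadStructure = ReadStructure(),
    error_rate: float = 0.0,
    seed: int = 0,
    path: str | Path | io.IOBase | None = None,
) -> str | None:
    """Materialize a count matrix as FASTQ reads.

    Emits exactly count(h, s) reads per cell, each built as
    index + spacer + antisense + random ACGT filler up to ``read_len``,
    then hit by independent per-base substitutions at ``error_rate``
    (a substituted base is always changed, never resampled to itself).
    Qualities are a constant 'I'; read ids are plain serials carrying no
    truth.  Returns the FASTQ text when ``path`` is None, else writes to
    ``path`` (gzip-compressed iff the name ends in .gz).
    """
    if not 0.0 <= error_rate < 1.0:
        raise ValueError(f"error_rate must be in [0,1), got {error_rate}")
    by_id = {h.hairpin_id: h for h in library}
    sample_by_id = {s.sample_id: s for s in samples}
    rng = np.random.default_rng(seed)
    L = structure.read_len
    qual = "I" * L
    spacer_code = _encode(structure.spacer) if structure.spacer else np.empty(0, np.uint8)

    qual_b = qual.encode()

    def cell_chunks():
        serial = 0
        for sample_id in counts.counts.columns:
            s = sample_by_id[sample_id]
            idx_code = _encode(s.index_seq)
            col = counts.counts[sample_id]
            for hairpin_id, n in col.items():
                n = int(n)
                if n == 0:
                    continue
                h = by_id[hairpin_id]
                structure.hairpin_span(len(h.antisense))  # raises if it cannot fit
                prefix = np.concatenate([idx_code, spacer_code, _encode(h.antisense)])
                reads = np.empty((n, L), dtype=np.uint8)
                reads[:, : len(prefix)] = prefix
                fill = L - len(prefix)
                if fill:
                    reads[:, len(prefix):] = rng.integers(
                        0, 4, size=(n, fill), dtype=np.uint8
                    )
                if error_rate > 0:
                    hit = rng.random((n, L)) < error_rate
                    shift = rng.integers(1, 4, size=int(hit.sum()), dtype=np.uint8)
                    reads[hit] = (reads[hit] + shift) % 4
                seqs = _BASE_BYTES[reads]
                buf = io.BytesIO()
                for i in range(n):
                    serial += 1
                    buf.write(b"@r%d\n" % serial)
                    buf.write(seqs[i].tobytes())
                    buf.write(b"\n+\n")
                    buf.write(qual_b)
                    buf.write(b"\n")
                yield buf.getvalue()

    if path is None:
        return b"".join(cell_chunks()).decode()
    if isinstance(path, (str, Path)):
        if str(path).endswith(".gz"):
            # fixed mtime keeps reruns byte-identical
            with open(path, "wb") as raw, gzip.GzipFile(
                fileobj=raw, mode="wb", mtime=0
            ) as fh:
                for chunk in cell_chunks():
                    fh.write(chunk)
        else:
            with open(path, "wb") as fh:
                for chunk in cell_chunks():
                    fh.write(chunk)
    else:
        for chunk in cell_chunks():
            path.write(chunk.decode())
    return None


# ---------------------------------------------------------------------------
# convenience constructors for simulated screens


def synthetic_library(
    n_pools: int = 2,
    hairpins_per_pool: int = 88,
    seed: int = 0,
    lengths: tuple[int, ...] = (19, 20, 21, 22),
    genes_per_pool: int | None = None,
) -> list[HairpinRecord]:
    """Random prefix-free hairpin library, ``hairpins_per_pool`` per pool.

    Gene symbols default to one gene per hairpin; pass ``genes_per_pool`` to
    assign several hairpins per gene, as in a real multi-clone library.
    """
    rng = np.random.default_rng(seed)
    recs: list[HairpinRecord] = []
    seen: set[str] = set()
    for p in range(n_pools):
        pool = f"pool{p + 1}"
        g_per = genes_per_pool or hairpins_per_pool
        for i in range(hairpins_per_pool):
            while True:
                length = int(rng.choice(lengths))
                seq = "".join("ACGT"[j] for j in rng.integers(0, 4, size=length))
                if any(seq.startswith(t) or t.startswith(seq) for t in seen):
                    continue
                seen.add(seq)
                break
            gene = f"Gene{p + 1}_{i % g_per + 1}"
            recs.append(HairpinRecord(f"hp{p + 1}_{i + 1:03d}", gene, seq, pool))
    validate_library(recs)
    return recs


def synthetic_samples(
    pools: Sequence[str],
    replicates: int = 3,
    seed: int = 0,
) -> list[SampleRecord]:
    """Sample sheet with ``replicates`` T2 + T14 samples per pool and
    distinct random 5 bp indices."""
    rng = np.random.default_rng(seed)
    n_needed = len(pools) * replicates * 2
    if n_needed > 4**5:
        raise ValueError("more samples than distinct 5 bp indices")
    indices: list[str] = []
    seen: set[str] = set()
    while len(indices) < n_needed:
        seq = "".join("ACGT"[j] for j in rng.integers(0, 4, size=5))
        if seq not in seen:
            seen.add(seq)
            indices.append(seq)
    recs = []
    k = 0
    for pool in pools:
        for tp in ("T2", "T14"):
            for r in range(1, replicates + 1):
                recs.append(SampleRecord(f"{pool}_{tp}_r{r}", indices[k], pool, tp, r))
                k += 1
    validate_samples(recs)
    return recs
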