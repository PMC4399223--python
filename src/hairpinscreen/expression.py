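"""Expression-based candidate filtering.

Screen hits are cross-referenced against RNA-seq expression of the target
genes in the sorted epithelial populations (MaSC/basal, LP, ML) and in
mammospheres: a gene is "expressed" in a population when its average CPM
exceeds 0.5, and hits whose targets are expressed nowhere are suspected
off-target effects.  The module provides CPM computation, TMM
normalization factors, the expressed calls, the four-way cross-reference
partition, and the highest-average-expression probe collapse used when
matching microarray data to RNA-seq by gene symbol.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "cpm",
    "tmm_factors",
    "expressed_calls",
    "cross_reference",
    "collapse_probes",
]


def cpm(
    counts: pd.DataFrame,
    log: bool = False,
    prior: float = 0.25,
    norm_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Counts per million per column, optionally log2 with a prior.

    Library size is the column sum, multiplied by its TMM factor when
    ``norm_factors`` is given.  In log mode the prior is scaled per sample
    in proportion to its library size (so a prior of 0.25 means 0.25 reads
    in an average-depth library) and the library size is inflated by twice
    the scaled prior, keeping log-CPM finite and comparable across depths:
    ``log2((count + prior_s) / (libsize_s + 2 * prior_s) * 1e6)``.
    """
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    if np.any(lib == 0):
        raise ValueError("a column sums to zero; CPM undefined")
    if norm_factors is not None:
        lib = lib * norm_factors.loc[counts.columns].to_numpy(dtype=float)
    if not log:
        return counts / lib * 1e6
    if prior < 0:
        raise ValueError("prior must be non-negative")
    pc = prior * lib / lib.mean()
    return np.log2((counts + pc) / (lib + 2 * pc) * 1e6)


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              logratio_trim: float = 0.3, sum_trim: float = 0.05) -> float:
    """Weighted trimmed mean of M-values of one column against the reference.

    M = log2 relative abundance ratio, A = average log2 abundance; the top
    and bottom 30% of M and 5% of A are trimmed and the rest averaged with
    inverse-asymptotic-variance (delta-method binomial) weights.
    """
    both = (obs > 0) & (ref > 0)
    obs, ref = obs[both], ref[both]
    if obs.size == 0:
        return 1.0
    M = np.log2((obs / n_obs) / (ref / n_ref))
    A = 0.5 * (np.log2(obs / n_obs) + np.log2(ref / n_ref))
    v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    finite = np.isfinite(M) & np.isfinite(A)
    M, A, v = M[finite], A[finite], v[finite]
    if M.size == 0 or np.max(np.abs(M)) < 1e-6:
        return 1.0
    n = M.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(M).rank().to_numpy()
    rank_a = pd.Series(A).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(M[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0**f)


def tmm_factors(counts: pd.DataFrame, ref: str | None = None) -> pd.Series:
    """Trimmed-mean-of-M-values normalization factors, product 1.

    The reference defaults to the column whose upper-quartile
    depth-normalized count is closest to the mean upper quartile.  Factors
    multiply library sizes: an effective library is colsum * factor.
    """
    if counts.shape[1] < 2:
        raise ValueError("tmm_factors needs at least 2 columns")
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    if np.any(lib == 0):
        raise ValueError("a column is all zeros; TMM undefined")
    x = counts.to_numpy(dtype=float)
    if ref is None:
        uq = np.array([np.quantile(x[:, j] / lib[j], 0.75) for j in range(x.shape[1])])
        ref_j = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_j = list(counts.columns).index(ref)
    f = np.array(
        [_tmm_pair(x[:, j], x[:, ref_j], lib[j], lib[ref_j]) for j in range(x.shape[1])]
    )
    f = f / np.exp(np.mean(np.log(f)))
    return pd.Series(f, index=counts.columns, name="tmm_factor")


def expressed_calls(
    expr: pd.DataFrame,
    threshold: float = 0.5,
    replicate_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Boolean gene x population table of average-CPM > threshold calls.

    ``expr`` is linear CPM.  With ``replicate_map`` (column -> population),
    replicate columns are averaged before the strict-inequality threshold;
    otherwise each column is its own population.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if replicate_map is not None:
        pops = pd.Series({c: replicate_map[c] for c in expr.columns})
        expr = expr.T.groupby(pops).mean().T
    return expr > threshold


def cross_reference(
    hit_genes: Iterable[str],
    calls: pd.DataFrame,
    primary_pops: Sequence[str],
    sphere_pop: str,
) -> dict:
    """Partition hit genes by where their expression is detected.

    Four disjoint counts covering every hit gene: expressed in at least one
    primary population (and, of those, how many are also expressed in
    spheres), expressed in spheres only, expressed nowhere.  Percentages
    are against the hit-gene total.  Gene matching is case-insensitive;
    hit genes absent from the calls table raise rather than being dropped.
    """
    for p in [*primary_pops, sphere_pop]:
        if p not in calls.columns:
            raise ValueError(f"unknown population label {p!r}")
    genes = sorted({str(g).upper() for g in hit_genes})
    table = calls.copy()
    table.index = table.index.astype(str).str.upper()
    table = table[~table.index.duplicated()]
    missing = [g for g in genes if g not in table.index]
    if missing:
        raise ValueError(f"hit genes absent from expression table: {missing}")
    sub = table.loc[genes]
    in_primary = sub[list(primary_pops)].any(axis=1)
    in_sphere = sub[sphere_pop]
    n = len(genes)
    n_primary = int(in_primary.sum())
    n_primary_and_sphere = int((in_primary & in_sphere).sum())
    n_sphere_only = int((~in_primary & in_sphere).sum())
    n_nowhere = n - n_primary - n_sphere_only
    pct = lambda k: round(100.0 * k / n, 1) if n else 0.0
    return {
        "n_hit_genes": n,
        "n_primary": n_primary,
        "n_primary_and_sphere": n_primary_and_sphere,
        "n_sphere_only": n_sphere_only,
        "n_nowhere": n_nowhere,
        "pct_primary": pct(n_primary),
        "pct_primary_and_sphere": pct(n_primary_and_sphere),
        "pct_sphere_only": pct(n_sphere_only),
        "pct_nowhere": pct(n_nowhere),
    }


def collapse_probes(
    probe_table: pd.DataFrame, probe_to_gene: Mapping[str, str]
) -> pd.DataFrame:
    """Collapse a probe x sample matrix to gene level.

    Per gene the single probe with the highest mean across samples is kept
    (ties broken by lexicographically smallest probe id); genes with no
    probes are simply absent from the output.
    """
    unknown = [p for p in probe_table.index if p not in probe_to_gene]
    if unknown:
        raise ValueError(f"probes without a gene mapping: {unknown[:5]}")
    means = probe_table.mean(axis=1)
    best: dict[str, str] = {}
    for probe in sorted(probe_table.index):  # lexicographic: first seen wins ties
        gene = probe_to_gene[probe]
        if gene not in best or means[probe] > means[best[gene]]:
            best[gene] = probe
    genes = sorted(best)
    out = probe_table.loc[[best[g] for g in genes]].copy()
    out.index = pd.Index(genes, name="gene")
    return out
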