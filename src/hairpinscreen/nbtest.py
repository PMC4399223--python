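"""Negative-binomial exact testing of hairpin abundance changes.

The screen contrasts T14 against T2 replicate counts per hairpin.  The
model is the classic two-group NB setup for small designed experiments:
counts are NB with variance mu + phi*mu^2 and a single dispersion phi
shared by all hairpins.  Three steps:

1.  Library sizes are equalized by linear scaling to the geometric-mean
    depth, producing "pseudo-counts" comparable across samples.
2.  phi is estimated by maximizing the conditional log-likelihood of the
    within-group counts given their group sums, summed over hairpins — the
    conditioning removes the unknown per-hairpin means.
3.  For each hairpin the two group sums (A, B) are compared by an exact
    conditional test: given S = A + B, the null distribution of A is the
    negative hypergeometric induced by A ~ NB(n1*mu, phi/n1) and
    B ~ NB(n2*mu, phi/n2) (a group sum of n iid NB(mu, phi) is
    NB(n*mu, phi/n)).  The two-sided p-value sums the probabilities of all
    splits no more likely than the observed one; for phi = 0 the
    conditional law is Binomial(S, n1/(n1+n2)).

Everything is computed in log space by direct enumeration over 0..S.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .records import CountMatrix

__all__ = [
    "DispersionEstimate",
    "equalize_libsizes",
    "common_dispersion",
    "exact_test",
    "bh_fdr",
    "screen_exact_test",
]

#: splits whose log-probability is within this of the observed one count as ties
_TIE_TOL = 1e-8
_MAX_ENUM = 10**7
PHI_BOUNDS = (1e-8, 20.0)


@dataclass(frozen=True)
class DispersionEstimate:
    phi: float
    loglik_at_phi: float
    n_hairpins_used: int


def _as_frame(counts) -> pd.DataFrame:
    return counts.counts if isinstance(counts, CountMatrix) else pd.DataFrame(counts)


def _group_masks(columns, groups) -> tuple[np.ndarray, np.ndarray]:
    g = pd.Series(list(groups), index=list(columns)) if not isinstance(groups, pd.Series) else groups.loc[list(columns)]
    levels = pd.unique(g)
    if len(levels) != 2:
        raise ValueError(f"expected exactly two group labels, got {list(levels)}")
    # T2 is the baseline whenever present; otherwise first level seen
    if "T2" in set(levels):
        base = "T2"
        other = [l for l in levels if l != "T2"][0]
    else:
        base, other = levels[0], levels[1]
    return (g == base).to_numpy(), (g == other).to_numpy()


def equalize_libsizes(counts) -> tuple[pd.DataFrame, float]:
    """Scale each column to the geometric mean of the column sums.

    Returns (pseudo-count DataFrame, common library size).  After scaling
    every column sums to the common size, so group sums are comparable
    without per-sample offsets.
    """
    df = _as_frame(counts)
    colsums = df.sum(axis=0).to_numpy(dtype=float)
    if np.all(colsums == 0):
        raise ValueError("all columns sum to zero; library sizes undefined")
    if np.any(colsums == 0):
        raise ValueError("a column sums to zero; cannot equalize its library size")
    common = float(np.exp(np.mean(np.log(colsums))))
    pseudo = df * (common / colsums)
    return pseudo, common


def _cond_loglik(y: np.ndarray, phi: float) -> float:
    """Sum over rows of log P(row | row sum) for iid NB(mu, phi) entries.

    The conditional law is Dirichlet-multinomial with shape r = 1/phi per
    entry: P(y|z) = prod_i C(y_i+r-1, y_i) / C(z+n*r-1, z).
    """
    r = 1.0 / phi
    n = y.shape[1]
    z = y.sum(axis=1)
    ll = (
        gammaln(y + r).sum(axis=1)
        - gammaln(y + 1).sum(axis=1)
        - n * gammaln(r)
        - gammaln(z + n * r)
        + gammaln(n * r)
        + gammaln(z + 1)
    )
    return float(ll.sum())


def common_dispersion(pseudo, groups) -> DispersionEstimate:
    """Maximum conditional-likelihood estimate of the common dispersion.

    Pseudo-counts are rounded to integers; every group with >= 2 samples
    contributes its conditional likelihood.  The 1-D maximization runs over
    phi in [1e-8, 20] to absolute tolerance 1e-8.
    """
    df = _as_frame(pseudo)
    m1, m2 = _group_masks(df.columns, groups)
    y = np.round(df.to_numpy(dtype=float)).astype(np.int64)
    blocks = [y[:, m] for m in (m1, m2) if m.sum() >= 2]
    if not blocks:
        raise ValueError("dispersion not estimable: no group has >= 2 samples")

    def neg(phi: float) -> float:
        return -sum(_cond_loglik(b, phi) for b in blocks)

    res = minimize_scalar(neg, bounds=PHI_BOUNDS, method="bounded",
                          options={"xatol": 1e-8})
    phi = float(res.x)
    # the likelihood can be monotone decreasing (Poisson-like data): take the
    # boundary when it beats the interior optimum
    if neg(PHI_BOUNDS[0]) <= res.fun:
        phi = PHI_BOUNDS[0]
    return DispersionEstimate(phi, -neg(phi), int(y.shape[0]))


def _log_cond_pmf(S: int, n1: int, n2: int, phi: float) -> np.ndarray:
    """log P(A = a | A + B = S) for a = 0..S under the common-mean null."""
    a = np.arange(S + 1)
    if phi == 0.0:
        # Poisson limit: Binomial(S, n1/(n1+n2))
        p = n1 / (n1 + n2)
        logpmf = (
            gammaln(S + 1) - gammaln(a + 1) - gammaln(S - a + 1)
            + a * np.log(p) + (S - a) * np.log1p(-p)
        )
        return logpmf
    r1 = n1 / phi
    r2 = n2 / phi
    logw = (
        gammaln(a + r1) - gammaln(a + 1) + gammaln(S - a + r2) - gammaln(S - a + 1)
    )
    return logw - logsumexp(logw)


def _exact_pvalue(A: int, S: int, n1: int, n2: int, phi: float) -> float:
    """Two-sided minimum-likelihood exact p-value for the observed split A of S."""
    if S == 0:
        return 1.0
    if S > _MAX_ENUM:
        raise ValueError(
            f"conditional total S={S} exceeds the enumeration cap {_MAX_ENUM}; "
            "downsample the counts before testing"
        )
    logpmf = _log_cond_pmf(S, n1, n2, phi)
    keep = logpmf <= logpmf[A] + _TIE_TOL
    return float(min(1.0, np.exp(logsumexp(logpmf[keep]))))


def exact_test(
    pseudo,
    groups,
    phi: float,
    prior_count: float = 0.5,
    common_size: float | None = None,
) -> pd.DataFrame:
    """Per-hairpin exact NB test of the two group sums.

    Returns a DataFrame (indexed like the input rows) with columns logFC,
    logCPM and pvalue.  logFC = log2((B/n2 + c)/(A/n1 + c)) with prior
    count c stabilizing zeros; logCPM uses the common library size, i.e.
    log2 CPM of the average pseudo-count.  Rows with S = 0 get p = 1 and
    logFC = 0 by convention.
    """
    if phi < 0:
        raise ValueError(f"dispersion must be >= 0, got {phi}")
    df = _as_frame(pseudo)
    m1, m2 = _group_masks(df.columns, groups)
    n1, n2 = int(m1.sum()), int(m2.sum())
    if common_size is None:
        common_size = float(df.sum(axis=0).mean())
    y = df.to_numpy(dtype=float)
    A = np.round(y[:, m1].sum(axis=1)).astype(np.int64)
    B = np.round(y[:, m2].sum(axis=1)).astype(np.int64)
    S = A + B
    c = prior_count
    logfc = np.log2((B / n2 + c) / np.where(S == 0, 1.0, A / n1 + c))
    logfc[S == 0] = 0.0
    # prior 0 with a zero group sum yields an infinite logFC by design;
    # any c > 0 keeps logFC finite
    logcpm = np.log2((S + 2 * c) / (common_size * (n1 + n2)) * 1e6)
    pvals = np.array([_exact_pvalue(int(a), int(s), n1, n2, phi) for a, s in zip(A, S)])
    return pd.DataFrame(
        {"logFC": logfc, "logCPM": logcpm, "pvalue": pvals}, index=df.index
    )


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and (np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def screen_exact_test(
    counts: CountMatrix,
    prior_count: float = 0.5,
    per_pool_fdr: bool = True,
    phi: float | None = None,
) -> pd.DataFrame:
    """Full differential-abundance analysis of a screen count matrix.

    Each pool is analyzed independently (its own library-size equalization,
    dispersion estimate and exact tests), matching a per-pool experimental
    design; BH adjustment runs within pools by default, globally otherwise.
    Pass ``phi`` to override dispersion estimation (e.g. 0 for Poisson).

    Returns one row per hairpin: gene, pool_id, logFC, logCPM, pvalue, fdr,
    phi (the dispersion used for that pool).
    """
    if counts.samples is None or counts.hairpins is None:
        raise ValueError("screen_exact_test needs full hairpin and sample metadata")
    frames = []
    for pool in pd.unique(counts.pool_of_hairpin()):
        sub = counts.subset_pool(pool)
        groups = sub.timepoint_of_sample()
        pseudo, common = equalize_libsizes(sub)
        pool_phi = phi if phi is not None else common_dispersion(pseudo, groups).phi
        res = exact_test(pseudo, groups, pool_phi, prior_count, common)
        res.insert(0, "gene", sub.genes)
        res.insert(1, "pool_id", pool)
        res["phi"] = pool_phi
        if per_pool_fdr:
            res["fdr"] = bh_fdr(res["pvalue"].to_numpy())
        frames.append(res)
    out = pd.concat(frames)
    if not per_pool_fdr:
        out["fdr"] = bh_fdr(out["pvalue"].to_numpy())
    out.index.name = "hairpin_id"
    return out
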