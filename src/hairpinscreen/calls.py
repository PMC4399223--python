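"""Hit calling, screen design arithmetic, sample QC and the
limiting-dilution frequency estimator.

``classify_hits`` applies the screen's published decision rule: a hairpin
is a hit when its BH-adjusted FDR is at or below ``fdr_max`` (0.01) and
its linear fold-change crosses ``fold_min`` (1.5) strictly in either
direction.  ``mds_qc`` reproduces the leading-fold-change
multidimensional-scaling view used to spot outlier samples, and
``limiting_dilution_frequency`` fits the single-hit Poisson model behind
stem-cell frequency estimates such as "1 in 298".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar
from scipy.stats import chi2

__all__ = [
    "classify_hits",
    "expected_representation",
    "mds_qc",
    "MDSResult",
    "limiting_dilution_frequency",
    "DilutionFit",
]

CLASSES = ("enriched", "depleted", "significant_only", "not_significant")


def classify_hits(
    results: pd.DataFrame,
    fdr_max: float = 0.01,
    fold_min: float = 1.5,
) -> tuple[pd.DataFrame, dict]:
    """Partition test results into enriched / depleted / significant_only /
    not_significant.

    ``results`` needs columns logFC, fdr and gene.  Significance is
    inclusive (fdr <= fdr_max); the fold threshold is strict
    (2^logFC > fold_min, or < 1/fold_min for depletion), so a hairpin at
    exactly the fold bound is significant_only.  The summary counts unique
    genes case-insensitively over significant rows.
    """
    if not fold_min > 1:
        raise ValueError(f"fold_min must exceed 1, got {fold_min}")
    if not 0 < fdr_max <= 1:
        raise ValueError(f"fdr_max must be in (0, 1], got {fdr_max}")
    for col in ("logFC", "fdr"):
        if col not in results.columns:
            raise ValueError(f"results lack a {col!r} column")
        if not np.all(np.isfinite(results[col])):
            raise ValueError(f"non-finite values in {col!r}")
    out = results.copy()
    fold = np.power(2.0, out["logFC"].to_numpy(dtype=float))
    sig = out["fdr"].to_numpy(dtype=float) <= fdr_max
    cls = np.where(
        ~sig,
        "not_significant",
        np.where(fold > fold_min, "enriched",
                 np.where(fold < 1 / fold_min, "depleted", "significant_only")),
    )
    out["fold_linear"] = fold
    out["call"] = cls
    genes = out.loc[sig, "gene"].astype(str).str.upper() if "gene" in out else pd.Series(dtype=str)
    summary = {
        "n_significant": int(sig.sum()),
        "n_enriched": int((cls == "enriched").sum()),
        "n_depleted": int((cls == "depleted").sum()),
        "n_unique_genes": int(genes.nunique()),
    }
    return out, summary


def expected_representation(
    n_cells: float, sphere_rate: float, infection_rate: float, pool_size: int
) -> float:
    """Expected sphere-forming transduced cells per hairpin.

    The screen's design arithmetic: of ``n_cells`` plated, a fraction
    ``sphere_rate`` forms spheres and ``infection_rate`` carries a hairpin,
    spread over ``pool_size`` library members.
    """
    for name, r in (("sphere_rate", sphere_rate), ("infection_rate", infection_rate)):
        if not 0 <= r <= 1:
            raise ValueError(f"{name} must be in [0, 1], got {r}")
    if pool_size < 1:
        raise ValueError(f"pool_size must be >= 1, got {pool_size}")
    if n_cells < 0:
        raise ValueError("n_cells must be non-negative")
    return n_cells * sphere_rate * infection_rate / pool_size


@dataclass
class MDSResult:
    coords: pd.DataFrame  # samples x (dim1, dim2)
    distances: pd.DataFrame  # samples x samples
    outliers: list[str]  # advisory flags; removal is the analyst's call


def mds_qc(counts, top_k: int = 500, mad_factor: float = 5.0) -> MDSResult:
    """Leading-fold-change MDS of samples with advisory outlier flags.

    The distance between two samples is the root mean square of the
    ``top_k`` largest absolute per-hairpin log2 differences of their CPM
    (0.5 added before log).  Samples are embedded by classical (Torgerson)
    scaling into 2-D; a sample is flagged when either coordinate sits more
    than ``mad_factor`` median-absolute-deviations from the median.
    """
    df = counts.counts if hasattr(counts, "counts") else pd.DataFrame(counts)
    if df.shape[1] < 3:
        raise ValueError("mds_qc needs at least 3 samples")
    colsums = df.sum(axis=0).to_numpy(dtype=float)
    logcpm = np.log2((df.to_numpy(dtype=float) + 0.5) / colsums * 1e6)
    n = df.shape[1]
    k = min(top_k, df.shape[0])
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = np.abs(logcpm[:, i] - logcpm[:, j])
            top = np.partition(d, len(d) - k)[len(d) - k:]
            D[i, j] = D[j, i] = float(np.sqrt(np.mean(top**2)))
    # Torgerson double centering
    J = np.eye(n) - np.ones((n, n)) / n
    Bmat = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(Bmat)
    order = np.argsort(vals)[::-1][:2]
    lam = np.clip(vals[order], 0.0, None)
    X = vecs[:, order] * np.sqrt(lam)
    coords = pd.DataFrame(X, index=df.columns, columns=["dim1", "dim2"])
    flagged: set[str] = set()
    for ax in coords.columns:
        x = coords[ax].to_numpy()
        med = np.median(x)
        mad = np.median(np.abs(x - med))
        dev = np.abs(x - med)
        flagged |= set(coords.index[dev > mad_factor * mad + 1e-12])
    return MDSResult(coords, pd.DataFrame(D, index=df.columns, columns=df.columns),
                     sorted(flagged))


@dataclass
class DilutionFit:
    """Single-hit fit: active-cell frequency f with 95% CI.

    ``frequency`` is the conventional "1 in N" denominator (1/f); the CI
    bounds are on the same scale, with ``frequency_upper`` = inf when all
    outgrowths were negative.
    """

    f: float
    f_lower: float
    f_upper: float

    @property
    def frequency(self) -> float:
        return np.inf if self.f == 0 else 1.0 / self.f

    @property
    def frequency_lower(self) -> float:  # optimistic bound (more frequent)
        return np.inf if self.f_lower == 0 else 1.0 / self.f_lower

    @property
    def frequency_upper(self) -> float:
        return np.inf if self.f_upper == 0 else 1.0 / self.f_upper


def limiting_dilution_frequency(assay: pd.DataFrame) -> DilutionFit:
    """MLE of the active-cell frequency under the single-hit Poisson model.

    ``assay`` has columns dose (cells per transplant), n (transplants) and
    positive (outgrowths).  Pr(outgrowth | dose d) = 1 - exp(-f d); f
    maximizes the binomial likelihood and the 95% CI inverts the likelihood
    ratio at the chi-square(1) 0.95 quantile.  All-positive tables leave f
    unbounded above and raise; all-negative tables give f = 0 with lower
    bound 0.
    """
    req = {"dose", "n", "positive"}
    if not req <= set(assay.columns):
        raise ValueError(f"assay table needs columns {sorted(req)}")
    dose = assay["dose"].to_numpy(dtype=float)
    n = assay["n"].to_numpy(dtype=float)
    pos = assay["positive"].to_numpy(dtype=float)
    if np.any(dose <= 0) or np.any(n < 0) or np.any(pos < 0) or np.any(pos > n):
        raise ValueError("assay table violates 0 <= positive <= n, dose > 0")
    informative = n > 0
    if not informative.any():
        raise ValueError("assay table has no transplants")
    dose, n, pos = dose[informative], n[informative], pos[informative]
    if np.all(pos == n):
        raise ValueError("every transplant positive: frequency unbounded above")

    def loglik(f: float) -> float:
        if f < 0:
            return -np.inf
        if f == 0:
            return -np.inf if pos.sum() > 0 else 0.0
        p = -np.expm1(-f * dose)
        with np.errstate(divide="ignore"):
            hit_term = np.where(pos > 0, pos * np.log(p), 0.0)
        return float(np.sum(hit_term - (n - pos) * f * dose))

    f_hi_bracket = 100.0 / dose.min()
    if pos.sum() == 0:
        f_hat, ll_hat = 0.0, 0.0
    else:
        res = minimize_scalar(
            lambda t: -loglik(np.exp(t)),
            bounds=(np.log(1e-12 / dose.max()), np.log(f_hi_bracket)),
            method="bounded",
            options={"xatol": 1e-13},
        )
        f_hat = float(np.exp(res.x))
        ll_hat = loglik(f_hat)

    drop = chi2.ppf(0.95, df=1) / 2.0

    def g(f: float) -> float:
        return loglik(f) - (ll_hat - drop)

    if f_hat == 0 or g(1e-15 / dose.max()) > 0:
        f_lo = 0.0
    else:
        f_lo = float(brentq(g, 1e-15 / dose.max(), f_hat, xtol=1e-16))
    if g(f_hi_bracket) > 0:
        f_up = np.inf
    else:
        f_up = float(brentq(g, max(f_hat, 1e-300), f_hi_bracket, xtol=1e-16))
    return DilutionFit(f_hat, f_lo, f_up)
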