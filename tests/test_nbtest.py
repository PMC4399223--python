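"""Statistical core: equalization, dispersion, exact test, FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import gammaln
from scipy.stats import binom, kstest, nbinom

import hairpinscreen as hs
from hairpinscreen.nbtest import _exact_pvalue

GROUPS_2V2 = ["T2", "T2", "T14", "T14"]
GROUPS_3V3 = ["T2"] * 3 + ["T14"] * 3


# ---------------------------------------------------------------- oracles

def oracle_pvalues(S, n1, n2, phi, mu=7.0):
    """Brute-force conditional p-values for every split of S, built from
    scipy count pmfs rather than the implementation's gamma-function route."""
    a = np.arange(S + 1)
    if phi == 0:
        pmf = binom.pmf(a, S, n1 / (n1 + n2))
    else:
        r1, r2 = n1 / phi, n2 / phi
        w = nbinom.pmf(a, r1, r1 / (r1 + n1 * mu)) * nbinom.pmf(
            S - a, r2, r2 / (r2 + n2 * mu)
        )
        pmf = w / w.sum()
    return np.array(
        [min(1.0, pmf[pmf <= pmf[A] * (1 + 1e-8)].sum()) for A in range(S + 1)]
    )


# ----------------------------------------------------------- equalization

def test_equal_depths_are_identity(rng):
    df = pd.DataFrame(rng.integers(0, 50, (30, 4)))
    df.iloc[0] += (df.sum(0).max() - df.sum(0)).to_numpy()
    pseudo, common = hs.equalize_libsizes(df)
    assert np.allclose(pseudo, df)
    assert common == pytest.approx(df.sum(0).iloc[0])


def test_geometric_mean_scaling():
    df = pd.DataFrame({"a": [60, 40], "b": [300, 100]})  # colsums 100 and 400
    pseudo, common = hs.equalize_libsizes(df)
    assert common == pytest.approx(200.0)
    assert np.allclose(pseudo["a"], df["a"] * 2)
    assert np.allclose(pseudo["b"], df["b"] * 0.5)
    assert np.allclose(pseudo.sum(0), common)


def test_equalize_rejects_all_zero():
    with pytest.raises(ValueError):
        hs.equalize_libsizes(pd.DataFrame({"a": [0, 0], "b": [0, 0]}))


# ------------------------------------------------------------- dispersion

def test_dispersion_argmax_matches_grid_oracle(rng):
    """The bounded optimizer lands on the same phi as a dense grid over the
    summed conditional log-likelihood of a small toy matrix."""
    mu = rng.lognormal(3, 1, 20)
    r = 1 / 0.3
    df = pd.DataFrame(
        {f"s{j}": rng.negative_binomial(r, r / (r + mu)) for j in range(4)}
    )
    est = hs.common_dispersion(df, GROUPS_2V2)

    def cond_ll(y, phi):  # independent gamma-function route, per group
        rr = 1.0 / phi
        n = y.shape[1]
        z = y.sum(1)
        return float(
            (gammaln(y + rr).sum(1) - gammaln(y + 1).sum(1) - n * gammaln(rr)
             - gammaln(z + n * rr) + gammaln(n * rr) + gammaln(z + 1)).sum()
        )

    y = np.round(df.to_numpy(float)).astype(int)
    grid = np.linspace(1e-4, 2.0, 2000)
    lls = [cond_ll(y[:, :2], p) + cond_ll(y[:, 2:], p) for p in grid]
    assert abs(est.phi - grid[int(np.argmax(lls))]) < 2e-3  # grid spacing 1e-3
    # refined grid pins it to the optimizer tolerance
    fine = np.linspace(est.phi - 2e-3, est.phi + 2e-3, 2000)
    lls = [cond_ll(y[:, :2], p) + cond_ll(y[:, 2:], p) for p in fine]
    assert abs(est.phi - fine[int(np.argmax(lls))]) < 1e-4


def test_dispersion_recovery_poisson():
    lib = hs.synthetic_library(1, 1000, seed=21)
    smp = hs.synthetic_samples(["pool1"], 3, seed=21)
    cfg = hs.SimulationConfig(hit_fraction=0.0, phi=0.0, mean_libsize=5e5)
    truth = hs.simulate_truth(lib, smp, cfg, seed=22)
    cm = hs.simulate_counts(truth, lib, smp, seed=23)
    pseudo, _ = hs.equalize_libsizes(cm)
    est = hs.common_dispersion(pseudo, cm.timepoint_of_sample())
    assert est.phi <= 0.01


def test_dispersion_requires_replication():
    df = pd.DataFrame({"a": [1, 2], "b": [3, 4]})
    with pytest.raises(ValueError, match="estimable"):
        hs.common_dispersion(df, ["T2", "T14"])


# ------------------------------------------------------------- exact test

def test_balanced_split_has_p_one():
    assert _exact_pvalue(5, 10, 1, 1, 0.0) == pytest.approx(1.0)


def test_extreme_split_matches_binomial_tail():
    # A=0, B=10 under Binomial(10, 1/2): p = 2 * (1/2)^10
    assert _exact_pvalue(0, 10, 1, 1, 0.0) == pytest.approx(2 * 0.5**10, rel=1e-12)


def test_logfc_arithmetic_forced():
    ps = pd.DataFrame({"a1": [50], "a2": [50], "b1": [200], "b2": [200]})
    res = hs.exact_test(ps, GROUPS_2V2, 0.1, prior_count=0.0)
    assert res["logFC"].iloc[0] == pytest.approx(2.0)


def test_zero_total_convention():
    ps = pd.DataFrame({"a1": [0], "a2": [0], "b1": [0], "b2": [0]})
    res = hs.exact_test(ps, GROUPS_2V2, 0.1, common_size=100.0)
    assert res["pvalue"].iloc[0] == 1.0 and res["logFC"].iloc[0] == 0.0


def test_negative_dispersion_rejected():
    with pytest.raises(ValueError):
        hs.exact_test(pd.DataFrame({"a": [1], "b": [2]}), ["T2", "T14"], -0.1)


@pytest.mark.parametrize("phi", [0.0, 0.1, 0.5])
@pytest.mark.parametrize("n", [1, 2, 3])
def test_exact_test_equals_enumeration_oracle(phi, n):
    """Spot grid of conditional totals; the full S<=200 sweep runs in the
    acceptance suite."""
    for S in (1, 2, 7, 33, 100, 200):
        ours = np.array([_exact_pvalue(A, S, n, n, phi) for A in range(S + 1)])
        assert np.allclose(ours, oracle_pvalues(S, n, n, phi), rtol=1e-12)


def test_unequal_group_sizes_against_oracle():
    for S in (5, 40, 120):
        for phi in (0.0, 0.2):
            ours = np.array([_exact_pvalue(A, S, 2, 3, phi) for A in range(S + 1)])
            assert np.allclose(ours, oracle_pvalues(S, 2, 3, phi), rtol=1e-12)


def test_binomial_limit_total_variation():
    """At phi=0 and 1 vs 1 the conditional law is Binomial(S, 1/2)."""
    from hairpinscreen.nbtest import _log_cond_pmf

    S = 60
    ours = np.exp(_log_cond_pmf(S, 1, 1, 0.0))
    tv = 0.5 * np.abs(ours - binom.pmf(np.arange(S + 1), S, 0.5)).sum()
    assert tv < 1e-12


def test_group_swap_antisymmetry(rng):
    df = pd.DataFrame(rng.integers(0, 400, (50, 6)),
                      columns=[f"s{j}" for j in range(6)])
    fwd = hs.exact_test(df, GROUPS_3V3, 0.1)
    rev = hs.exact_test(df, ["T14"] * 3 + ["T2"] * 3, 0.1)
    assert np.allclose(fwd["logFC"], -rev["logFC"])
    assert np.allclose(fwd["pvalue"], rev["pvalue"])


def test_null_pvalues_super_uniform():
    """Simulated null screen: exact-test p-values do not reject uniformity.

    Discreteness makes the exact test conservative, so the KS statistic is
    only checked against rejection, not equality."""
    lib = hs.synthetic_library(1, 2000, seed=31)
    smp = hs.synthetic_samples(["pool1"], 3, seed=31)
    cfg = hs.SimulationConfig(hit_fraction=0.0, phi=0.1, mean_libsize=2000 * 200.0)
    truth = hs.simulate_truth(lib, smp, cfg, seed=32)
    cm = hs.simulate_counts(truth, lib, smp, seed=33)
    pseudo, common = hs.equalize_libsizes(cm)
    phi = hs.common_dispersion(pseudo, cm.timepoint_of_sample()).phi
    res = hs.exact_test(pseudo, cm.timepoint_of_sample(), phi, common_size=common)
    assert kstest(res["pvalue"], "uniform").pvalue > 0.001
    assert (res["pvalue"] < 0.05).mean() < 0.065


# -------------------------------------------------------------------- FDR

def test_bh_examples():
    assert hs.bh_fdr([0.03]) == pytest.approx([0.03])
    assert hs.bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])


def test_bh_rejects_out_of_range():
    for bad in ([0.0], [1.1], [np.nan]):
        with pytest.raises(ValueError):
            hs.bh_fdr(bad)


@settings(deadline=None, derandomize=True)
@given(st.lists(st.floats(1e-12, 1.0, exclude_min=False), min_size=1, max_size=40))
def test_bh_is_monotone_and_dominates_p(ps):
    adj = hs.bh_fdr(ps)
    assert np.all(adj >= np.asarray(ps) - 1e-15)
    assert np.all(adj <= 1.0)
    order = np.argsort(ps)
    assert np.all(np.diff(adj[order]) >= -1e-15)


def test_screen_results_fdr_dominates_p(small_screen):
    _, counts = small_screen
    res = hs.screen_exact_test(counts)
    assert (res["fdr"] >= res["pvalue"] - 1e-15).all()
    assert np.isfinite(res.loc[counts.counts.sum(1) > 0, "logFC"]).all()
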