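"""CPM, TMM, expressed calls, cross-reference, probe collapse."""

import numpy as np
import pandas as pd
import pytest

import hairpinscreen as hs


# -------------------------------------------------------------------- CPM

def test_cpm_unit_count_in_million():
    df = pd.DataFrame({"s": [1, 10**6 - 1]})
    assert hs.cpm(df)["s"].iloc[0] == pytest.approx(1.0)


def test_cpm_scale_invariance(rng):
    df = pd.DataFrame(rng.integers(1, 100, (50, 4)))
    assert np.allclose(hs.cpm(df), hs.cpm(df * 2))


def test_cpm_columns_sum_to_million(rng):
    df = pd.DataFrame(rng.integers(0, 100, (50, 4)) + 1)
    assert np.allclose(hs.cpm(df).sum(0), 1e6)


def test_cpm_zero_column_rejected():
    with pytest.raises(ValueError):
        hs.cpm(pd.DataFrame({"a": [1, 2], "b": [0, 0]}))


def test_log_cpm_finite_at_zero(rng):
    df = pd.DataFrame(rng.integers(0, 5, (30, 3)) * rng.integers(0, 2, (30, 3)) + 0)
    df.iloc[0] = 0
    out = hs.cpm(df + pd.DataFrame(np.eye(30, 3, dtype=int) * 0), log=True)
    assert np.isfinite(out.to_numpy()).all()


# -------------------------------------------------------------------- TMM

def test_identical_columns_give_unit_factors(rng):
    col = rng.integers(1, 500, 200)
    df = pd.DataFrame({"a": col, "b": col})
    assert np.allclose(hs.tmm_factors(df), 1.0)


def test_pure_depth_change_gives_unit_factors(rng):
    col = rng.integers(1, 500, 200)
    df = pd.DataFrame({"a": col, "b": 2 * col})
    assert np.allclose(hs.tmm_factors(df), 1.0)


def test_tmm_matches_step_by_step_oracle(rng):
    """Planted asymmetric composition: 10% of genes 8-fold up in one column.
    The factors must match an independently coded trimmed-mean calculation."""
    base = rng.integers(50, 1000, 400).astype(float)
    other = base.copy()
    other[:40] *= 8
    df = pd.DataFrame({"ref": base, "obs": other})
    factors = hs.tmm_factors(df, ref="ref")

    # oracle: literal transcription of the weighted trimmed mean of M-values
    n_o, n_r = other.sum(), base.sum()
    M = np.log2((other / n_o) / (base / n_r))
    A = 0.5 * (np.log2(other / n_o) + np.log2(base / n_r))
    w = (n_o - other) / (n_o * other) + (n_r - base) / (n_r * base)
    n = len(M)
    lo_m, hi_m = np.floor(n * 0.3) + 1, n - np.floor(n * 0.3)
    lo_a, hi_a = np.floor(n * 0.05) + 1, n - np.floor(n * 0.05)
    rm = pd.Series(M).rank().to_numpy()
    ra = pd.Series(A).rank().to_numpy()
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    f_obs = 2 ** (np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep]))
    expected = np.array([1.0, f_obs])
    expected /= np.exp(np.mean(np.log(expected)))
    assert np.allclose(factors.to_numpy(), expected, atol=1e-9)


def test_tmm_product_is_one(rng):
    df = pd.DataFrame(rng.integers(1, 1000, (300, 5)))
    assert np.prod(hs.tmm_factors(df)) == pytest.approx(1.0, abs=1e-12)


def test_tmm_rejects_degenerate_input(rng):
    with pytest.raises(ValueError):
        hs.tmm_factors(pd.DataFrame({"a": [1, 2]}))
    with pytest.raises(ValueError):
        hs.tmm_factors(pd.DataFrame({"a": [1, 2], "b": [0, 0]}))


# -------------------------------------------------------- expressed calls

def test_expressed_calls_strict_threshold():
    expr = pd.DataFrame({"P": [0.5, 0.51, 0.0]}, index=["g1", "g2", "g3"])
    calls = hs.expressed_calls(expr, threshold=0.5)
    assert calls["P"].tolist() == [False, True, False]


def test_expressed_calls_average_replicates_first():
    expr = pd.DataFrame({"P_r1": [0.2], "P_r2": [1.0]}, index=["g"])
    calls = hs.expressed_calls(expr, replicate_map={"P_r1": "P", "P_r2": "P"})
    assert calls.columns.tolist() == ["P"]
    assert bool(calls.loc["g", "P"]) is True  # mean 0.6 > 0.5


def test_expressed_calls_monotone_in_threshold(rng):
    expr = pd.DataFrame(rng.uniform(0, 5, (40, 3)), columns=list("abc"))
    lo = hs.expressed_calls(expr, threshold=0.5)
    hi = hs.expressed_calls(expr, threshold=2.0)
    assert not (hi & ~lo).any().any()  # raising threshold never adds a call
    with pytest.raises(ValueError):
        hs.expressed_calls(expr, threshold=-1)


# -------------------------------------------------------- cross-reference

POPS = ["Basal", "LP", "ML"]


def _calls(table):
    return pd.DataFrame(table, columns=POPS + ["Sphere"]).T.rename(
        columns=lambda i: f"g{i}"
    ).T


def test_cross_reference_all_expressed():
    calls = pd.DataFrame(True, index=[f"g{i}" for i in range(5)],
                         columns=POPS + ["Sphere"])
    out = hs.cross_reference(calls.index, calls, POPS, "Sphere")
    assert (out["n_primary"], out["n_primary_and_sphere"],
            out["n_sphere_only"], out["n_nowhere"]) == (5, 5, 0, 0)


def test_cross_reference_none_expressed():
    calls = pd.DataFrame(False, index=[f"g{i}" for i in range(4)],
                         columns=POPS + ["Sphere"])
    out = hs.cross_reference(calls.index, calls, POPS, "Sphere")
    assert out["n_nowhere"] == 4 and out["n_primary"] == 0


def test_cross_reference_matches_set_arithmetic(rng):
    genes = [f"g{i}" for i in range(10)]
    calls = pd.DataFrame(
        rng.random((10, 4)) < 0.5, index=genes, columns=POPS + ["Sphere"]
    )
    out = hs.cross_reference(genes, calls, POPS, "Sphere")
    prim = {g for g in genes if calls.loc[g, POPS].any()}
    sphere = {g for g in genes if calls.loc[g, "Sphere"]}
    assert out["n_primary"] == len(prim)
    assert out["n_primary_and_sphere"] == len(prim & sphere)
    assert out["n_sphere_only"] == len(sphere - prim)
    assert out["n_nowhere"] == len(set(genes) - prim - sphere)
    total = out["n_primary"] + out["n_sphere_only"] + out["n_nowhere"]
    assert total == out["n_hit_genes"] == 10


def test_cross_reference_case_insensitive_and_strict():
    calls = pd.DataFrame(True, index=["MYOG"], columns=POPS + ["Sphere"])
    out = hs.cross_reference(["Myog"], calls, POPS, "Sphere")
    assert out["n_primary"] == 1
    with pytest.raises(ValueError, match="absent"):
        hs.cross_reference(["missing"], calls, POPS, "Sphere")
    with pytest.raises(ValueError, match="population"):
        hs.cross_reference(["MYOG"], calls, POPS, "NoPop")


# ---------------------------------------------------------- probe collapse

def test_collapse_identity_when_one_probe_per_gene(rng):
    df = pd.DataFrame(rng.random((3, 2)), index=["p1", "p2", "p3"])
    mapping = {"p1": "A", "p2": "B", "p3": "C"}
    out = hs.collapse_probes(df, mapping)
    assert np.allclose(out.to_numpy(), df.to_numpy())


def test_collapse_keeps_highest_average_probe():
    df = pd.DataFrame({"s1": [5.0, 7.0], "s2": [5.0, 7.0]}, index=["pA", "pB"])
    out = hs.collapse_probes(df, {"pA": "G", "pB": "G"})
    assert out.loc["G", "s1"] == 7.0


def test_collapse_tie_breaks_lexicographically():
    df = pd.DataFrame({"s1": [5.0, 5.0]}, index=["pZ", "pA"])
    out = hs.collapse_probes(df, {"pZ": "G", "pA": "G"})
    assert out.loc["G", "s1"] == 5.0
    # the retained probe is pA: modify it and observe the change
    df.loc["pA", "s1"] = 6.0
    assert hs.collapse_probes(df, {"pZ": "G", "pA": "G"}).loc["G", "s1"] == 6.0


def test_collapse_rejects_unmapped_probes():
    df = pd.DataFrame({"s1": [1.0]}, index=["p1"])
    with pytest.raises(ValueError):
        hs.collapse_probes(df, {})
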