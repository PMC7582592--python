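from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from mirqpcr import (
    candidate_filter,
    combine_sss,
    cv_score,
    genorm_m,
    genorm_stepwise,
    normfinder_rho,
    rank_candidates,
    select_references,
)
from conftest import make_ct, make_sheet

DATA = Path(__file__).parent / "data"


# ---------------------------------------------------------------- candidates

def test_candidate_filter_keeps_complete_rows():
    vals = np.full((3, 4), 30.0)
    vals[0, 2] = np.nan
    vals[2, 0] = np.nan
    ct = make_ct(vals)
    assert candidate_filter(ct) == ["mir-2"]
    full = make_ct(np.full((3, 4), 30.0))
    assert candidate_filter(full) == full.mirna_ids


def test_candidate_filter_matches_row_scan(rng):
    vals = rng.uniform(20, 34, size=(40, 10))
    vals[rng.random((40, 10)) < 0.15] = np.nan
    ct = make_ct(vals)
    expect = [m for i, m in enumerate(ct.mirna_ids) if not np.isnan(vals[i]).any()]
    assert candidate_filter(ct) == expect


def test_candidate_filter_empty_is_error():
    vals = np.full((2, 3), 30.0)
    vals[0, 0] = vals[1, 2] = np.nan
    with pytest.raises(ValueError, match="detection threshold|QC"):
        candidate_filter(make_ct(vals))


# ------------------------------------------------------------------- geNorm

def _brute_force_m(arr):
    n = arr.shape[0]
    m = np.zeros(n)
    for j in range(n):
        vs = []
        for k in range(n):
            if k != j:
                vs.append(np.std(arr[j] - arr[k], ddof=1))
        m[j] = np.mean(vs)
    return m


def test_genorm_matches_pairwise_double_loop(rng):
    arr = rng.uniform(18, 34, size=(8, 10))
    got = genorm_m(make_ct(arr)).to_numpy()
    assert np.allclose(got, _brute_force_m(arr), atol=1e-10, rtol=0)


def test_constant_ratio_pair_has_equal_m(rng):
    base = rng.uniform(20, 30, size=10)
    third = rng.uniform(20, 30, size=10)
    ct = make_ct([base, base + 2.0, third])
    m = genorm_m(ct)
    # V(mir-1, mir-2) = 0, so both share the same single nonzero partner term
    assert m["mir-1"] == pytest.approx(m["mir-2"], abs=1e-12)


def test_genorm_invariant_to_sample_offsets(rng):
    arr = rng.uniform(18, 34, size=(6, 8))
    offsets = rng.normal(0, 2, size=8)
    m0 = genorm_m(make_ct(arr)).to_numpy()
    m1 = genorm_m(make_ct(arr + offsets[None, :])).to_numpy()
    assert np.allclose(m0, m1, atol=1e-9)


def test_genorm_requires_three_candidates():
    with pytest.raises(ValueError, match="3 candidate"):
        genorm_m(make_ct(np.full((2, 5), 30.0)))


def test_genorm_stepwise_keeps_most_stable_last(rng):
    stable = np.tile(rng.uniform(24, 25, size=6), (2, 1)) + rng.normal(0, 0.01, (2, 6))
    noisy = rng.uniform(20, 34, size=(4, 6))
    ct = make_ct(np.vstack([noisy, stable]),
                 mirnas=[f"noisy-{i}" for i in range(4)] + ["stab-1", "stab-2"])
    order = genorm_stepwise(ct)
    assert set(order[-2:]) == {"stab-1", "stab-2"}


# --------------------------------------------------------------- NormFinder

def _normfinder_oracle(arr, groups):
    """Step-by-step spreadsheet-style recomputation with explicit loops."""
    n_genes, n_samples = arr.shape
    labels = list(dict.fromkeys(groups))
    d = arr.copy()
    for j in range(n_samples):  # sample centering
        d[:, j] -= np.mean(arr[:, j])
    means, s2 = {}, {}
    for g in labels:
        cols = [j for j, lab in enumerate(groups) if lab == g]
        means[g] = np.array([np.mean(d[i, cols]) for i in range(n_genes)])
        s2[g] = np.array([np.var(d[i, cols], ddof=1) for i in range(n_genes)])
    sigma2 = {}
    for g in labels:
        corr = (s2[g] - np.mean(s2[g]) / (n_genes - 1)) / (1 - 2 / n_genes)
        sigma2[g] = np.maximum(corr, 0.0)
    grand = np.zeros(n_genes)
    for g in labels:
        grand += means[g]
    grand /= len(labels)
    z = {g: means[g] - grand for g in labels}
    n_per = {g: groups.count(g) for g in labels}
    samp_var = {g: sigma2[g] / n_per[g] for g in labels}
    num = sum(float(np.sum(z[g] ** 2)) for g in labels)
    gamma2 = num / ((n_genes - 1) * (len(labels) - 1)) - float(
        np.mean([samp_var[g] for g in labels])
    )
    gamma2 = max(gamma2, 0.0)
    rho = np.zeros(n_genes)
    for g in labels:
        if gamma2 > 0:
            zhat = z[g] * gamma2 / (gamma2 + samp_var[g])
        else:
            zhat = np.zeros(n_genes)
        rho += np.abs(zhat) + np.sqrt(samp_var[g])
    return rho / len(labels)


def _load_fixture():
    df = pd.read_csv(DATA / "normfinder_synthetic_6x15.csv", index_col=0)
    ct = make_ct(df.to_numpy(), mirnas=list(df.index), samples=list(df.columns))
    groups = [s.split("-")[0] for s in df.columns]
    return ct, make_sheet(groups, samples=list(df.columns))


def test_normfinder_matches_loop_oracle_on_fixture():
    ct, sheet = _load_fixture()
    got = normfinder_rho(ct, sheet).to_numpy()
    expect = _normfinder_oracle(ct.values.to_numpy(), [s.split("-")[0] for s in ct.sample_ids])
    assert np.allclose(got, expect, atol=1e-12, rtol=0)
    # frozen values from the oracle, regression guard
    frozen = [0.15637671, 0.22972947, 0.35537638, 0.18897887, 0.21293262, 0.17071991]
    assert np.allclose(got, frozen, atol=1e-6)


def test_perfectly_stable_gene_attains_minimal_rho(rng):
    n = 8
    arr = rng.uniform(20, 32, size=(6, 3 * n)) + rng.normal(0, 0.6, size=(6, 3 * n))
    offsets = rng.normal(0, 0.5, size=3 * n)
    arr += offsets[None, :]
    # gene 0 tracks the per-sample offset exactly: zero residual variance and
    # identical group means after centering up to the others' noise leakage
    arr[0] = 25.0 + offsets
    groups = ["A"] * n + ["B"] * n + ["C"] * n
    rho = normfinder_rho(make_ct(arr), make_sheet(groups))
    assert rho.idxmin() == "mir-1"


def test_normfinder_group_label_permutation_keeps_distribution(rng):
    arr = rng.normal(27, 0.5, size=(5, 12))
    groups = ["A"] * 4 + ["B"] * 4 + ["C"] * 4
    sheet = make_sheet(groups)
    rho0 = normfinder_rho(make_ct(arr), sheet)
    # exchangeable data, equal n: relabeling groups permutes nothing material
    perm = ["B"] * 4 + ["C"] * 4 + ["A"] * 4
    rho1 = normfinder_rho(make_ct(arr), make_sheet(perm))
    assert np.allclose(rho0.to_numpy(), rho1.to_numpy(), atol=1e-12)


def test_normfinder_small_group_errors():
    arr = np.full((3, 5), 30.0)
    with pytest.raises(ValueError, match="fewer than 2"):
        normfinder_rho(make_ct(arr), make_sheet(["A"] * 4 + ["B"]))


# ----------------------------------------------------------------- CV score

def test_cv_score_constant_row_is_zero(rng):
    arr = np.vstack([np.full(6, 30.0), rng.uniform(20, 34, size=(2, 6))])
    s = cv_score(make_ct(arr))
    assert s["mir-1"] == 0.0
    assert s.sum() == pytest.approx(1.0, abs=1e-12)


def test_cv_score_symmetry():
    # two rows with identical CV by construction
    a = np.array([20.0, 22.0, 24.0])
    s = cv_score(make_ct([a, 2 * a]))
    assert np.allclose(s.to_numpy(), [0.5, 0.5], atol=1e-12)


def test_cv_score_sums_to_one(rng):
    for _ in range(5):
        arr = rng.uniform(18, 36, size=(rng.integers(3, 12), rng.integers(3, 10)))
        assert cv_score(make_ct(arr)).sum() == pytest.approx(1.0, abs=1e-12)


def test_cv_score_all_constant_is_error():
    with pytest.raises(ValueError, match="constant"):
        cv_score(make_ct(np.full((3, 4), 30.0)))


def test_cv_score_not_offset_invariant(rng):
    """Unlike geNorm M, the CV score responds to per-sample offsets."""
    arr = np.tile(rng.uniform(22, 30, size=4)[:, None], (1, 8))
    arr += rng.normal(0, 0.05, size=arr.shape)
    offsets = np.linspace(-2, 2, 8)
    s0 = cv_score(make_ct(arr))
    s1 = cv_score(make_ct(arr + offsets[None, :]))
    assert not np.allclose(s0.to_numpy(), s1.to_numpy(), atol=1e-3)


# ---------------------------------------------------------------------- SSS

def test_sss_closed_forms():
    idx = pd.Index(["a", "b"], name="mirna")
    tab = combine_sss(
        pd.Series([0.0, 3.0], index=idx),
        pd.Series([0.0, 4.0], index=idx),
        pd.Series([0.0, 0.0], index=idx),
    )
    assert tab.table.set_index("mirna").loc["a", "sss"] == 0.0
    assert tab.table.set_index("mirna").loc["b", "sss"] == pytest.approx(5.0)
    assert tab.table.set_index("mirna").loc["a", "rank"] == 1


def test_sss_ties_break_lexicographically():
    idx = pd.Index(["zz", "aa"], name="mirna")
    ones = pd.Series([1.0, 1.0], index=idx)
    tab = combine_sss(ones, ones, ones)
    ordered = tab.table.sort_values("rank")["mirna"].tolist()
    assert ordered == ["aa", "zz"]


def test_sss_monotone_in_each_component(rng):
    idx = pd.Index(["a", "b", "c"], name="mirna")
    m = pd.Series(rng.uniform(0, 1, 3), index=idx)
    r = pd.Series(rng.uniform(0, 1, 3), index=idx)
    c = pd.Series(rng.uniform(0, 0.2, 3), index=idx)
    base = combine_sss(m, r, c).table.set_index("mirna")["sss"]
    bumped = combine_sss(m + pd.Series([0.5, 0, 0], index=idx), r, c)
    assert bumped.table.set_index("mirna").loc["a", "sss"] > base["a"]


def test_ranking_invariant_to_candidate_order(rng, three_group_sheet):
    arr = rng.uniform(20, 32, size=(10, 15))
    ct = make_ct(arr)
    tab0 = rank_candidates(ct, three_group_sheet)
    perm = list(rng.permutation(ct.mirna_ids))
    tab1 = rank_candidates(ct.subset_mirnas(perm), three_group_sheet)
    r0 = tab0.table.set_index("mirna")["rank"]
    r1 = tab1.table.set_index("mirna")["rank"]
    assert r0.sort_index().tolist() == r1.sort_index().tolist()


def test_select_references_edges():
    idx = pd.Index(["a", "b", "c"], name="mirna")
    tab = combine_sss(
        pd.Series([0.3, 0.1, 0.2], index=idx),
        pd.Series([0.0, 0.0, 0.0], index=idx),
        pd.Series([0.0, 0.0, 0.0], index=idx),
    )
    assert select_references(tab, k=1) == ["b"]
    assert select_references(tab, k=3) == ["b", "c", "a"]
    with pytest.raises(ValueError):
        select_references(tab, k=0)
    with pytest.raises(ValueError):
        select_references(tab, k=4)


def test_misaligned_inputs_rejected():
    a = pd.Series([1.0], index=pd.Index(["a"], name="mirna"))
    b = pd.Series([1.0], index=pd.Index(["b"], name="mirna"))
    with pytest.raises(ValueError, match="same miRNAs"):
        combine_sss(a, b, a)
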