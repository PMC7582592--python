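from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from mirqpcr import (
    DEThresholds,
    mann_whitney_test,
    profiling_de,
    spearman_correlation,
    validation_de,
    volcano_table,
)
from conftest import make_ct, make_sheet


# ------------------------------------------------------------- Mann-Whitney

def _mw_enumeration_p(a, b):
    """Exact two-sided p by enumerating all rank assignments (no ties)."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n_a = len(a)
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2
    u_obs = min(u_obs, len(a) * len(b) - u_obs)  # two-sided via min(U, U')
    count = 0
    total = 0
    for idx in combinations(range(len(pooled)), n_a):
        u = sum(ranks[list(idx)]) - n_a * (n_a + 1) / 2
        u = min(u, len(a) * len(b) - u)
        total += 1
        if u <= u_obs:
            count += 1
    return count / total


def test_mann_whitney_separated_triplets():
    assert mann_whitney_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)


def test_mann_whitney_identical_samples():
    assert mann_whitney_test([2.0, 2.0, 2.0], [2.0, 2.0, 2.0]) == 1.0


@pytest.mark.parametrize("n_a,n_b", [(2, 3), (3, 3), (4, 5), (5, 5), (7, 6)])
def test_mann_whitney_matches_enumeration(n_a, n_b, rng):
    vals = rng.normal(size=n_a + n_b)
    while np.unique(vals).size < vals.size:
        vals = rng.normal(size=n_a + n_b)
    a, b = vals[:n_a], vals[n_a:]
    assert mann_whitney_test(a, b) == pytest.approx(_mw_enumeration_p(a, b), abs=1e-12)


def test_mann_whitney_tie_fallback_is_finite(rng):
    a = [1.0, 2.0, 2.0, 3.0]
    b = [2.0, 4.0, 4.0, 5.0]
    p = mann_whitney_test(a, b)
    assert 0 < p <= 1


# ------------------------------------------------------------- profiling DE

def _planted_ct(rng, n_null=20, shift=np.log2(3), noise=0.1):
    """3 refs + 1 planted DE miRNA + nulls on a 5/5/5 layout."""
    n = 4 + n_null
    base = rng.uniform(22, 30, size=n)
    vals = base[:, None] + rng.normal(0, noise, size=(n, 15))
    vals[3, 10:] += shift  # mir-4 shifted up (down-expressed) in the third group
    return make_ct(vals), make_sheet(["CTR"] * 5 + ["D"] * 5 + ["DME"] * 5)


def test_profiling_de_calls_planted_and_skips_null(rng):
    ct, sheet = _planted_ct(rng)
    res = profiling_de(ct, sheet, refs=["mir-1", "mir-2", "mir-3"])
    assert "mir-4" in res.consensus_set("DME_vs_CTR")
    cons = set(res.consensus_set())
    assert cons == {"mir-4"}
    row = res.consensus[(res.consensus["mirna"] == "mir-4")
                        & (res.consensus["comparison"] == "DME_vs_CTR")]
    assert row["direction"].iloc[0] == "down"


def test_fold_gate_blocks_small_folds(rng):
    # strong p but only 2-fold: below the 2.5-fold cutoff
    ct, sheet = _planted_ct(rng, shift=1.0, noise=0.05)
    res = profiling_de(ct, sheet, refs=["mir-1", "mir-2", "mir-3"])
    assert res.consensus_set() == []
    sub = res.table[(res.table["mirna"] == "mir-4")
                    & (res.table["comparison"] == "DME_vs_CTR")]
    assert (sub["p"] <= 0.05).all()  # p passes; the fold gate is what blocks


def test_identical_groups_not_significant():
    vals = np.tile(np.linspace(22, 30, 5)[:, None], (1, 15))
    ct = make_ct(vals)
    sheet = make_sheet(["CTR"] * 5 + ["D"] * 5 + ["DME"] * 5)
    res = profiling_de(ct, sheet, refs=["mir-1", "mir-2", "mir-3"])
    assert not res.table["significant"].any()
    assert np.allclose(res.table["fc"].dropna().to_numpy(), 1.0)


def test_consensus_subset_of_each_strategy(rng):
    ct, sheet = _planted_ct(rng, noise=0.4)
    res = profiling_de(ct, sheet, refs=["mir-1", "mir-2", "mir-3"])
    for comp in res.consensus["comparison"].unique():
        cons = set(res.consensus_set(comp))
        for strat in ("global_mean", "reference"):
            assert cons <= set(res.significant_set(strat, comp))


def test_swapping_comparison_inverts_fc_preserves_p(rng):
    ct, sheet = _planted_ct(rng)
    kw = dict(refs=["mir-1", "mir-2", "mir-3"])
    ab = profiling_de(ct, sheet, comparisons=[("DME", "CTR")], **kw).table
    ba = profiling_de(ct, sheet, comparisons=[("CTR", "DME")], **kw).table
    m = ab.merge(ba, on=["mirna", "strategy"], suffixes=("_ab", "_ba"))
    assert np.allclose(m["fc_ab"] * m["fc_ba"], 1.0, atol=1e-12)
    assert np.allclose(m["p_ab"], m["p_ba"], atol=1e-12)


def test_t_pvalues_match_scipy_per_mirna(rng):
    ct, sheet = _planted_ct(rng, n_null=5)
    res = profiling_de(ct, sheet, refs=["mir-1", "mir-2", "mir-3"])
    from mirqpcr.normalization import reference_normalize

    dct = reference_normalize(ct, ["mir-1", "mir-2", "mir-3"]).dct
    sub = res.table[(res.table["strategy"] == "reference")
                    & (res.table["comparison"] == "DME_vs_CTR")]
    for row in sub.itertuples():
        a = dct.loc[row.mirna, [f"s{j}" for j in range(11, 16)]]
        b = dct.loc[row.mirna, [f"s{j}" for j in range(1, 6)]]
        expect = stats.ttest_ind(a, b, equal_var=True).pvalue
        assert row.p == pytest.approx(expect, abs=1e-12)


def test_null_type_one_error_near_alpha(rng):
    """Raw t p-values reject at ~alpha on null data (no fold gate applied)."""
    n_mir, reps = 200, 5
    hits = total = 0
    for _ in range(reps):
        vals = 28.0 + rng.normal(0, 0.3, size=(n_mir, 10))
        ct = make_ct(vals)
        sheet = make_sheet(["A"] * 5 + ["B"] * 5)
        res = profiling_de(ct, sheet, refs=["mir-1", "mir-2", "mir-3"])
        sub = res.table[res.table["strategy"] == "global_mean"]
        hits += int((sub["p"] <= 0.05).sum())
        total += len(sub)
    rate = hits / total
    se = np.sqrt(0.05 * 0.95 / total)
    assert abs(rate - 0.05) < 4 * se + 0.01


# --------------------------------------------------------------- validation

def test_validation_direction_flip_fails(rng):
    vals = 26.0 + rng.normal(0, 0.1, size=(2, 10))
    vals[1, 5:] -= 2.0  # strongly UP in group B
    ct = make_ct(vals, mirnas=["ref-1", "mir-x"])
    sheet = make_sheet(["A"] * 5 + ["B"] * 5)
    calls = validation_de(
        ct, sheet, refs=["ref-1"], profiling_directions={"mir-x": "down"},
        comparisons=[("B", "A")],
    )
    row = calls.iloc[0]
    assert row["direction"] == "up" and not row["trend_match"] and not row["validated"]


def test_validation_consistent_change_validates(rng):
    vals = 26.0 + rng.normal(0, 0.2, size=(2, 22))
    vals[1, 10:] += np.log2(3)  # 3-fold down in B, n = 10 vs 12
    ct = make_ct(vals, mirnas=["ref-1", "mir-x"])
    sheet = make_sheet(["A"] * 10 + ["B"] * 12)
    calls = validation_de(
        ct, sheet, refs=["ref-1"], profiling_directions={"mir-x": "down"},
        comparisons=[("B", "A")],
    )
    assert calls.iloc[0]["validated"]


def test_validation_two_reference_aggregate():
    vals = np.array([[20.0] * 4, [22.0] * 4, [24.0, 24.0, 26.0, 26.0]])
    ct = make_ct(vals, mirnas=["r1", "r2", "t"])
    sheet = make_sheet(["A"] * 2 + ["B"] * 2)
    calls = validation_de(
        ct, sheet, refs=["r1", "r2"], profiling_directions={"t": "down"},
        comparisons=[("B", "A")],
    )
    # normalizer = 21; dct 3 vs 5 -> rel 1/8 vs 1/32 -> fc (1/32)/(1/8) = 0.25
    assert calls.iloc[0]["fc"] == pytest.approx(0.25)


def test_validation_unknown_direction_errors(rng):
    ct = make_ct(26 + rng.normal(0, 0.1, size=(2, 4)), mirnas=["ref-1", "mir-x"])
    sheet = make_sheet(["A"] * 2 + ["B"] * 2)
    with pytest.raises(ValueError, match="direction"):
        validation_de(ct, sheet, refs=["ref-1"], profiling_directions={})


# ------------------------------------------------------------------ volcano

def test_volcano_closed_forms(rng):
    ct, sheet = _planted_ct(rng, n_null=3)
    res = profiling_de(ct, sheet, refs=["mir-1", "mir-2", "mir-3"])
    v = volcano_table(res, "reference")
    n_tested = res.table[res.table["strategy"] == "reference"].shape[0]
    assert len(v) == n_tested
    assert v.attrs["log2_fold_cutoff"] == pytest.approx(np.log2(2.5))
    assert v.attrs["neg_log10_alpha"] == pytest.approx(-np.log10(0.05))
    joined = v.merge(res.table[res.table["strategy"] == "reference"],
                     on=["mirna", "comparison"])
    assert np.allclose(joined["neg_log10_p"], -np.log10(joined["p"]), equal_nan=True)


# ----------------------------------------------------------------- Spearman

def test_spearman_monotone_limits():
    a = [1.0, 2.0, 3.0, 4.0, 5.0]
    up = spearman_correlation(a, [2.0, 4.0, 9.0, 16.0, 30.0])
    dn = spearman_correlation(a, [5.0, 4.0, 3.0, 2.0, 1.0])
    assert up.rho == pytest.approx(1.0)
    assert dn.rho == pytest.approx(-1.0)


def test_spearman_matches_rank_formula(rng):
    a = rng.normal(size=8)
    b = rng.normal(size=8)
    res = spearman_correlation(a, b)
    ra, rb = stats.rankdata(a), stats.rankdata(b)
    d = ra - rb
    expect = 1 - 6 * np.sum(d**2) / (8 * (8**2 - 1))
    assert res.rho == pytest.approx(expect, abs=1e-12)


def test_spearman_constant_flagged():
    res = spearman_correlation([1.0] * 5, [1.0, 2.0, 3.0, 4.0, 5.0])
    assert not res.valid and np.isnan(res.rho)


def test_spearman_needs_four_pairs():
    with pytest.raises(ValueError, match="4 complete pairs"):
        spearman_correlation([1, 2, 3], [1, 2, 3])


def test_thresholds_validate():
    with pytest.raises(ValueError):
        DEThresholds(fold_cutoff=0.9)
    with pytest.raises(ValueError):
        DEThresholds(alpha=1.5)
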