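"""Differential-expression calling for the profiling and validation stages.

Profiling: for each pairwise group comparison and each normalization
strategy (global mean; reference miRNAs), a two-sided pooled-variance
Student's t test on ΔCt plus a fold-change gate (default 2.5-fold either
way).  A miRNA is *significant* under a strategy when its strategy-specific
fold change passes the gate and p <= alpha; the *consensus* call requires
significance under both strategies, which trades a little sensitivity for
robustness to the normalization choice.

Validation: single-assay 2^-ΔCt values against one endogenous control (or
the mean of two, for plasma), compared between groups with the two-sided
Mann-Whitney U test; a miRNA is *validated* when the direction matches the
profiling call and p <= alpha.

No multiple-testing correction gates any call (raw p <= 0.05 throughout); a
Benjamini-Hochberg column is emitted for information only.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import CtMatrix, SampleSheet
from .normalization import (
    NormalizedExpression,
    ddct_fold_change,
    global_mean_normalize,
    reference_normalize,
)

__all__ = [
    "DEThresholds",
    "DEResult",
    "profiling_de",
    "strategy_de",
    "mann_whitney_test",
    "validation_de",
    "volcano_table",
    "spearman_correlation",
]


@dataclass(frozen=True)
class DEThresholds:
    """Fold-change and p-value gates for significance calls."""

    fold_cutoff: float = 2.5
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.fold_cutoff <= 1:
            raise ValueError("fold_cutoff must exceed 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    def passes_fold(self, fc: np.ndarray | float) -> np.ndarray | bool:
        return (fc >= self.fold_cutoff) | (fc <= 1.0 / self.fold_cutoff)


@dataclass(frozen=True)
class DEResult:
    """Long-format per-(miRNA, comparison, strategy) table plus consensus.

    ``table`` columns: mirna, comparison, strategy, ddct, fc, log2_fc, p,
    p_bh, significant, direction, evaluable.
    ``consensus`` columns: mirna, comparison, consensus, direction (the
    shared direction when the consensus holds).
    """

    table: pd.DataFrame
    consensus: pd.DataFrame
    thresholds: DEThresholds

    def significant_set(self, strategy: str, comparison: str | None = None) -> list[str]:
        t = self.table
        mask = ((t["strategy"] == strategy) & t["significant"]).to_numpy()
        if comparison is not None:
            mask = mask & (t["comparison"] == comparison).to_numpy()
        return sorted(t.loc[mask, "mirna"].unique())

    def consensus_set(self, comparison: str | None = None) -> list[str]:
        c = self.consensus
        mask = c["consensus"].to_numpy(copy=True)
        if comparison is not None:
            mask = mask & (c["comparison"] == comparison).to_numpy()
        return sorted(c.loc[mask, "mirna"].unique())


def _comparison_label(num: str, den: str) -> str:
    return f"{num}_vs_{den}"


def default_comparisons(groups: Sequence[str]) -> list[tuple[str, str]]:
    """All ordered pairs (later group vs earlier) in sheet group order."""
    return [(b, a) for a, b in combinations(list(groups), 2)]


def _pooled_t_pvalues(num: np.ndarray, den: np.ndarray, welch: bool = False) -> np.ndarray:
    """Row-wise two-sided Student's t test, NaNs omitted per row.

    Pooled-variance by default; ``welch=True`` drops the equal-variance
    assumption.

    Degenerate rows (zero pooled variance) get p = 1 when the means agree
    and p = 0 otherwise; rows with < 2 observations on either side get NaN.
    """
    import warnings

    with warnings.catch_warnings():
        # constant rows and censored-out rows are handled explicitly below
        warnings.simplefilter("ignore")
        res = stats.ttest_ind(num, den, axis=1, equal_var=not welch,
                              nan_policy="omit")
    p = np.asarray(res.pvalue, dtype=float)
    n_num = np.sum(~np.isnan(num), axis=1)
    n_den = np.sum(~np.isnan(den), axis=1)
    ok = (n_num >= 2) & (n_den >= 2)
    with np.errstate(invalid="ignore"):
        diff = np.nanmean(num, axis=1) - np.nanmean(den, axis=1)
    degenerate = ok & np.isnan(p)
    p[degenerate] = np.where(np.abs(diff[degenerate]) < 1e-12, 1.0, 0.0)
    p[~ok] = np.nan
    return p


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (informational column only)."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    m = ok.sum()
    if m == 0:
        return out
    order = np.argsort(p[ok], kind="stable")
    ranked = p[ok][order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    vals = np.empty(m)
    vals[order] = np.minimum(adj, 1.0)
    out[ok] = vals
    return out


def strategy_de(
    norm: NormalizedExpression,
    sheet: SampleSheet,
    comparisons: Sequence[tuple[str, str]] | None = None,
    thresholds: DEThresholds = DEThresholds(),
    welch: bool = False,
) -> pd.DataFrame:
    """DE table for one normalized matrix (one strategy) across comparisons."""
    if comparisons is None:
        comparisons = default_comparisons(sheet.groups)
    rows = []
    for num_group, den_group in comparisons:
        fc_tab = ddct_fold_change(norm, sheet, (num_group, den_group))
        num_samples = [s for s in sheet.samples_in_group(num_group) if s in norm.dct.columns]
        den_samples = [s for s in sheet.samples_in_group(den_group) if s in norm.dct.columns]
        p = _pooled_t_pvalues(
            norm.dct[num_samples].to_numpy(dtype=float),
            norm.dct[den_samples].to_numpy(dtype=float),
            welch=welch,
        )
        fc = fc_tab["fc"].to_numpy()
        evaluable = fc_tab["evaluable"].to_numpy() & ~np.isnan(p)
        sig = np.zeros(len(fc), dtype=bool)
        with np.errstate(invalid="ignore"):
            sig[evaluable] = np.asarray(
                thresholds.passes_fold(fc[evaluable])
            ) & (p[evaluable] <= thresholds.alpha)
        rows.append(
            pd.DataFrame(
                {
                    "mirna": norm.dct.index.astype(str),
                    "comparison": _comparison_label(num_group, den_group),
                    "strategy": norm.strategy,
                    "ddct": fc_tab["ddct"].to_numpy(),
                    "fc": fc,
                    "log2_fc": -fc_tab["ddct"].to_numpy(),
                    "p": p,
                    "significant": sig,
                    "direction": fc_tab["direction"].to_numpy(),
                    "evaluable": evaluable,
                }
            )
        )
    out = pd.concat(rows, ignore_index=True)
    out["p_bh"] = np.nan
    for comp in out["comparison"].unique():
        mask = out["comparison"] == comp
        out.loc[mask, "p_bh"] = _bh_adjust(out.loc[mask, "p"].to_numpy())
    return out


def profiling_de(
    ct: CtMatrix,
    sheet: SampleSheet,
    refs: Sequence[str],
    thresholds: DEThresholds = DEThresholds(),
    basis: Sequence[str] | None = None,
    comparisons: Sequence[tuple[str, str]] | None = None,
    welch: bool = False,
) -> DEResult:
    """Dual-strategy profiling DE with consensus calls.

    ``ct`` should already be restricted to the reliably-detected miRNA set;
    ``basis`` (default: all miRNAs of ``ct``) is the global-mean basis and
    ``refs`` the endogenous-control set for the reference strategy.
    """
    gm = global_mean_normalize(ct, basis=basis)
    rn = reference_normalize(ct, refs)
    tabs = [
        strategy_de(norm, sheet, comparisons=comparisons, thresholds=thresholds,
                    welch=welch)
        for norm in (gm, rn)
    ]
    table = pd.concat(tabs, ignore_index=True)

    wide_sig = table.pivot(
        index=["mirna", "comparison"], columns="strategy", values="significant"
    )
    wide_dir = table.pivot(
        index=["mirna", "comparison"], columns="strategy", values="direction"
    )
    strategies = ["global_mean", "reference"]
    both_sig = wide_sig[strategies].all(axis=1)
    same_dir = wide_dir[strategies[0]] == wide_dir[strategies[1]]
    consensus_flag = both_sig & same_dir
    consensus = pd.DataFrame(
        {
            "mirna": [m for m, _ in wide_sig.index],
            "comparison": [c for _, c in wide_sig.index],
            "consensus": consensus_flag.to_numpy(),
            "direction": wide_dir[strategies[1]].where(consensus_flag).to_numpy(),
        }
    ).reset_index(drop=True)
    result = DEResult(table=table, consensus=consensus, thresholds=thresholds)
    _assert_consensus_subset(result)
    return result


def _assert_consensus_subset(de: DEResult) -> None:
    """The consensus set must be contained in each strategy's significant set."""
    for comp in de.consensus["comparison"].unique():
        cons = set(de.consensus_set(comp))
        for strat in de.table["strategy"].unique():
            assert cons <= set(de.significant_set(strat, comp)), (
                "consensus call outside a single-strategy significant set"
            )


def mann_whitney_test(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact null distribution when n_a + n_b <= 20 and there are no ties;
    normal approximation with tie correction (and continuity correction)
    otherwise.  Two identical samples give p = 1 by convention.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size + b.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


def validation_de(
    single_assay_ct: CtMatrix,
    sheet: SampleSheet,
    refs: Sequence[str],
    profiling_directions: Mapping[str, str],
    thresholds: DEThresholds = DEThresholds(),
    comparisons: Sequence[tuple[str, str]] | None = None,
    cohort: str = "all_subjects",
) -> pd.DataFrame:
    """Single-assay validation calls against one (or two) reference miRNAs.

    ΔCt is computed against the reference (mean of two for plasma); groups
    are compared on the 2^-ΔCt scale with the Mann-Whitney U test.  The fold
    change is the ratio of group means of 2^-ΔCt.  A miRNA is validated for
    a comparison when its direction matches ``profiling_directions[mirna]``
    and p <= alpha.  Reference rows are excluded from the calls.
    """
    refs = list(refs)
    norm = reference_normalize(single_assay_ct, refs)
    rel = norm.rel_expr
    targets = [m for m in rel.index if m not in set(refs)]
    unknown = [m for m in targets if m not in profiling_directions]
    if unknown:
        raise ValueError(f"no profiling direction known for: {unknown}")
    if comparisons is None:
        comparisons = default_comparisons(sheet.groups)
    rows = []
    for num_group, den_group in comparisons:
        num_samples = [s for s in sheet.samples_in_group(num_group) if s in rel.columns]
        den_samples = [s for s in sheet.samples_in_group(den_group) if s in rel.columns]
        for mirna in targets:
            va = rel.loc[mirna, num_samples].dropna().to_numpy()
            vb = rel.loc[mirna, den_samples].dropna().to_numpy()
            if va.size < 2 or vb.size < 2:
                rows.append((mirna, _comparison_label(num_group, den_group),
                             np.nan, None, np.nan, False, False, False))
                continue
            fc = float(va.mean() / vb.mean())
            direction = "up" if fc > 1.0 else "down"
            p = mann_whitney_test(va, vb)
            trend = direction == profiling_directions[mirna]
            validated = bool(trend and p <= thresholds.alpha)
            rows.append((mirna, _comparison_label(num_group, den_group),
                         fc, direction, p, trend, validated, True))
    return pd.DataFrame(
        rows,
        columns=["mirna", "comparison", "fc", "direction", "p",
                 "trend_match", "validated", "evaluable"],
    ).assign(cohort=cohort)


def volcano_table(de: DEResult, strategy: str) -> pd.DataFrame:
    """Volcano-plot coordinates (log2 fc, -log10 p) for one strategy.

    Rows ordered by comparison then miRNA id; the fold and alpha cutoffs are
    attached in ``DataFrame.attrs`` for annotation.
    """
    t = de.table
    sub = t[t["strategy"] == strategy].copy()
    if sub.empty:
        raise ValueError(f"no rows for strategy {strategy!r}")
    with np.errstate(divide="ignore"):
        sub["neg_log10_p"] = -np.log10(sub["p"])
    out = (
        sub[["mirna", "comparison", "log2_fc", "neg_log10_p", "significant"]]
        .sort_values(["comparison", "mirna"], kind="stable")
        .reset_index(drop=True)
    )
    out.attrs["log2_fold_cutoff"] = float(np.log2(de.thresholds.fold_cutoff))
    out.attrs["neg_log10_alpha"] = float(-np.log10(de.thresholds.alpha))
    return out


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p: float
    valid: bool


def spearman_correlation(paired_a: Sequence[float], paired_b: Sequence[float]) -> SpearmanResult:
    """Spearman rank correlation on complete pairs (>= 4 required).

    Constant input leaves rho undefined; the result is flagged invalid
    rather than raising, since paired panels routinely contain flat assays.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired inputs must have equal length")
    ok = ~np.isnan(a) & ~np.isnan(b)
    a, b = a[ok], b[ok]
    if a.size < 4:
        raise ValueError("Spearman correlation needs >= 4 complete pairs")
    if np.unique(a).size == 1 or np.unique(b).size == 1:
        return SpearmanResult(float("nan"), float("nan"), False)
    rho, p = stats.spearmanr(a, b)
    return SpearmanResult(float(rho), float(p), True)
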