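"""Combined-stability ranking of candidate endogenous-control miRNAs.

Candidate reference miRNAs are the ones observed (non-missing Ct) in every
sample.  Three stability scores are computed per candidate, each on the Ct
scale (Ct is ~log2 of template abundance up to sign, so Ct differences are
log ratios):

* **geNorm M** — for each candidate pair (j, k), the pairwise variation
  V_jk is the standard deviation across samples of Ct_j - Ct_k; M_j is the
  mean of V_jk over all partners k != j.  Per-sample additive offsets
  (loading/pipetting) cancel in the difference, so M isolates biological and
  technical instability relative to the panel.
* **NormFinder rho** — a model-based score separating intragroup variance
  from systematic intergroup deviation; see :func:`normfinder_rho`.
* **CV score** — the per-candidate coefficient of variation of raw Ct
  (SD/mean over samples), scaled by the sum of all candidates' CVs so the
  scores sum to 1.  Unlike M and rho this is sensitive to per-sample
  offsets, deliberately penalizing candidates whose raw signal wanders.

The summarized stability score (SSS) merges the three as the Euclidean
distance from the origin in (M, rho, CV-score) space; candidates are ranked
by ascending SSS (smaller = more stable) and the top k (default 3) serve as
the endogenous-control set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CtMatrix, SampleSheet

__all__ = [
    "StabilityTable",
    "candidate_filter",
    "genorm_m",
    "genorm_stepwise",
    "normfinder_rho",
    "cv_score",
    "combine_sss",
    "select_references",
    "rank_candidates",
]


@dataclass(frozen=True)
class StabilityTable:
    """Per-candidate stability scores and the combined SSS ranking.

    ``table`` columns: mirna, M, rho, cv_score, sss, rank (1-based,
    ascending sss; ties broken by miRNA id lexicographic order).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"mirna", "M", "rho", "cv_score", "sss", "rank"}
        if not need <= set(self.table.columns):
            raise ValueError(f"StabilityTable requires columns {sorted(need)}")

    def top(self, k: int) -> list[str]:
        return select_references(self, k)


def candidate_filter(ct: CtMatrix) -> list[str]:
    """miRNAs with a non-missing Ct in every sample (reference candidates).

    Endogenous controls must be stably and abundantly detected everywhere;
    any censored well disqualifies a candidate.
    """
    complete = ~ct.values.isna().any(axis=1)
    out = list(ct.values.index[complete])
    if not out:
        raise ValueError(
            "no miRNA is observed in every sample; review the detection "
            "threshold and upstream QC before selecting references"
        )
    return out


def _require_complete(ct: CtMatrix) -> np.ndarray:
    arr = ct.values.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ValueError("stability scores require a complete (no-missing) Ct matrix")
    return arr


def genorm_m(ct_subset: CtMatrix) -> pd.Series:
    """geNorm stability M per candidate: mean pairwise variation.

    V_jk = SD across samples of (Ct_j - Ct_k), sample SD with ddof=1;
    M_j = mean of V_jk over k != j.  Requires >= 3 candidates (with two, both
    M values collapse to the single pairwise SD) and >= 2 samples.
    """
    arr = _require_complete(ct_subset)
    n_mir, n_samp = arr.shape
    if n_mir < 3:
        raise ValueError("geNorm M requires at least 3 candidate miRNAs")
    if n_samp < 2:
        raise ValueError("geNorm M requires at least 2 samples")
    # Var(Ct_j - Ct_k) = C_jj + C_kk - 2 C_jk from the candidate covariance
    cov = np.cov(arr, ddof=1)
    diag = np.diag(cov)
    var_pair = diag[:, None] + diag[None, :] - 2.0 * cov
    np.fill_diagonal(var_pair, 0.0)
    v = np.sqrt(np.maximum(var_pair, 0.0))
    m = v.sum(axis=1) / (n_mir - 1)
    return pd.Series(m, index=ct_subset.values.index, name="M")


def genorm_stepwise(ct_subset: CtMatrix, stop_at: int = 2) -> list[str]:
    """Classic iterative geNorm: repeatedly drop the worst-M candidate.

    Returns the elimination order, worst first, with the final ``stop_at``
    survivors appended in their last-round M order (best last).  Provided for
    comparison with the direct M ranking; not used by the default pipeline.
    """
    if stop_at < 2:
        raise ValueError("stepwise elimination must stop at >= 2 survivors")
    remaining = list(ct_subset.values.index)
    order: list[str] = []
    current = ct_subset
    while len(remaining) > stop_at:
        m = genorm_m(current)
        worst = m.sort_values(ascending=False, kind="stable").index[0]
        order.append(worst)
        remaining = [r for r in remaining if r != worst]
        current = current.subset_mirnas(remaining)
        if len(remaining) == 3:
            break
    final_m = genorm_m(current) if len(remaining) >= 3 else None
    if final_m is not None:
        order.extend(final_m.sort_values(ascending=False, kind="stable").index)
    else:
        order.extend(remaining)
    return order


def normfinder_rho(
    ct_subset: CtMatrix,
    sheet: SampleSheet | None = None,
    use_groups: bool = True,
) -> pd.Series:
    """NormFinder stability value rho per candidate.

    Model-based decomposition on sample-centered Ct: for gene i, group g,
    sample j,

        d_igj = Ct_igj - mean_i(Ct_igj)

    removes the per-sample loading effect.  The per-gene per-group intragroup
    variance sigma^2_ig is estimated from the sample variance of d_igj with a
    bias correction for the centering step (centering mixes 1/I of every
    other gene's noise into each residual, I = number of candidates):

        sigma^2_ig = (s^2_ig - mean_i(s^2_ig) / (I - 1)) / (1 - 2/I),  floored at 0

    Intergroup variation: z_ig = mean_j(d_igj) - mean_g(mean_j(d_igj)) is the
    gene's group-effect deviation; its prior variance gamma^2 is estimated by
    moments and each z_ig is shrunk by its sampling variance,

        zhat_ig = z_ig * gamma^2 / (gamma^2 + sigma^2_ig / n_g).

    The stability value averages the absolute shrunken intergroup effect and
    the intragroup uncertainty over groups:

        rho_i = mean_g( |zhat_ig| + sqrt(sigma^2_ig / n_g) )

    Lower rho = more stable.  With ``use_groups=False`` (or no sheet) all
    samples form a single group and rho reduces to the corrected intragroup
    SD of the sample-centered data.
    """
    arr = _require_complete(ct_subset)
    n_genes = arr.shape[0]
    if n_genes < 3:
        raise ValueError("NormFinder requires at least 3 candidate miRNAs")
    index = ct_subset.values.index

    if use_groups and sheet is not None:
        sheet.check_covers(ct_subset)
        group_of = sheet.group_of()
        groups = [g for g in sheet.groups]
        cols = list(ct_subset.values.columns)
        membership = [
            [i for i, s in enumerate(cols) if group_of[s] == g] for g in groups
        ]
        for g, idx in zip(groups, membership):
            if len(idx) < 2:
                raise ValueError(f"group {g!r} has fewer than 2 samples")
        if len(groups) < 2:
            raise ValueError("NormFinder with groups requires >= 2 groups")
    else:
        membership = [list(range(arr.shape[1]))]
        if len(membership[0]) < 2:
            raise ValueError("NormFinder requires at least 2 samples")

    n_groups = len(membership)
    d = arr - arr.mean(axis=0, keepdims=True)  # sample-centered

    group_means = np.empty((n_genes, n_groups))
    sigma2 = np.empty((n_genes, n_groups))
    n_per = np.array([len(idx) for idx in membership], dtype=float)
    for gi, idx in enumerate(membership):
        sub = d[:, idx]
        group_means[:, gi] = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        corrected = (s2 - s2.mean() / (n_genes - 1)) / (1.0 - 2.0 / n_genes)
        sigma2[:, gi] = np.maximum(corrected, 0.0)

    if n_groups == 1:
        rho = np.sqrt(sigma2[:, 0])
        return pd.Series(rho, index=index, name="rho")

    z = group_means - group_means.mean(axis=1, keepdims=True)
    samp_var = sigma2 / n_per[None, :]
    # z sums to ~0 over genes (centering) and exactly 0 over groups, hence
    # (I-1)(G-1) degrees of freedom in the moment estimator of gamma^2
    gamma2 = (z**2).sum() / ((n_genes - 1) * (n_groups - 1)) - samp_var.mean()
    gamma2 = max(gamma2, 0.0)
    shrink = gamma2 / (gamma2 + samp_var) if gamma2 > 0 else np.zeros_like(samp_var)
    z_hat = z * shrink
    rho = (np.abs(z_hat) + np.sqrt(samp_var)).mean(axis=1)
    return pd.Series(rho, index=index, name="rho")


def cv_score(ct_subset: CtMatrix) -> pd.Series:
    """Scaled coefficient of variation per candidate.

    CV_j = SD/mean of raw Ct over samples (ddof=1); the score is CV_j divided
    by the sum of all candidates' CVs, so scores sum to 1.
    """
    arr = _require_complete(ct_subset)
    if arr.shape[1] < 2:
        raise ValueError("CV requires at least 2 samples")
    means = arr.mean(axis=1)
    if np.any(means <= 0):
        raise ValueError("candidate mean Ct must be positive")
    cv = arr.std(axis=1, ddof=1) / means
    total = cv.sum()
    if total == 0:
        raise ValueError("all candidate rows are constant; CV score undefined")
    return pd.Series(cv / total, index=ct_subset.values.index, name="cv_score")


def combine_sss(m: pd.Series, rho: pd.Series, cv: pd.Series) -> StabilityTable:
    """Merge the three scores into the SSS ranking.

    sss = sqrt(M^2 + rho^2 + cv_score^2), the Euclidean distance from the
    origin; rank ascends with sss, ties broken by miRNA id.
    """
    if not (m.index.equals(rho.index) and m.index.equals(cv.index)):
        raise ValueError("M, rho and cv_score must be indexed by the same miRNAs")
    if (m < 0).any() or (rho < 0).any() or (cv < 0).any():
        raise ValueError("stability components must be non-negative")
    sss = np.sqrt(m.to_numpy() ** 2 + rho.to_numpy() ** 2 + cv.to_numpy() ** 2)
    tab = pd.DataFrame(
        {
            "mirna": m.index.astype(str),
            "M": m.to_numpy(),
            "rho": rho.to_numpy(),
            "cv_score": cv.to_numpy(),
            "sss": sss,
        }
    )
    order = tab.sort_values(["sss", "mirna"], kind="stable").index
    ranks = pd.Series(np.arange(1, len(tab) + 1), index=order)
    tab["rank"] = ranks.reindex(tab.index).to_numpy()
    return StabilityTable(tab.reset_index(drop=True))


def select_references(table: StabilityTable, k: int = 3) -> list[str]:
    """The k best-ranked candidates (ascending SSS)."""
    if k <= 0:
        raise ValueError("k must be positive")
    n = len(table.table)
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available candidates")
    ordered = table.table.sort_values("rank", kind="stable")
    return ordered["mirna"].head(k).tolist()


def rank_candidates(
    ct: CtMatrix,
    sheet: SampleSheet,
    candidates: list[str] | None = None,
) -> StabilityTable:
    """Convenience wrapper: candidate filter -> three scores -> SSS table."""
    if candidates is None:
        candidates = candidate_filter(ct)
    sub = ct.subset_mirnas(candidates)
    m = genorm_m(sub)
    rho = normfinder_rho(sub, sheet)
    cv = cv_score(sub)
    return combine_sss(m, rho, cv)
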