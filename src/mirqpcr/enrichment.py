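"""Arithmetic layer of pathway over-representation summaries.

Works from user-supplied counts — target genes hitting a pathway (k) out of
a recognized target-gene background (N), and optionally the pathway size (K)
within an annotation universe (M).  No annotation service is queried: live
database versions drift and make the mapping irreproducible, so the counts
file is the contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EnrichmentCounts",
    "gene_percentage",
    "fold_enrichment",
    "overrepresentation_p",
    "summarize_counts",
]


@dataclass(frozen=True)
class EnrichmentCounts:
    """Counts for one pathway row: k of N target genes, K of M universe genes."""

    pathway_label: str
    k: int
    N: int
    K: int | None = None
    M: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.k <= self.N:
            raise ValueError("need 0 <= k <= N")
        if self.K is not None and self.k > self.K:
            raise ValueError("k cannot exceed pathway size K")
        if self.M is not None:
            if self.K is None:
                raise ValueError("M given without K")
            if self.K > self.M or self.N > self.M:
                raise ValueError("K and N cannot exceed universe size M")


def gene_percentage(k: int, N: int, decimals: int = 1) -> float:
    """100*k/N rounded half-up to ``decimals`` (printed-table convention)."""
    if N <= 0:
        raise ValueError("background size N must be positive")
    if not 0 <= k <= N:
        raise ValueError("need 0 <= k <= N")
    q = Decimal(1).scaleb(-decimals)
    return float(
        (Decimal(100) * Decimal(k) / Decimal(N)).quantize(q, rounding=ROUND_HALF_UP)
    )


def fold_enrichment(k: int, N: int, K: int, M: int) -> float:
    """Observed/expected hit ratio (k/N) / (K/M)."""
    if min(k, N, K, M) <= 0:
        raise ValueError("all counts must be positive")
    if k > N or K > M:
        raise ValueError("need k <= N and K <= M")
    return (k / N) / (K / M)


def overrepresentation_p(k: int, N: int, K: int, M: int, ease: bool = False) -> float:
    """Upper-tail hypergeometric p-value P(X >= k).

    X counts pathway members in a size-N draw (the target genes) from a
    size-M universe containing K pathway members.  ``ease=True`` applies the
    conservative EASE-score variant that discounts one observed hit
    (P(X >= k-1) computed with k-1 in place of k).
    """
    if N < 0 or K < 0 or M <= 0:
        raise ValueError("invalid counts")
    if k < 0 or k > min(N, K) or N > M or K > M:
        raise ValueError("inconsistent 2x2 counts")
    k_eff = max(k - 1, 0) if ease else k
    return float(stats.hypergeom.sf(k_eff - 1, M, K, N))


def summarize_counts(path_or_df: str | Path | pd.DataFrame) -> pd.DataFrame:
    """Summarize a counts table into percentage / fold-enrichment / p columns.

    Input columns: pathway_label, k, N and optionally K, M.  Output mirrors a
    printed enrichment table: genes_count, genes_pct, and — when K and M are
    available — fold_enrichment and p_hypergeom, plus an informational
    Benjamini-Hochberg column (never used to gate anything here).
    """
    df = (
        pd.read_csv(path_or_df)
        if not isinstance(path_or_df, pd.DataFrame)
        else path_or_df.copy()
    )
    need = {"pathway_label", "k", "N"}
    if not need <= set(df.columns):
        raise ValueError(f"counts table requires columns {sorted(need)}")
    out = pd.DataFrame({"pathway_label": df["pathway_label"]})
    out["genes_count"] = df["k"].astype(int)
    out["genes_pct"] = [
        gene_percentage(int(k), int(n)) for k, n in zip(df["k"], df["N"])
    ]
    if {"K", "M"} <= set(df.columns) and df[["K", "M"]].notna().all().all():
        out["fold_enrichment"] = [
            fold_enrichment(int(k), int(n), int(kk), int(mm))
            for k, n, kk, mm in zip(df["k"], df["N"], df["K"], df["M"])
        ]
        p = np.array(
            [
                overrepresentation_p(int(k), int(n), int(kk), int(mm))
                for k, n, kk, mm in zip(df["k"], df["N"], df["K"], df["M"])
            ]
        )
        out["p_hypergeom"] = p
        order = np.argsort(p, kind="stable")
        m = len(p)
        ranked = p[order] * m / np.arange(1, m + 1)
        adj = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
        bh = np.empty(m)
        bh[order] = adj
        out["p_bh"] = bh
    return out
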