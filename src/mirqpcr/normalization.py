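"""Delta-Ct normalization and ddCt fold changes.

Two strategies produce a ΔCt (and 2^-ΔCt) matrix from raw Ct:

* ``global_mean`` — each sample's normalizer is the mean Ct over a broad
  *basis* miRNA set (by default the reliably-detected set); ΔCt is Ct minus
  that per-sample mean, so the per-sample mean ΔCt over the basis is 0.
* ``reference`` — the normalizer is the arithmetic mean of a small set of
  endogenous-control miRNAs' Ct in the same sample (arithmetic mean on the
  Ct/log scale = geometric mean of linear quantities, the standard
  multi-housekeeper aggregate).

Fold change between groups uses the comparative Ct method:
ΔΔCt = mean ΔCt(numerator group) - mean ΔCt(denominator group), and
fc = 2^-ΔΔCt.  Fold changes are reported as positive ratios with a
direction label (fc > 1 ⇒ "up" in the numerator group); missing Ct
propagates to missing ΔCt and is never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CtMatrix, SampleSheet

__all__ = [
    "NormalizedExpression",
    "global_mean_normalize",
    "reference_normalize",
    "ddct_fold_change",
]


@dataclass(frozen=True)
class NormalizedExpression:
    """ΔCt grid plus the strategy and normalizer set that produced it."""

    dct: pd.DataFrame  # miRNA x sample ΔCt; NaN where Ct was missing
    strategy: str  # "global_mean" | "reference"
    normalizer_set: tuple[str, ...] = ()
    basis_set: tuple[str, ...] = ()

    @property
    def rel_expr(self) -> pd.DataFrame:
        """Relative expression 2^-ΔCt (NaN propagates)."""
        return 2.0 ** (-self.dct)


def global_mean_normalize(
    ct: CtMatrix, basis: Sequence[str] | None = None
) -> NormalizedExpression:
    """ΔCt against each sample's mean Ct over the basis miRNA set.

    The basis defaults to every miRNA in the matrix; in the pipeline it is
    the detection module's reliably-detected set, so censored/unreliable
    wells do not drag the mean.  Within a sample, only basis miRNAs with an
    observed Ct contribute; a sample with no observed basis Ct is an error.
    """
    if basis is None:
        basis = ct.mirna_ids
    basis = list(dict.fromkeys(basis))
    missing = [m for m in basis if m not in ct.values.index]
    if missing:
        raise ValueError(f"basis miRNAs not in matrix: {missing}")
    sub = ct.values.loc[basis]
    per_sample_mean = sub.mean(axis=0, skipna=True)
    empty = per_sample_mean.index[per_sample_mean.isna()].tolist()
    if empty:
        raise ValueError(f"samples with no observed basis Ct: {empty}")
    dct = ct.values.sub(per_sample_mean, axis=1)
    return NormalizedExpression(
        dct, strategy="global_mean", basis_set=tuple(basis)
    )


def reference_normalize(ct: CtMatrix, refs: Sequence[str]) -> NormalizedExpression:
    """ΔCt against the arithmetic mean Ct of the reference miRNAs per sample.

    Every reference must be observed in every sample (guaranteed when refs
    come from the candidate filter).
    """
    refs = list(refs)
    if not refs:
        raise ValueError("at least one reference miRNA is required")
    missing = [m for m in refs if m not in ct.values.index]
    if missing:
        raise ValueError(f"reference miRNAs not in matrix: {missing}")
    ref_ct = ct.values.loc[refs]
    if ref_ct.isna().any().any():
        bad = ref_ct.columns[ref_ct.isna().any(axis=0)].tolist()
        raise ValueError(f"reference Ct missing in samples: {bad}")
    normalizer = ref_ct.mean(axis=0)
    dct = ct.values.sub(normalizer, axis=1)
    return NormalizedExpression(dct, strategy="reference", normalizer_set=tuple(refs))


def ddct_fold_change(
    norm: NormalizedExpression,
    sheet: SampleSheet,
    comparison: tuple[str, str],
    min_per_group: int = 2,
) -> pd.DataFrame:
    """Per-miRNA ΔΔCt fold change for an ordered group pair.

    Returns a DataFrame indexed by miRNA with columns ddct, fc, direction,
    n_num, n_den, evaluable.  ΔΔCt = mean ΔCt(numerator) - mean ΔCt
    (denominator) over the samples with observed ΔCt; a miRNA with fewer
    than ``min_per_group`` observed values in either group is flagged
    evaluable=False and carries NaN ddct/fc.
    """
    num_group, den_group = comparison
    num_samples = [s for s in sheet.samples_in_group(num_group) if s in norm.dct.columns]
    den_samples = [s for s in sheet.samples_in_group(den_group) if s in norm.dct.columns]
    if len(num_samples) < 2 or len(den_samples) < 2:
        raise ValueError("both comparison groups need >= 2 samples in the matrix")

    num = norm.dct[num_samples]
    den = norm.dct[den_samples]
    n_num = num.notna().sum(axis=1)
    n_den = den.notna().sum(axis=1)
    evaluable = (n_num >= min_per_group) & (n_den >= min_per_group)
    ddct = num.mean(axis=1, skipna=True) - den.mean(axis=1, skipna=True)
    ddct = ddct.where(evaluable)
    fc = 2.0 ** (-ddct)
    direction = pd.Series(
        np.where(fc > 1.0, "up", "down"), index=fc.index, dtype=object
    ).where(evaluable)
    return pd.DataFrame(
        {
            "ddct": ddct,
            "fc": fc,
            "direction": direction,
            "n_num": n_num,
            "n_den": n_den,
            "evaluable": evaluable,
        }
    )
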