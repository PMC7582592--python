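"""Group-wise detection filtering of Ct matrices.

A miRNA counts as *detected* in a group when its Ct is at or below the
reliability threshold (35 cycles by default) in at least a minimum number of
that group's samples — 4 of 5 in the original design, generalized to
``ceil(min_frac * n_group)``.  A miRNA is reliably detected overall when it
is detected in at least one group.  Missing Ct (no amplification call) can
never satisfy the threshold and counts as not detected for that sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd

from .io import CtMatrix, SampleSheet

__all__ = ["DetectionResult", "detect_flags", "venn_partition"]

#: The 7 regions of a 3-set Venn diagram, keyed by detection signature
#: (tuple of flags in the sheet's group order).
_SIGNATURES_3 = [
    (True, False, False),
    (False, True, False),
    (False, False, True),
    (True, True, False),
    (True, False, True),
    (False, True, True),
    (True, True, True),
]


@dataclass(frozen=True)
class DetectionResult:
    """Per-miRNA per-group detection flags and derived summaries."""

    flags: pd.DataFrame  # bool, miRNA x group
    ct_threshold: float
    min_counts: dict[str, int]  # per-group minimum detected subjects

    @property
    def groups(self) -> list[str]:
        return list(self.flags.columns)

    @property
    def detected_set(self) -> list[str]:
        """miRNAs detected in at least one group (matrix order)."""
        mask = self.flags.any(axis=1)
        return list(self.flags.index[mask])

    @property
    def per_group_counts(self) -> dict[str, int]:
        return {g: int(self.flags[g].sum()) for g in self.flags.columns}

    def venn(self) -> dict[tuple[bool, bool, bool], int]:
        return venn_partition(self)

    def summary(self) -> dict:
        """JSON-serializable report (counts, regions keyed by group subset)."""
        out: dict = {
            "ct_threshold": self.ct_threshold,
            "min_counts": dict(self.min_counts),
            "n_detected": len(self.detected_set),
            "per_group_counts": self.per_group_counts,
        }
        if len(self.groups) == 3:
            regions = venn_partition(self)
            out["venn"] = {
                "+".join(g for g, f in zip(self.groups, sig) if f): n
                for sig, n in regions.items()
            }
        return out


def detect_flags(
    ct: CtMatrix,
    sheet: SampleSheet,
    ct_threshold: float = 35.0,
    min_frac: float = 0.8,
    min_count: int | None = None,
) -> DetectionResult:
    """Apply the detection criterion per miRNA per group.

    Parameters
    ----------
    ct_threshold
        Reliability bound on Ct; wells above it (or with no call) do not
        count toward detection.
    min_frac
        A miRNA is detected in a group when at least ``ceil(min_frac * n)``
        of the group's ``n`` samples have Ct <= threshold.  The default 0.8
        reproduces the 4-of-5 rule at n = 5.
    min_count
        Absolute per-group minimum overriding ``min_frac`` (same value for
        every group).
    """
    if ct_threshold <= 0:
        raise ValueError("ct_threshold must be positive")
    sheet.check_covers(ct)
    groups = sheet.groups
    arr = ct.values
    flags = {}
    min_counts: dict[str, int] = {}
    for g in groups:
        samples = [s for s in sheet.samples_in_group(g) if s in arr.columns]
        if not samples:
            raise ValueError(f"group {g!r} has no samples in the Ct matrix")
        need = min_count if min_count is not None else ceil(min_frac * len(samples))
        if need < 1:
            raise ValueError(f"per-group minimum must be >= 1 (got {need})")
        sub = arr[samples].to_numpy(dtype=float)
        n_ok = np.sum(~np.isnan(sub) & (sub <= ct_threshold), axis=1)
        flags[g] = n_ok >= need
        min_counts[g] = need
    flag_df = pd.DataFrame(flags, index=arr.index)[groups]
    return DetectionResult(flag_df, float(ct_threshold), min_counts)


def venn_partition(dr: DetectionResult) -> dict[tuple[bool, bool, bool], int]:
    """Counts for the 7 regions of the 3-group detection Venn diagram.

    Keys are detection signatures in the result's group order; every detected
    miRNA falls in exactly one region, so the counts sum to |detected_set|.
    """
    if len(dr.groups) != 3:
        raise ValueError("Venn partition is defined for exactly 3 groups")
    sigs = [tuple(bool(v) for v in row) for row in dr.flags.to_numpy()]
    return {
        sig: sum(1 for s in sigs if s == sig)
        for sig in _SIGNATURES_3
    }
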