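"""Synthetic Ct matrices with the structure the analysis assumes.

The generator emulates a TaqMan low-density miRNA array experiment: a panel
of miRNAs measured in a handful of patients per clinical group.  The Ct of
miRNA i in sample j is

    Ct_ij = baseline_i + offset_j + shift(group(j), i) + eps_ij

with per-miRNA baselines drawn uniformly over an abundance window,
per-sample additive offsets (input-amount/pipetting variation that
normalization is supposed to remove), optional planted group shifts
(positive shift = higher Ct = lower expression), and Gaussian technical
noise on the Ct (log) scale.  A small minority of "stable" miRNAs carry a
much lower noise SD and no shift — the planted endogenous-control trio the
stability ranking should recover.  Wells whose true Ct exceeds the limit of
detection are censored to missing, as are a Bernoulli fraction of wells in
the 1-Ct band just below the limit (weak signals near the LOD drop out
stochastically on real cards).

Every generated bundle carries its ground truth so recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .de import DEResult
from .io import CtMatrix, SampleSheet
from .stability import StabilityTable

__all__ = [
    "SyntheticSpec",
    "SyntheticTruth",
    "generate",
    "profiling_spec",
    "plant_recovery_report",
]

LOG2_2_5 = float(np.log2(2.5))  # ~1.322 Ct, the fold-cutoff-sized shift


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters; defaults emulate the 378-assay profiling card.

    ``de_plan`` rows are (miRNA index, affected group, shift in Ct units);
    positive shift means reduced expression in that group.  Planted stable
    miRNAs occupy the *first* ``n_stable`` indices and may not appear in the
    DE plan.
    """

    n_mirnas: int = 378
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"CTR": 5, "D": 5, "DME": 5}
    )
    baseline_ct_range: tuple[float, float] = (22.0, 34.0)
    stable_baseline_ct_range: tuple[float, float] = (22.0, 28.0)
    sample_offset_sd: float = 0.5
    tech_noise_sd: float = 0.3
    n_stable: int = 3
    stable_noise_sd: float = 0.05
    de_plan: tuple[tuple[int, str, float], ...] = ()
    lod_ct: float = 35.0
    p_dropout_near_lod: float = 0.2
    compartment: str = "AH"
    cohort_stage: str = "profiling"

    def __post_init__(self) -> None:
        if self.n_stable < 0 or self.n_stable > self.n_mirnas:
            raise ValueError("n_stable out of range")
        for g, n in self.group_sizes.items():
            if n < 2:
                raise ValueError(f"group {g!r} needs >= 2 samples")
        for idx, group, _ in self.de_plan:
            if idx < self.n_stable:
                raise ValueError(
                    f"de_plan index {idx} is a planted stable miRNA; plants must not overlap"
                )
            if not self.n_stable <= idx < self.n_mirnas:
                raise ValueError(f"de_plan index {idx} out of range")
            if group not in self.group_sizes:
                raise ValueError(f"de_plan group {group!r} not in group_sizes")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth emitted with every generated bundle."""

    stable_set: tuple[str, ...]
    de_table: pd.DataFrame  # mirna, group, shift_ct, true_fold
    sample_offsets: pd.Series  # sample_id -> true additive offset
    true_ct: pd.DataFrame  # pre-censoring Ct grid


def _mirna_name(i: int, n_stable: int) -> str:
    return f"stab-mir-{i + 1:03d}" if i < n_stable else f"sim-mir-{i + 1:03d}"


def profiling_spec(**overrides) -> SyntheticSpec:
    """The default profiling-card spec with a fold-cutoff-sized DE plan.

    Plants 8 miRNAs shifted up by log2(2.5) Ct (2.5-fold down-expression) in
    the DME group, mirroring the expected minority of disease-responsive
    assays; pass ``de_plan=()`` for a fully null card.
    """
    base = SyntheticSpec()
    if "de_plan" not in overrides:
        overrides["de_plan"] = tuple(
            (base.n_stable + i, "DME", LOG2_2_5) for i in range(8)
        )
    return replace(base, **overrides)


def generate(
    spec: SyntheticSpec, seed: int
) -> tuple[CtMatrix, SampleSheet, SyntheticTruth]:
    """Generate one (CtMatrix, SampleSheet, SyntheticTruth) bundle.

    The seed is mandatory and fully determines the output; no global random
    state is touched.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_mirnas
    groups = list(spec.group_sizes)
    sample_ids: list[str] = []
    sample_groups: list[str] = []
    for g in groups:
        for r in range(spec.group_sizes[g]):
            sample_ids.append(f"{g}-{r + 1:02d}")
            sample_groups.append(g)
    n_samp = len(sample_ids)
    mirnas = [_mirna_name(i, spec.n_stable) for i in range(n)]

    lo, hi = spec.baseline_ct_range
    baseline = rng.uniform(lo, hi, size=n)
    slo, shi = spec.stable_baseline_ct_range
    baseline[: spec.n_stable] = rng.uniform(slo, shi, size=spec.n_stable)

    offsets = rng.normal(0.0, spec.sample_offset_sd, size=n_samp)
    noise_sd = np.full(n, spec.tech_noise_sd)
    noise_sd[: spec.n_stable] = spec.stable_noise_sd
    eps = rng.normal(0.0, 1.0, size=(n, n_samp)) * noise_sd[:, None]

    shift = np.zeros((n, n_samp))
    de_rows = []
    for idx, group, s in spec.de_plan:
        cols = [j for j, g in enumerate(sample_groups) if g == group]
        shift[idx, cols] += s
        de_rows.append((mirnas[idx], group, float(s), float(2.0 ** (-s))))

    true_ct = baseline[:, None] + offsets[None, :] + shift + eps

    observed = true_ct.copy()
    observed[true_ct > spec.lod_ct] = np.nan
    near = (true_ct > spec.lod_ct - 1.0) & (true_ct <= spec.lod_ct)
    dropout = rng.random(size=true_ct.shape) < spec.p_dropout_near_lod
    observed[near & dropout] = np.nan

    ct = CtMatrix(pd.DataFrame(observed, index=pd.Index(mirnas, name="mirna"),
                               columns=sample_ids))
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "group": sample_groups,
                "compartment": spec.compartment,
                "cohort_stage": spec.cohort_stage,
            }
        ),
        group_labels=tuple(groups),
    )
    truth = SyntheticTruth(
        stable_set=tuple(mirnas[: spec.n_stable]),
        de_table=pd.DataFrame(
            de_rows, columns=["mirna", "group", "shift_ct", "true_fold"]
        ),
        sample_offsets=pd.Series(offsets, index=sample_ids, name="offset"),
        true_ct=pd.DataFrame(true_ct, index=pd.Index(mirnas, name="mirna"),
                             columns=sample_ids),
    )
    return ct, sheet, truth


def plant_recovery_report(
    truth: SyntheticTruth,
    stability: StabilityTable | None = None,
    de: DEResult | None = None,
    k: int = 3,
) -> dict:
    """Score how well the pipeline recovered the planted structure.

    Reference recovery: |planted stable set ∩ top-k of the SSS ranking| / k.
    DE recall: fraction of planted (miRNA, group) shifts called, per strategy
    and for the consensus — a plant counts as recalled when it is significant
    with the true direction in at least one comparison involving its group.
    False-call rate: fraction of unplanted, tested miRNAs significant in any
    comparison.
    """
    report: dict = {}
    if stability is not None:
        known = set(stability.table["mirna"])
        top = set(stability.top(min(k, len(stability.table))))
        hits = top & set(truth.stable_set)
        report["reference_recovery"] = {
            "top_k": sorted(top),
            "n_recovered": len(hits),
            "recovery_rate": len(hits) / max(len(truth.stable_set), 1),
            # plants censored out of the candidate pool are worth surfacing
            "planted_missing_from_candidates": sorted(set(truth.stable_set) - known),
        }
    if de is not None:
        planted = {
            (row.mirna, row.group): ("down" if row.shift_ct > 0 else "up")
            for row in truth.de_table.itertuples()
        }
        tested = set(de.table["mirna"])
        planted_mirnas = {m for m, _ in planted}
        strategies = list(de.table["strategy"].unique()) + ["consensus"]
        de_report: dict = {}
        for strat in strategies:
            if strat == "consensus":
                calls = de.consensus[de.consensus["consensus"]]
            else:
                sub = de.table[(de.table["strategy"] == strat) & de.table["significant"]]
                calls = sub
            recalled = 0
            for (mirna, group), direction in planted.items():
                mask = (
                    (calls["mirna"] == mirna)
                    & calls["comparison"].str.contains(group)
                    & (calls["direction"] == direction)
                )
                if mask.any():
                    recalled += 1
            null_tested = tested - planted_mirnas
            false_calls = set(calls["mirna"]) & null_tested
            de_report[strat] = {
                "recall": recalled / max(len(planted), 1),
                "n_recalled": recalled,
                "false_positive_rate": len(false_calls) / max(len(null_tested), 1),
                "n_false_calls": len(false_calls),
                "n_null_tested": len(null_tested),
            }
        report["de"] = de_report
    return report
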