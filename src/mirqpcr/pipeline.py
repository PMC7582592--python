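"""End-to-end orchestration: detection -> reference selection -> dual
normalization -> profiling DE -> single-assay validation -> plasma.

The profiling stage mirrors the study workflow on an array card: filter to
reliably-detected miRNAs, rank fully-observed candidates by SSS, take the
top-k endogenous controls, normalize under both strategies and call
consensus DE for every pairwise group comparison.  The validation stage
re-tests promoted miRNAs in single assays on the full cohort (one reference
miRNA), then takes only the validated ones to plasma (two references, per
circulating-miRNA practice) — the plasma-tested set is by construction a
subset of the validated set.

Every stage is a pure function of (inputs, config); a manifest with SHA-256
checksums of all inputs and outputs makes rerun determinism checkable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .de import (
    DEResult,
    DEThresholds,
    profiling_de,
    spearman_correlation,
    validation_de,
    volcano_table,
)
from .detection import DetectionResult, detect_flags
from .io import CtMatrix, SampleSheet, read_ct_table, read_sample_sheet
from .stability import StabilityTable, candidate_filter, rank_candidates, select_references

logger = logging.getLogger("mirqpcr")

__all__ = [
    "RunConfig",
    "ProfilingBundle",
    "profile_stage",
    "run_profiling",
    "validation_stage",
    "run_validation",
]


@dataclass(frozen=True)
class RunConfig:
    """Structured configuration for a full pipeline run."""

    profiling_ct: str
    profiling_sheet: str
    out_dir: str = "mirqpcr_out"
    validation_ah_ct: str | None = None
    validation_ah_sheet: str | None = None
    plasma_ct: str | None = None
    plasma_sheet: str | None = None
    ct_threshold: float = 35.0
    min_detect_frac: float = 0.8
    fold_cutoff: float = 2.5
    alpha: float = 0.05
    k_references: int = 3
    reference_override: tuple[str, ...] | None = None
    ah_validation_ref: str | None = None  # default: best-ranked reference
    plasma_refs: tuple[str, ...] | None = None  # default: ah_validation_ref
    promote_include: tuple[str, ...] = ()
    promote_exclude: tuple[str, ...] = ()
    seed: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("reference_override", "plasma_refs", "promote_include", "promote_exclude"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def thresholds(self) -> DEThresholds:
        return DEThresholds(fold_cutoff=self.fold_cutoff, alpha=self.alpha)

    def check_paths(self) -> None:
        for name in ("profiling_ct", "profiling_sheet", "validation_ah_ct",
                     "validation_ah_sheet", "plasma_ct", "plasma_sheet"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config field {name}: no such file: {p}")


@dataclass(frozen=True)
class ProfilingBundle:
    """In-memory results of the profiling stage."""

    detection: DetectionResult
    stability: StabilityTable
    references: tuple[str, ...]
    de: DEResult

    def consensus_directions(self) -> dict[str, str]:
        """Direction per consensus miRNA (for validation trend checks)."""
        cons = self.de.consensus[self.de.consensus["consensus"]]
        out: dict[str, str] = {}
        for row in cons.itertuples():
            out.setdefault(row.mirna, row.direction)
        return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, index=index)


def profile_stage(
    ct: CtMatrix,
    sheet: SampleSheet,
    thresholds: DEThresholds = DEThresholds(),
    ct_threshold: float = 35.0,
    min_detect_frac: float = 0.8,
    k_references: int = 3,
    reference_override: Sequence[str] | None = None,
) -> ProfilingBundle:
    """Library entry point for the profiling stage on in-memory objects."""
    sheet = sheet.subset(ct.sample_ids)
    detection = detect_flags(ct, sheet, ct_threshold=ct_threshold, min_frac=min_detect_frac)
    candidates = candidate_filter(ct)
    stability = rank_candidates(ct, sheet, candidates=candidates)
    if reference_override is not None:
        refs = tuple(reference_override)
        absent = [r for r in refs if r not in set(candidates)]
        if absent:
            raise ValueError(f"overridden references are not complete candidates: {absent}")
    else:
        refs = tuple(select_references(stability, k=k_references))
    detected = detection.detected_set
    keep = list(dict.fromkeys([*detected, *refs]))
    ct_de = ct.subset_mirnas(keep)
    de = profiling_de(ct_de, sheet, refs=refs, thresholds=thresholds, basis=detected)
    return ProfilingBundle(detection=detection, stability=stability,
                           references=refs, de=de)


def run_profiling(config: RunConfig) -> dict[str, Any]:
    """File-in/file-out profiling run; returns the manifest dict."""
    config.check_paths()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    ct = read_ct_table(config.profiling_ct)
    sheet = read_sample_sheet(config.profiling_sheet, groups=None)
    logger.info("profiling: %d miRNAs x %d samples", ct.n_mirnas, ct.n_samples)

    bundle = profile_stage(
        ct,
        sheet,
        thresholds=config.thresholds(),
        ct_threshold=config.ct_threshold,
        min_detect_frac=config.min_detect_frac,
        k_references=config.k_references,
        reference_override=config.reference_override,
    )

    outputs: dict[str, Path] = {}
    det_path = out_dir / "detection.json"
    det_path.write_text(json.dumps(bundle.detection.summary(), indent=2, sort_keys=True))
    outputs["detection"] = det_path

    stab_path = out_dir / "stability.csv"
    _write_csv(bundle.stability.table, stab_path)
    outputs["stability"] = stab_path

    from .normalization import global_mean_normalize, reference_normalize

    detected = bundle.detection.detected_set
    keep = list(dict.fromkeys([*detected, *bundle.references]))
    ct_de = ct.subset_mirnas(keep)
    for strategy, norm in (
        ("global_mean", global_mean_normalize(ct_de, basis=detected)),
        ("reference", reference_normalize(ct_de, bundle.references)),
    ):
        p = out_dir / f"dct_{strategy}.csv"
        _write_csv(norm.dct, p, index=True)
        outputs[f"dct_{strategy}"] = p

    de_path = out_dir / "de.csv"
    _write_csv(bundle.de.table, de_path)
    outputs["de"] = de_path
    cons_path = out_dir / "consensus.csv"
    _write_csv(bundle.de.consensus, cons_path)
    outputs["consensus"] = cons_path
    for strategy in ("global_mean", "reference"):
        p = out_dir / f"volcano_{strategy}.csv"
        _write_csv(volcano_table(bundle.de, strategy), p)
        outputs[f"volcano_{strategy}"] = p

    manifest = _manifest(config, stage="profiling", outputs=outputs, t0=t0)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _promoted(bundle_directions: Mapping[str, str], config: RunConfig) -> dict[str, str]:
    promoted = dict(bundle_directions)
    for m in config.promote_exclude:
        promoted.pop(m, None)
    for m in config.promote_include:
        promoted.setdefault(m, "down")
    return promoted


def validation_stage(
    ah_ct: CtMatrix,
    ah_sheet: SampleSheet,
    profiling_directions: Mapping[str, str],
    ah_ref: str,
    thresholds: DEThresholds = DEThresholds(),
    plasma_ct: CtMatrix | None = None,
    plasma_sheet: SampleSheet | None = None,
    plasma_refs: Sequence[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Single-assay validation in AH, then plasma, then AH-plasma correlation.

    Only miRNAs validated in AH (direction-consistent, p <= alpha in at
    least one comparison) proceed to plasma; the gating is asserted.
    """
    targets = [m for m in ah_ct.mirna_ids if m != ah_ref and m in profiling_directions]
    ah_calls = validation_de(
        ah_ct.subset_mirnas([*targets, ah_ref]),
        ah_sheet.subset(ah_ct.sample_ids),
        refs=[ah_ref],
        profiling_directions=profiling_directions,
        thresholds=thresholds,
        cohort="all_subjects",
    )
    validated = sorted(set(ah_calls.loc[ah_calls["validated"], "mirna"]))
    out: dict[str, pd.DataFrame] = {"ah": ah_calls}

    if plasma_ct is None:
        if validated:
            logger.info("no plasma table provided; stopping after AH validation")
        return out
    if not validated:
        logger.info("empty AH-validated set; plasma stage skipped")
        out["plasma"] = pd.DataFrame(
            columns=["mirna", "comparison", "fc", "direction", "p",
                     "trend_match", "validated", "evaluable", "cohort"]
        )
        return out
    if plasma_refs is None:
        raise ValueError("plasma_refs required when a plasma Ct table is given")
    plasma_targets = [m for m in validated if m in set(plasma_ct.mirna_ids)]
    plasma_calls = validation_de(
        plasma_ct.subset_mirnas([*plasma_targets, *plasma_refs]),
        plasma_sheet.subset(plasma_ct.sample_ids),
        refs=list(plasma_refs),
        profiling_directions=profiling_directions,
        thresholds=thresholds,
        cohort="all_subjects",
    )
    assert set(plasma_calls["mirna"]) <= set(validated), (
        "plasma-tested set must be a subset of the AH-validated set"
    )
    out["plasma"] = plasma_calls

    # per-miRNA rank correlation of AH vs plasma relative expression on the
    # samples shared between compartments (matched by sample_id)
    from .normalization import reference_normalize

    shared = [s for s in ah_ct.sample_ids if s in set(plasma_ct.sample_ids)]
    corr_rows = []
    if len(shared) >= 4:
        ah_rel = reference_normalize(ah_ct, [ah_ref]).rel_expr
        pl_rel = reference_normalize(plasma_ct, list(plasma_refs)).rel_expr
        for m in plasma_targets:
            res = spearman_correlation(
                ah_rel.loc[m, shared].to_numpy(), pl_rel.loc[m, shared].to_numpy()
            )
            corr_rows.append((m, res.rho, res.p, res.valid, len(shared)))
    out["correlation"] = pd.DataFrame(
        corr_rows, columns=["mirna", "rho", "p", "valid", "n_pairs"]
    )
    return out


def run_validation(config: RunConfig, profiling_manifest: Mapping | None = None) -> dict[str, Any]:
    """File-in/file-out validation run.

    Requires a prior profiling run in ``config.out_dir`` (its consensus
    table supplies the profiling directions).
    """
    config.check_paths()
    out_dir = Path(config.out_dir)
    cons_path = out_dir / "consensus.csv"
    if not cons_path.exists():
        raise FileNotFoundError(
            f"profiling output missing: {cons_path}; run the profiling stage first"
        )
    if config.validation_ah_ct is None or config.validation_ah_sheet is None:
        raise ValueError("validation_ah_ct and validation_ah_sheet are required")
    t0 = time.perf_counter()
    cons = pd.read_csv(cons_path)
    directions = {
        row.mirna: row.direction
        for row in cons[cons["consensus"].astype(bool)].itertuples()
    }
    directions = _promoted(directions, config)

    stab = pd.read_csv(out_dir / "stability.csv")
    default_ref = stab.sort_values("rank", kind="stable")["mirna"].iloc[0]
    ah_ref = config.ah_validation_ref or default_ref
    plasma_refs = config.plasma_refs or (ah_ref,)

    ah_ct = read_ct_table(config.validation_ah_ct)
    ah_sheet = read_sample_sheet(config.validation_ah_sheet, groups=None)
    plasma_ct = read_ct_table(config.plasma_ct) if config.plasma_ct else None
    plasma_sheet = (
        read_sample_sheet(config.plasma_sheet, groups=None) if config.plasma_sheet else None
    )

    tables = validation_stage(
        ah_ct, ah_sheet, directions, ah_ref,
        thresholds=config.thresholds(),
        plasma_ct=plasma_ct, plasma_sheet=plasma_sheet, plasma_refs=plasma_refs,
    )
    outputs: dict[str, Path] = {}
    for name, df in tables.items():
        p = out_dir / f"validation_{name}.csv"
        _write_csv(df, p)
        outputs[f"validation_{name}"] = p
    manifest = _manifest(config, stage="validation", outputs=outputs, t0=t0)
    (out_dir / "manifest_validation.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    return manifest


def _manifest(config: RunConfig, stage: str, outputs: Mapping[str, Path], t0: float) -> dict:
    inputs = {}
    for name in ("profiling_ct", "profiling_sheet", "validation_ah_ct",
                 "validation_ah_sheet", "plasma_ct", "plasma_sheet"):
        p = getattr(config, name)
        if p is not None and Path(p).exists():
            inputs[name] = _sha256(Path(p))
    return {
        "stage": stage,
        "package_version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "input_checksums": inputs,
        "output_checksums": {k: _sha256(p) for k, p in sorted(outputs.items())},
        "elapsed_seconds": round(time.perf_counter() - t0, 3),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()),
    }
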