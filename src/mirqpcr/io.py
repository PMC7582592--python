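"""Reading and writing of Ct matrices and sample sheets.

The on-disk canonical layout is *wide*: one row per miRNA, one column per
sample, the first column holding miRNA identifiers and the header row the
sample identifiers.  Wells that did not amplify are encoded by a missing
marker (``"Undetermined"``, ``"NA"`` or an empty cell by default) and become
``NaN`` in memory; every other cell must parse as a finite positive real.

Identifiers are case-sensitive throughout: miRNA nomenclature distinguishes
e.g. ``hsa-miR-199a-3p`` from ``hsa-miR-199a-5p`` and lowercasing would merge
distinct assays.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CtMatrix",
    "SampleSheet",
    "DEFAULT_MISSING_MARKERS",
    "GROUPS",
    "COMPARTMENTS",
    "COHORT_STAGES",
    "read_ct_table",
    "read_ct_table_long",
    "write_ct_table",
    "read_sample_sheet",
    "write_sample_sheet",
]

#: Cell contents treated as "no Ct called" when reading a Ct table.
DEFAULT_MISSING_MARKERS: tuple[str, ...] = ("Undetermined", "NA", "")

#: Default clinical group vocabulary (non-diabetic controls, diabetics
#: without retinopathy, diabetics with macular edema).  User-defined labels
#: are accepted when ``groups=None`` is passed to :func:`read_sample_sheet`.
GROUPS: tuple[str, ...] = ("CTR", "D", "DME")
COMPARTMENTS: tuple[str, ...] = ("AH", "plasma")
COHORT_STAGES: tuple[str, ...] = ("profiling", "validation")

_SHEET_COLUMNS = ("sample_id", "group", "compartment", "cohort_stage")


@dataclass(frozen=True)
class CtMatrix:
    """A miRNA x sample grid of raw cycle-threshold values.

    ``values`` is a float DataFrame indexed by miRNA id with sample ids as
    columns; missing wells are ``NaN`` (never a sentinel Ct).  Present values
    must be finite and strictly positive.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate miRNA identifiers: {dupes}")
        if df.columns.has_duplicates:
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dupes}")
        arr = df.to_numpy(dtype=float, copy=False)
        present = ~np.isnan(arr)
        if np.any(~np.isfinite(arr[present])):
            raise ValueError("Ct values must be finite")
        if np.any(arr[present] <= 0):
            raise ValueError("Ct values must be strictly positive")

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_mirnas(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_mirnas(self, mirnas: Sequence[str]) -> "CtMatrix":
        missing = [m for m in mirnas if m not in self.values.index]
        if missing:
            raise KeyError(f"miRNAs not in matrix: {missing}")
        return CtMatrix(self.values.loc[list(mirnas)])

    def subset_samples(self, samples: Sequence[str]) -> "CtMatrix":
        missing = [s for s in samples if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return CtMatrix(self.values[list(samples)])


@dataclass(frozen=True)
class SampleSheet:
    """Sample metadata: group, compartment and cohort stage per sample."""

    table: pd.DataFrame
    group_labels: tuple[str, ...] = GROUPS

    def __post_init__(self) -> None:
        missing = [c for c in _SHEET_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        ids = self.table["sample_id"]
        if ids.duplicated().any():
            raise ValueError(
                f"duplicate sample ids in sheet: {ids[ids.duplicated()].tolist()}"
            )
        bad_comp = set(self.table["compartment"]) - set(COMPARTMENTS)
        if bad_comp:
            raise ValueError(f"unknown compartment labels: {sorted(bad_comp)}")
        bad_stage = set(self.table["cohort_stage"]) - set(COHORT_STAGES)
        if bad_stage:
            raise ValueError(f"unknown cohort_stage labels: {sorted(bad_stage)}")
        if self.group_labels is not None:
            bad_grp = set(self.table["group"]) - set(self.group_labels)
            if bad_grp:
                raise ValueError(f"unknown group labels: {sorted(bad_grp)}")

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def groups(self) -> list[str]:
        """Group labels in first-appearance order."""
        return list(dict.fromkeys(self.table["group"]))

    def group_of(self) -> pd.Series:
        """sample_id -> group mapping."""
        return self.table.set_index("sample_id")["group"]

    def samples_in_group(self, group: str) -> list[str]:
        if group not in set(self.table["group"]):
            raise KeyError(f"group {group!r} absent from sample sheet")
        mask = self.table["group"] == group
        return self.table.loc[mask, "sample_id"].tolist()

    def subset(self, sample_ids: Iterable[str]) -> "SampleSheet":
        wanted = set(sample_ids)
        sub = self.table[self.table["sample_id"].isin(wanted)].reset_index(drop=True)
        return SampleSheet(sub, group_labels=self.group_labels)

    def check_covers(self, ct: CtMatrix) -> None:
        """Every Ct-matrix sample must have exactly one sheet row."""
        absent = [s for s in ct.sample_ids if s not in set(self.sample_ids)]
        if absent:
            raise ValueError(f"samples in Ct table absent from sheet: {absent}")


def read_ct_table(
    path: str | Path,
    sep: str = ",",
    missing_markers: Sequence[str] = DEFAULT_MISSING_MARKERS,
) -> CtMatrix:
    """Read a wide Ct table (miRNA rows x sample columns).

    Cells equal to any marker in ``missing_markers`` (after stripping
    whitespace) become missing; every other cell must parse as a finite
    real number.  Parsing is locale-independent: decimal point only,
    scientific notation accepted.
    """
    import csv

    with open(path, newline="", encoding="utf-8") as fh:
        header = next(csv.reader(fh, delimiter=sep), None)
    if header is None:
        raise ValueError(f"empty Ct table: {path}")
    samples = [h.strip() for h in header[1:]]
    # pandas mangles duplicate columns (s1, s1.1); validate before it can
    if len(set(samples)) != len(samples):
        dupes = sorted({s for s in samples if samples.count(s) > 1})
        raise ValueError(f"duplicate sample identifiers in header: {dupes}")
    raw = pd.read_csv(
        path, sep=sep, index_col=0, dtype=str, keep_default_na=False, na_values=[]
    )
    raw.columns = samples
    raw.index = raw.index.astype(str).str.strip()
    raw.columns = raw.columns.astype(str).str.strip()
    markers = set(missing_markers)

    def _parse(cell: str, mirna: str, sample: str) -> float:
        cell = cell.strip()
        if cell in markers:
            return np.nan
        try:
            return float(cell)
        except ValueError:
            raise ValueError(
                f"unparseable Ct cell {cell!r} at miRNA {mirna!r}, sample {sample!r}"
            ) from None

    parsed = pd.DataFrame(
        {
            sample: [_parse(raw.at[m, sample], m, sample) for m in raw.index]
            for sample in raw.columns
        },
        index=raw.index,
        dtype=float,
    )
    parsed.index.name = "mirna"
    return CtMatrix(parsed)


def read_ct_table_long(
    path: str | Path,
    sep: str = ",",
    missing_markers: Sequence[str] = DEFAULT_MISSING_MARKERS,
) -> CtMatrix:
    """Convenience reader for long-format tables (columns mirna, sample, ct)."""
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, na_values=[])
    need = {"mirna", "sample", "ct"}
    if not need <= set(raw.columns):
        raise ValueError(f"long Ct table must have columns {sorted(need)}")
    markers = set(missing_markers)
    ct = raw["ct"].str.strip().map(lambda c: np.nan if c in markers else float(c))
    wide = (
        raw.assign(ct=ct)
        .pivot_table(index="mirna", columns="sample", values="ct", aggfunc="first", dropna=False)
        .rename_axis(index="mirna", columns=None)
    )
    # preserve first-appearance order rather than pivot's lexicographic sort
    wide = wide.loc[
        list(dict.fromkeys(raw["mirna"])), list(dict.fromkeys(raw["sample"]))
    ]
    return CtMatrix(wide.astype(float))


def write_ct_table(ct: CtMatrix, path: str | Path, sep: str = ",") -> None:
    """Write a Ct matrix in the wide canonical layout; missing cells as "NA".

    Column order is the matrix's own sample order (deterministic), and values
    are written with ``repr`` precision so read/write round-trips bit-exactly.
    """
    df = ct.values
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(sep.join(["mirna", *df.columns.astype(str)]) + "\n")
        for mirna, row in zip(df.index, df.to_numpy()):
            cells = ["NA" if np.isnan(v) else repr(float(v)) for v in row]
            fh.write(sep.join([str(mirna), *cells]) + "\n")


def read_sample_sheet(
    path: str | Path,
    sep: str = ",",
    groups: Sequence[str] | None = GROUPS,
) -> SampleSheet:
    """Read a sample sheet CSV (sample_id, group, compartment, cohort_stage).

    ``groups=None`` disables group-vocabulary validation (user-defined labels).
    """
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, na_values=[])
    raw.columns = raw.columns.str.strip()
    for col in _SHEET_COLUMNS:
        if col in raw.columns:
            raw[col] = raw[col].str.strip()
    return SampleSheet(raw, group_labels=tuple(groups) if groups is not None else None)


def write_sample_sheet(sheet: SampleSheet, path: str | Path, sep: str = ",") -> None:
    sheet.table.loc[:, list(_SHEET_COLUMNS)].to_csv(path, sep=sep, index=False)
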