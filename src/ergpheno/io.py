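"""Readers and writers for the tabular interchange formats.

All tables are UTF-8 CSV with a header row and "." as the decimal
separator. Reading validates the schema and raises
:class:`~ergpheno.errors.ValidationError` naming the offending row.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import pandas as pd

from ergpheno.config import STIMULI
from ergpheno.errors import ValidationError

TRACE_COLUMNS = ["patient_id", "eye", "stimulus", "repeat", "time_ms", "voltage_uV"]
COHORT_COLUMNS = [
    "patient_id",
    "age_years",
    "sex",
    "pupil_class",
    "compliance",
    "group_label",
    "variant_a",
    "variant_b",
]
COHORT_REQUIRED = ["patient_id", "age_years", "sex", "pupil_class", "compliance"]

EYES = ("L", "R")
SEXES = ("M", "F")
PUPIL_CLASSES = (">=7mm", "<7mm")


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{what}: missing column(s) {missing}")


def read_trace_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format trace table.

    Checks stimulus/eye labels, positive integer repeat indices, and
    strictly increasing time within each (patient, eye, stimulus, repeat)
    in file order; returns rows sorted by key, preserving time order.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, TRACE_COLUMNS, f"trace table {path}")

    bad = df.loc[~df["stimulus"].isin(STIMULI)]
    if not bad.empty:
        row = bad.index[0]
        raise ValidationError(
            f"trace table {path}: unknown stimulus {bad['stimulus'].iloc[0]!r} "
            f"at row {row}"
        )
    bad = df.loc[~df["eye"].isin(EYES)]
    if not bad.empty:
        raise ValidationError(
            f"trace table {path}: unknown eye {bad['eye'].iloc[0]!r} at row {bad.index[0]}"
        )
    if (df["repeat"] < 1).any():
        row = df.index[df["repeat"] < 1][0]
        raise ValidationError(f"trace table {path}: repeat < 1 at row {row}")

    for key, grp in df.groupby(["patient_id", "eye", "stimulus", "repeat"], sort=False):
        dt = grp["time_ms"].diff().iloc[1:]
        if (dt <= 0).any():
            row = dt.index[dt <= 0][0]
            raise ValidationError(
                f"trace table {path}: non-monotone time at row {row} (trace {key})"
            )
    return df.sort_values(
        ["patient_id", "eye", "stimulus", "repeat"], kind="mergesort"
    ).reset_index(drop=True)


def write_trace_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    """Read and validate the cohort metadata table."""
    df = pd.read_csv(path, keep_default_na=True, float_precision="round_trip")
    _require_columns(df, COHORT_REQUIRED, f"cohort table {path}")
    dup = df["patient_id"].duplicated()
    if dup.any():
        pid = df.loc[dup, "patient_id"].iloc[0]
        raise ValidationError(f"cohort table {path}: duplicate patient_id {pid!r}")
    if (df["age_years"] < 0).any():
        row = df.index[df["age_years"] < 0][0]
        raise ValidationError(f"cohort table {path}: negative age at row {row}")
    bad = df.loc[~df["sex"].isin(SEXES)]
    if not bad.empty:
        raise ValidationError(
            f"cohort table {path}: unknown sex {bad['sex'].iloc[0]!r} at row {bad.index[0]}"
        )
    bad = df.loc[~df["pupil_class"].isin(PUPIL_CLASSES)]
    if not bad.empty:
        raise ValidationError(
            f"cohort table {path}: unknown pupil class "
            f"{bad['pupil_class'].iloc[0]!r} at row {bad.index[0]}"
        )
    bad = df.loc[~df["compliance"].isin([1, 2, 3, 4, 5])]
    if not bad.empty:
        raise ValidationError(
            f"cohort table {path}: compliance outside 1-5 at row {bad.index[0]}"
        )
    if "group_label" in df.columns:
        present = df["group_label"].dropna()
        if not present.isin([1, 2, 3]).all():
            bad_idx = present.index[~present.isin([1, 2, 3])][0]
            raise ValidationError(
                f"cohort table {path}: group label outside {{1,2,3}} at row {bad_idx}"
            )
    for col in ("variant_a", "variant_b"):
        if col in df.columns:
            df[col] = df[col].fillna("")
    return df


def write_cohort_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def write_json(data: dict[str, Any], path: str | Path) -> None:
    """Deterministic JSON output (sorted keys, fixed separators)."""
    Path(path).write_text(
        json.dumps(data, indent=2, sort_keys=True, allow_nan=True) + "\n"
    )


def write_outputs(results: dict[str, Any], out_dir: str | Path) -> list[Path]:
    """Write a result bundle: DataFrames as CSV, everything else as JSON.

    Keys become file stems; DataFrames with a meaningful index keep it.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, obj in sorted(results.items()):
        if isinstance(obj, pd.DataFrame):
            path = out_dir / f"{name}.csv"
            obj.to_csv(path, index=obj.index.name is not None or isinstance(obj.index, pd.MultiIndex))
        else:
            path = out_dir / f"{name}.json"
            write_json(obj, path)
        written.append(path)
    return written
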