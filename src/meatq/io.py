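"""Reading and writing of the pipeline's CSV tables with schema validation.

CSV dialect: UTF-8, comma separator, mandatory header row, "." decimal,
muscle labels exactly "LTL"/"SM".  Validation errors name the file, row and
column so malformed inputs fail loudly at the boundary.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "read_cohort",
    "write_cohort",
    "read_sensory",
    "write_sensory",
    "read_echo_trains",
    "write_echo_trains",
    "read_fits",
    "write_fits",
]

COHORT_COLUMNS = [
    "carcass_id",
    "muscle",
    "pH",
    "imf_pct",
    "collagen_mg_g",
    "collagen_solubility_pct",
    "nirs_1",
    "nirs_2",
    "nirs_3",
]

SENSORY_COLUMNS = [
    "participant_id",
    "session_id",
    "day",
    "carcass_id",
    "muscle",
    "tenderness",
    "juiciness",
    "flavor",
    "overall",
    "off_flavor",
    "purchase_intent",
    "quality_grade",
]

ECHO_COLUMNS = ["sample_id", "replicate", "echo_time_ms", "intensity"]

FIT_COLUMNS = [
    "sample_id",
    "replicate",
    "p_2f",
    "p_21",
    "p_22",
    "T_21_ms",
    "T_22_ms",
    "scale",
    "residual_rms",
    "converged",
]

#: Plausible physical ranges enforced on read (row-level, named in errors).
_COHORT_RANGES = {
    "pH": (4.5, 7.5),
    "imf_pct": (0.0, 25.0),
    "collagen_mg_g": (0.0, 50.0),
    "collagen_solubility_pct": (0.0, 100.0),
    "nirs_1": (0.0, 50.0),
    "nirs_2": (0.0, 50.0),
    "nirs_3": (0.0, 50.0),
}

_SENSORY_RANGES = {
    "tenderness": (0.0, 100.0),
    "juiciness": (0.0, 100.0),
    "flavor": (0.0, 100.0),
    "overall": (0.0, 100.0),
    "off_flavor": (0, 1),
    "purchase_intent": (1, 5),
    "quality_grade": (1, 4),
}


class SchemaError(ValueError):
    """A table violated its schema; message names file, row and column."""


def _require_columns(df: pd.DataFrame, columns, path: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def _check_ranges(df: pd.DataFrame, ranges: dict, path: str) -> None:
    for col, (lo, hi) in ranges.items():
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = ~vals.between(lo, hi) | vals.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(
                f"{path}: line {row + 2}, column '{col}': value "
                f"{df[col].iloc[row]!r} outside [{lo}, {hi}]"
            )


def _check_muscle(df: pd.DataFrame, path: str) -> None:
    bad = ~df["muscle"].isin(["LTL", "SM"])
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(
            f"{path}: line {row + 2}, column 'muscle': "
            f"{df['muscle'].iloc[row]!r} is not 'LTL'/'SM'"
        )


def read_cohort(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, COHORT_COLUMNS, path)
    _check_muscle(df, path)
    _check_ranges(df, _COHORT_RANGES, path)
    return df[COHORT_COLUMNS]


def write_cohort(df: pd.DataFrame, path: str) -> None:
    _require_columns(df, COHORT_COLUMNS, "cohort table")
    df[COHORT_COLUMNS].to_csv(path, index=False)


def read_sensory(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, SENSORY_COLUMNS, path)
    _check_muscle(df, path)
    _check_ranges(df, _SENSORY_RANGES, path)
    for col in ("participant_id", "session_id", "carcass_id"):
        empty = df[col].isna() | (df[col].astype(str).str.len() == 0)
        if empty.any():
            row = int(np.flatnonzero(empty.to_numpy())[0])
            raise SchemaError(f"{path}: line {row + 2}, column '{col}': empty id")
    return df[SENSORY_COLUMNS]


def write_sensory(df: pd.DataFrame, path: str) -> None:
    _require_columns(df, SENSORY_COLUMNS, "sensory table")
    df[SENSORY_COLUMNS].to_csv(path, index=False)


def read_echo_trains(path: str) -> pd.DataFrame:
    """Long-format echo trains; times must increase within each measurement."""
    df = pd.read_csv(path)
    _require_columns(df, ECHO_COLUMNS, path)
    for (sample, rep), grp in df.groupby(["sample_id", "replicate"], sort=False):
        t = grp["echo_time_ms"].to_numpy(dtype=float)
        if t.size and (np.any(t <= 0) or np.any(np.diff(t) <= 0)):
            raise SchemaError(
                f"{path}: measurement {sample}/{rep}: echo times must be "
                "positive and strictly increasing"
            )
    return df


def write_echo_trains(df: pd.DataFrame, path: str) -> None:
    _require_columns(df, ECHO_COLUMNS, "echo table")
    df[ECHO_COLUMNS].to_csv(path, index=False)


def read_fits(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, FIT_COLUMNS, path)
    return df


def write_fits(df: pd.DataFrame, path: str) -> None:
    _require_columns(df, FIT_COLUMNS, "fits table")
    df[FIT_COLUMNS].to_csv(path, index=False)
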