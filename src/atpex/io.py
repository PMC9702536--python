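"""Readers and writers for the toolkit's CSV and JSON dialects.

Column names carry their units (``time_min``, ``de_m2_per_s``) because
the surrounding literature freely mixes minutes, W/L, °C and m²/s; a
renamed column is a schema error, not a silent unit bug.  All files are
UTF-8 CSV with '.' as the decimal separator.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .diffusion import KineticsCurve
from .exceptions import ParseError, SchemaError, ValidationError

__all__ = ["DIALECTS", "read_table", "write_table", "kinetics_to_curves", "write_json"]

#: Required columns per dialect; extra columns are preserved.
DIALECTS = {
    "binodal": ["w2", "w1"],
    "kinetics": ["time_min", "yield_mg_per_g", "aed_w_per_l", "temp_c", "phase"],
    "de_table": ["aed_w_per_l", "temp_c", "de_m2_per_s"],
    "ann_dataset": ["aed_w_per_l", "temp_c", "time_min", "yield_mg_per_g"],
    "partition": ["c_top", "c_bottom", "v_top", "v_bottom", "analyte"],
}

_NON_NUMERIC = {"phase", "analyte"}


def _validate(df: pd.DataFrame, dialect: str) -> pd.DataFrame:
    checks = {
        "binodal": [("w2", lambda s: (s >= 0) & (s <= 1), "w2 outside [0, 1]"),
                    ("w1", lambda s: (s >= 0) & (s <= 1), "w1 outside [0, 1]")],
        "kinetics": [("time_min", lambda s: s >= 0, "negative time"),
                     ("yield_mg_per_g", lambda s: s >= 0, "negative yield")],
        "de_table": [("de_m2_per_s", lambda s: s > 0, "non-positive De")],
        "ann_dataset": [("yield_mg_per_g", lambda s: s >= 0, "negative yield")],
        "partition": [("c_top", lambda s: s >= 0, "negative concentration"),
                      ("c_bottom", lambda s: s >= 0, "negative concentration"),
                      ("v_top", lambda s: s > 0, "non-positive volume"),
                      ("v_bottom", lambda s: s > 0, "non-positive volume")],
    }
    for col, ok, msg in checks.get(dialect, []):
        bad = ~ok(df[col])
        if bad.any():
            row = int(df.index[bad][0]) + 2  # 1-based with header row
            raise ValidationError(f"{msg} in column {col!r} at file row {row}")
    return df


def read_table(path, dialect: str) -> pd.DataFrame:
    """Read and validate a CSV table of the given dialect.

    Raises :class:`SchemaError` for a missing/renamed column or an empty
    file, :class:`ParseError` for a non-numeric cell (with row index) and
    :class:`ValidationError` when values violate the consuming module's
    invariants.
    """
    if dialect not in DIALECTS:
        raise SchemaError(f"unknown dialect {dialect!r}; expected one of {sorted(DIALECTS)}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file, expected header {DIALECTS[dialect]}") from exc
    missing = [c for c in DIALECTS[dialect] if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: row 1 is missing required column(s) {missing} "
            f"for dialect {dialect!r} (found {list(df.columns)})"
        )
    for col in DIALECTS[dialect]:
        if col in _NON_NUMERIC:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        # empty cells stay NaN (legal for metadata columns such as AED in a
        # bare simulation); only a non-empty unparseable cell is an error
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(df.index[bad][0]) + 2
            raise ParseError(f"{path}: non-numeric value in column {col!r} at file row {row}")
        df[col] = coerced.astype(float)
    return _validate(df, dialect)


def write_table(df: pd.DataFrame, path, dialect: str) -> None:
    """Write a table, verifying the dialect columns are present."""
    missing = [c for c in DIALECTS[dialect] if c not in df.columns]
    if missing:
        raise SchemaError(f"cannot write dialect {dialect!r}: missing columns {missing}")
    df.to_csv(path, index=False)


def kinetics_to_curves(df: pd.DataFrame) -> dict:
    """Group a kinetics table into ``{(aed, temp, phase): KineticsCurve}``."""
    out = {}
    for (aed, temp, phase), grp in df.groupby(
        ["aed_w_per_l", "temp_c", "phase"], dropna=False
    ):
        grp = grp.sort_values("time_min")
        out[(float(aed), float(temp), str(phase))] = KineticsCurve.from_minutes(
            grp["time_min"].to_numpy(),
            grp["yield_mg_per_g"].to_numpy(),
            aed=float(aed),
            temperature=float(temp),
        )
    return out


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return super().default(obj)


def write_json(payload: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, cls=_NumpyEncoder)
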