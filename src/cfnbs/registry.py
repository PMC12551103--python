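"""Screening-registry schema and CSV I/O.

A registry is a pandas DataFrame with one row per screened newborn. The
mandatory column set (and CSV header order) is fixed; extra columns such as
``delay_reason`` are preserved on load and round-tripped on write.

Column semantics
----------------
infant_id        opaque identifier (string)
specimen_date    dried-blood-spot collection date (datetime64)
kit_id           IRT reagent-kit identifier (string)
irt              immunoreactive trypsinogen, ng/mL (float, >= 0)
race             one of Black, Multiracial, OtherRace, White, Unknown
ethnicity        one of Hispanic, NonHispanic, Unknown
sex              F or M
has_cf           eventual cystic-fibrosis diagnosis (bool)
variant1/2       CFTR variant legacy names; empty string when absent
meconium_ileus   neonatal meconium ileus/plug (bool)
diagnosis_date   CF diagnosis date, NaT when absent
sweat_dates      semicolon-joined ISO dates of sweat tests ("" = none)
sweat_results    semicolon-joined chloride mmol/L values or the QNS token
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import pandas as pd

REGISTRY_COLUMNS = [
    "infant_id",
    "specimen_date",
    "kit_id",
    "irt",
    "race",
    "ethnicity",
    "sex",
    "has_cf",
    "variant1",
    "variant2",
    "meconium_ileus",
    "diagnosis_date",
    "sweat_dates",
    "sweat_results",
]

RACES = ("Black", "Multiracial", "OtherRace", "White", "Unknown")
ETHNICITIES = ("Hispanic", "NonHispanic", "Unknown")
SEXES = ("F", "M")

#: token recorded when a sweat collection yielded an insufficient quantity
QNS = "QNS"

_DATE_COLS = ("specimen_date", "diagnosis_date")
_BOOL_COLS = ("has_cf", "meconium_ileus")
_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no"}


class RegistrySchemaError(ValueError):
    """A required registry column is missing or malformed."""


class RegistryParseError(ValueError):
    """A registry cell could not be parsed; carries the offending row."""


def _parse_bool(series: pd.Series, col: str) -> pd.Series:
    lowered = series.str.strip().str.lower()
    bad = ~lowered.isin(_TRUE | _FALSE)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise RegistryParseError(
            f"column {col!r}, row {row}: cannot parse boolean {series.iloc[row]!r}"
        )
    return lowered.isin(_TRUE)


def load_registry(path: str | Path | io.TextIOBase) -> pd.DataFrame:
    """Read a registry CSV, validating the mandatory schema.

    Lines starting with ``#`` (provenance headers) are skipped. Raises
    :class:`RegistrySchemaError` naming any missing column and
    :class:`RegistryParseError` citing the first unparseable row.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    missing = [c for c in REGISTRY_COLUMNS if c not in raw.columns]
    if missing:
        raise RegistrySchemaError(f"registry is missing required column(s): {missing}")

    df = raw.copy()
    irt = pd.to_numeric(df["irt"], errors="coerce")
    bad = irt.isna() | (irt < 0)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise RegistryParseError(
            f"column 'irt', row {row}: invalid IRT value {df['irt'].iloc[row]!r}"
        )
    df["irt"] = irt.astype(float)

    for col in _DATE_COLS:
        blank = df[col].str.strip() == ""
        parsed = pd.to_datetime(df[col].where(~blank), format="%Y-%m-%d", errors="coerce")
        bad = parsed.isna() & ~blank
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise RegistryParseError(
                f"column {col!r}, row {row}: invalid date {df[col].iloc[row]!r}"
            )
        if col == "specimen_date" and blank.any():
            row = int(np.flatnonzero(blank.to_numpy())[0])
            raise RegistryParseError(f"column 'specimen_date', row {row}: date required")
        df[col] = parsed

    for col in _BOOL_COLS:
        df[col] = _parse_bool(df[col], col)

    # keep mandatory columns first, preserve any extras (e.g. delay_reason)
    extras = [c for c in df.columns if c not in REGISTRY_COLUMNS]
    return df[REGISTRY_COLUMNS + extras]


def write_registry(df: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> None:
    """Write a registry DataFrame as CSV; inverse of :func:`load_registry`."""
    missing = [c for c in REGISTRY_COLUMNS if c not in df.columns]
    if missing:
        raise RegistrySchemaError(f"registry is missing required column(s): {missing}")
    out = df.copy()
    for col in _DATE_COLS:
        out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d").fillna("")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        out.to_csv(fh, index=False)


def genotype_of(row: pd.Series) -> list[str]:
    """Return the 0-2 variant names recorded for one infant."""
    return [v for v in (row["variant1"], row["variant2"]) if isinstance(v, str) and v != ""]


def parse_sweat_tests(sweat_dates: str, sweat_results: str) -> list[tuple[pd.Timestamp, float | str]]:
    """Decode the semicolon-joined sweat-test columns of one row.

    Results are chloride values in mmol/L, or the literal ``QNS`` token for
    quantity-not-sufficient collections.
    """
    if not sweat_dates and not sweat_results:
        return []
    dates = [d for d in str(sweat_dates).split(";") if d != ""]
    results = [r for r in str(sweat_results).split(";") if r != ""]
    if len(dates) != len(results):
        raise RegistryParseError(
            f"sweat_dates/sweat_results length mismatch: {sweat_dates!r} vs {sweat_results!r}"
        )
    out: list[tuple[pd.Timestamp, float | str]] = []
    for d, r in zip(dates, results):
        value: float | str
        if r.strip().upper() == QNS:
            value = QNS
        else:
            value = float(r)
            if value < 0:
                raise RegistryParseError(f"negative sweat chloride {r!r}")
        out.append((pd.Timestamp(d), value))
    return out


def format_sweat_tests(tests: list[tuple[pd.Timestamp, float | str]]) -> tuple[str, str]:
    """Inverse of :func:`parse_sweat_tests`."""
    dates = ";".join(pd.Timestamp(d).strftime("%Y-%m-%d") for d, _ in tests)
    results = ";".join(QNS if r == QNS else format(r, "g") for _, r in tests)
    return dates, results
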