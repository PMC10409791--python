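"""Readers, validators and summarizers for the cardiotoxicity dataset schema.

The published dataset ships as three CSV files: clinical variables (531
patients x 27 columns), the functional variable (270 patients x 1 CTRCD
column + 1001 velocity columns on the [0, 1] grid), and a combined file
(531 x 1028) where patients without a preprocessed image carry NAs in the
functional part.  This module reads those layouts into pandas DataFrames,
checks the schema and the variables' domain invariants, and reproduces the
descriptive summary tables (six-number summaries for numeric variables,
count/percentage pairs for binary ones).

Percentages for binary variables use the non-missing count of that variable
as denominator; quantiles follow the linear-interpolation convention (the
default in both numpy and R's ``quantile``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ContractError, SchemaError

__all__ = [
    "CLINICAL_COLUMNS",
    "NUMERIC_VARIABLES",
    "BINARY_VARIABLES",
    "SummaryRow",
    "BinarySummary",
    "Issue",
    "read_clinical",
    "read_functional",
    "summarize_numeric",
    "summarize_binary",
    "summary_tables",
    "validate",
]

CLINICAL_COLUMNS = [
    "age", "weight", "height", "CTRCD", "time", "LVEF", "heart_rate",
    "heart_rhythm", "PWT", "LAd", "LVDd", "LVSd", "AC", "antiHER2",
    "ACprev", "antiHER2prev", "HTA", "DL", "DM", "smoker", "exsmoker",
    "RTprev", "CIprev", "ICMprev", "ARRprev", "VALVprev", "cxvalv",
]

NUMERIC_VARIABLES = [
    "age", "weight", "height", "time", "LVEF", "heart_rate",
    "PWT", "LAd", "LVDd", "LVSd",
]

BINARY_VARIABLES = [c for c in CLINICAL_COLUMNS if c not in NUMERIC_VARIABLES]

# "valvsurgprev" appears as a synonym for previous valve surgery in some
# descriptions of the schema; cxvalv is canonical.
COLUMN_ALIASES = {"valvsurgprev": "cxvalv"}

N_GRID = 1001
_NA_TOKENS = ["", "NA", "NaN", "nan"]


@dataclass(frozen=True)
class SummaryRow:
    """Six-number summary of one numeric variable, in its own units."""

    min: float
    q1: float
    median: float
    mean: float
    q3: float
    max: float

    def __post_init__(self) -> None:
        if not (self.min <= self.q1 <= self.median <= self.q3 <= self.max):
            raise ContractError("summary order statistics out of order")
        tol = 1e-9 * max(1.0, abs(self.min), abs(self.max))  # fp roundoff in the mean
        if not (self.min - tol <= self.mean <= self.max + tol):
            raise ContractError("mean outside [min, max]")


@dataclass(frozen=True)
class BinarySummary:
    """Counts and percentages of the 0/1 codes among non-missing values."""

    n0: int
    pct0: float
    n1: int
    pct1: float


@dataclass(frozen=True)
class Issue:
    """One invariant breach found by :func:`validate`."""

    row: int
    rule: str
    message: str


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"dataset file not found: {path}")
    return pd.read_csv(
        path, na_values=_NA_TOKENS, keep_default_na=False, skipinitialspace=True
    )


def read_clinical(path) -> pd.DataFrame:
    """Read the clinical-variables CSV (27 columns, order-sensitive header).

    Empty cells and "NA" become missing.  A header that deviates from the
    published schema raises :class:`SchemaError` naming the offending
    columns; a non-numeric cell in a numeric column raises
    :class:`SchemaError` locating it.
    """
    df = _read_csv(path)
    cols = [COLUMN_ALIASES.get(c, c) for c in df.columns]
    if cols != CLINICAL_COLUMNS:
        bad = [
            f"position {i}: expected {e!r}, found {f!r}"
            for i, (e, f) in enumerate(zip(CLINICAL_COLUMNS, cols))
            if e != f
        ]
        if len(cols) != len(CLINICAL_COLUMNS):
            bad.append(f"expected 27 columns, found {len(cols)}")
        raise SchemaError("clinical header mismatch: " + "; ".join(bad))
    df.columns = cols
    for col in CLINICAL_COLUMNS:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            bad_rows = df.index[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            raise SchemaError(
                f"non-numeric value in column {col!r}, row(s) {list(bad_rows[:5])}"
            ) from exc
    return df


def read_functional(path) -> pd.DataFrame:
    """Read the functional-variable CSV: CTRCD plus 1001 grid columns.

    Accepts both the functional-only layout (1002 columns) and the combined
    clinical+functional layout (1028 columns, functional part possibly all
    missing for patients without a preprocessed image).  Grid headers are
    accepted with or without a space ("t 1" or "t1").  Returns a DataFrame
    with a ``CTRCD`` column, columns ``t1``..``t1001``, and a boolean
    ``functional_present`` column.
    """
    df = _read_csv(path)
    cols = [c.replace(" ", "") for c in df.columns]
    df.columns = cols
    grid_names = [f"t{i}" for i in range(1, N_GRID + 1)]
    if len(cols) == 1 + N_GRID:
        if cols[0] != "CTRCD":
            raise SchemaError(f"first column must be CTRCD, found {cols[0]!r}")
    elif len(cols) == len(CLINICAL_COLUMNS) + N_GRID:
        if "CTRCD" not in cols:
            raise SchemaError("combined layout lacks a CTRCD column")
    else:
        raise SchemaError(
            f"expected {1 + N_GRID} or {len(CLINICAL_COLUMNS) + N_GRID} columns, "
            f"found {len(cols)}"
        )
    missing = [g for g in grid_names if g not in cols]
    if missing:
        raise SchemaError(
            f"missing grid column(s): {missing[:3]}{'...' if len(missing) > 3 else ''}"
        )
    out = df[["CTRCD"] + grid_names].copy()
    out[grid_names] = out[grid_names].apply(pd.to_numeric, errors="coerce")
    out["functional_present"] = out[grid_names].notna().all(axis=1)
    return out


def summarize_numeric(df: pd.DataFrame, variable: str) -> SummaryRow | None:
    """Min/Q1/median/mean/Q3/max of a numeric variable over non-missing rows.

    Quantiles use linear interpolation of order statistics.  Returns ``None``
    when every value is missing.
    """
    if variable not in NUMERIC_VARIABLES:
        raise ContractError(f"{variable!r} is not a numeric variable")
    x = pd.to_numeric(df[variable], errors="coerce").dropna().to_numpy(dtype=float)
    if x.size == 0:
        return None
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])
    return SummaryRow(
        min=float(x.min()), q1=float(q1), median=float(med),
        mean=float(x.mean()), q3=float(q3), max=float(x.max()),
    )


def summarize_binary(df: pd.DataFrame, variable: str) -> BinarySummary:
    """Counts of 0/1 and their percentages of the non-missing total."""
    if variable not in BINARY_VARIABLES:
        raise ContractError(f"{variable!r} is not a binary variable")
    x = pd.to_numeric(df[variable], errors="coerce").dropna()
    n0 = int((x == 0).sum())
    n1 = int((x == 1).sum())
    total = n0 + n1
    pct0 = round(100.0 * n0 / total, 2) if total else 0.0
    pct1 = round(100.0 * n1 / total, 2) if total else 0.0
    return BinarySummary(n0=n0, pct0=pct0, n1=n1, pct1=pct1)


def summary_tables(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Descriptive tables for all numeric and all binary variables."""
    num_rows = {}
    for var in NUMERIC_VARIABLES:
        s = summarize_numeric(df, var)
        if s is not None:
            num_rows[var] = [s.min, s.q1, s.median, s.mean, s.q3, s.max]
    numeric = pd.DataFrame.from_dict(
        num_rows, orient="index", columns=["Min", "Q1", "Median", "Mean", "Q3", "Max"]
    )
    bin_rows = {}
    for var in BINARY_VARIABLES:
        b = summarize_binary(df, var)
        bin_rows[var] = [b.n0, b.pct0, b.n1, b.pct1]
    binary = pd.DataFrame.from_dict(
        bin_rows, orient="index", columns=["n0", "pct0", "n1", "pct1"]
    )
    return numeric, binary


def validate(
    clinical: pd.DataFrame | None = None, functional: pd.DataFrame | None = None
) -> list[Issue]:
    """Detect (never correct) invariant breaches in parsed records.

    Rules: LVEF within (0, 100]; time positive; binary variables coded
    0/1/missing; functional rows either complete (1001 finite values) or
    entirely absent.
    """
    issues: list[Issue] = []
    if clinical is not None:
        for row, lvef in clinical["LVEF"].items():
            if pd.notna(lvef) and not 0 < lvef <= 100:
                issues.append(Issue(int(row), "lvef_range", f"LVEF={lvef} outside (0, 100]"))
        for row, t in clinical["time"].items():
            if pd.notna(t) and t <= 0:
                issues.append(Issue(int(row), "time_positive", f"time={t} not positive"))
        for var in BINARY_VARIABLES:
            bad = clinical[var].dropna()
            for row, val in bad[~bad.isin([0, 1])].items():
                issues.append(
                    Issue(int(row), "binary_code", f"{var}={val} not in {{0, 1}}")
                )
    if functional is not None:
        grid_names = [f"t{i}" for i in range(1, N_GRID + 1)]
        vals = functional[grid_names]
        n_present = vals.notna().sum(axis=1)
        for row, n in n_present.items():
            if 0 < n < N_GRID:
                issues.append(
                    Issue(
                        int(row),
                        "functional_length",
                        f"functional part has {n} of {N_GRID} values",
                    )
                )
        for row, ctrcd in functional["CTRCD"].items():
            if pd.notna(ctrcd) and ctrcd not in (0, 1):
                issues.append(
                    Issue(int(row), "binary_code", f"CTRCD={ctrcd} not in {{0, 1}}")
                )
    return issues
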