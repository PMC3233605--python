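"""Readers and writers for the THIN-style CSV tables.

Schemas (all dates ISO-8601, empty string = missing where allowed):

* ``patients.csv``: patient_id,sex,birth_date,reg_start,reg_end,quality_date,townsend
* ``diagnoses.csv``: patient_id,date,code
* ``prescriptions.csv``: patient_id,date,drug_code
* ``codelists.csv``: condition,code

Rows that fail a type or invariant check are rejected individually and
reported as :class:`RowIssue` records; a bad row never aborts the read.
Missing files and missing columns do abort, naming the problem.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

PATIENT_COLUMNS = ["patient_id", "sex", "birth_date", "reg_start", "reg_end", "quality_date", "townsend"]
DIAGNOSIS_COLUMNS = ["patient_id", "date", "code"]
PRESCRIPTION_COLUMNS = ["patient_id", "date", "drug_code"]
CODELIST_COLUMNS = ["condition", "code"]

SEXES = {"male", "female"}


@dataclass
class RowIssue:
    """One rejected input row: where it was and why."""

    table: str
    row: int  # 0-based data-row index (header excluded)
    field: str
    value: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.table} row {self.row}: {self.field}={self.value!r}: {self.message}"


@dataclass
class ReadResult:
    """A typed table plus the rows rejected while reading it."""

    frame: pd.DataFrame
    rejected: list[RowIssue] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejected)


def _load_raw(path, columns: list[str], table: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{table} table not found: {path}")
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in raw.columns]
    if missing:
        raise ValueError(f"{table} table {path} missing required column(s): {', '.join(missing)}")
    return raw[columns]


def _parse_dates(raw: pd.DataFrame, col: str, table: str, required: bool,
                 issues: list[RowIssue], bad: np.ndarray) -> pd.Series:
    parsed = pd.to_datetime(raw[col], format="%Y-%m-%d", errors="coerce")
    empty = raw[col].str.strip() == ""
    invalid = parsed.isna() & ~empty
    if required:
        invalid = invalid | empty
    for i in np.flatnonzero(invalid.to_numpy() & ~bad):
        issues.append(RowIssue(table, int(i), col, raw[col].iat[i], "unparseable or missing date"))
    bad |= invalid.to_numpy()
    return parsed


def read_patients(path) -> ReadResult:
    """Read patients.csv into a typed frame.

    ``reg_end`` and ``quality_date`` may be empty (still registered /
    no quality cut); ``townsend`` may be empty (missing quintile).
    """
    raw = _load_raw(path, PATIENT_COLUMNS, "patients")
    issues: list[RowIssue] = []
    bad = np.zeros(len(raw), dtype=bool)

    birth = _parse_dates(raw, "birth_date", "patients", True, issues, bad)
    reg_start = _parse_dates(raw, "reg_start", "patients", True, issues, bad)
    reg_end = _parse_dates(raw, "reg_end", "patients", False, issues, bad)
    quality = _parse_dates(raw, "quality_date", "patients", False, issues, bad)

    sex = raw["sex"].str.strip().str.lower()
    bad_sex = ~sex.isin(SEXES)
    for i in np.flatnonzero(bad_sex.to_numpy() & ~bad):
        issues.append(RowIssue("patients", int(i), "sex", raw["sex"].iat[i], "sex must be male or female"))
    bad |= bad_sex.to_numpy()

    townsend = pd.to_numeric(raw["townsend"].replace("", np.nan), errors="coerce")
    bad_town = townsend.notna() & ~townsend.isin([1, 2, 3, 4, 5])
    bad_town |= (raw["townsend"].str.strip() != "") & townsend.isna()
    for i in np.flatnonzero(bad_town.to_numpy() & ~bad):
        issues.append(RowIssue("patients", int(i), "townsend", raw["townsend"].iat[i],
                               "townsend quintile must be 1..5 or empty"))
    bad |= bad_town.to_numpy()

    inverted = (reg_start.notna() & reg_end.notna() & (reg_start > reg_end)).to_numpy()
    for i in np.flatnonzero(inverted & ~bad):
        issues.append(RowIssue("patients", int(i), "reg_end", raw["reg_end"].iat[i],
                               "registration end precedes registration start"))
    bad |= inverted

    frame = pd.DataFrame({
        "patient_id": raw["patient_id"],
        "sex": sex,
        "birth_date": birth,
        "reg_start": reg_start,
        "reg_end": reg_end,
        "quality_date": quality,
        "townsend": townsend,
    })[~bad].reset_index(drop=True)
    log.info("patients: %d rows read, %d rejected", len(frame), int(bad.sum()))
    return ReadResult(frame, issues)


def _read_events(path, columns: list[str], table: str) -> ReadResult:
    raw = _load_raw(path, columns, table)
    issues: list[RowIssue] = []
    bad = np.zeros(len(raw), dtype=bool)
    date = _parse_dates(raw, columns[1], table, True, issues, bad)
    frame = pd.DataFrame({
        "patient_id": raw["patient_id"],
        columns[1]: date,
        columns[2]: raw[columns[2]].str.strip(),
    })[~bad].reset_index(drop=True)
    log.info("%s: %d rows read, %d rejected", table, len(frame), int(bad.sum()))
    return ReadResult(frame, issues)


def read_diagnoses(path) -> ReadResult:
    """Read diagnoses.csv (patient_id, date, code)."""
    return _read_events(path, DIAGNOSIS_COLUMNS, "diagnoses")


def read_prescriptions(path) -> ReadResult:
    """Read prescriptions.csv (patient_id, date, drug_code)."""
    return _read_events(path, PRESCRIPTION_COLUMNS, "prescriptions")


def read_codelists(path) -> dict[str, set[str]]:
    """Read codelists.csv into {condition: set of codes}.

    Duplicate codes within one condition raise, per the uniqueness invariant.
    """
    raw = _load_raw(path, CODELIST_COLUMNS, "codelists")
    out: dict[str, set[str]] = {}
    for cond, grp in raw.groupby("condition"):
        codes = grp["code"].str.strip()
        if codes.duplicated().any():
            dup = codes[codes.duplicated()].iloc[0]
            raise ValueError(f"codelist {cond!r} contains duplicate code {dup!r}")
        out[str(cond)] = set(codes)
    return out


# -- writers ------------------------------------------------------------------

def _date_str(s: pd.Series) -> pd.Series:
    return s.dt.strftime("%Y-%m-%d").fillna("")


def write_patients(frame: pd.DataFrame, path) -> None:
    out = pd.DataFrame({
        "patient_id": frame["patient_id"],
        "sex": frame["sex"],
        "birth_date": _date_str(frame["birth_date"]),
        "reg_start": _date_str(frame["reg_start"]),
        "reg_end": _date_str(frame["reg_end"]),
        "quality_date": _date_str(frame["quality_date"]),
        "townsend": frame["townsend"].map(lambda v: "" if pd.isna(v) else str(int(v))),
    })
    out.to_csv(path, index=False)


def write_events(frame: pd.DataFrame, path, date_col: str, code_col: str) -> None:
    out = pd.DataFrame({
        "patient_id": frame["patient_id"],
        date_col: _date_str(frame[date_col]),
        code_col: frame[code_col],
    })
    out.to_csv(path, index=False)


def write_diagnoses(frame: pd.DataFrame, path) -> None:
    write_events(frame, path, "date", "code")


def write_prescriptions(frame: pd.DataFrame, path) -> None:
    write_events(frame, path, "date", "drug_code")


def write_codelists(codelists: dict[str, set[str]], path) -> None:
    rows = [(cond, code) for cond in sorted(codelists) for code in sorted(codelists[cond])]
    pd.DataFrame(rows, columns=CODELIST_COLUMNS).to_csv(path, index=False)
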