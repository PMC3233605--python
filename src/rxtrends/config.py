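"""Study configuration.

All analysis parameters live in a single :class:`StudyConfig` object so that
every convention (gap threshold, forward coverage of a script, age bands,
denominators) is explicit and auditable.  Dates written in input/output CSVs
are inclusive calendar dates; internally every interval is half-open
``[start, end)`` with the exclusive end being the inclusive end plus one day.
"""

from __future__ import annotations

import datetime as dt
from typing import Literal, Sequence

import yaml
from pydantic import BaseModel, Field, model_validator

ONE_DAY = dt.timedelta(days=1)


class StudyConfig(BaseModel):
    """Parameters governing cohort construction and all downstream analyses.

    Parameters
    ----------
    study_start, study_end
        Inclusive calendar bounds of the analysis window.  Defaults cover
        1995-01-01 through 2009-12-31.
    gap_days
        A gap of at least this many days between consecutive prescription
        issue dates ends a treatment session.  Default 91 (~3 months /
        13 weeks); the threshold itself, not the day count, is the
        convention-bearing choice.
    coverage_days
        Days of treatment a prescription is assumed to cover forward from
        its issue date; a session extends this far past its last script
        (truncated at follow-up end).  Default 28, the modal UK repeat
        prescription length.  Zero reproduces a strict last-script-date
        session end.
    age_bands
        Inclusive ``[low, high]`` age bands used for stratified reporting.
        Person-time of patients outside every band is kept in the overall
        analysis and reported under an ``outside-bands`` label.
    childbearing_age
        Inclusive age band defining women of childbearing age.
    min_prescriptions_treated
        Scripts (of any classified psychotropic) within follow-up required
        for a patient to count as treated.
    follow_up_from_diagnosis
        If True, follow-up additionally starts no earlier than the first
        in-window bipolar diagnosis (incident-style cohort).  Default False:
        prevalent-cohort person-time independent of diagnosis date.
    denominator
        ``"all"`` pools person-time over every eligible cohort member;
        ``"treated_only"`` restricts to treated members.
    proportion_method
        ``"pooled"`` divides summed covered days by summed follow-up days;
        ``"patient_mean"`` averages per-patient proportions (sensitivity
        variant).
    multi_drug_level
        Granularity at which "two or more psychotropics" is counted:
        ``"generic"`` (distinct generic drugs, default) or ``"class"``.
    birth_imputation_monthday
        Month-day imputed when a source supplies year of birth only.
    """

    study_start: dt.date = dt.date(1995, 1, 1)
    study_end: dt.date = dt.date(2009, 12, 31)
    gap_days: int = Field(default=91, gt=0)
    coverage_days: int = Field(default=28, ge=0)
    age_bands: list[tuple[int, int]] = Field(
        default_factory=lambda: [(18, 29), (30, 44), (45, 59), (60, 75)]
    )
    childbearing_age: tuple[int, int] = (18, 45)
    min_prescriptions_treated: int = Field(default=2, ge=1)
    follow_up_from_diagnosis: bool = False
    denominator: Literal["all", "treated_only"] = "all"
    proportion_method: Literal["pooled", "patient_mean"] = "pooled"
    multi_drug_level: Literal["generic", "class"] = "generic"
    birth_imputation_monthday: str = "07-01"

    @model_validator(mode="after")
    def _check(self) -> "StudyConfig":
        if self.study_start >= self.study_end:
            raise ValueError("study_start must precede study_end")
        prev_high = None
        for low, high in self.age_bands:
            if low > high:
                raise ValueError(f"age band [{low},{high}] is inverted")
            if prev_high is not None and low <= prev_high:
                raise ValueError("age bands must be ascending and non-overlapping")
            prev_high = high
        lo, hi = self.childbearing_age
        if lo > hi:
            raise ValueError("childbearing_age band is inverted")
        mm, dd = self.birth_imputation_monthday.split("-")
        dt.date(2001, int(mm), int(dd))  # validates the month-day
        return self

    # -- derived conveniences -------------------------------------------------

    @property
    def study_end_exclusive(self) -> dt.date:
        """Exclusive end of the study window (study_end + 1 day)."""
        return self.study_end + ONE_DAY

    def years(self) -> list[int]:
        """Calendar years wholly or partly inside the study window."""
        return list(range(self.study_start.year, self.study_end.year + 1))

    # -- (de)serialisation ----------------------------------------------------

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = self.model_dump(mode="json")
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def year_interval(year: int) -> tuple[dt.date, dt.date]:
    """Half-open [Jan 1, next Jan 1) interval of a calendar year."""
    return dt.date(year, 1, 1), dt.date(year + 1, 1, 1)
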