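"""Cohort eligibility, follow-up windows and the treated/untreated split.

Eligibility: at least one bipolar-disorder diagnosis code dated inside the
study window, no epilepsy code at any date (anticonvulsants double as mood
stabilisers, so epileptic patients would contaminate the exposure), and the
patient reaches age 18 before follow-up ends.  Follow-up is the half-open
intersection of the study window, the registration window, the period after
the practice's data-quality date, and adulthood.  A patient is *treated* if
at least ``min_prescriptions_treated`` classified psychotropic scripts fall
inside follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import StudyConfig
from .drugs import UNCLASSIFIED, DrugDictionary

REASON_NO_BIPOLAR = "no bipolar diagnosis in study window"
REASON_EPILEPSY = "epilepsy diagnosis"
REASON_UNDER_18 = "under 18 throughout follow-up"
REASON_NO_FOLLOW_UP = "empty follow-up window"

MEMBER_COLUMNS = [
    "patient_id", "sex", "birth_date", "townsend",
    "fu_start", "fu_end", "first_bipolar_date", "treated", "n_classified_scripts",
]


@dataclass
class CohortResult:
    """Eligible members with follow-up windows, plus exclusion bookkeeping."""

    members: pd.DataFrame          # one row per eligible member (MEMBER_COLUMNS)
    exclusions: pd.DataFrame       # patient_id, reason
    attrition: dict[str, int] = field(default_factory=dict)
    n_unclassified_scripts: int = 0


def _eighteenth_birthday(birth: pd.Series) -> pd.Series:
    # vectorised; Feb 29 births roll to Mar 1 in non-leap years via DateOffset
    return birth + pd.DateOffset(years=18)


def eligible(patient: pd.Series, diagnoses: pd.DataFrame,
             bipolar_codes: set[str], epilepsy_codes: set[str],
             config: StudyConfig) -> tuple[bool, str | None]:
    """Single-patient eligibility check; returns (is_eligible, reason).

    ``diagnoses`` holds that patient's diagnosis events.  Epilepsy codes at
    ANY date exclude; bipolar codes must fall inside the study window.
    """
    start = pd.Timestamp(config.study_start)
    end = pd.Timestamp(config.study_end_exclusive)
    is_bip = diagnoses["code"].isin(bipolar_codes)
    in_window = is_bip & (diagnoses["date"] >= start) & (diagnoses["date"] < end)
    if not in_window.any():
        return False, REASON_NO_BIPOLAR
    if diagnoses["code"].isin(epilepsy_codes).any():
        return False, REASON_EPILEPSY
    adult = patient["birth_date"] + pd.DateOffset(years=18)
    fu_end = min(end, patient["reg_end"] + pd.Timedelta(days=1)) \
        if pd.notna(patient.get("reg_end")) else end
    if adult >= fu_end:
        return False, REASON_UNDER_18
    return True, None


def follow_up_window(patient: pd.Series, config: StudyConfig,
                     first_bipolar: pd.Timestamp | None = None
                     ) -> tuple[pd.Timestamp, pd.Timestamp] | None:
    """Half-open observable window for one patient, or None if empty.

    start = max(study start, registration start, practice quality date,
    18th birthday [, first in-window bipolar diagnosis if configured]);
    end = min(study end + 1 day, registration end + 1 day).
    """
    starts = [pd.Timestamp(config.study_start), patient["birth_date"] + pd.DateOffset(years=18)]
    for key in ("reg_start", "quality_date"):
        if pd.notna(patient.get(key)):
            starts.append(patient[key])
    if config.follow_up_from_diagnosis and first_bipolar is not None:
        starts.append(first_bipolar)
    start = max(starts)
    end = pd.Timestamp(config.study_end_exclusive)
    if pd.notna(patient.get("reg_end")):
        end = min(end, patient["reg_end"] + pd.Timedelta(days=1))
    if start >= end:
        return None
    return start, end


def flag_treated(n_classified_in_window: int, config: StudyConfig) -> bool:
    return n_classified_in_window >= config.min_prescriptions_treated


def build_cohort(patients: pd.DataFrame, diagnoses: pd.DataFrame,
                 prescriptions: pd.DataFrame, dictionary: DrugDictionary,
                 codelists: dict[str, set[str]], config: StudyConfig) -> CohortResult:
    """Apply eligibility + window construction to the whole patient table."""
    bipolar_codes = codelists.get("bipolar", set())
    epilepsy_codes = codelists.get("epilepsy", set())
    start = pd.Timestamp(config.study_start)
    end = pd.Timestamp(config.study_end_exclusive)

    pts = patients.reset_index(drop=True).copy()
    attrition: dict[str, int] = {"patients_read": len(pts)}

    dx = diagnoses[diagnoses["patient_id"].isin(pts["patient_id"])]
    bip = dx[dx["code"].isin(bipolar_codes) & (dx["date"] >= start) & (dx["date"] < end)]
    first_bip = bip.groupby("patient_id")["date"].min()
    epi_ids = set(dx.loc[dx["code"].isin(epilepsy_codes), "patient_id"])

    pts["first_bipolar_date"] = pts["patient_id"].map(first_bip)
    pts["adult_date"] = _eighteenth_birthday(pts["birth_date"])
    reg_end_excl = pts["reg_end"] + pd.Timedelta(days=1)
    pts["fu_end"] = reg_end_excl.fillna(end).clip(upper=end)

    start_parts = [pd.Series(start, index=pts.index), pts["adult_date"],
                   pts["reg_start"].fillna(start), pts["quality_date"].fillna(start)]
    if config.follow_up_from_diagnosis:
        start_parts.append(pts["first_bipolar_date"].fillna(start))
    pts["fu_start"] = pd.concat(start_parts, axis=1).max(axis=1)

    reason = pd.Series(pd.NA, index=pts.index, dtype=object)
    reason[pts["adult_date"] >= pts["fu_end"]] = REASON_UNDER_18
    reason[(pts["fu_start"] >= pts["fu_end"]) & reason.isna()] = REASON_NO_FOLLOW_UP
    reason[pts["patient_id"].isin(epi_ids)] = REASON_EPILEPSY
    reason[pts["first_bipolar_date"].isna()] = REASON_NO_BIPOLAR

    excluded = pts[reason.notna()]
    exclusions = pd.DataFrame({
        "patient_id": excluded["patient_id"],
        "reason": reason[reason.notna()],
    }).reset_index(drop=True)
    for r in (REASON_NO_BIPOLAR, REASON_EPILEPSY, REASON_UNDER_18, REASON_NO_FOLLOW_UP):
        attrition[r] = int((exclusions["reason"] == r).sum())

    members = pts[reason.isna()].reset_index(drop=True)
    attrition["eligible"] = len(members)

    # treated flag: classified scripts inside the member's follow-up window
    rx = dictionary.classify_frame(
        prescriptions[prescriptions["patient_id"].isin(members["patient_id"])]
    )
    n_unclassified = int((rx["generic_name"] == UNCLASSIFIED).sum())
    rx = rx[rx["generic_name"] != UNCLASSIFIED]
    rx = rx.merge(members[["patient_id", "fu_start", "fu_end"]], on="patient_id")
    rx = rx[(rx["date"] >= rx["fu_start"]) & (rx["date"] < rx["fu_end"])]
    counts = rx.groupby("patient_id").size()
    members["n_classified_scripts"] = members["patient_id"].map(counts).fillna(0).astype(int)
    members["treated"] = members["n_classified_scripts"] >= config.min_prescriptions_treated
    attrition["treated"] = int(members["treated"].sum())
    attrition["untreated"] = int((~members["treated"]).sum())

    return CohortResult(
        members=members[MEMBER_COLUMNS],
        exclusions=exclusions,
        attrition=attrition,
        n_unclassified_scripts=n_unclassified,
    )


def in_window_prescriptions(prescriptions: pd.DataFrame, dictionary: DrugDictionary,
                            cohort: pd.DataFrame) -> pd.DataFrame:
    """Classified scripts of cohort members restricted to follow-up windows.

    Returns one row per script with generic/class/group columns attached;
    unclassified codes are excluded.
    """
    rx = dictionary.classify_frame(
        prescriptions[prescriptions["patient_id"].isin(cohort["patient_id"])]
    )
    rx = rx[rx["generic_name"] != UNCLASSIFIED]
    rx = rx.merge(cohort[["patient_id", "fu_start", "fu_end"]], on="patient_id")
    rx = rx[(rx["date"] >= rx["fu_start"]) & (rx["date"] < rx["fu_end"])]
    return rx.drop(columns=["fu_start", "fu_end"]).reset_index(drop=True)


def demographics_summary(cohort: pd.DataFrame) -> pd.DataFrame:
    """Treated-vs-untreated demographic table.

    Age is taken at follow-up start; follow-up years = window days / 365.25.
    Degenerate (empty) strata yield NaN statistics rather than errors.
    """
    rows = {}
    for label, grp in (("treated", cohort[cohort["treated"]]),
                       ("untreated", cohort[~cohort["treated"]])):
        n = len(grp)
        col: dict[str, float] = {"n": n}
        if n:
            col["pct_male"] = 100.0 * (grp["sex"] == "male").mean()
            age = (grp["fu_start"] - grp["birth_date"]).dt.days / 365.25
            col["mean_age"] = age.mean()
            col["sd_age"] = age.std(ddof=1) if n > 1 else np.nan
            fy = (grp["fu_end"] - grp["fu_start"]).dt.days / 365.25
            col["median_follow_up_years"] = fy.median()
            col["follow_up_iqr_low"] = fy.quantile(0.25)
            col["follow_up_iqr_high"] = fy.quantile(0.75)
            known = grp["townsend"].notna().sum()
            for q in range(1, 6):
                nq = int((grp["townsend"] == q).sum())
                col[f"townsend_{q}_n"] = nq
                col[f"townsend_{q}_pct"] = 100.0 * nq / known if known else np.nan
            col["townsend_missing_n"] = int(n - known)
        else:
            for key in ("pct_male", "mean_age", "sd_age", "median_follow_up_years",
                        "follow_up_iqr_low", "follow_up_iqr_high"):
                col[key] = np.nan
            for q in range(1, 6):
                col[f"townsend_{q}_n"] = 0
                col[f"townsend_{q}_pct"] = np.nan
            col["townsend_missing_n"] = 0
        rows[label] = col
    return pd.DataFrame(rows)
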