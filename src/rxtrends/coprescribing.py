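"""Yearly co-prescribing: multi-drug counts, set overlaps and time shares.

A patient is "on" a generic drug in a calendar year if they were issued at
least two prescriptions of it that year (the same intention-to-treat
threshold used for the treated flag).  Membership of the lithium /
anticonvulsant / antipsychotic sets derives from the drugs a patient is on,
and the three-set overlap is reported as the seven disjoint Euler regions
plus the pairwise (inclusive) combination counts.  Counts are
prescription-based: no temporal overlap of sessions is required.  The
time-share analysis, being time-based, instead requires at least one day of
concurrent sessions of both components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import StudyConfig, year_interval
from .drugs import HierarchyUnit
from .persontime import round_half_up

SETS = ("lithium", "anticonvulsant", "antipsychotic")

REGIONS = (
    "lithium_only", "anticonvulsant_only", "antipsychotic_only",
    "lithium+anticonvulsant", "lithium+antipsychotic",
    "anticonvulsant+antipsychotic", "lithium+anticonvulsant+antipsychotic",
)

COMBINATIONS = (
    ("lithium", "antipsychotic"),
    ("anticonvulsant", "antipsychotic"),
    ("lithium", "anticonvulsant"),
)


@dataclass
class CoPrescribingSummary:
    year: int
    n_treated: int                       # >=2 scripts of >=1 psychotropic
    n_multi: int                         # >=2 scripts of >=2 distinct drugs
    combinations: dict[str, int] = field(default_factory=dict)  # inclusive pair counts
    regions: dict[str, int] = field(default_factory=dict)       # 7 disjoint regions


def drugs_on(prescriptions: pd.DataFrame, year: int, config: StudyConfig,
             threshold: int | None = None) -> pd.DataFrame:
    """Per (patient, generic) script counts for the year, with class columns.

    Only rows meeting the per-drug threshold (default
    ``min_prescriptions_treated``) are returned.
    """
    threshold = threshold or config.min_prescriptions_treated
    y0, y1 = (pd.Timestamp(d) for d in year_interval(year))
    rx = prescriptions[(prescriptions["date"] >= y0) & (prescriptions["date"] < y1)]
    counts = (rx.groupby(["patient_id", "generic_name", "level2_class", "level1_group"])
              .size().reset_index(name="n_scripts"))
    return counts[counts["n_scripts"] >= threshold].reset_index(drop=True)


def multi_drug_counts(cohort: pd.DataFrame, prescriptions: pd.DataFrame, year: int,
                      config: StudyConfig, threshold: int | None = None
                      ) -> CoPrescribingSummary:
    """Yearly multi-drug summary for the cohort.

    ``prescriptions`` must be classified and window-restricted.  n_treated
    uses total classified scripts (any mix of drugs); n_multi and the set
    counts use the per-drug threshold.
    """
    threshold = threshold or config.min_prescriptions_treated
    y0, y1 = (pd.Timestamp(d) for d in year_interval(year))
    rx = prescriptions[prescriptions["patient_id"].isin(cohort["patient_id"])
                       & (prescriptions["date"] >= y0) & (prescriptions["date"] < y1)]
    total = rx.groupby("patient_id").size()
    n_treated = int((total >= threshold).sum())

    on = drugs_on(rx, year, config, threshold)
    if config.multi_drug_level == "class":
        per_patient = on.groupby("patient_id")["level2_class"].nunique()
    else:
        per_patient = on.groupby("patient_id")["generic_name"].nunique()
    n_multi = int((per_patient >= 2).sum())

    membership: dict[str, set[str]] = {
        "lithium": set(on.loc[on["level2_class"] == "lithium", "patient_id"]),
        "anticonvulsant": set(on.loc[on["level2_class"] == "anticonvulsant", "patient_id"]),
        "antipsychotic": set(on.loc[on["level1_group"] == "antipsychotic", "patient_id"]),
    }
    combos = {f"{a}+{b}": len(membership[a] & membership[b]) for a, b in COMBINATIONS}

    li, ac, ap = (membership[s] for s in SETS)
    regions = {
        "lithium_only": len(li - ac - ap),
        "anticonvulsant_only": len(ac - li - ap),
        "antipsychotic_only": len(ap - li - ac),
        "lithium+anticonvulsant": len((li & ac) - ap),
        "lithium+antipsychotic": len((li & ap) - ac),
        "anticonvulsant+antipsychotic": len((ac & ap) - li),
        "lithium+anticonvulsant+antipsychotic": len(li & ac & ap),
    }
    return CoPrescribingSummary(year, n_treated, n_multi, combos, regions)


def multi_drug_percent(summary: CoPrescribingSummary) -> float:
    """Percent of the year's treated patients on two or more drugs (1 dp)."""
    if summary.n_treated == 0:
        return float("nan")
    return round_half_up(100.0 * summary.n_multi / summary.n_treated)


def summary_table(cohort: pd.DataFrame, prescriptions: pd.DataFrame,
                  config: StudyConfig) -> pd.DataFrame:
    """One row per study year: treated/multi counts, percent, regions, pairs."""
    rows = []
    for year in config.years():
        s = multi_drug_counts(cohort, prescriptions, year, config)
        row = {"year": year, "n_treated": s.n_treated, "n_multi": s.n_multi,
               "pct_multi": multi_drug_percent(s)}
        row.update({f"pair_{k}": v for k, v in s.combinations.items()})
        row.update({f"region_{k}": v for k, v in s.regions.items()})
        rows.append(row)
    return pd.DataFrame(rows)


# -- time shares for co-treated patients --------------------------------------

COMPONENT_UNITS = {
    "antipsychotic": HierarchyUnit(1, "antipsychotic"),
    "mood_stabiliser": HierarchyUnit(1, "mood_stabiliser"),
    "FGA": HierarchyUnit(2, "FGA"),
    "SGA": HierarchyUnit(2, "SGA"),
    "lithium": HierarchyUnit(2, "lithium"),
    "anticonvulsant": HierarchyUnit(2, "anticonvulsant"),
}


def component_unit(label: str) -> HierarchyUnit:
    """Map a combination component name to its hierarchy unit (L3 fallback)."""
    return COMPONENT_UNITS.get(label, HierarchyUnit(3, label))


@dataclass
class CoTreatmentTimeShare:
    combination: tuple[str, str]
    n_patients: int
    mean_share: dict[str, float]  # component -> mean proportion of follow-up


def _unit_sessions(sessions: pd.DataFrame, unit: HierarchyUnit) -> pd.DataFrame:
    return sessions[(sessions["level"] == unit.level) & (sessions["label"] == unit.label)]


def _intervals_overlap(a: pd.DataFrame, b: pd.DataFrame, lo, hi) -> bool:
    for sa, ea in zip(a["start"], a["end"]):
        sa, ea = max(sa, lo), min(ea, hi)
        if sa >= ea:
            continue
        for sb, eb in zip(b["start"], b["end"]):
            if max(sa, sb) < min(ea, eb):
                return True
    return False


def time_share(cohort: pd.DataFrame, sessions: pd.DataFrame,
               combination: tuple[str, str], period: tuple,
               config: StudyConfig) -> CoTreatmentTimeShare:
    """Mean per-patient share of follow-up spent on each component.

    Patients qualify if, within ``period`` intersected with their follow-up,
    sessions of both components overlap for at least one day.  For each
    qualifying patient the component share is covered days / follow-up days
    over that same interval; the summary is the mean across patients.
    """
    lo, hi = pd.Timestamp(period[0]), pd.Timestamp(period[1])
    ua, ub = (component_unit(c) for c in combination)
    sa_all, sb_all = _unit_sessions(sessions, ua), _unit_sessions(sessions, ub)
    qualifying = []
    shares_a, shares_b = [], []
    idx = cohort.set_index("patient_id")
    candidates = set(sa_all["patient_id"]) & set(sb_all["patient_id"])
    for pid in sorted(candidates):
        w0, w1 = max(idx.at[pid, "fu_start"], lo), min(idx.at[pid, "fu_end"], hi)
        if w0 >= w1:
            continue
        sa = sa_all[sa_all["patient_id"] == pid]
        sb = sb_all[sb_all["patient_id"] == pid]
        if not _intervals_overlap(sa, sb, w0, w1):
            continue
        fu_days = (w1 - w0).days
        for s, acc in ((sa, shares_a), (sb, shares_b)):
            d = (s["end"].clip(upper=w1) - s["start"].clip(lower=w0)).dt.days
            acc.append(int(d[d > 0].sum()) / fu_days)
        qualifying.append(pid)
    if not qualifying:
        return CoTreatmentTimeShare(combination, 0, {})
    return CoTreatmentTimeShare(
        combination, len(qualifying),
        {combination[0]: float(np.mean(shares_a)),
         combination[1]: float(np.mean(shares_b))})
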