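"""Treatment-session (drug-era) construction under the gap rule.

A treatment session is a maximal period of continuous prescribing of one
hierarchy unit for one patient: consecutive prescription issue dates less
than ``gap_days`` apart belong to the same session, and a gap of
``gap_days`` or more starts a new one.  A session runs from its first
script to ``coverage_days`` past its last script, truncated at the
follow-up end (a script covers forward time; 28 days is the modal UK
repeat length).  Scripts are projected onto every hierarchy unit they
belong to before sessionization, so a quetiapine script feeds
L3:quetiapine, L2:SGA and L1:antipsychotic.

All interval arithmetic is half-open; sessions of one (patient, unit) are
pairwise disjoint by construction because between-session gaps (>= gap_days)
exceed the forward coverage whenever coverage_days < gap_days.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import StudyConfig
from .drugs import DrugDictionary, HierarchyUnit

SESSION_COLUMNS = ["patient_id", "level", "label", "start", "end", "n_prescriptions"]


@dataclass(frozen=True)
class TreatmentSession:
    patient_id: str
    unit: HierarchyUnit
    start: pd.Timestamp          # first prescription of the session
    end: pd.Timestamp            # exclusive: last script + coverage, truncated
    n_prescriptions: int


def build_sessions(dates, window: tuple, config: StudyConfig,
                   patient_id: str = "", unit: HierarchyUnit | None = None
                   ) -> list[TreatmentSession]:
    """Partition one sorted prescription-date stream into sessions.

    ``dates`` may contain same-day duplicates; duplicates collapse for the
    continuity test but still count toward ``n_prescriptions``.  Dates must
    lie inside ``window`` (half-open).  Empty input returns an empty list.
    """
    dates = pd.to_datetime(pd.Series(list(dates)))
    if dates.empty:
        return []
    if not dates.is_monotonic_increasing:
        raise ValueError("prescription dates must be sorted ascending")
    win_start, win_end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    if (dates.iloc[0] < win_start) or (dates.iloc[-1] >= win_end):
        raise ValueError("prescription dates must fall inside the follow-up window")

    days = dates.astype("int64") // 86_400_000_000_000  # ns -> epoch days
    starts, ends, counts = _sessionize_days(
        days.to_numpy(), (win_end - pd.Timestamp(0)).days,
        config.gap_days, config.coverage_days,
    )
    unit = unit or HierarchyUnit(3, "")
    epoch = pd.Timestamp(0)
    return [
        TreatmentSession(patient_id, unit,
                         epoch + pd.Timedelta(days=int(s)),
                         epoch + pd.Timedelta(days=int(e)), int(n))
        for s, e, n in zip(starts, ends, counts)
    ]


def _sessionize_days(days: np.ndarray, win_end_day: int, gap_days: int,
                     coverage_days: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Core greedy partition on integer epoch days (may contain duplicates)."""
    uniq, dup_counts = np.unique(days, return_counts=True)
    breaks = np.flatnonzero(np.diff(uniq) >= gap_days)
    first = np.concatenate(([0], breaks + 1))
    last = np.concatenate((breaks, [len(uniq) - 1]))
    starts = uniq[first]
    ends = np.minimum(uniq[last] + coverage_days, win_end_day)
    csum = np.concatenate(([0], np.cumsum(dup_counts)))
    counts = csum[last + 1] - csum[first]
    return starts, ends, counts


def sessions_for_all_units(prescriptions: pd.DataFrame, dictionary: DrugDictionary,
                           cohort: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    """Build sessions for every (patient, hierarchy unit) as one long frame.

    ``prescriptions`` must already be classified and restricted to follow-up
    windows (see :func:`rxtrends.cohort.in_window_prescriptions`).  Returns a
    frame with SESSION_COLUMNS; ``end`` is exclusive.
    """
    if prescriptions.empty:
        empty = pd.DataFrame(columns=SESSION_COLUMNS)
        empty["start"] = pd.to_datetime(empty["start"])
        empty["end"] = pd.to_datetime(empty["end"])
        return empty
    proj = pd.concat([
        prescriptions.assign(level=1, label=prescriptions["level1_group"]),
        prescriptions.assign(level=2, label=prescriptions["level2_class"]),
        prescriptions.assign(level=3, label=prescriptions["generic_name"]),
    ], ignore_index=True)[["patient_id", "date", "level", "label"]]

    windows = cohort.set_index("patient_id")[["fu_start", "fu_end"]]
    rows = []
    for (pid, level, label), grp in proj.groupby(["patient_id", "level", "label"], sort=True):
        win_end_day = (windows.at[pid, "fu_end"] - pd.Timestamp(0)).days
        days = np.sort(grp["date"].astype("int64").to_numpy() // 86_400_000_000_000)
        starts, ends, counts = _sessionize_days(days, win_end_day,
                                                config.gap_days, config.coverage_days)
        for s, e, n in zip(starts, ends, counts):
            rows.append((pid, level, label, int(s), int(e), int(n)))
    out = pd.DataFrame(rows, columns=SESSION_COLUMNS)
    out["start"] = pd.Timestamp(0) + pd.to_timedelta(out["start"], unit="D")
    out["end"] = pd.Timestamp(0) + pd.to_timedelta(out["end"], unit="D")
    return out


def covered_days(sessions: pd.DataFrame, interval: tuple) -> int:
    """Person-days of ``interval`` covered by the union of the sessions.

    Sessions must belong to a single (patient, unit) — they are disjoint by
    construction, so summing overlaps never double counts.
    """
    if len(sessions) == 0:
        return 0
    lo, hi = pd.Timestamp(interval[0]), pd.Timestamp(interval[1])
    start = sessions["start"].clip(lower=lo)
    end = sessions["end"].clip(upper=hi)
    d = (end - start).dt.days
    return int(d[d > 0].sum())
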