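"""Shared test utilities: independent oracles and small data builders."""

from __future__ import annotations

import pandas as pd

from rxtrends.drugs import DrugDictionary

EPOCH = pd.Timestamp(0)

# generic -> (level2_class); level1 derives from the class
GENERICS = {
    "lithium": "lithium",
    "valproate": "anticonvulsant",
    "carbamazepine": "anticonvulsant",
    "lamotrigine": "anticonvulsant",
    "olanzapine": "SGA",
    "quetiapine": "SGA",
    "haloperidol": "FGA",
    "chlorpromazine": "FGA",
}
GROUP_OF = {"FGA": "antipsychotic", "SGA": "antipsychotic",
            "anticonvulsant": "mood_stabiliser", "lithium": "mood_stabiliser"}


def tiny_dictionary() -> DrugDictionary:
    rows = [(f"C-{g.upper()[:5]}", g, c) for g, c in GENERICS.items()]
    return DrugDictionary(pd.DataFrame(rows, columns=["drug_code", "generic_name",
                                                      "level2_class"]))


def oracle_day_runs(script_days, win_end_day, gap_days, coverage_days):
    """Brute-force day-grid session oracle, independent of the package.

    A day is covered iff it lies within coverage_days after a script or
    between two scripts fewer than gap_days apart; sessions are the maximal
    covered runs, each annotated with the scripts it contains.
    Returns a list of (start_day, end_day_exclusive, n_scripts).
    """
    days = sorted(script_days)
    if not days:
        return []
    covered = set()
    for d in set(days):
        for t in range(d, min(d + coverage_days, win_end_day)):
            covered.add(t)
    uniq = sorted(set(days))
    for a, b in zip(uniq[:-1], uniq[1:]):
        if b - a < gap_days:
            for t in range(a, b):
                covered.add(t)
    runs = []
    for t in sorted(covered):
        if runs and t == runs[-1][1]:
            runs[-1][1] = t + 1
        else:
            runs.append([t, t + 1])
    out = []
    for lo, hi in runs:
        n = sum(1 for d in days if lo <= d < hi)
        out.append((lo, hi, n))
    return out


def member(pid, sex="female", birth="1960-07-01", fu_start="1995-01-01",
           fu_end="2010-01-01", treated=True, townsend=3.0,
           first_bipolar="1995-06-01", n_scripts=2):
    return {
        "patient_id": pid, "sex": sex, "birth_date": pd.Timestamp(birth),
        "townsend": townsend, "fu_start": pd.Timestamp(fu_start),
        "fu_end": pd.Timestamp(fu_end), "first_bipolar_date": pd.Timestamp(first_bipolar),
        "treated": treated, "n_classified_scripts": n_scripts,
    }


def cohort_frame(members) -> pd.DataFrame:
    return pd.DataFrame(list(members))


def rx_frame(rows) -> pd.DataFrame:
    """rows: (patient_id, date, generic) -> classified prescriptions frame."""
    cols = ["patient_id", "date", "drug_code", "generic_name",
            "level2_class", "level1_group"]
    recs = []
    for pid, date, generic in rows:
        cls = GENERICS[generic]
        recs.append({"patient_id": pid, "date": pd.Timestamp(date),
                     "drug_code": f"C-{generic.upper()[:5]}", "generic_name": generic,
                     "level2_class": cls, "level1_group": GROUP_OF[cls]})
    if not recs:
        df = pd.DataFrame(columns=cols)
        df["date"] = pd.to_datetime(df["date"])
        return df
    return pd.DataFrame(recs)


def session_frame(rows) -> pd.DataFrame:
    """rows: (patient_id, level, label, start, end, n) -> sessions frame."""
    df = pd.DataFrame(rows, columns=["patient_id", "level", "label",
                                     "start", "end", "n_prescriptions"])
    df["start"] = pd.to_datetime(df["start"])
    df["end"] = pd.to_datetime(df["end"])
    return df
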