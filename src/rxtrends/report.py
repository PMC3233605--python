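"""End-to-end orchestration: cohort -> sessions -> trends -> co-prescribing.

``run_all`` reads the five input CSVs from one directory, runs every stage,
and writes the full artifact set: table1.csv, table2.csv, proportions.csv,
coprescribing.csv, percent_treated.csv, sessions.csv, cohort.csv,
headline.json, attrition.log and run_metadata.json.  All outputs are plain
CSV/JSON; identical inputs and configuration produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__, io as rio
from .cohort import CohortResult, build_cohort, demographics_summary, in_window_prescriptions
from .config import StudyConfig
from .coprescribing import summary_table, time_share
from .drugs import DrugDictionary, HierarchyUnit
from .persontime import (childbearing_valproate, mean_annual_change, proportion_table,
                         percent_treated_series, round_half_up, trend_table)
from .sessions import sessions_for_all_units

log = logging.getLogger(__name__)

INPUT_FILES = ("patients.csv", "diagnoses.csv", "prescriptions.csv",
               "drug_dictionary.csv", "codelists.csv")


@dataclass
class PipelineResult:
    cohort: CohortResult
    sessions: pd.DataFrame
    proportions: pd.DataFrame
    percent_treated: pd.DataFrame
    table1: pd.DataFrame
    table2: pd.DataFrame
    coprescribing: pd.DataFrame
    headline: dict


def run_pipeline(input_dir, config: StudyConfig) -> PipelineResult:
    """Run every stage in memory; raises with the stage name on failure."""
    input_dir = Path(input_dir)
    stage = "read"
    try:
        patients = rio.read_patients(input_dir / "patients.csv")
        diagnoses = rio.read_diagnoses(input_dir / "diagnoses.csv")
        prescriptions = rio.read_prescriptions(input_dir / "prescriptions.csv")
        dictionary = DrugDictionary.from_csv(input_dir / "drug_dictionary.csv")
        codelists = rio.read_codelists(input_dir / "codelists.csv")

        stage = "cohort"
        cohort = build_cohort(patients.frame, diagnoses.frame, prescriptions.frame,
                              dictionary, codelists, config)
        cohort.attrition["rejected_patient_rows"] = patients.n_rejected
        cohort.attrition["rejected_event_rows"] = (diagnoses.n_rejected
                                                   + prescriptions.n_rejected)
        rx = in_window_prescriptions(prescriptions.frame, dictionary, cohort.members)

        stage = "sessions"
        sessions = sessions_for_all_units(rx, dictionary, cohort.members, config)

        stage = "trends"
        proportions = proportion_table(cohort.members, sessions, config,
                                       units=dictionary.units())
        pct_series = percent_treated_series(cohort.members, rx, config)
        table1 = demographics_summary(cohort.members)
        y0, y1 = config.years()[0], config.years()[-1]
        tables2 = []
        for unit in (HierarchyUnit(1, "antipsychotic"), HierarchyUnit(1, "mood_stabiliser")):
            t = trend_table(proportions, unit, y0, y1)
            t.insert(0, "unit", unit.label)
            tables2.append(t)
        table2 = pd.concat(tables2, ignore_index=True)

        stage = "coprescribe"
        coprx = summary_table(cohort.members, rx, config)

        stage = "headline"
        headline = headline_numbers(pct_series, proportions, coprx, cohort.members,
                                    rx, sessions, config)
    except Exception as exc:  # noqa: BLE001 - annotate with the failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return PipelineResult(cohort, sessions, proportions, pct_series, table1,
                          table2, coprx, headline)


def headline_numbers(pct_series: pd.DataFrame, proportions: pd.DataFrame,
                     coprescribing: pd.DataFrame, cohort: pd.DataFrame,
                     prescriptions: pd.DataFrame, sessions: pd.DataFrame,
                     config: StudyConfig) -> dict:
    """Headline statistics, each traceable to a cell of the output CSVs."""
    y0, y1 = config.years()[0], config.years()[-1]
    first = pct_series[pct_series["year"] == y0].iloc[0]
    last = pct_series[pct_series["year"] == y1].iloc[0]
    series = pct_series.set_index("year")["pct_treated"]

    def overall_pct(unit_label, level, year):
        row = proportions[(proportions["dimension"] == "overall")
                          & (proportions["level"] == level)
                          & (proportions["label"] == unit_label)
                          & (proportions["year"] == year)]
        if row.empty or row.iloc[0]["denominator_days"] == 0:
            return float("nan")
        return round_half_up(100.0 * row.iloc[0]["proportion"])

    cb = childbearing_valproate(cohort, prescriptions, sessions, y1, config)
    co0 = coprescribing[coprescribing["year"] == y0].iloc[0]
    co1 = coprescribing[coprescribing["year"] == y1].iloc[0]

    out = {
        f"pct_treated_{y0}": float(first["pct_treated"]),
        f"pct_treated_{y1}": float(last["pct_treated"]),
        f"n_treated_{y0}": int(first["n_treated"]),
        f"n_at_risk_{y0}": int(first["n_at_risk"]),
        f"n_treated_{y1}": int(last["n_treated"]),
        f"n_at_risk_{y1}": int(last["n_at_risk"]),
        "mean_annual_change_pct": round_half_up(mean_annual_change(series)),
    }
    for label, level in (("antipsychotic", 1), ("mood_stabiliser", 1),
                         ("FGA", 2), ("SGA", 2), ("lithium", 2), ("valproate", 3)):
        p0, p1 = overall_pct(label, level, y0), overall_pct(label, level, y1)
        out[f"time_pct_{label}_{y0}"] = p0
        out[f"time_pct_{label}_{y1}"] = p1
        out[f"time_pct_{label}_change"] = round_half_up(p1 - p0)
    out.update({
        f"valproate_childbearing_pct_{y1}": cb.percent,
        f"valproate_childbearing_n_{y1}": cb.n_on_valproate,
        f"valproate_childbearing_denom_{y1}": cb.n_treated_women,
        f"pct_multi_drug_{y0}": float(co0["pct_multi"]),
        f"pct_multi_drug_{y1}": float(co1["pct_multi"]),
    })
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(input_dir, out_dir, config: StudyConfig, seed: int | None = None) -> dict:
    """Run the pipeline and write the artifact set; returns paths written."""
    input_dir, out_dir = Path(input_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result = run_pipeline(input_dir, config)

    members = result.cohort.members.copy()
    for c in ("birth_date", "fu_start", "fu_end", "first_bipolar_date"):
        members[c] = members[c].dt.strftime("%Y-%m-%d")
    members.to_csv(out_dir / "cohort.csv", index=False)
    result.cohort.exclusions.to_csv(out_dir / "exclusions.csv", index=False)

    sessions = result.sessions.copy()
    for c in ("start", "end"):
        sessions[c] = sessions[c].dt.strftime("%Y-%m-%d")
    sessions.to_csv(out_dir / "sessions.csv", index=False)

    result.table1.to_csv(out_dir / "table1.csv")
    result.table2.to_csv(out_dir / "table2.csv", index=False)
    result.proportions.to_csv(out_dir / "proportions.csv", index=False)
    result.percent_treated.to_csv(out_dir / "percent_treated.csv", index=False)
    result.coprescribing.to_csv(out_dir / "coprescribing.csv", index=False)

    with open(out_dir / "headline.json", "w") as fh:
        json.dump(result.headline, fh, indent=2, sort_keys=True, default=float)

    att = result.cohort.attrition
    lines = [f"{k}: {v}" for k, v in att.items()]
    lines.append(f"unclassified scripts excluded: {result.cohort.n_unclassified_scripts}")
    (out_dir / "attrition.log").write_text("\n".join(lines) + "\n")

    metadata = {
        "rxtrends_version": __version__,
        "config": config.model_dump(mode="json"),
        "seed": seed,
        "inputs": {name: _sha256(input_dir / name)
                   for name in INPUT_FILES if (input_dir / name).exists()},
    }
    with open(out_dir / "run_metadata.json", "w") as fh:
        json.dump(metadata, fh, indent=2, sort_keys=True)

    return {p.name: str(p) for p in sorted(out_dir.glob("*"))}


def cotreatment_shares(cohort: pd.DataFrame, sessions: pd.DataFrame,
                       config: StudyConfig) -> pd.DataFrame:
    """Whole-study time shares for the two headline combinations."""
    period = (config.study_start, config.study_end_exclusive)
    rows = []
    for combo in (("lithium", "antipsychotic"), ("valproate", "antipsychotic")):
        ts = time_share(cohort, sessions, combo, period, config)
        rows.append({
            "combination": "+".join(combo),
            "n_patients": ts.n_patients,
            f"share_{combo[0]}": ts.mean_share.get(combo[0], float("nan")),
            "share_antipsychotic": ts.mean_share.get("antipsychotic", float("nan")),
        })
    return pd.DataFrame(rows)
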