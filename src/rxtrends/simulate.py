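"""Synthetic THIN-like EHR generator with known ground truth.

Emulates a primary-care cohort of adults with bipolar disorder: registration
windows with entry/exit churn and a practice data-quality date, one or more
bipolar diagnosis codes (a configurable fraction dated outside the study
window to exercise exclusion), epilepsy contamination, and per-drug
prescription streams with explicit session structure — within-session refill
intervals strictly below the gap threshold, between-session gaps at or above
it — plus optional lithium→antipsychotic co-prescription coupling and junk
(unclassifiable) prescription codes.

Ground truth is computed from the *realized* data, not the analytic
expectation: per hierarchy unit a day-grid oracle (a day is covered iff it
is within ``coverage_days`` after a script or lies between two scripts less
than ``gap_days`` apart) marks covered person-days over each truth-eligible
patient's window.  Recovery tests against the pipeline are therefore exact
up to the sessionizer's conventions rather than Monte-Carlo-noisy.

Everything is driven by one ``numpy`` Generator seeded from
``SimulationConfig.seed``; the same seed yields byte-identical tables.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .config import StudyConfig, year_interval
from .drugs import LEVEL2_TO_LEVEL1, DrugDictionary

EPOCH = pd.Timestamp(0)


def _day(d) -> int:
    return (pd.Timestamp(d) - EPOCH).days


def _date(day: int) -> pd.Timestamp:
    return EPOCH + pd.Timedelta(days=int(day))


class DrugProfile(BaseModel):
    """Era- and stratum-varying prescribing model for one generic drug.

    ``start_hazard`` is the per-calendar-year probability that a patient not
    currently in (or blocked after) a session starts one.  The hazard is
    multiplied by ``female_hazard_ratio`` for women and by
    ``exp(age_hazard_slope * (age - 40)/10)``, then clipped to [0, 1].
    Session lengths are log-normal (median/sigma parametrisation), refill
    intervals truncated-normal capped strictly below the gap threshold, and
    post-session blocks are the gap threshold plus an exponential excess.
    """

    generic_name: str
    level2_class: str
    start_hazard: dict[int, float] = Field(default_factory=dict)
    female_hazard_ratio: float = 1.0
    age_hazard_slope: float = 0.0
    refill_mean_days: float = 28.0
    refill_sd_days: float = 7.0
    session_length_median_days: float = 200.0
    session_length_sigma: float = 0.6
    between_gap_extra_mean_days: float = 90.0
    start_day: int | None = None  # fixed day-of-year for session starts
    n_codes: int = Field(default=2, ge=1)

    @model_validator(mode="after")
    def _check(self) -> "DrugProfile":
        if self.level2_class not in LEVEL2_TO_LEVEL1:
            raise ValueError(f"unknown level2_class {self.level2_class!r}")
        for y, h in self.start_hazard.items():
            if not 0.0 <= h <= 1.0:
                raise ValueError(f"hazard for {y} outside [0,1]")
        return self


class SimulationConfig(BaseModel):
    """Full generator configuration; ``seed`` determines output exactly."""

    n_patients: int = Field(ge=0)
    seed: int = 0
    study: StudyConfig = Field(default_factory=StudyConfig)
    female_fraction: float = Field(default=0.614, ge=0, le=1)
    age_mean: float = 44.5          # age at study start, years
    age_sd: float = 15.2
    min_age: float = 10.0           # floor; minors may turn 18 in-window
    townsend_probs: tuple[float, float, float, float, float] = (0.20, 0.19, 0.21, 0.22, 0.18)
    townsend_missing_rate: float = Field(default=0.03, ge=0, le=1)
    pre_registered_fraction: float = Field(default=0.6, ge=0, le=1)
    registration_entry_years: tuple[int, int] = (1985, 2007)
    exit_hazard_per_year: float = Field(default=0.04, ge=0)
    quality_date_years: tuple[int, int] = (1990, 1998)
    ineligible_fraction: float = Field(default=0.03, ge=0, le=1)  # diagnosis pre-window only
    never_treated_fraction: float = Field(default=0.10, ge=0, le=1)  # no prescribing at all
    epilepsy_rate: float = Field(default=0.02, ge=0, le=1)
    unclassified_rate: float = Field(default=0.01, ge=0, le=1)    # junk scripts per script
    lithium_antipsychotic_coupling: float = Field(default=0.35, ge=0, le=1)
    drugs: list[DrugProfile] = Field(default_factory=list)

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if abs(sum(self.townsend_probs) - 1.0) > 1e-9:
            raise ValueError("townsend_probs must sum to 1")
        names = [p.generic_name for p in self.drugs]
        if len(names) != len(set(names)):
            raise ValueError("duplicate generic_name in drug profiles")
        for p in self.drugs:
            if p.refill_mean_days >= self.study.gap_days:
                raise ValueError(
                    f"{p.generic_name}: refill mean must be below gap_days "
                    "so within-session gaps stay continuous")
        return self


@dataclass
class GroundTruth:
    """Realized-data truth the pipeline should recover."""

    proportions: pd.DataFrame   # year, dimension, value, level, label, num/den days, proportion
    yearly: pd.DataFrame        # year, n_at_risk, n_treated, pct_treated, n_multi, pct_multi


@dataclass
class SimulationResult:
    patients: pd.DataFrame
    diagnoses: pd.DataFrame
    prescriptions: pd.DataFrame
    dictionary: DrugDictionary
    truth: GroundTruth
    true_sessions: pd.DataFrame  # patient_id, generic_name, start, end, n_prescriptions
    eligible_ids: list[str] = field(default_factory=list)


# -- independent day-grid coverage oracle -------------------------------------

def grid_covered(script_days: np.ndarray, win_start: int, win_end: int,
                 gap_days: int, coverage_days: int) -> np.ndarray:
    """Boolean coverage over the window's day grid (oracle definition)."""
    n = win_end - win_start
    covered = np.zeros(n, dtype=bool)
    s = np.unique(script_days)
    for d in s:
        covered[d - win_start:min(d - win_start + coverage_days, n)] = True
    for a, b in zip(s[:-1], s[1:]):
        if b - a < gap_days:
            covered[a - win_start:b - win_start] = True
    return covered


# -- generation ---------------------------------------------------------------

def _year_span_days(year: int) -> tuple[int, int]:
    a, b = year_interval(year)
    return _day(a), _day(b)


def _simulate_drug_stream(rng: np.random.Generator, profile: DrugProfile,
                          win: tuple[int, int], female: bool, birth_year: int,
                          gap_days: int, forced_starts: list[int] | None = None
                          ) -> tuple[list[int], list[tuple[int, int, int]]]:
    """Script days + realized sessions (first, last script, n) for one drug."""
    win_start, win_end = win
    candidates: list[int] = list(forced_starts or [])
    y0 = _date(win_start).year
    y1 = _date(win_end - 1).year
    for year in range(y0, y1 + 1):
        base = profile.start_hazard.get(year, 0.0)
        if base <= 0:
            continue
        age = year - birth_year
        h = base
        if female:
            h *= profile.female_hazard_ratio
        h *= float(np.exp(profile.age_hazard_slope * (age - 40) / 10))
        h = min(max(h, 0.0), 1.0)
        if rng.random() >= h:
            continue
        ys, ye = _year_span_days(year)
        lo, hi = max(ys, win_start), min(ye, win_end)
        if lo >= hi:
            continue
        if profile.start_day is not None:
            day = ys + profile.start_day
            if not (lo <= day < hi):
                continue
        else:
            day = int(rng.integers(lo, hi))
        candidates.append(day)

    candidates.sort()
    scripts: list[int] = []
    sessions: list[tuple[int, int, int]] = []
    next_eligible = win_start
    for start in candidates:
        if start < next_eligible or start >= win_end:
            continue
        length = profile.session_length_median_days * float(
            np.exp(rng.normal(0.0, profile.session_length_sigma)))
        sess = [start]
        t = start
        while True:
            r = rng.normal(profile.refill_mean_days, profile.refill_sd_days)
            r = int(min(max(round(r), 1), gap_days - 1))
            t += r
            if t - start > length or t >= win_end:
                break
            sess.append(t)
        scripts.extend(sess)
        sessions.append((sess[0], sess[-1], len(sess)))
        extra = rng.exponential(profile.between_gap_extra_mean_days)
        next_eligible = sess[-1] + gap_days + int(extra)
    return scripts, sessions


def generate(config: SimulationConfig) -> SimulationResult:
    """Generate the four tables plus ground truth for one seeded replicate."""
    rng = np.random.default_rng(config.seed)
    study = config.study
    s0, s1 = _day(study.study_start), _day(study.study_end_exclusive)
    years = study.years()
    mm, dd = (int(v) for v in study.birth_imputation_monthday.split("-"))
    dictionary = _build_dictionary(config)
    codes_by_generic = {
        g: list(dictionary.frame.loc[dictionary.frame["generic_name"] == g, "drug_code"])
        for g in dictionary.generics()
    }
    antipsychotics = [p for p in config.drugs
                      if LEVEL2_TO_LEVEL1[p.level2_class] == "antipsychotic"]
    mood = [p for p in config.drugs if p not in antipsychotics]

    pat_rows, dx_rows, rx_rows, sess_rows = [], [], [], []
    eligible_ids: list[str] = []
    truth_acc = _TruthAccumulator(study, dictionary)

    for i in range(config.n_patients):
        pid = f"P{i + 1:06d}"
        female = rng.random() < config.female_fraction
        age0 = max(float(rng.normal(config.age_mean, config.age_sd)), config.min_age)
        birth_year = study.study_start.year - int(age0)
        birth = pd.Timestamp(dt.date(birth_year, mm, dd))

        if rng.random() < config.townsend_missing_rate:
            townsend = np.nan
        else:
            townsend = float(rng.choice(np.arange(1, 6), p=list(config.townsend_probs)))

        e0, e1 = config.registration_entry_years
        if rng.random() < config.pre_registered_fraction:
            ry = int(rng.integers(e0, study.study_start.year))
        else:
            ry = int(rng.integers(study.study_start.year, e1 + 1))
        ys, ye = _year_span_days(ry)
        reg_start = int(rng.integers(ys, ye))
        if config.exit_hazard_per_year > 0:
            stay = rng.exponential(365.25 / config.exit_hazard_per_year)
        else:
            stay = np.inf
        reg_end_day = reg_start + stay
        reg_end = None if reg_end_day >= s1 else int(reg_end_day)
        q0, q1 = config.quality_date_years
        quality = max(reg_start, _day(dt.date(int(rng.integers(q0, q1 + 1)), 1, 1))
                      + int(rng.integers(0, 365)))

        # diagnoses
        ineligible = rng.random() < config.ineligible_fraction
        if ineligible:
            bip_day = int(rng.integers(_day(dt.date(1990, 1, 1)), s0))
        else:
            bip_day = int(rng.integers(s0, s1))
        dx_rows.append((pid, bip_day, "BIP01" if rng.random() < 0.7 else "BIP02"))
        epileptic = rng.random() < config.epilepsy_rate
        if epileptic:
            dx_rows.append((pid, int(rng.integers(_day(dt.date(1980, 1, 1)), s1)), "EPI01"))

        # follow-up window (pipeline convention)
        adult = _day(birth + pd.DateOffset(years=18))
        win_start = max(s0, reg_start, quality, adult)
        win_end = min(s1, (reg_end + 1) if reg_end is not None else s1)

        pat_rows.append((pid, "female" if female else "male", birth,
                         reg_start, reg_end, quality, townsend))

        if win_start >= win_end:
            continue

        # prescriptions: mood stabilisers first so lithium starts can couple
        scripts_by_generic: dict[str, list[int]] = {}
        lithium_starts: list[int] = []
        never_treated = rng.random() < config.never_treated_fraction
        drug_sets = ([], []) if never_treated else (mood, antipsychotics)
        for profile in drug_sets[0]:
            scripts, sessions = _simulate_drug_stream(
                rng, profile, (win_start, win_end), female, birth_year, study.gap_days)
            if scripts:
                scripts_by_generic[profile.generic_name] = scripts
                sess_rows.extend((pid, profile.generic_name, a, b, n) for a, b, n in sessions)
            if profile.level2_class == "lithium":
                lithium_starts = [a for a, _, _ in sessions]
        forced: dict[str, list[int]] = {}
        for start in lithium_starts:
            if rng.random() >= config.lithium_antipsychotic_coupling or not antipsychotics:
                continue
            year = _date(start).year
            avail = [p for p in antipsychotics if p.start_hazard.get(year, 0.0) > 0]
            if not avail:
                continue
            chosen = avail[int(rng.integers(0, len(avail)))]
            forced.setdefault(chosen.generic_name, []).append(
                start + int(rng.integers(0, 15)))
        for profile in drug_sets[1]:
            scripts, sessions = _simulate_drug_stream(
                rng, profile, (win_start, win_end), female, birth_year,
                study.gap_days, forced.get(profile.generic_name))
            if scripts:
                scripts_by_generic[profile.generic_name] = scripts
                sess_rows.extend((pid, profile.generic_name, a, b, n) for a, b, n in sessions)

        n_scripts = sum(len(v) for v in scripts_by_generic.values())
        for generic, days in scripts_by_generic.items():
            codes = codes_by_generic[generic]
            for d in days:
                rx_rows.append((pid, d, codes[int(rng.integers(0, len(codes)))]))
        n_junk = int(rng.binomial(n_scripts, config.unclassified_rate)) if n_scripts else 0
        for _ in range(n_junk):
            rx_rows.append((pid, int(rng.integers(win_start, win_end)),
                            f"JUNK{int(rng.integers(0, 100)):02d}"))

        truth_ok = (not ineligible) and (not epileptic)
        if truth_ok:
            eligible_ids.append(pid)
            truth_acc.add(pid, "female" if female else "male", birth,
                          (win_start, win_end), scripts_by_generic)

    patients = pd.DataFrame(pat_rows, columns=[
        "patient_id", "sex", "birth_date", "reg_start", "reg_end", "quality_date", "townsend"])
    patients["reg_start"] = patients["reg_start"].map(_date)
    patients["reg_end"] = patients["reg_end"].map(
        lambda d: pd.NaT if d is None or pd.isna(d) else _date(d))
    patients["quality_date"] = patients["quality_date"].map(_date)
    patients["birth_date"] = pd.to_datetime(patients["birth_date"])

    diagnoses = pd.DataFrame(dx_rows, columns=["patient_id", "date", "code"])
    diagnoses["date"] = diagnoses["date"].map(_date)
    prescriptions = pd.DataFrame(rx_rows, columns=["patient_id", "date", "drug_code"])
    if len(prescriptions):
        prescriptions = prescriptions.sort_values(
            ["patient_id", "date", "drug_code"], ignore_index=True)
        prescriptions["date"] = prescriptions["date"].map(_date)
    else:
        prescriptions["date"] = pd.to_datetime(prescriptions["date"])

    true_sessions = pd.DataFrame(
        sess_rows, columns=["patient_id", "generic_name", "start", "last_script",
                            "n_prescriptions"])
    if len(true_sessions):
        # same end convention as the sessionizer: last script + coverage, truncated
        true_sessions["end"] = true_sessions["last_script"] + study.coverage_days
        wend = patients.set_index("patient_id")["reg_end"].map(
            lambda d: _day(d) + 1 if pd.notna(d) else s1).clip(upper=s1)
        true_sessions["end"] = np.minimum(
            true_sessions["end"], true_sessions["patient_id"].map(wend).to_numpy())
        true_sessions["start"] = true_sessions["start"].map(_date)
        true_sessions["end"] = true_sessions["end"].map(_date)
        true_sessions = true_sessions.drop(columns=["last_script"])

    truth = truth_acc.finalize()
    return SimulationResult(patients, diagnoses, prescriptions, dictionary, truth,
                            true_sessions, eligible_ids)


def _build_dictionary(config: SimulationConfig) -> DrugDictionary:
    rows = []
    for p in config.drugs:
        for k in range(p.n_codes):
            rows.append((f"{p.generic_name[:6].upper()}-{k:02d}", p.generic_name,
                         p.level2_class))
    return DrugDictionary(pd.DataFrame(rows, columns=["drug_code", "generic_name",
                                                      "level2_class"]))


class _TruthAccumulator:
    """Per-patient day-grid bookkeeping pooled into the truth tables."""

    def __init__(self, study: StudyConfig, dictionary: DrugDictionary):
        self.study = study
        self.dict = dictionary
        self.class_of = dict(zip(dictionary.frame["generic_name"],
                                 dictionary.frame["level2_class"]))
        self.group_of = dict(zip(dictionary.frame["generic_name"],
                                 dictionary.frame["level1_group"]))
        self.num: dict[tuple, int] = {}   # (year, dim, value, level, label) -> days
        self.den: dict[tuple, int] = {}   # (year, dim, value) -> days
        self.at_risk: dict[int, int] = {y: 0 for y in study.years()}
        self.treated: dict[int, int] = {y: 0 for y in study.years()}
        self.multi: dict[int, int] = {y: 0 for y in study.years()}

    def add(self, pid: str, sex: str, birth: pd.Timestamp, win: tuple[int, int],
            scripts_by_generic: dict[str, list[int]]) -> None:
        study = self.study
        win_start, win_end = win
        unit_scripts: dict[tuple[int, str], list[int]] = {}
        for g, days in scripts_by_generic.items():
            unit_scripts.setdefault((3, g), []).extend(days)
            unit_scripts.setdefault((2, self.class_of[g]), []).extend(days)
            unit_scripts.setdefault((1, self.group_of[g]), []).extend(days)
        grids = {
            u: grid_covered(np.asarray(sorted(d)), win_start, win_end,
                            study.gap_days, study.coverage_days)
            for u, d in unit_scripts.items()
        }
        for year in study.years():
            ys, ye = _year_span_days(year)
            lo, hi = max(ys, win_start), min(ye, win_end)
            if lo >= hi:
                continue
            days = hi - lo
            for key in (("overall", "all"), ("sex", sex)):
                self.den[(year, *key)] = self.den.get((year, *key), 0) + days
            for (level, label), grid in grids.items():
                cov = int(grid[lo - win_start:hi - win_start].sum())
                for key in (("overall", "all"), ("sex", sex)):
                    k = (year, *key, level, label)
                    self.num[k] = self.num.get(k, 0) + cov
            self.at_risk[year] += 1
            in_year = {g: sum(1 for d in days_ if ys <= d < ye)
                       for g, days_ in scripts_by_generic.items()}
            total = sum(in_year.values())
            if total >= self.study.min_prescriptions_treated:
                self.treated[year] += 1
            n_on = sum(1 for n in in_year.values()
                       if n >= self.study.min_prescriptions_treated)
            if n_on >= 2:
                self.multi[year] += 1

    def finalize(self) -> GroundTruth:
        units = [(u.level, u.label) for u in self.dict.units()]
        rows = []
        for (year, dim, value), dd in sorted(self.den.items()):
            for level, label in units:
                nn = self.num.get((year, dim, value, level, label), 0)
                rows.append((year, dim, value, level, label, nn, dd,
                             nn / dd if dd else np.nan))
        proportions = pd.DataFrame(rows, columns=[
            "year", "dimension", "value", "level", "label",
            "numerator_days", "denominator_days", "proportion"])
        yearly = pd.DataFrame({
            "year": list(self.at_risk),
            "n_at_risk": list(self.at_risk.values()),
            "n_treated": list(self.treated.values()),
            "n_multi": list(self.multi.values()),
        })
        yearly["pct_treated"] = np.where(
            yearly["n_at_risk"] > 0,
            100.0 * yearly["n_treated"] / yearly["n_at_risk"].replace(0, 1), np.nan)
        yearly["pct_multi"] = np.where(
            yearly["n_treated"] > 0,
            100.0 * yearly["n_multi"] / yearly["n_treated"].replace(0, 1), np.nan)
        return GroundTruth(proportions, yearly)


# -- shipped preset ------------------------------------------------------------

def _ramp(y_from: int, v_from: float, y_to: int, v_to: float) -> dict[int, float]:
    """Linear hazard ramp over [y_from, y_to]; zero before y_from."""
    if y_to == y_from:
        return {y_from: v_to}
    return {y: v_from + (v_to - v_from) * (y - y_from) / (y_to - y_from)
            for y in range(y_from, y_to + 1)}


def uk_prescribing_preset(n_patients: int = 3000, seed: int = 0) -> SimulationConfig:
    """Shipped preset qualitatively mirroring late-1990s/2000s UK trends:
    SGA uptake zero before 1996 then rising steeply, valproate zero in 1995
    then rising, lithium roughly flat with strong age gradient, FGAs
    declining.  Hazards are per-year session-start probabilities.
    """
    # The first-year hazard is boosted for drugs in established use by 1995:
    # the cohort opens with no prescribing history, so prevalent users are
    # emulated by a high chance of (re)starting in the opening year.
    drugs = [
        DrugProfile(generic_name="lithium", level2_class="lithium",
                    start_hazard={1995: 0.50, **{y: 0.22 for y in range(1996, 2010)}},
                    age_hazard_slope=0.30, session_length_median_days=420,
                    session_length_sigma=0.5),
        DrugProfile(generic_name="valproate", level2_class="anticonvulsant",
                    start_hazard=_ramp(1996, 0.02, 2009, 0.22),
                    session_length_median_days=330, session_length_sigma=0.5),
        DrugProfile(generic_name="carbamazepine", level2_class="anticonvulsant",
                    start_hazard={1995: 0.16, **_ramp(1996, 0.07, 2004, 0.09),
                                  **_ramp(2005, 0.085, 2009, 0.06)},
                    session_length_median_days=300),
        DrugProfile(generic_name="lamotrigine", level2_class="anticonvulsant",
                    start_hazard=_ramp(1998, 0.01, 2009, 0.06),
                    session_length_median_days=300),
        DrugProfile(generic_name="olanzapine", level2_class="SGA",
                    start_hazard=_ramp(1997, 0.02, 2009, 0.16),
                    female_hazard_ratio=0.9, session_length_median_days=300),
        DrugProfile(generic_name="quetiapine", level2_class="SGA",
                    start_hazard=_ramp(1998, 0.01, 2009, 0.12),
                    female_hazard_ratio=1.3, session_length_median_days=280),
        DrugProfile(generic_name="risperidone", level2_class="SGA",
                    start_hazard=_ramp(1996, 0.01, 2009, 0.06),
                    session_length_median_days=250),
        DrugProfile(generic_name="aripiprazole", level2_class="SGA",
                    start_hazard=_ramp(2004, 0.005, 2009, 0.03),
                    age_hazard_slope=-0.30, session_length_median_days=250),
        DrugProfile(generic_name="chlorpromazine", level2_class="FGA",
                    start_hazard={1995: 0.28, **_ramp(1996, 0.11, 2009, 0.02)},
                    session_length_median_days=250),
        DrugProfile(generic_name="haloperidol", level2_class="FGA",
                    start_hazard={1995: 0.20, **_ramp(1996, 0.08, 2009, 0.025)},
                    session_length_median_days=250),
        DrugProfile(generic_name="trifluoperazine", level2_class="FGA",
                    start_hazard={1995: 0.12, **_ramp(1996, 0.05, 2009, 0.01)},
                    session_length_median_days=250),
    ]
    return SimulationConfig(n_patients=n_patients, seed=seed, drugs=drugs)


def write_dataset(result: SimulationResult, out_dir) -> dict[str, str]:
    """Write the four input CSVs plus the truth tables to ``out_dir``."""
    from pathlib import Path

    from . import io as rio
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rio.write_patients(result.patients, out / "patients.csv")
    rio.write_diagnoses(result.diagnoses, out / "diagnoses.csv")
    rio.write_prescriptions(result.prescriptions, out / "prescriptions.csv")
    result.dictionary.to_csv(out / "drug_dictionary.csv")
    rio.write_codelists({"bipolar": {"BIP01", "BIP02"}, "epilepsy": {"EPI01"}},
                        out / "codelists.csv")
    result.truth.proportions.to_csv(out / "truth.csv", index=False)
    result.truth.yearly.to_csv(out / "truth_yearly.csv", index=False)
    return {p.name: str(p) for p in out.glob("*.csv")}
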