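"""Annual person-time-in-treatment proportions and trend summaries.

The primary estimand is the pooled proportion of person-time: for a calendar
year, stratum and hierarchy unit, the summed days of follow-up covered by
that unit's sessions divided by the summed days of follow-up, across every
cohort member in the stratum (treated and untreated alike by default).  A
per-patient-mean variant is available as a sensitivity analysis.  Percentages
are rounded half-up to one decimal place at the reporting edge only; all
internal arithmetic is exact integer day counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .config import StudyConfig, year_interval
from .drugs import HierarchyUnit

DIMENSIONS = ("overall", "sex", "age_band", "townsend")
OUTSIDE_BANDS = "outside-bands"


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero at ``ndigits`` decimals (report convention)."""
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return float("nan")
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Stratum:
    dimension: str  # overall | sex | age_band | townsend
    value: str


@dataclass
class ProportionEstimate:
    year: int
    stratum: Stratum
    unit: HierarchyUnit
    numerator_days: int
    denominator_days: int
    proportion: float = None  # pooled ratio unless a variant estimator filled it

    def __post_init__(self):
        if self.proportion is None:
            self.proportion = (self.numerator_days / self.denominator_days
                               if self.denominator_days else float("nan"))


def age_on_july1(birth_date: pd.Series, year: int) -> pd.Series:
    """Completed age at July 1 of ``year`` (band-assignment convention)."""
    after_jul1 = (birth_date.dt.month > 7) | ((birth_date.dt.month == 7) & (birth_date.dt.day > 1))
    return year - birth_date.dt.year - after_jul1.astype(int)


def _age_band_label(age: pd.Series, config: StudyConfig) -> pd.Series:
    out = pd.Series(OUTSIDE_BANDS, index=age.index, dtype=object)
    for lo, hi in config.age_bands:
        out[(age >= lo) & (age <= hi)] = f"{lo}-{hi}"
    return out


def person_time_by_year(cohort: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    """One row per (member, calendar year) with follow-up days and stratum labels."""
    frames = []
    for year in config.years():
        y0, y1 = (pd.Timestamp(d) for d in year_interval(year))
        days = (cohort["fu_end"].clip(upper=y1) - cohort["fu_start"].clip(lower=y0)).dt.days
        sel = days > 0
        if not sel.any():
            continue
        sub = cohort[sel]
        age = age_on_july1(sub["birth_date"], year)
        frames.append(pd.DataFrame({
            "patient_id": sub["patient_id"],
            "year": year,
            "days": days[sel].astype(int),
            "sex": sub["sex"],
            "age": age,
            "age_band": _age_band_label(age, config),
            "townsend": sub["townsend"],
            "treated": sub["treated"],
        }))
    if not frames:
        return pd.DataFrame(columns=["patient_id", "year", "days", "sex", "age",
                                     "age_band", "townsend", "treated"])
    return pd.concat(frames, ignore_index=True)


def session_days_by_year(sessions: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    """Covered days of each (patient, unit) per calendar year (year-sliced)."""
    if sessions.empty:
        return pd.DataFrame(columns=["patient_id", "level", "label", "year", "covered_days"])
    frames = []
    for year in config.years():
        y0, y1 = (pd.Timestamp(d) for d in year_interval(year))
        d = (sessions["end"].clip(upper=y1) - sessions["start"].clip(lower=y0)).dt.days
        sel = d > 0
        if not sel.any():
            continue
        frames.append(sessions.loc[sel, ["patient_id", "level", "label"]]
                      .assign(year=year, covered_days=d[sel].astype(int)))
    if not frames:
        return pd.DataFrame(columns=["patient_id", "level", "label", "year", "covered_days"])
    out = pd.concat(frames, ignore_index=True)
    return (out.groupby(["patient_id", "level", "label", "year"], as_index=False)
            ["covered_days"].sum())


def _stratum_value(pt: pd.DataFrame, dimension: str) -> pd.Series:
    if dimension == "overall":
        return pd.Series("all", index=pt.index)
    if dimension == "sex":
        return pt["sex"]
    if dimension == "age_band":
        return pt["age_band"]
    if dimension == "townsend":
        return pt["townsend"].map(lambda v: None if pd.isna(v) else str(int(v)))
    raise ValueError(f"unknown stratum dimension {dimension!r}")


def proportion_table(cohort: pd.DataFrame, sessions: pd.DataFrame, config: StudyConfig,
                     units: list[HierarchyUnit] | None = None,
                     dimensions: tuple[str, ...] = DIMENSIONS) -> pd.DataFrame:
    """Long table of annual proportions: year x stratum x hierarchy unit.

    Missing Townsend quintiles drop out of the townsend dimension only.
    Units with no sessions in a stratum-year get numerator 0, never a
    missing row, so additivity checks can run over the full grid.
    """
    denom_members = cohort if config.denominator == "all" else cohort[cohort["treated"]]
    pt = person_time_by_year(denom_members, config)
    sd = session_days_by_year(
        sessions[sessions["patient_id"].isin(denom_members["patient_id"])], config)
    if units is None:
        units = [HierarchyUnit(int(l), str(lab))
                 for l, lab in sorted(set(zip(sessions.get("level", []),
                                              sessions.get("label", []))))]
    sd = sd.merge(pt, on=["patient_id", "year"], how="inner")

    rows = []
    for dim in dimensions:
        pv = _stratum_value(pt, dim)
        pt_d = pt[pv.notna()]
        den = pt_d.assign(value=pv[pv.notna()]).groupby(["year", "value"])["days"].sum()
        per_pat = pt_d.assign(value=pv[pv.notna()]).set_index(["patient_id", "year"])["days"]
        sv = _stratum_value(sd, dim)
        sd_d = sd[sv.notna()].assign(value=sv[sv.notna()])
        num = sd_d.groupby(["year", "value", "level", "label"])["covered_days"].sum()
        for (year, value), dd in den.items():
            for u in units:
                nn = int(num.get((year, value, u.level, u.label), 0))
                if config.proportion_method == "pooled":
                    prop = nn / dd if dd else np.nan
                else:
                    prop = _patient_mean(sd_d, pt_d, pv, year, value, u)
                rows.append((year, dim, value, u.level, u.label, nn, int(dd), prop))
    out = pd.DataFrame(rows, columns=["year", "dimension", "value", "level", "label",
                                      "numerator_days", "denominator_days", "proportion"])
    return out.sort_values(["dimension", "value", "level", "label", "year"],
                           ignore_index=True)


def _patient_mean(sd_d, pt_d, pv, year, value, unit) -> float:
    """Sensitivity variant: mean over patients of individual yearly proportions."""
    pats = pt_d[(pt_d["year"] == year) & (pv.loc[pt_d.index] == value)]
    if pats.empty:
        return np.nan
    cov = sd_d[(sd_d["year"] == year) & (sd_d["value"] == value)
               & (sd_d["level"] == unit.level) & (sd_d["label"] == unit.label)]
    cov = cov.set_index("patient_id")["covered_days"]
    frac = pats["patient_id"].map(cov).fillna(0).to_numpy() / pats["days"].to_numpy()
    return float(frac.mean())


def annual_proportion(cohort: pd.DataFrame, sessions: pd.DataFrame, year: int,
                      stratum: Stratum, unit: HierarchyUnit,
                      config: StudyConfig) -> ProportionEstimate:
    """Single-cell convenience wrapper around :func:`proportion_table`."""
    tab = proportion_table(cohort, sessions, config, units=[unit],
                           dimensions=(stratum.dimension,))
    row = tab[(tab["year"] == year) & (tab["value"] == stratum.value)]
    if row.empty:
        return ProportionEstimate(year, stratum, unit, 0, 0)
    r = row.iloc[0]
    return ProportionEstimate(year, stratum, unit, int(r["numerator_days"]),
                              int(r["denominator_days"]), float(r["proportion"]))


# -- patients-treated-per-year counts ----------------------------------------

def percent_treated(cohort: pd.DataFrame, prescriptions: pd.DataFrame, year: int,
                    config: StudyConfig) -> tuple[int, int, float]:
    """(n_treated, n_at_risk, percent) for one calendar year.

    At risk: any follow-up inside the year.  Treated: at least
    ``min_prescriptions_treated`` classified in-window scripts dated in the
    year.  Percent is rounded half-up to 1 dp; NaN when nobody is at risk.
    """
    y0, y1 = (pd.Timestamp(d) for d in year_interval(year))
    days = (cohort["fu_end"].clip(upper=y1) - cohort["fu_start"].clip(lower=y0)).dt.days
    at_risk = set(cohort.loc[days > 0, "patient_id"])
    rx = prescriptions[(prescriptions["date"] >= y0) & (prescriptions["date"] < y1)]
    counts = rx.groupby("patient_id").size()
    treated = {p for p, n in counts.items()
               if n >= config.min_prescriptions_treated and p in at_risk}
    n_at_risk, n_treated = len(at_risk), len(treated)
    pct = round_half_up(100.0 * n_treated / n_at_risk) if n_at_risk else float("nan")
    return n_treated, n_at_risk, pct


def percent_treated_series(cohort: pd.DataFrame, prescriptions: pd.DataFrame,
                           config: StudyConfig) -> pd.DataFrame:
    rows = [(y, *percent_treated(cohort, prescriptions, y, config))
            for y in config.years()]
    return pd.DataFrame(rows, columns=["year", "n_treated", "n_at_risk", "pct_treated"])


def mean_annual_change(series) -> float:
    """(last - first) / (inclusive year span - 1) for a year-indexed series.

    Accepts a mapping/Series keyed by year, or a plain sequence of yearly
    values (consecutive years assumed).
    """
    if isinstance(series, dict):
        series = pd.Series(series)
    if isinstance(series, pd.Series):
        series = series.sort_index()
        span = int(series.index[-1]) - int(series.index[0])
        return (series.iloc[-1] - series.iloc[0]) / span if span else 0.0
    values = list(series)
    if len(values) < 2:
        return 0.0
    return (values[-1] - values[0]) / (len(values) - 1)


# -- endpoint trend table ------------------------------------------------------

def trend_table(proportions: pd.DataFrame, unit: HierarchyUnit,
                first_year: int, last_year: int) -> pd.DataFrame:
    """Stratified endpoint comparison for one unit.

    Per stratum: percent of person-time in treatment and total person-years
    at ``first_year`` and ``last_year``, the percentage-point difference and
    the last/first ratio (NaN when the first-year percent is 0, printed as
    undefined).  Percentages/ratios at 1 dp, from the rounded endpoint cells.
    """
    tab = proportions[(proportions["level"] == unit.level)
                      & (proportions["label"] == unit.label)]
    rows = []
    for (dim, value), grp in tab.groupby(["dimension", "value"], sort=False):
        cells = {}
        for year, tag in ((first_year, "first"), (last_year, "last")):
            row = grp[grp["year"] == year]
            if row.empty or row.iloc[0]["denominator_days"] == 0:
                cells[f"pct_{tag}"] = float("nan")
                cells[f"person_years_{tag}"] = 0.0
            else:
                r = row.iloc[0]
                cells[f"pct_{tag}"] = round_half_up(100.0 * r["proportion"])
                cells[f"person_years_{tag}"] = round_half_up(r["denominator_days"] / 365.25)
        p0, p1 = cells["pct_first"], cells["pct_last"]
        diff = round_half_up(p1 - p0) if not (np.isnan(p0) or np.isnan(p1)) else float("nan")
        ratio = round_half_up(p1 / p0) if p0 and not np.isnan(p0) and not np.isnan(p1) \
            else float("nan")
        rows.append((dim, value, cells["pct_first"], cells["person_years_first"],
                     cells["pct_last"], cells["person_years_last"], diff, ratio))
    return pd.DataFrame(rows, columns=[
        "dimension", "value", f"pct_{first_year}", f"person_years_{first_year}",
        f"pct_{last_year}", f"person_years_{last_year}", "difference", "ratio"])


# -- valproate in women of childbearing age ------------------------------------

@dataclass
class ChildbearingValproate:
    year: int
    n_on_valproate: int
    n_treated_women: int
    percent: float
    proportion_of_year_in_treatment: float


def childbearing_valproate(cohort: pd.DataFrame, prescriptions: pd.DataFrame,
                           sessions: pd.DataFrame, year: int,
                           config: StudyConfig) -> ChildbearingValproate:
    """Valproate exposure among treated women of childbearing age in a year.

    Denominator: women in the childbearing age band (age at July 1) with >=2
    classified scripts that year; numerator: the subset with >=2 valproate
    scripts.  Also returns the pooled share of the numerator women's
    follow-up time that year spent inside valproate sessions.
    """
    y0, y1 = (pd.Timestamp(d) for d in year_interval(year))
    lo, hi = config.childbearing_age
    women = cohort[cohort["sex"] == "female"].copy()
    if not women.empty:
        age = age_on_july1(women["birth_date"], year)
        women = women[(age >= lo) & (age <= hi)]
    days = (women["fu_end"].clip(upper=y1) - women["fu_start"].clip(lower=y0)).dt.days
    women = women[days > 0]

    rx = prescriptions[prescriptions["patient_id"].isin(women["patient_id"])
                       & (prescriptions["date"] >= y0) & (prescriptions["date"] < y1)]
    total = rx.groupby("patient_id").size()
    denominator = set(total[total >= config.min_prescriptions_treated].index)
    valp = rx[rx["generic_name"] == "valproate"].groupby("patient_id").size()
    numerator = {p for p in valp[valp >= config.min_prescriptions_treated].index
                 if p in denominator}

    pct = round_half_up(100.0 * len(numerator) / len(denominator)) \
        if denominator else float("nan")

    sub = women[women["patient_id"].isin(numerator)]
    denom_days = int((sub["fu_end"].clip(upper=y1) - sub["fu_start"].clip(lower=y0))
                     .dt.days.clip(lower=0).sum())
    vsess = sessions[(sessions["level"] == 3) & (sessions["label"] == "valproate")
                     & sessions["patient_id"].isin(numerator)]
    cov = (vsess["end"].clip(upper=y1) - vsess["start"].clip(lower=y0)).dt.days
    num_days = int(cov[cov > 0].sum())
    share = num_days / denom_days if denom_days else float("nan")
    return ChildbearingValproate(year, len(numerator), len(denominator), pct, share)
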