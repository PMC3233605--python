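import numpy as np
import pandas as pd
import pytest

from helpers import cohort_frame, member, rx_frame, session_frame
from rxtrends.config import StudyConfig
from rxtrends.drugs import HierarchyUnit
from rxtrends.persontime import (Stratum, annual_proportion, childbearing_valproate,
                                 mean_annual_change, percent_treated,
                                 proportion_table, round_half_up, trend_table)

CONFIG = StudyConfig()
LITHIUM = HierarchyUnit(2, "lithium")
OVERALL = Stratum("overall", "all")


class TestAnnualProportion:
    def test_single_patient_fraction_of_year(self):
        cohort = cohort_frame([member("P1", fu_start="1995-01-01", fu_end="1996-01-01")])
        sess = session_frame([("P1", 2, "lithium", "1995-02-01", "1995-04-15", 3)])
        est = annual_proportion(cohort, sess, 1995, OVERALL, LITHIUM, CONFIG)
        assert est.denominator_days == 365
        assert est.numerator_days == 73
        assert est.proportion == pytest.approx(0.2)

    def test_pooling_weights_by_follow_up_not_by_patient(self):
        # full-year covered + full-year uncovered + half-year fully covered:
        # pooled (365+184)/(365+365+184) != patient-mean (1+0+1)/3
        cohort = cohort_frame([
            member("P1", fu_start="1995-01-01", fu_end="1996-01-01"),
            member("P2", fu_start="1995-01-01", fu_end="1996-01-01"),
            member("P3", fu_start="1995-07-01", fu_end="1996-01-01"),
        ])
        sess = session_frame([
            ("P1", 2, "lithium", "1995-01-01", "1996-01-01", 12),
            ("P3", 2, "lithium", "1995-07-01", "1996-01-01", 6),
        ])
        est = annual_proportion(cohort, sess, 1995, OVERALL, LITHIUM, CONFIG)
        assert est.proportion == pytest.approx((365 + 184) / (365 + 365 + 184))
        cfg_mean = StudyConfig(proportion_method="patient_mean")
        est_mean = annual_proportion(cohort, sess, 1995, OVERALL, LITHIUM, cfg_mean)
        assert est_mean.proportion == pytest.approx(2 / 3)

    def test_empty_stratum_year_gives_undefined(self):
        cohort = cohort_frame([member("P1", fu_start="2000-01-01", fu_end="2001-01-01")])
        est = annual_proportion(cohort, session_frame([]), 1996, OVERALL, LITHIUM, CONFIG)
        assert est.denominator_days == 0
        assert np.isnan(est.proportion)


class TestAdditivityAndNesting:
    def test_stratum_additivity_and_hierarchy_inequalities(self, sim_small_pipeline):
        """Sex and age-band strata partition overall person-time exactly, and
        coverage proportions nest L1 >= L2 >= L3 in every year/stratum."""
        config, _, cohort, _, sessions, dictionary = sim_small_pipeline
        props = proportion_table(cohort.members, sessions, config.study,
                                 units=dictionary.units())
        overall = props[props["dimension"] == "overall"].set_index(
            ["year", "level", "label"])
        for dim in ("sex", "age_band"):
            sub = props[props["dimension"] == dim]
            agg = sub.groupby(["year", "level", "label"])[
                ["numerator_days", "denominator_days"]].sum()
            joined = agg.join(overall[["numerator_days", "denominator_days"]],
                              rsuffix="_ov")
            assert (joined["numerator_days"] == joined["numerator_days_ov"]).all()
            assert (joined["denominator_days"] == joined["denominator_days_ov"]).all()
        # proportions within [0,1] and hierarchy nesting on the overall stratum
        assert props["proportion"].dropna().between(0, 1).all()
        ov = overall["numerator_days"]
        class_of = dict(zip(dictionary.frame["generic_name"],
                            dictionary.frame["level2_class"]))
        group_of = {"FGA": "antipsychotic", "SGA": "antipsychotic",
                    "anticonvulsant": "mood_stabiliser", "lithium": "mood_stabiliser"}
        for (year, level, label), num in ov.items():
            if level == 2:
                assert ov[(year, 1, group_of[label])] >= num
            elif level == 3:
                assert ov[(year, 2, class_of[label])] >= num


class TestPercentTreated:
    def test_counts_and_rounding(self):
        members = [member(f"P{i}", fu_start="1995-01-01", fu_end="1996-01-01")
                   for i in range(3)]
        cohort = cohort_frame(members)
        rx = rx_frame([("P0", "1995-02-01", "lithium"), ("P0", "1995-03-01", "lithium"),
                       ("P1", "1995-02-01", "lithium")])  # P1: only one script
        n_treated, n_at_risk, pct = percent_treated(cohort, rx, 1995, CONFIG)
        assert (n_treated, n_at_risk) == (1, 3)
        assert pct == 33.3

    def test_no_one_at_risk_gives_nan(self):
        cohort = cohort_frame([member("P1", fu_start="2000-01-01", fu_end="2001-01-01")])
        _, n_at_risk, pct = percent_treated(cohort, rx_frame([]), 1995, CONFIG)
        assert n_at_risk == 0 and np.isnan(pct)


class TestMeanAnnualChange:
    def test_endpoint_formula_on_year_indexed_series(self):
        series = {1995: 40.6, 2002: 55.0, 2009: 78.5}
        assert round_half_up(mean_annual_change(series)) == 2.7

    def test_constant_series_is_zero(self):
        assert mean_annual_change([5.0] * 15) == 0.0

    def test_linear_series_recovers_slope_exactly(self):
        s = 1.7
        series = [10 + s * i for i in range(15)]
        assert mean_annual_change(series) == pytest.approx(s)


class TestTrendTable:
    def _props(self, cells):
        # cells: (year, dimension, value, num, den)
        return pd.DataFrame(
            [(y, d, v, 1, "antipsychotic", n, dd, n / dd) for y, d, v, n, dd in cells],
            columns=["year", "dimension", "value", "level", "label",
                     "numerator_days", "denominator_days", "proportion"])

    def test_difference_and_ratio(self):
        props = self._props([(1995, "sex", "female", 112, 1000),
                             (2009, "sex", "female", 419, 1000)])
        tab = trend_table(props, HierarchyUnit(1, "antipsychotic"), 1995, 2009)
        row = tab.iloc[0]
        assert (row["pct_1995"], row["pct_2009"]) == (11.2, 41.9)
        assert row["difference"] == 30.7
        assert row["ratio"] == 3.7

    def test_zero_baseline_marks_ratio_undefined(self):
        props = self._props([(1995, "age_band", "18-29", 0, 500),
                             (2009, "age_band", "18-29", 170, 500)])
        tab = trend_table(props, HierarchyUnit(1, "antipsychotic"), 1995, 2009)
        row = tab.iloc[0]
        assert row["difference"] == 34.0
        assert np.isnan(row["ratio"])

    def test_equal_percentages(self):
        props = self._props([(1995, "overall", "all", 100, 1000),
                             (2009, "overall", "all", 100, 1000)])
        row = trend_table(props, HierarchyUnit(1, "antipsychotic"), 1995, 2009).iloc[0]
        assert row["difference"] == 0.0 and row["ratio"] == 1.0


class TestChildbearingValproate:
    def test_counts_and_time_share(self):
        members = [member("W1", birth="1980-07-01", fu_start="2009-01-01",
                          fu_end="2010-01-01"),
                   member("W2", birth="1980-07-01", fu_start="2009-01-01",
                          fu_end="2010-01-01"),
                   member("M1", sex="male", birth="1980-07-01",
                          fu_start="2009-01-01", fu_end="2010-01-01"),
                   member("W3", birth="1950-07-01", fu_start="2009-01-01",
                          fu_end="2010-01-01")]  # too old for the band
        cohort = cohort_frame(members)
        rx = rx_frame([
            ("W1", "2009-02-01", "valproate"), ("W1", "2009-03-01", "valproate"),
            ("W2", "2009-02-01", "lithium"), ("W2", "2009-03-01", "lithium"),
            ("M1", "2009-02-01", "valproate"), ("M1", "2009-03-01", "valproate"),
            ("W3", "2009-02-01", "valproate"), ("W3", "2009-03-01", "valproate"),
        ])
        sess = session_frame([("W1", 3, "valproate", "2009-02-01", "2009-03-29", 2)])
        cb = childbearing_valproate(cohort, rx, sess, 2009, CONFIG)
        assert (cb.n_on_valproate, cb.n_treated_women) == (1, 2)
        assert cb.percent == 50.0
        assert cb.proportion_of_year_in_treatment == pytest.approx(56 / 365)

    def test_no_valproate_scripts(self):
        cohort = cohort_frame([member("W1", birth="1980-07-01",
                                      fu_start="2009-01-01", fu_end="2010-01-01")])
        rx = rx_frame([("W1", "2009-02-01", "lithium"), ("W1", "2009-03-01", "lithium")])
        cb = childbearing_valproate(cohort, rx, session_frame([]), 2009, CONFIG)
        assert cb.percent == 0.0 and cb.n_on_valproate == 0


class TestParameterRecovery:
    def test_estimates_match_generator_truth(self, sim_small_pipeline):
        """Pipeline annual proportions equal the generator's day-grid truth
        (exact structural recovery at matched conventions)."""
        config, result, cohort, _, sessions, dictionary = sim_small_pipeline
        props = proportion_table(cohort.members, sessions, config.study,
                                 units=dictionary.units(),
                                 dimensions=("overall", "sex"))
        tr = result.truth.proportions
        joined = props.merge(tr, on=["year", "dimension", "value", "level", "label"],
                             suffixes=("_est", "_tru"))
        assert len(joined) == len(tr)
        assert (joined["numerator_days_est"] == joined["numerator_days_tru"]).all()
        assert (joined["denominator_days_est"] == joined["denominator_days_tru"]).all()
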