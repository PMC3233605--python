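import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import cohort_frame, member, oracle_day_runs, rx_frame, tiny_dictionary
from rxtrends.config import StudyConfig
from rxtrends.sessions import build_sessions, covered_days, sessions_for_all_units

EPOCH = pd.Timestamp(0)
BASE = pd.Timestamp("2000-01-01")
BASE_DAY = (BASE - EPOCH).days


def _dates(day_offsets):
    return [BASE + pd.Timedelta(days=d) for d in day_offsets]


def _spans(sessions):
    return [((s.start - BASE).days, (s.end - BASE).days, s.n_prescriptions)
            for s in sessions]


class TestBuildSessions:
    @pytest.mark.parametrize("offsets,expected", [
        # 120-day gap splits; 28-day coverage extends past the last script
        ([0, 30, 150], [(0, 58, 2), (150, 178, 1)]),
        # 90 < 91 keeps continuity across the near-threshold gap
        ([0, 90], [(0, 118, 2)]),
        # exactly the threshold breaks
        ([0, 91], [(0, 28, 1), (91, 119, 1)]),
        ([], []),
    ])
    def test_gap_rule_examples(self, offsets, expected):
        config = StudyConfig(gap_days=91, coverage_days=28)
        window = (BASE, BASE + pd.Timedelta(days=4000))
        assert _spans(build_sessions(_dates(offsets), window, config)) == expected

    def test_truncation_at_window_end(self):
        config = StudyConfig(coverage_days=28)
        window = (BASE, BASE + pd.Timedelta(days=10))
        (sess,) = build_sessions(_dates([5]), window, config)
        assert (sess.end - BASE).days == 10

    def test_same_day_duplicates_collapse_but_count(self):
        config = StudyConfig()
        window = (BASE, BASE + pd.Timedelta(days=400))
        (sess,) = build_sessions(_dates([0, 0, 30]), window, config)
        assert sess.n_prescriptions == 3
        assert (sess.end - BASE).days == 58

    def test_unsorted_input_rejected(self):
        config = StudyConfig()
        window = (BASE, BASE + pd.Timedelta(days=400))
        with pytest.raises(ValueError, match="sorted"):
            build_sessions(_dates([30, 0]), window, config)


@settings(max_examples=300, deadline=None, derandomize=True)
@given(
    offsets=st.lists(st.integers(0, 1200), min_size=1, max_size=50),
    gap_days=st.integers(10, 200),
    coverage=st.integers(1, 199),
)
def test_sessionizer_equals_day_grid_oracle(offsets, gap_days, coverage):
    """Property: greedy gap partition == brute-force day-grid oracle whenever
    forward coverage is shorter than the gap threshold."""
    coverage = min(coverage, gap_days - 1)
    config = StudyConfig(gap_days=gap_days, coverage_days=coverage)
    window = (BASE, BASE + pd.Timedelta(days=1400))
    sessions = build_sessions(_dates(sorted(offsets)), window, config)
    expected = oracle_day_runs([BASE_DAY + o for o in offsets], BASE_DAY + 1400,
                               gap_days, coverage)
    got = [((s.start - EPOCH).days, (s.end - EPOCH).days, s.n_prescriptions)
           for s in sessions]
    assert got == expected


@settings(max_examples=150, deadline=None, derandomize=True)
@given(offsets=st.lists(st.integers(0, 1000), min_size=1, max_size=40),
       gap_small=st.integers(30, 100), gap_delta=st.integers(1, 100))
def test_gap_threshold_monotonicity(offsets, gap_small, gap_delta):
    """Raising gap_days never increases session count nor decreases coverage."""
    window = (BASE, BASE + pd.Timedelta(days=1200))
    dates = _dates(sorted(offsets))
    small = build_sessions(dates, window, StudyConfig(gap_days=gap_small, coverage_days=28))
    large = build_sessions(dates, window,
                           StudyConfig(gap_days=gap_small + gap_delta, coverage_days=28))
    assert len(large) <= len(small)
    total = lambda ss: sum((s.end - s.start).days for s in ss)
    assert total(large) >= total(small)


class TestUnitsProjection:
    config = StudyConfig()

    def _sessions(self, rx_rows, members):
        cohort = cohort_frame(members)
        rx = rx_frame(rx_rows)
        return sessions_for_all_units(rx, tiny_dictionary(), cohort, self.config)

    def test_single_drug_projects_identically_to_all_levels(self):
        m = [member("P1")]
        rows = [("P1", "2000-01-01", "olanzapine"), ("P1", "2000-02-01", "olanzapine")]
        sess = self._sessions(rows, m)
        spans = {(r.level, r.label): (r.start, r.end, r.n_prescriptions)
                 for r in sess.itertuples()}
        assert spans[(3, "olanzapine")] == spans[(2, "SGA")] == spans[(1, "antipsychotic")]

    def test_alternating_drugs_fragment_lower_levels_only(self):
        m = [member("P1")]
        rows = []
        for i in range(6):  # haloperidol/olanzapine alternating 60 days apart
            drug = "haloperidol" if i % 2 == 0 else "olanzapine"
            rows.append(("P1", pd.Timestamp("2000-01-01") + pd.Timedelta(days=60 * i), drug))
        sess = self._sessions(rows, m)
        n_l1 = len(sess[(sess.level == 1) & (sess.label == "antipsychotic")])
        n_l3 = len(sess[sess.level == 3])
        assert n_l1 == 1        # 60-day gaps keep L1 continuous
        assert n_l3 == 6        # 120-day within-drug gaps split every script

    def test_mood_stabiliser_union_of_concurrent_streams(self):
        m = [member("P1")]
        rows = [("P1", "2000-01-01", "lithium"), ("P1", "2000-03-01", "lithium"),
                ("P1", "2000-02-01", "valproate"), ("P1", "2000-04-01", "valproate")]
        sess = self._sessions(rows, m)
        l1 = sess[(sess.level == 1) & (sess.label == "mood_stabiliser")]
        assert len(l1) == 1
        assert l1.iloc[0]["start"] == pd.Timestamp("2000-01-01")
        assert l1.iloc[0]["end"] == pd.Timestamp("2000-04-01") + pd.Timedelta(days=28)

    def test_hierarchy_nesting_on_random_streams(self):
        rng = np.random.default_rng(42)
        generics = list(tiny_dictionary().generics())
        for _ in range(30):
            m = [member("P1")]
            rows = [("P1", pd.Timestamp("1998-01-01")
                     + pd.Timedelta(days=int(rng.integers(0, 3000))),
                     generics[int(rng.integers(0, len(generics)))])
                    for _ in range(int(rng.integers(1, 30)))]
            sess = self._sessions(rows, m)
            year = (pd.Timestamp("2000-01-01"), pd.Timestamp("2001-01-01"))
            cov = lambda lvl, lab: covered_days(
                sess[(sess.level == lvl) & (sess.label == lab)], year)
            assert cov(1, "antipsychotic") >= max(cov(2, "FGA"), cov(2, "SGA"))
            assert cov(1, "mood_stabiliser") >= max(cov(2, "lithium"),
                                                    cov(2, "anticonvulsant"))
            for g in generics:
                cls = {"lithium": "lithium", "valproate": "anticonvulsant",
                       "carbamazepine": "anticonvulsant", "lamotrigine": "anticonvulsant",
                       "olanzapine": "SGA", "quetiapine": "SGA",
                       "haloperidol": "FGA", "chlorpromazine": "FGA"}[g]
                assert cov(2, cls) >= cov(3, g)

    def test_script_counts_conserved_per_unit(self, sim_small_pipeline):
        """Sum of n_prescriptions over a unit's sessions equals that unit's
        in-window script count."""
        _, _, _, rx, sessions, _ = sim_small_pipeline
        by_unit = sessions.groupby(["level", "label"])["n_prescriptions"].sum()
        for level, col in ((1, "level1_group"), (2, "level2_class"), (3, "generic_name")):
            counts = rx.groupby(col).size()
            for label, n in counts.items():
                assert by_unit[(level, label)] == n


class TestCoveredDays:
    def test_direct_length(self):
        sess = pd.DataFrame({"start": [pd.Timestamp("2000-01-01")],
                             "end": [pd.Timestamp("2000-03-01")]})
        year = (pd.Timestamp("2000-01-01"), pd.Timestamp("2001-01-01"))
        assert covered_days(sess, year) == 60

    def test_session_straddling_year_boundary_splits(self):
        sess = pd.DataFrame({"start": [pd.Timestamp("1999-12-02")],
                             "end": [pd.Timestamp("2000-01-31")]})
        y1999 = (pd.Timestamp("1999-01-01"), pd.Timestamp("2000-01-01"))
        y2000 = (pd.Timestamp("2000-01-01"), pd.Timestamp("2001-01-01"))
        assert covered_days(sess, y1999) == 30
        assert covered_days(sess, y2000) == 30
        assert covered_days(sess, y1999) + covered_days(sess, y2000) == 60

    def test_empty_sessions(self):
        year = (pd.Timestamp("2000-01-01"), pd.Timestamp("2001-01-01"))
        assert covered_days(pd.DataFrame(columns=["start", "end"]), year) == 0
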