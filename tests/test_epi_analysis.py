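import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diastress.cohort_simulator import AgentRecord, SimConfig, simulate_cohort
from diastress.epi_analysis import (
    curve_to_frame,
    declining_incidence_stat,
    hazard_in_window,
    kaplan_meier,
    km_onset,
    monthly_recovery_table,
    onset_by_baseline_symptoms,
    parameter_sweep,
    recovery_curve,
    recurrence_by_history,
    summarize_cohort,
)


def product_limit_oracle(durations, observed):
    """Exact-rational product-limit estimate, independent of the package."""
    events = sorted({t for t, obs in zip(durations, observed) if obs})
    survival = []
    s = Fraction(1)
    for t in events:
        n = sum(1 for u in durations if u >= t)
        d = sum(1 for u, obs in zip(durations, observed) if obs and u == t)
        s *= 1 - Fraction(d, n)
        survival.append(s)
    return events, survival


def make_record(
    agent_id=0,
    baseline_symptoms=2.0,
    baseline_state="low",
    onset_day=None,
    episode_count=0,
    episodes_years_1_9=0,
    episode_in_year_10=False,
    episode_starting_in_year_10=False,
    first_episode_duration_days=None,
    first_episode_censored=None,
):
    return AgentRecord(
        agent_id=agent_id,
        diathesis=1.0,
        baseline_symptoms=baseline_symptoms,
        baseline_state=baseline_state,
        ever_episode=episode_count > 0,
        onset_day=onset_day,
        episode_count=episode_count,
        episodes_years_1_9=episodes_years_1_9,
        episode_in_year_10=episode_in_year_10,
        episode_starting_in_year_10=episode_starting_in_year_10,
        first_episode_duration_days=first_episode_duration_days,
        first_episode_censored=first_episode_censored,
    )


class TestKaplanMeier:
    def test_three_subject_hand_fixture(self):
        # onsets at 100 and 200, one censored at 3652
        curve = kaplan_meier([100, 200, 3652], [True, True, False])
        np.testing.assert_array_equal(curve.time_points, [100, 200])
        np.testing.assert_array_equal(curve.n_at_risk, [3, 2])
        np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3])
        assert curve.survival_at(99) == 1.0
        assert curve.survival_at(100) == pytest.approx(2 / 3)
        assert curve.survival_at(5000) == pytest.approx(1 / 3)

    def test_ties_and_censoring_against_rational_oracle(self):
        durations = [5, 5, 5, 8, 8, 10, 10, 12, 12, 12]
        observed = [True, True, False, True, False, True, True, False, True, True]
        curve = kaplan_meier(durations, observed)
        times, survival = product_limit_oracle(durations, observed)
        np.testing.assert_array_equal(curve.time_points, times)
        np.testing.assert_allclose(curve.survival, [float(s) for s in survival],
                                   rtol=1e-12)

    def test_all_censored_survival_stays_one(self):
        curve = kaplan_meier([10, 20, 30], [False, False, False])
        assert curve.time_points.size == 0
        assert curve.survival_at(1000) == 1.0

    def test_curve_invariants_fixture(self):
        curve = kaplan_meier([5, 5, 8, 10, 12], [True, False, True, True, False])
        frame = curve_to_frame(curve)
        assert (frame["survival"].diff().dropna() <= 0).all()
        assert ((frame["survival"] >= 0) & (frame["survival"] <= 1)).all()

    def test_validation(self):
        with pytest.raises(ValueError, match="at least one"):
            kaplan_meier([], [])
        with pytest.raises(ValueError, match="equal length"):
            kaplan_meier([1, 2], [True])
        with pytest.raises(ValueError, match="positive"):
            kaplan_meier([0, 2], [True, True])

    @settings(max_examples=50, deadline=None)
    @given(
        durations=st.lists(st.integers(min_value=1, max_value=30),
                           min_size=1, max_size=15),
        flags=st.data(),
    )
    def test_matches_rational_oracle_property(self, durations, flags):
        observed = [
            flags.draw(st.booleans(), label=f"obs{i}")
            for i in range(len(durations))
        ]
        curve = kaplan_meier(durations, observed)
        times, survival = product_limit_oracle(durations, observed)
        np.testing.assert_array_equal(curve.time_points, times)
        np.testing.assert_allclose(curve.survival, [float(s) for s in survival],
                                   rtol=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(durations=st.lists(st.integers(min_value=1, max_value=50),
                              min_size=1, max_size=20))
    def test_no_censoring_matches_empirical_cdf(self, durations):
        curve = kaplan_meier(durations, [True] * len(durations))
        last = max(durations)
        assert 1 - curve.survival_at(last) == pytest.approx(1.0)
        mid = float(np.median(durations))
        empirical = sum(1 for t in durations if t <= mid) / len(durations)
        assert 1 - curve.survival_at(mid) == pytest.approx(empirical)


class TestKmOnset:
    def test_excludes_baseline_depressed(self):
        records = [
            make_record(0, baseline_state="depressed", onset_day=14,
                        episode_count=1, first_episode_duration_days=100,
                        first_episode_censored=False),
            make_record(1, onset_day=100, episode_count=1,
                        first_episode_duration_days=10,
                        first_episode_censored=False),
            make_record(2),
        ]
        curve = km_onset(records)
        assert curve.n_subjects == 2
        assert curve.survival_at(100) == pytest.approx(1 / 2)

    def test_all_event_free_survival_one(self):
        curve = km_onset([make_record(i) for i in range(4)])
        assert curve.survival_at(3652) == 1.0

    def test_empty_after_exclusion_raises(self):
        with pytest.raises(ValueError, match="exclusion"):
            km_onset([make_record(0, baseline_state="depressed")])


class TestDecliningIncidence:
    def test_constant_hazard_ratio_near_one(self):
        # exponential onset times have a flat hazard: ratio should be ~1
        rng = np.random.default_rng(0)
        onsets = np.ceil(rng.exponential(scale=5000, size=10_000)).astype(int)
        observed = onsets <= 3652
        durations = np.where(observed, onsets, 3652)
        curve = kaplan_meier(durations, observed)
        stat = declining_incidence_stat(curve)
        assert 0.8 < stat.ratio < 1.25
        assert not stat.undefined

    def test_no_late_events_flagged_infinite(self):
        durations = [100, 200, 3652, 3652]
        observed = [True, True, False, False]
        stat = declining_incidence_stat(kaplan_meier(durations, observed))
        assert math.isinf(stat.ratio)
        assert stat.declining

    def test_no_events_flagged_undefined(self):
        stat = declining_incidence_stat(
            kaplan_meier([3652, 3652], [False, False])
        )
        assert stat.undefined
        assert math.isnan(stat.ratio)

    def test_hazard_window_validation(self):
        curve = kaplan_meier([10], [True])
        with pytest.raises(ValueError, match="window"):
            hazard_in_window(curve, 10, 5)


class TestRecurrenceByHistory:
    def test_no_episodes_single_zero_row(self):
        table = recurrence_by_history([make_record(i) for i in range(5)])
        assert len(table) == 1
        assert table.loc[0, "prior_episodes"] == 0
        assert table.loc[0, "proportion"] == 0.0

    def test_hand_built_six_agent_fixture(self):
        records = [
            make_record(0),
            make_record(1, episode_count=1, onset_day=50, episodes_years_1_9=1,
                        first_episode_duration_days=5,
                        first_episode_censored=False),
            make_record(2, episode_count=1, onset_day=50, episodes_years_1_9=1,
                        episode_in_year_10=True,
                        first_episode_duration_days=5,
                        first_episode_censored=False),
            make_record(3, episode_count=2, onset_day=50, episodes_years_1_9=2,
                        episode_in_year_10=True,
                        first_episode_duration_days=5,
                        first_episode_censored=False),
            make_record(4, episode_count=7, onset_day=50, episodes_years_1_9=6,
                        episode_in_year_10=True,
                        episode_starting_in_year_10=True,
                        first_episode_duration_days=5,
                        first_episode_censored=False),
            make_record(5, episode_count=6, onset_day=50, episodes_years_1_9=6,
                        first_episode_duration_days=5,
                        first_episode_censored=False),
        ]
        table = recurrence_by_history(records, top_bin=5)
        expected = pd.DataFrame(
            {
                "prior_episodes": [0, 1, 2, 5],
                "n_agents": [1, 2, 1, 2],
                "n_with_year10_episode": [0, 1, 1, 1],
                "proportion": [0.0, 0.5, 1.0, 0.5],
            }
        )
        pd.testing.assert_frame_equal(table, expected)
        strict = recurrence_by_history(records, top_bin=5, count_ongoing=False)
        assert strict["n_with_year10_episode"].tolist() == [0, 0, 0, 1]

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            recurrence_by_history([])


class TestOnsetByBaseline:
    def test_fixture_strata(self):
        records = [
            make_record(0, baseline_symptoms=8.0, baseline_state="elevated",
                        onset_day=50, episode_count=1,
                        first_episode_duration_days=5,
                        first_episode_censored=False),
            make_record(1, baseline_symptoms=7.0, baseline_state="elevated",
                        onset_day=60, episode_count=1,
                        first_episode_duration_days=5,
                        first_episode_censored=False),
            make_record(2, baseline_symptoms=2.0),
            make_record(3, baseline_symptoms=3.0),
        ]
        curves = onset_by_baseline_symptoms(records, elevated_cut=6.0)
        assert curves["elevated"].survival_at(60) == pytest.approx(0.0)
        assert curves["low"].survival_at(3652) == 1.0

    def test_empty_stratum_omitted(self):
        curves = onset_by_baseline_symptoms(
            [make_record(0, baseline_symptoms=2.0)], elevated_cut=6.0
        )
        assert curves["elevated"] is None
        assert curves["low"] is not None


class TestRecoveryCurve:
    def test_all_same_duration_jumps_to_one(self):
        records = [
            make_record(i, episode_count=1, onset_day=50,
                        first_episode_duration_days=10,
                        first_episode_censored=False)
            for i in range(5)
        ]
        curve = recovery_curve(records)
        assert curve.survival_at(9) == 1.0
        assert curve.survival_at(10) == 0.0

    def test_hand_fixture_with_censoring(self):
        # durations 30 and 60 remitted, one still open at 45:
        # S(30) = 2/3, S(60) = 2/3 * (1 - 1/1) = 0
        records = [
            make_record(0, episode_count=1, onset_day=50,
                        first_episode_duration_days=30,
                        first_episode_censored=False),
            make_record(1, episode_count=1, onset_day=50,
                        first_episode_duration_days=60,
                        first_episode_censored=False),
            make_record(2, episode_count=1, onset_day=3600,
                        first_episode_duration_days=45,
                        first_episode_censored=True),
        ]
        curve = recovery_curve(records)
        np.testing.assert_array_equal(curve.time_points, [30, 60])
        np.testing.assert_allclose(curve.survival, [2 / 3, 0.0])
        uncensored = recovery_curve(records, uncensored_only=True)
        assert uncensored.n_subjects == 2
        table = monthly_recovery_table(curve, n_months=3)
        assert table.loc[0, "proportion_unrecovered"] == pytest.approx(2 / 3)
        assert table.loc[2, "cumulative_recovery"] == pytest.approx(1.0)

    def test_no_episodes_rejected(self):
        with pytest.raises(ValueError, match="first episodes"):
            recovery_curve([make_record(0)])


class TestSummarizeCohort:
    def test_counts_and_duration_conventions(self):
        records = [
            make_record(0),
            make_record(1, episode_count=2, onset_day=50, episodes_years_1_9=2,
                        first_episode_duration_days=100,
                        first_episode_censored=False),
            make_record(2, episode_count=1, onset_day=3600,
                        first_episode_duration_days=53,
                        first_episode_censored=True),
        ]
        summary = summarize_cohort(records)
        assert summary["cumulative_incidence"] == pytest.approx(2 / 3)
        assert summary["mean_episode_count_affected"] == pytest.approx(1.5)
        # headline duration counts the open episode at its truncated length
        assert summary["mean_first_episode_duration_days"] == pytest.approx(76.5)
        assert summary["mean_first_episode_duration_uncensored"] == pytest.approx(100)
        assert summary["n_censored_first_episodes"] == 1

    def test_no_affected_agents(self):
        summary = summarize_cohort([make_record(0)])
        assert summary["cumulative_incidence"] == 0
        assert math.isnan(summary["mean_episode_count_affected"])


class TestParameterSweep:
    BASE = SimConfig(n_agents=400, horizon_days=1200, seed=21)

    def test_single_cell_matches_direct_simulation(self):
        table = parameter_sweep(self.BASE, {"threshold": [15.0]})
        direct = summarize_cohort(simulate_cohort(self.BASE))
        assert len(table) == 1
        assert table.loc[0, "cumulative_incidence"] == pytest.approx(
            direct["cumulative_incidence"]
        )

    def test_threshold_monotone_on_identical_traces(self):
        table = parameter_sweep(self.BASE, {"threshold": [15.0, 20.0]})
        inc = table.set_index("value")["cumulative_incidence"]
        assert inc[20.0] <= inc[15.0]

    def test_adaptation_constant_monotone(self):
        table = parameter_sweep(
            self.BASE, {"adaptation_constant": [0.0, 3.0]}
        )
        inc = table.set_index("value")["cumulative_incidence"]
        assert inc[0.0] <= inc[3.0]

    def test_cell_failure_recorded_and_sweep_continues(self):
        table = parameter_sweep(self.BASE, {"threshold": [-1.0, 15.0]})
        assert table.loc[0, "error"] != ""
        assert table.loc[1, "error"] == ""
        assert table.loc[1, "cumulative_incidence"] >= 0

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            parameter_sweep(self.BASE, {})
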