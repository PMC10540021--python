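"""Schedules, latent trajectories, respondent simulation and study runs."""

from datetime import datetime

import numpy as np
import pandas as pd
import pytest

from promcat import (
    CATConfig,
    Intervention,
    NormalPrior,
    ScheduleRegime,
    SimulatedRespondent,
    StudyConfigError,
    TrajectoryProfile,
    category_probabilities,
    compare_cat_full_length,
    error_statistics,
    generate_schedule,
    latent_theta_at,
    run_study,
    simulate_response,
    summarize_study,
)

START = datetime(2022, 7, 13)


class TestSchedules:
    @pytest.mark.parametrize(
        "kind,weeks,expected",
        [
            ("thrice_weekly", 12, 36),
            ("daily", 12, 84),
            ("thrice_daily", 12, 252),
            ("daily", 1, 7),
        ],
    )
    def test_occasion_counts(self, kind, weeks, expected):
        occ = generate_schedule(ScheduleRegime(kind=kind, start=START, weeks=weeks))
        assert len(occ) == expected
        assert occ == sorted(occ)

    def test_thrice_weekly_lands_on_configured_weekdays(self):
        occ = generate_schedule(ScheduleRegime(kind="thrice_weekly", start=START, weeks=1))
        assert len(occ) == 3
        assert {t.weekday() for t in occ} == {0, 2, 4}  # Mon/Wed/Fri
        assert all(t.hour == 9 for t in occ)

    def test_thrice_daily_clock_times(self):
        occ = generate_schedule(ScheduleRegime(kind="thrice_daily", start=START, weeks=1))
        assert [t.hour for t in occ[:3]] == [9, 14, 20]

    def test_zero_duration_empty(self):
        assert generate_schedule(ScheduleRegime(kind="daily", start=START, weeks=0)) == []

    def test_counts_independent_of_start_weekday(self):
        # any 7-day block contains each weekday once
        for day in range(13, 20):
            occ = generate_schedule(
                ScheduleRegime(kind="thrice_weekly", start=datetime(2022, 7, day), weeks=2)
            )
            assert len(occ) == 6


class TestTrajectories:
    def test_recovery_starts_at_baseline(self):
        p = TrajectoryProfile(kind="recovery", baseline=1.5, recovery_rate=0.1, asymptote=-1.0)
        assert latent_theta_at(p, 0.0) == pytest.approx(1.5)

    def test_recovery_limits_to_asymptote(self):
        p = TrajectoryProfile(kind="recovery", baseline=1.5, recovery_rate=0.1, asymptote=-1.0)
        assert latent_theta_at(p, 1e4) == pytest.approx(-1.0, abs=1e-9)

    def test_recovery_monotone_decreasing(self):
        p = TrajectoryProfile(kind="recovery", baseline=1.0, recovery_rate=0.05, asymptote=-0.5)
        vals = [latent_theta_at(p, d) for d in range(0, 84, 7)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_intervention_dip_and_rebound(self):
        p = TrajectoryProfile(
            kind="fluctuating",
            baseline=1.0,
            diurnal_amplitude=0.0,
            noise_scale=0.0,
            intervention=Intervention(at_day=30.0, depth=1.2, rebound_days=10.0),
        )
        days = np.linspace(0, 84, 3000)
        vals = np.array([latent_theta_at(p, float(d)) for d in days])
        t_min = days[np.argmin(vals)]
        assert 30.0 < t_min <= 40.0
        end_val = latent_theta_at(p, 40.0)
        assert abs(end_val - 1.0) <= 0.1 * abs(1.0)

    def test_diurnal_variation_peaks_at_configured_hour(self):
        p = TrajectoryProfile(
            kind="fluctuating", baseline=0.0, diurnal_amplitude=0.5,
            diurnal_peak_hour=17.0, noise_scale=0.0,
        )
        hours = np.arange(0, 24, 0.25)
        vals = np.array([latent_theta_at(p, h / 24.0) for h in hours])
        assert hours[np.argmax(vals)] == pytest.approx(17.0)
        assert vals.max() == pytest.approx(0.5)

    def test_noise_deterministic_given_seed(self):
        kw = dict(kind="fluctuating", baseline=0.5, noise_scale=0.3, noise_seed=99)
        p1, p2 = TrajectoryProfile(**kw), TrajectoryProfile(**kw)
        days = [3.2, 17.9, 60.4]
        assert [latent_theta_at(p1, d) for d in days] == [latent_theta_at(p2, d) for d in days]

    def test_timestamp_evaluation_needs_start(self):
        p = TrajectoryProfile(kind="recovery", baseline=1.0)
        with pytest.raises(ValueError, match="start"):
            latent_theta_at(p, pd.Timestamp("2022-08-01"))
        v = latent_theta_at(p, pd.Timestamp("2022-07-14"), start=START)
        assert v == pytest.approx(latent_theta_at(p, 1.0))


class TestSimulateResponse:
    def test_degenerate_limit_top_category(self, four_cat_item):
        from promcat import ItemParameters

        steep = ItemParameters("s", a=50.0, thresholds=(-1.0, 0.0, 1.0))
        rng = np.random.default_rng(0)
        draws = {simulate_response(5.0, steep, rng) for _ in range(50)}
        assert draws == {4}

    def test_frequencies_match_model(self, four_cat_item):
        rng = np.random.default_rng(1)
        n = 20_000
        counts = np.zeros(4)
        for _ in range(n):
            counts[simulate_response(0.3, four_cat_item, rng) - 1] += 1
        p = category_probabilities(0.3, four_cat_item)
        se = np.sqrt(p * (1 - p) / n)
        np.testing.assert_array_less(np.abs(counts / n - p), 3 * se + 1e-12)

    def test_reproducible_with_seed(self, four_cat_item):
        a = simulate_response(0.0, four_cat_item, np.random.default_rng(5))
        b = simulate_response(0.0, four_cat_item, np.random.default_rng(5))
        assert a == b


def _cohort(n, kind="daily", weeks=1, compliance=1.0, noise=0.0):
    cohort, regimes = [], {}
    for i in range(n):
        rid = f"p{i}"
        cohort.append(
            SimulatedRespondent(
                respondent_id=rid,
                profile=TrajectoryProfile(
                    kind="fluctuating", baseline=0.3, diurnal_amplitude=0.1,
                    noise_scale=noise, noise_seed=i,
                ),
                compliance=compliance,
                seed=i,
            )
        )
        regimes[rid] = ScheduleRegime(kind=kind, start=START, weeks=weeks)
    return cohort, regimes


class TestRunStudy:
    def test_full_compliance_completes_every_occasion(self, bank):
        cohort, regimes = _cohort(2, weeks=1, compliance=1.0)
        result = run_study(cohort, bank, CATConfig(), regimes, seed=0)
        assert len(result.assessments) == 14
        assert result.scheduled == {"p0": 7, "p1": 7}

    def test_zero_compliance_completes_nothing(self, bank):
        cohort, regimes = _cohort(1, weeks=1, compliance=0.0)
        result = run_study(cohort, bank, CATConfig(), regimes, seed=0)
        assert len(result.assessments) == 0
        summary = summarize_study(result)
        assert summary.response_rates["p0"] == 0.0

    def test_reproducible_given_master_seed(self, bank):
        cohort1, regimes1 = _cohort(2, weeks=1, compliance=0.8, noise=0.2)
        cohort2, regimes2 = _cohort(2, weeks=1, compliance=0.8, noise=0.2)
        r1 = run_study(cohort1, bank, CATConfig(), regimes1, seed=11)
        r2 = run_study(cohort2, bank, CATConfig(), regimes2, seed=11)
        pd.testing.assert_frame_equal(r1.response_log, r2.response_log)
        pd.testing.assert_frame_equal(r1.assessments, r2.assessments)
        pd.testing.assert_frame_equal(r1.full_length, r2.full_length)

    def test_config_mismatch_errors(self, bank):
        cohort, regimes = _cohort(2, weeks=1)
        with pytest.raises(StudyConfigError, match="without a regime"):
            run_study(cohort, bank, CATConfig(), {"p0": regimes["p0"]}, seed=0)
        bad = dict(regimes)
        bad["ghost"] = regimes["p0"]
        with pytest.raises(StudyConfigError, match="unknown"):
            run_study(cohort, bank, CATConfig(), bad, seed=0)

    def test_dynamic_priors_no_less_efficient_than_static(self, bank):
        """With a flat trajectory, carrying the posterior forward should not
        increase the items needed per assessment (paired seeds)."""
        means = {}
        for policy in ("dynamic", "static"):
            cohort, regimes = _cohort(3, weeks=2, compliance=1.0, noise=0.0)
            result = run_study(
                cohort, bank, CATConfig(), regimes, seed=5, prior_policy=policy
            )
            means[policy] = result.assessments["n_items"].mean()
        assert means["dynamic"] <= means["static"]

    def test_full_length_records_at_scheduled_weeks(self, bank):
        cohort, regimes = _cohort(1, weeks=2, compliance=1.0)
        result = run_study(cohort, bank, CATConfig(), regimes, seed=3,
                           full_length_weeks=(0, 1))
        assert len(result.full_length) == 2
        assert set(result.full_length["n_items"]) == {len(bank)}


class TestSummarizeStudy:
    def test_response_rate_and_exposure_conservation(self, bank):
        cohort, regimes = _cohort(3, weeks=2, compliance=0.85, noise=0.2)
        result = run_study(cohort, bank, CATConfig(), regimes, seed=2)
        summary = summarize_study(result)
        for pid, rate in summary.response_rates.items():
            n_completed = (result.assessments["participant_id"] == pid).sum()
            assert rate == pytest.approx(n_completed / result.scheduled[pid])
            assert 0.0 <= rate <= 1.0
        assert sum(summary.exposure_counts.values()) == int(
            result.assessments["n_items"].sum()
        )
        lo, hi = summary.items_range
        assert lo <= summary.items_median <= hi

    def test_constant_item_count_summary(self, bank):
        from promcat.ema import StudyResult

        assess = pd.DataFrame(
            {
                "participant_id": ["p0"] * 4,
                "assessment_id": [f"a{i}" for i in range(4)],
                "timestamp": pd.date_range("2022-07-13", periods=4),
                "eap": [0.0] * 4,
                "se": [0.3] * 4,
                "ci_low": [-0.6] * 4,
                "ci_high": [0.6] * 4,
                "n_items": [2] * 4,
                "termination_reason": ["se_met"] * 4,
            }
        )
        log = pd.DataFrame(
            {
                "participant_id": ["p0"] * 8,
                "assessment_id": np.repeat([f"a{i}" for i in range(4)], 2),
                "scheduled_time": pd.to_datetime(["2022-07-13"] * 8),
                "response_time": pd.to_datetime(["2022-07-13 01:00"] * 8),
                "item_id": ["item01", "item02"] * 4,
                "category": [3] * 8,
                "step_eap": [0.0] * 8,
                "step_se": [0.5] * 8,
            }
        )
        result = StudyResult(
            response_log=log, assessments=assess, full_length=assess.iloc[:0],
            scheduled={"p0": 10}, start=START,
        )
        s = summarize_study(result)
        assert s.items_median == 2 and s.items_range == (2, 2)
        assert s.response_rates["p0"] == pytest.approx(0.4)
        assert s.median_delay_minutes == pytest.approx(60.0)

    def test_empty_logs_rejected(self, bank):
        from promcat.ema import StudyResult, _LOG_COLUMNS, _SUMMARY_COLUMNS

        empty = StudyResult(
            response_log=pd.DataFrame(columns=_LOG_COLUMNS),
            assessments=pd.DataFrame(columns=_SUMMARY_COLUMNS),
            full_length=pd.DataFrame(columns=_SUMMARY_COLUMNS),
            scheduled={},
            start=START,
        )
        with pytest.raises(ValueError, match="empty"):
            summarize_study(empty)


class TestCompare:
    def test_error_statistics_arithmetic(self):
        stats = error_statistics(np.array([0.5, -0.5]), np.array([0.4, -0.4]))
        assert stats.mean_error == pytest.approx(0.0)
        assert stats.mae == pytest.approx(0.1)
        assert stats.rmse == pytest.approx(0.1)

    def test_identical_scores_flag_undefined_correlation(self):
        stats = error_statistics(np.array([0.2, 0.2]), np.array([0.2, 0.2]))
        assert stats.mean_error == 0.0 and stats.mae == 0.0
        assert np.isnan(stats.correlation)

    def test_no_pairs_rejected(self):
        with pytest.raises(ValueError):
            error_statistics(np.array([]), np.array([]))

    def test_same_day_pairing_from_study(self, bank):
        cohort, regimes = _cohort(2, weeks=2, compliance=1.0)
        result = run_study(cohort, bank, CATConfig(), regimes, seed=4)
        stats = compare_cat_full_length(result.assessments, result.full_length)
        assert stats.n_pairs == len(result.full_length)
        assert stats.mae < 1.0  # same-day latent values: scores agree loosely

    def test_empty_inputs_rejected(self, bank):
        with pytest.raises(ValueError):
            compare_cat_full_length(pd.DataFrame(), pd.DataFrame())
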