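"""Trial scoring and the behavioral analysis battery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from chickvision import behavior as beh
from chickvision.stimuli import FAMILIAR_RANGE_ID, range_center
from chickvision.synthetic_behavior import (
    CohortParams,
    elevation_gradient_effects,
    simulate_trials,
)


def _trial(subject="s1", day=1, idx=1, kind="test", rid=1, ti=100.0, tu=50.0):
    az, el = range_center(rid) if rid else (0.0, 0.0)
    return dict(
        subject_id=subject,
        day=day,
        trial_index=idx,
        trial_kind=kind,
        viewpoint_range_id=rid,
        azimuth_center=az,
        elevation=el,
        is_familiar_range=int(rid == FAMILIAR_RANGE_ID),
        time_imprinted_s=ti,
        time_unfamiliar_s=tu,
    )


class TestTrialScoring:
    @pytest.mark.parametrize(
        "ti,tu,expected",
        [(300.0, 100.0, "correct"), (100.0, 100.0, "incorrect"), (0.0, 0.0, "undefined")],
    )
    def test_score_rule(self, ti, tu, expected):
        assert beh.score_trial(_trial(ti=ti, tu=tu)) == expected

    def test_preference_value(self):
        assert beh.preference_score(300.0, 100.0) == pytest.approx(75.0)
        assert beh.preference_score(0.0, 0.0) is None

    def test_rest_trials_rejected(self):
        with pytest.raises(ValueError):
            beh.score_trial(_trial(kind="rest"))

    @given(
        st.floats(0.1, 1000.0),
        st.floats(0.1, 1000.0),
        st.floats(0.01, 100.0),
    )
    def test_correctness_invariant_to_common_rescale(self, ti, tu, k):
        base = beh.score_trial(_trial(ti=ti, tu=tu))
        scaled = beh.score_trial(_trial(ti=k * ti, tu=k * tu))
        assert base == scaled

    def test_preference_bounds(self):
        df = pd.DataFrame([_trial(ti=a, tu=b) for a, b in
                           [(0, 1), (1, 0), (5, 5), (1000, 0.1)]])
        scored = beh.add_trial_scores(df)
        assert scored["preference"].between(0.0, 100.0).all()


class TestSubjectAndGroup:
    def test_perfect_week_binomial(self):
        df = pd.DataFrame([_trial(idx=i, ti=200, tu=10) for i in range(1, 8)])
        s = beh.subject_summary(df, "s1")
        assert (s.n_correct, s.n_trials) == (7, 7)
        assert s.binomial_p == pytest.approx(0.0078125)

    def test_familiar_exclusion_and_undefined_count(self):
        rows = [_trial(idx=1, rid=FAMILIAR_RANGE_ID, ti=200, tu=10),
                _trial(idx=2, rid=1, ti=10, tu=200),
                _trial(idx=3, rid=2, ti=0, tu=0)]
        df = pd.DataFrame(rows)
        s_all = beh.subject_summary(df, "s1")
        assert (s_all.n_correct, s_all.n_trials, s_all.n_undefined) == (1, 2, 1)
        s_exc = beh.subject_summary(df, "s1", exclude_familiar=True)
        assert (s_exc.n_correct, s_exc.n_trials) == (0, 1)

    def test_no_defined_trials_raises(self):
        df = pd.DataFrame([_trial(ti=0, tu=0)])
        with pytest.raises(ValueError):
            beh.subject_summary(df, "s1")

    def test_group_mean_and_sem_hand_case(self):
        rows = []
        # two subjects: 40% and 80% correct over 5 trials each
        for sid, n_corr in (("a", 2), ("b", 4)):
            for i in range(5):
                good = i < n_corr
                rows.append(_trial(subject=sid, idx=i,
                                   ti=200 if good else 10,
                                   tu=10 if good else 200))
        mean, sem = beh.group_performance(pd.DataFrame(rows))
        assert mean == pytest.approx(60.0)
        assert sem == pytest.approx(20.0)

    def test_all_perfect(self):
        rows = [_trial(subject=s, idx=i, ti=100, tu=1)
                for s in ("a", "b", "c") for i in range(4)]
        mean, sem = beh.group_performance(pd.DataFrame(rows))
        assert (mean, sem) == (100.0, 0.0)


class TestRestPeriods:
    def test_all_near_imprint(self):
        df = pd.DataFrame([_trial(kind="rest", rid=0, idx=i, ti=100, tu=1)
                           for i in range(10)])
        res = beh.rest_period_check(df)
        assert res.loc[0, "proportion_near_imprint"] == 1.0
        assert res.loc[0, "imprinting_ok"]

    def test_chance_level_flagged(self):
        rows = [_trial(kind="rest", rid=0, idx=i,
                       ti=100 if i % 2 else 1, tu=1 if i % 2 else 100)
                for i in range(20)]
        res = beh.rest_period_check(pd.DataFrame(rows))
        assert res.loc[0, "binomial_p"] > 0.5
        assert not res.loc[0, "imprinting_ok"]

    def test_no_rest_trials_raises(self):
        with pytest.raises(ValueError):
            beh.rest_period_check(pd.DataFrame([_trial()]))


class TestViewpointMap:
    def test_perfect_subjects_fill_map(self):
        rows = [_trial(subject=s, idx=r, rid=r, ti=100, tu=1)
                for s in ("a", "b") for r in range(1, 28)]
        vm = beh.viewpoint_map(pd.DataFrame(rows))
        assert len(vm) == 27
        assert (vm["percent_correct"] == 100.0).all()

    def test_missing_range_is_nan_not_error(self):
        rows = [_trial(rid=r, idx=r, ti=100, tu=1) for r in range(1, 27)]  # no 27
        vm = beh.viewpoint_map(pd.DataFrame(rows))
        assert np.isnan(vm.loc[vm.viewpoint_range_id == 27, "percent_correct"]).all()

    def test_planted_elevation_gradient_recovered(self):
        params = CohortParams(seed=3, range_effects=elevation_gradient_effects(0.02),
                              subject_sd=0.0)
        vm = beh.viewpoint_map(simulate_trials(params))
        r = np.corrcoef(vm["elevation"], vm["percent_correct"])[0, 1]
        assert r > 0.7


class TestViewpointEffects:
    def test_flat_profile_near_zero(self):
        params = CohortParams(seed=4, range_effects=None, subject_sd=0.0)
        res = beh.elevation_magnitude_correlation(simulate_trials(params))
        assert res.df == 3  # 5 magnitudes -> n-2
        assert abs(res.r) < 0.9  # no systematic magnitude effect

    def test_planted_magnitude_decline(self):
        effects = np.array(
            [-0.02 * abs(range_center(rid)[1]) for rid in range(1, 28)]
        )
        params = CohortParams(seed=5, range_effects=effects, subject_sd=0.0)
        res = beh.elevation_magnitude_correlation(simulate_trials(params))
        assert res.r < -0.8

    def test_foreground_correlation_recovers_planted_dependence(self):
        counts = {rid: 1000.0 + 40.0 * range_center(rid)[1] for rid in range(1, 28)}
        effects = elevation_gradient_effects(0.02)  # performance tracks elevation
        params = CohortParams(seed=6, range_effects=effects, subject_sd=0.0)
        trials = simulate_trials(params)
        res = beh.foreground_correlation(trials, counts)
        assert res.r > 0.5

    def test_foreground_missing_range_raises(self, default_cohort):
        with pytest.raises(ValueError):
            beh.foreground_correlation(default_cohort, {1: 100.0})


class TestSubjectCorrelations:
    def test_identical_profiles(self):
        rows = [_trial(subject=s, idx=r, rid=r, ti=ti, tu=100.0 - ti)
                for s in ("a", "b", "c")
                for r, ti in ((r, 30.0 + 2.0 * r) for r in range(1, 28))]
        res = beh.subject_correlation_matrix(pd.DataFrame(rows))
        assert res.mean_r == pytest.approx(1.0)
        assert (np.diag(res.matrix.to_numpy()) == 1.0).all()

    def test_ten_subjects_give_45_pairs(self, default_cohort):
        res = beh.subject_correlation_matrix(default_cohort)
        assert res.pair_r.size == 45
        assert res.t_test.df == 44
        m = res.matrix.to_numpy()
        assert np.allclose(m, m.T, equal_nan=True)
        assert sorted(res.cluster_order) == sorted(res.subjects)

    def test_constant_profile_subject_excluded(self):
        rows = [_trial(subject=s, idx=r, rid=r, ti=ti, tu=100.0 - ti)
                for s in ("a", "b", "c")
                for r, ti in ((r, 30.0 + 2.0 * r) for r in range(1, 28))]
        rows += [_trial(subject="flat", idx=r, rid=r, ti=60.0, tu=40.0)
                 for r in range(1, 28)]
        res = beh.subject_correlation_matrix(pd.DataFrame(rows))
        assert res.excluded_subjects == ("flat",)
        assert res.pair_r.size == 3  # only the 3 defined pairs

    def test_shared_range_effects_raise_mean_r(self):
        weak = CohortParams(seed=7, range_effects=elevation_gradient_effects(0.004))
        strong = CohortParams(seed=7, range_effects=elevation_gradient_effects(0.025))
        r_weak = beh.subject_correlation_matrix(simulate_trials(weak)).mean_r
        r_strong = beh.subject_correlation_matrix(simulate_trials(strong)).mean_r
        assert r_strong > r_weak


class TestDailyPerformance:
    def test_identical_days_give_zero_F(self):
        rows = [_trial(subject=s, day=d, idx=r, rid=r,
                       ti=100 if r % 2 else 10, tu=10 if r % 2 else 100)
                for s in ("a", "b") for d in range(1, 8) for r in range(1, 28)]
        daily, anova = beh.daily_performance(pd.DataFrame(rows))
        assert anova.F == pytest.approx(0.0)
        assert anova.df_between == 6

    def test_stationary_cohort_df_and_stability(self, default_cohort):
        daily, anova = beh.daily_performance(default_cohort)
        assert len(daily) == 7
        assert (anova.df_between, anova.df_within) == (6, 63)
        assert anova.p_value > 0.001  # no planted day effect

    def test_planted_day1_deficit_detected(self):
        params = CohortParams(seed=8, subject_sd=0.0)
        trials = simulate_trials(params)
        # degrade day 1 to chance-minus
        d1 = trials.index[(trials.day == 1) & (trials.trial_kind == "test")]
        rng = np.random.default_rng(0)
        flip = rng.random(len(d1)) < 0.8
        ti = trials.loc[d1, "time_imprinted_s"].to_numpy()
        tu = trials.loc[d1, "time_unfamiliar_s"].to_numpy()
        trials.loc[d1, "time_imprinted_s"] = np.where(flip, np.minimum(ti, tu), ti)
        trials.loc[d1, "time_unfamiliar_s"] = np.where(flip, np.maximum(ti, tu), tu)
        _, anova = beh.daily_performance(trials)
        assert anova.p_value < 0.01


class TestFamiliarRangeControl:
    def test_planted_preference_recovered(self):
        params = CohortParams(seed=9, fixed_intercept=1.5)
        res = beh.familiar_range_control(simulate_trials(params))
        assert res["n_trials"] == 70  # 10 subjects x 7 familiar trials
        assert res["logistic"].b > 0
        assert res["logistic"].p_value < 0.05
        assert res["linear"].b > 0

    def test_symmetric_behavior_near_zero(self):
        params = CohortParams(seed=10, fixed_intercept=0.0, subject_sd=0.0,
                              range_effects=None)
        res = beh.familiar_range_control(simulate_trials(params))
        assert abs(res["linear"].b) < 0.1

    def test_saturated_correctness_flagged(self):
        params = CohortParams(seed=12, fixed_intercept=10.0, subject_sd=0.0)
        res = beh.familiar_range_control(simulate_trials(params))
        assert not res["logistic"].converged  # complete separation


class TestRegression:
    def test_constant_preference_zero_slope(self):
        rng = np.random.default_rng(13)
        res = beh.regress_preference_on_difference(
            np.full(54, 62.0), rng.random(54)
        )
        assert res.slope == pytest.approx(0.0, abs=1e-9)

    def test_54_conditions_df(self):
        rng = np.random.default_rng(14)
        x = rng.random(54)
        y = 60 - 5 * x + rng.normal(0, 1, 54)
        res = beh.regress_preference_on_difference(y, x)
        assert res.df == 52
        assert res.slope < 0


class TestTrialIO:
    def test_csv_round_trip(self, tmp_path, default_cohort):
        path = tmp_path / "trials.csv"
        beh.write_trials(default_cohort, path)
        back = beh.read_trials(path)
        pd.testing.assert_frame_equal(
            back[beh.TRIAL_COLUMNS], default_cohort[beh.TRIAL_COLUMNS],
            check_dtype=False,
        )

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"subject_id": ["a"]}).to_csv(path, index=False)
        with pytest.raises(ValueError):
            beh.read_trials(path)
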