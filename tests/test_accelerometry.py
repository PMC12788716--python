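"""Minute classification, wear validity, weekly summaries and PA patterns."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pa_optim.accelerometry import (
    ActivityWeek,
    Cutpoints,
    InvalidWearError,
    MINUTES_PER_DAY,
    PAPattern,
    WeeklySummary,
    classify_minutes,
    classify_pattern,
    lpa_dose_response,
    rcs_basis,
    summarize_week,
    wear_valid,
)
from pa_optim.synthetic import ActivityTarget, generate_activity_week


def make_week(values, wear=None, dialect="nhanes", start="2023-01-02"):
    n = len(values)
    if wear is None:
        wear = [True] * n
    return ActivityWeek(
        participant_id="P0",
        data=pd.DataFrame(
            {
                "timestamp": pd.Timestamp(start) + pd.to_timedelta(np.arange(n), unit="min"),
                "value": np.asarray(values, dtype=float),
                "wear": np.asarray(wear, dtype=bool),
            }
        ),
        dialect=dialect,
    )


class TestClassifyMinutes:
    def test_waist_cutpoint_boundaries(self):
        week = make_week([99, 100, 2019, 2020, 0])
        labels = classify_minutes(week, Cutpoints.nhanes())
        assert list(labels) == ["sedentary", "lpa", "lpa", "mvpa", "sedentary"]

    def test_all_zero_worn_week_is_sedentary(self):
        week = make_week([0] * 100)
        assert (classify_minutes(week, Cutpoints.nhanes()) == "sedentary").all()

    def test_nonworn_minutes_are_nonwear(self):
        week = make_week([3000, 3000], wear=[True, False])
        assert list(classify_minutes(week, Cutpoints.nhanes())) == ["mvpa", "nonwear"]

    @pytest.mark.parametrize("lo,hi", [(30.0, 100.0), (45.0, 93.0)])
    def test_wrist_boundaries_for_any_cutpoints(self, lo, hi):
        cp = Cutpoints.wrist(lo, hi)
        week = make_week([lo - 1e-6, lo, hi - 1e-6, hi], dialect="wrist")
        labels = list(classify_minutes(week, cp))
        assert labels == ["sedentary", "lpa", "lpa", "mvpa"]

    def test_dialect_mismatch_rejected(self):
        week = make_week([0], dialect="wrist")
        with pytest.raises(ValueError, match="dialect"):
            classify_minutes(week, Cutpoints.nhanes())


class TestWearValidity:
    def test_full_week_valid_under_ukb(self):
        week = make_week([50] * (7 * MINUTES_PER_DAY))
        assert wear_valid(week, "ukb") is True

    def test_71_hours_spread_over_clock_fails_72h_rule(self):
        # 71 h worn, covering every clock hour, still below the 72 h floor
        n = 7 * MINUTES_PER_DAY
        wear = np.zeros(n, dtype=bool)
        wear[: 71 * 60] = True
        week = make_week([50] * n, wear=wear)
        assert wear_valid(week, "ukb") is False

    def test_single_600_minute_day_valid_under_nhanes(self):
        wear = [True] * 600 + [False] * 840
        week = make_week([50] * MINUTES_PER_DAY, wear=wear)
        assert wear_valid(week, "nhanes") is True

    def test_long_zero_run_recoded_nonwear_under_nhanes(self):
        # 600 worn minutes but 100 of them are a zero-count run > 60 min:
        # the run is recoded nonwear, leaving < 600, so the day is invalid
        values = [50] * 500 + [0] * 100 + [50] * 840
        wear = [True] * 600 + [False] * 840
        week = make_week(values, wear=wear)
        assert wear_valid(week, "nhanes") is False

    def test_empty_week_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            wear_valid(make_week([]), "ukb")


class TestSummarizeWeek:
    def test_mvpa_by_day_arithmetic(self):
        # MVPA minutes per day (120, 60, 5, 5, 5, 5, 0)
        per_day = [120, 60, 5, 5, 5, 5, 0]
        values = np.full(7 * MINUTES_PER_DAY, 50.0)
        for d, m in enumerate(per_day):
            values[d * MINUTES_PER_DAY : d * MINUTES_PER_DAY + m] = 3000.0
        s = summarize_week(make_week(values), Cutpoints.nhanes())
        assert s.mvpa_min_week == 200
        assert s.top2_share == pytest.approx(0.90)

    def test_no_mvpa_gives_zero_share(self):
        s = summarize_week(make_week([50] * MINUTES_PER_DAY), Cutpoints.nhanes())
        assert s.mvpa_min_week == 0 and s.top2_share == 0.0

    def test_permutation_invariant_within_days(self):
        rng = np.random.default_rng(0)
        values = np.full(7 * MINUTES_PER_DAY, 50.0)
        values[rng.choice(7 * MINUTES_PER_DAY, 300, replace=False)] = 3000.0
        week = make_week(values)
        shuffled = values.copy()
        for d in range(7):
            sl = slice(d * MINUTES_PER_DAY, (d + 1) * MINUTES_PER_DAY)
            shuffled[sl] = rng.permutation(shuffled[sl])
        s1 = summarize_week(week, Cutpoints.nhanes())
        s2 = summarize_week(make_week(shuffled), Cutpoints.nhanes())
        assert s1 == s2

    def test_generator_round_trip(self):
        cp = Cutpoints.nhanes()
        target = ActivityTarget(mvpa_min_week=200, lpa_min_week=400, top2_share=0.9)
        s = summarize_week(generate_activity_week(target, cp, seed=3), cp)
        assert (s.mvpa_min_week, s.lpa_min_week, s.top2_share) == (200, 400, 0.9)


def brute_force_pattern(mvpa: float, lpa: float, top2: float) -> PAPattern:
    """Independent re-statement of the four printed rules."""
    if mvpa >= 150 and top2 >= 0.5:
        return PAPattern.ACTIVE_WW
    if mvpa >= 150:
        return PAPattern.ACTIVE_REGULAR
    if lpa >= 1900:
        return PAPattern.ACTIVE_LPA
    return PAPattern.BASELINE


class TestClassifyPattern:
    @pytest.mark.parametrize(
        "mvpa,lpa,top2,expected",
        [
            (200, 0, 0.90, PAPattern.ACTIVE_WW),
            (150, 0, 2 / 7, PAPattern.ACTIVE_REGULAR),
            (140, 1900, 0.3, PAPattern.ACTIVE_LPA),
            (140, 1899, 0.3, PAPattern.BASELINE),
            (0, 0, 0.0, PAPattern.BASELINE),
            (150, 0, 0.5, PAPattern.ACTIVE_WW),
            (149, 1900, 1.0, PAPattern.ACTIVE_LPA),
        ],
    )
    def test_printed_rules(self, mvpa, lpa, top2, expected):
        s = WeeklySummary(mvpa, lpa, 0.0, top2, True, 7)
        assert classify_pattern(s) is expected

    def test_invalid_wear_refused(self):
        s = WeeklySummary(200, 0, 0.0, 0.9, False, 2)
        with pytest.raises(InvalidWearError):
            classify_pattern(s)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        mvpa=st.floats(0, 1000),
        lpa=st.floats(0, 4000),
        top2=st.floats(0, 1),
    )
    def test_matches_brute_force_and_is_exhaustive(self, mvpa, lpa, top2):
        s = WeeklySummary(mvpa, lpa, 0.0, top2, True, 7)
        assert classify_pattern(s) is brute_force_pattern(mvpa, lpa, top2)


class TestRCS:
    def test_basis_has_knots_minus_one_columns(self):
        x = np.linspace(0, 10, 50)
        for k in (3, 4, 5):
            assert rcs_basis(x, np.linspace(1, 9, k)).shape == (50, k - 1)

    def test_basis_linear_beyond_boundary_knots(self):
        knots = [1.0, 3.0, 5.0, 9.0]
        x = np.array([9.5, 10.5, 11.5])
        b = rcs_basis(x, knots)
        d1 = b[1] - b[0]
        d2 = b[2] - b[1]
        assert np.allclose(d1, d2, atol=1e-9)

    @staticmethod
    def _simulate(n, slope, seed):
        rng = np.random.default_rng(seed)
        lpa = rng.uniform(0, 3000, n)
        lp = slope * (lpa - 1500.0)
        T = 20.0 * (rng.exponential(size=n) / np.exp(lp)) ** (1 / 1.2)
        C = rng.uniform(2, 25, n)
        return pd.DataFrame(
            {"lpa_min_week": lpa, "time": np.minimum(T, C), "event": (T <= C).astype(int)}
        )

    def test_reference_hr_is_one(self):
        df = self._simulate(2000, 4e-4, 0)
        fit = lpa_dose_response(df)
        assert fit.hazard_ratio(fit.reference)[0] == pytest.approx(1.0, abs=1e-12)

    def test_linear_truth_recovered(self):
        slope = 4e-4
        df = self._simulate(10_000, slope, 1)
        fit = lpa_dose_response(df)
        # the fitted curve should be monotone increasing in LPA hazard
        hr = fit.hr
        assert (np.diff(np.log(hr)) > -1e-3).mean() > 0.95
        # compare the overall slope with a plain linear Cox fit
        from lifelines import CoxPHFitter

        cph = CoxPHFitter().fit(df, "time", "event")
        b, se = cph.params_["lpa_min_week"], cph.standard_errors_["lpa_min_week"]
        rcs_slope = (np.log(hr[-1]) - np.log(hr[0])) / (fit.grid[-1] - fit.grid[0])
        assert abs(rcs_slope - b) < 3 * se + 5e-5

    def test_null_truth_ci_covers_one(self):
        covered = []
        for seed in range(60):
            df = self._simulate(800, 0.0, 100 + seed)
            if df["event"].sum() < 50:
                continue
            fit = lpa_dose_response(df)
            covered.append(np.mean((fit.hr_lower <= 1.0) & (fit.hr_upper >= 1.0)))
        assert np.mean(covered) >= 0.90

    def test_constant_lpa_rejected(self):
        df = self._simulate(500, 0.0, 2)
        df["lpa_min_week"] = 100.0
        with pytest.raises(ValueError):
            lpa_dose_response(df)


class TestActivityWeekValidation:
    def test_negative_values_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            make_week([-1.0])

    def test_nonmonotone_timestamps_rejected(self):
        df = pd.DataFrame(
            {
                "timestamp": pd.to_datetime(["2023-01-02 00:01", "2023-01-02 00:00"]),
                "value": [0.0, 0.0],
                "wear": [True, True],
            }
        )
        with pytest.raises(ValueError, match="increasing"):
            ActivityWeek(participant_id="P0", data=df)
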