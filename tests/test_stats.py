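import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from quadgait.simulate import StudyDesign, simulate_daily_records
from quadgait.stats import (
    da_percent_change,
    daily_means,
    fit_gait_ancova,
    fit_speed_adjusted,
    rank_welch_test,
)


def _records(seed=0, slopes_m=-1.25, slopes_f=0.616, isd=0.0, rsd=0.0):
    rng = np.random.default_rng(seed)
    return simulate_daily_records(
        StudyDesign(seed=0),
        baselines={"F": {"speed": 20.0}, "M": {"speed": 22.0}},
        slopes={"F": {"speed": slopes_f}, "M": {"speed": slopes_m}},
        intercept_sd={"speed": isd},
        residual_sd={"speed": rsd},
        rng=rng,
    )


class TestDailyMeans:
    def _meta(self):
        return pd.DataFrame(
            {
                "trial_id": ["t1", "t2"],
                "mouse_id": ["m1", "m1"],
                "gender": ["M", "M"],
                "cohort": [1, 1],
                "day": [0, 1],
            }
        )

    def _metrics_row(self, trial, speed, included=True, sway=105.0, sway_usable=True):
        return {
            "trial_id": trial,
            "stride_index": 0,
            "included": included,
            "speed_cm_s": speed,
            "stride_length_cm": 5.0,
            "stride_frequency_hz": speed / 5.0,
            "mean_support_number": 2.4,
            "sway_index": sway,
            "sway_usable": sway_usable,
        }

    def test_single_stride_record_equals_stride(self):
        metrics = pd.DataFrame([self._metrics_row("t1", 17.0)])
        daily = daily_means(metrics, self._meta())
        assert len(daily) == 1
        assert daily.loc[0, "speed"] == pytest.approx(17.0)
        assert daily.loc[0, "n_strides"] == 1

    def test_mean_of_two_strides(self):
        metrics = pd.DataFrame(
            [self._metrics_row("t1", 10.0), self._metrics_row("t1", 20.0)]
        )
        daily = daily_means(metrics, self._meta())
        assert daily.loc[0, "speed"] == pytest.approx(15.0)
        assert daily.loc[0, "n_strides"] == 2

    def test_sway_mean_skips_unusable_strides(self):
        metrics = pd.DataFrame(
            [
                self._metrics_row("t1", 10.0, sway=104.0),
                self._metrics_row("t1", 12.0, sway=np.nan, sway_usable=False),
            ]
        )
        daily = daily_means(metrics, self._meta())
        assert daily.loc[0, "sway_index"] == pytest.approx(104.0)
        assert daily.loc[0, "n_strides"] == 2

    def test_mouse_day_without_included_strides_omitted(self, caplog):
        metrics = pd.DataFrame(
            [
                self._metrics_row("t1", 10.0),
                self._metrics_row("t2", 12.0, included=False),
            ]
        )
        import logging

        with caplog.at_level(logging.WARNING, logger="quadgait.stats"):
            daily = daily_means(metrics, self._meta())
        assert len(daily) == 1
        assert any("omitted" in r.message for r in caplog.records)


class TestAncova:
    def test_zero_noise_is_exact(self):
        records = _records()
        r = fit_gait_ancova(records, "speed")
        assert r.slope_male == pytest.approx(-1.25, abs=1e-10)
        assert r.slope_female == pytest.approx(0.616, abs=1e-10)
        assert r.interaction_estimate == pytest.approx(-1.866, abs=1e-10)

    def test_interaction_is_slope_difference(self):
        records = _records(isd=0.5, rsd=1.0)
        r = fit_gait_ancova(records, "speed")
        assert r.interaction_estimate == pytest.approx(
            r.slope_male - r.slope_female, abs=1e-10
        )

    def test_identical_responses_zero_slopes(self):
        records = _records(slopes_m=0.0, slopes_f=0.0)
        records["speed"] = 20.0
        r = fit_gait_ancova(records, "speed")
        assert r.slope_male == pytest.approx(0.0, abs=1e-12)
        assert r.slope_female == pytest.approx(0.0, abs=1e-12)
        assert r.interaction_estimate == pytest.approx(0.0, abs=1e-12)
        assert r.interaction_p == 1.0

    def test_containment_df_matches_design(self):
        # 9 mice x 6 days each = 54 records; 54 - 9 mice - 2 within-mouse
        # fixed effects (day, gender x day) = 43
        records = _records(isd=0.4, rsd=0.8)
        r = fit_gait_ancova(records, "speed")
        assert (r.df_num, r.df_den) == (1, 43)

    def test_requires_both_genders(self):
        records = _records()
        with pytest.raises(ValueError, match="gender"):
            fit_gait_ancova(records[records["gender"] == "M"], "speed")

    def test_ci_brackets_estimate(self):
        records = _records(isd=0.4, rsd=0.8, seed=3)
        r = fit_gait_ancova(records, "speed")
        assert r.slope_male_ci[0] <= r.slope_male <= r.slope_male_ci[1]
        assert r.slope_female_ci[0] <= r.slope_female <= r.slope_female_ci[1]


class TestSpeedAdjusted:
    def _male_records(self, seed=0, a=0.0, b=1.0, noise=0.0):
        rng = np.random.default_rng(seed)
        rows = []
        for mouse in ("M1", "M2", "M3", "M4", "M5"):
            for day in range(8):
                speed = 20.0 + rng.normal(0, 2.0)
                rows.append(
                    {
                        "mouse_id": mouse,
                        "gender": "M",
                        "cohort": 1,
                        "day": day,
                        "speed": speed,
                        "resp": a * day + b * speed + rng.normal(0, noise),
                    }
                )
        return pd.DataFrame(rows)

    def test_pure_speed_response_gives_zero_day_slope(self):
        records = self._male_records(a=0.0, b=0.7)
        r = fit_speed_adjusted(records, "resp")
        assert r.day_estimate == pytest.approx(0.0, abs=1e-9)

    def test_recovers_day_effect_within_ci(self):
        records = self._male_records(seed=5, a=0.3, b=0.5, noise=0.4)
        r = fit_speed_adjusted(records, "resp")
        assert r.day_ci[0] <= 0.3 <= r.day_ci[1]

    def test_collinear_design_rejected(self):
        records = self._male_records()
        records["speed"] = 10.0 + 2.0 * records["day"]  # speed exactly linear in day
        records["resp"] = records["speed"]
        with pytest.raises(ValueError, match="collinear|rank"):
            fit_speed_adjusted(records, "resp")

    def test_day_only_data_consistent_with_male_ancova_arm(self):
        # with speed omitted as a predictor of the response, the day slope
        # from the male arm of the ANCOVA matches a day+speed fit where
        # speed has no effect and is uncorrelated noise, approximately
        records = _records(isd=0.3, rsd=0.6, seed=11)
        males = records[records["gender"] == "M"].copy()
        rng = np.random.default_rng(99)
        males["covar"] = rng.normal(size=len(males))  # irrelevant covariate
        full = fit_gait_ancova(records, "speed")
        part = fit_speed_adjusted(males, "speed", speed_column="covar")
        assert part.day_estimate == pytest.approx(full.slope_male, abs=0.2)


class TestRankWelch:
    def test_identical_groups_t_zero(self):
        r = rank_welch_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == pytest.approx(0.0)

    def test_all_identical_values_p_one(self):
        r = rank_welch_test([5.0, 5.0], [5.0, 5.0, 5.0])
        assert r.pvalue == 1.0
        assert r.statistic == 0.0

    def test_hand_arithmetic_oracle(self):
        # ranks {1,2,3} vs {4,5,6}: means 2 and 5, variances 1 and 1
        r = rank_welch_test([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        se = np.sqrt(1.0 / 3 + 1.0 / 3)
        expected_t = (2.0 - 5.0) / se
        expected_df = (2.0 / 3) ** 2 / (2 * (1.0 / 9) / 2)
        assert r.statistic == pytest.approx(expected_t)
        assert r.df == pytest.approx(expected_df)
        assert r.pvalue == pytest.approx(2 * sps.t.sf(abs(expected_t), expected_df))

    def test_groups_too_small(self):
        with pytest.raises(ValueError):
            rank_welch_test([1.0], [2.0, 3.0])

    @settings(max_examples=50, deadline=None)
    @given(
        a=st.lists(st.integers(-500, 500).map(float), min_size=3, max_size=8, unique=True),
        b=st.lists(st.integers(-500, 500).map(float), min_size=3, max_size=8, unique=True),
    )
    def test_monotone_transform_invariance(self, a, b):
        r1 = rank_welch_test(a, b)
        transform = lambda x: np.exp(np.asarray(x) / 500.0) + 3.0  # strictly monotone
        r2 = rank_welch_test(transform(a), transform(b))
        assert r2.statistic == pytest.approx(r1.statistic, rel=1e-9, abs=1e-12)
        assert r2.pvalue == pytest.approx(r1.pvalue, rel=1e-9, abs=1e-12)


class TestDaPercentChange:
    def _records(self, values_m, values_f=()):
        rows = [
            {"mouse_id": f"M{i}", "gender": "M", "striatal_da": v}
            for i, v in enumerate(values_m)
        ] + [
            {"mouse_id": f"F{i}", "gender": "F", "striatal_da": v}
            for i, v in enumerate(values_f)
        ]
        return pd.DataFrame(rows)

    def test_value_equal_to_control_is_zero(self):
        out = da_percent_change(self._records([19037.0]), control_mean=19037.0)
        assert out["M"]["mean_percent_change"] == pytest.approx(0.0)

    def test_half_control_is_minus_fifty(self):
        out = da_percent_change(self._records([9518.5]), control_mean=19037.0)
        assert out["M"]["mean_percent_change"] == pytest.approx(-50.0)

    def test_group_at_452_pct_of_control(self):
        # group mean at 45.2% of control corresponds to a 54.8% decrease
        values = np.array([0.40, 0.452, 0.504]) * 19037.0
        out = da_percent_change(self._records(values), control_mean=19037.0)
        assert out["M"]["mean_percent_change"] == pytest.approx(-54.8)

    def test_nonpositive_value_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            da_percent_change(self._records([-1.0]))

    def test_test_vs_control_group(self, rng):
        treated = self._records(rng.normal(9000, 500, 5))
        control = rng.normal(19000, 800, 6)
        out = da_percent_change(treated, control_values=control)
        assert out["M"]["test_vs_control"]["p"] < 0.05
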