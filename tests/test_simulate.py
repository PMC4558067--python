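import numpy as np
import pytest
from scipy import integrate

from quadgait.io import PipelineConfig
from quadgait.kinematics import compute_com, path_length, trunk_length_cv
from quadgait.metrics import compute_all
from quadgait.pipeline import compute_study_metrics, run_analysis
from quadgait.simulate import (
    DEFAULT_DAY_SCHEDULE,
    EffectModel,
    GaitPattern,
    StudyDesign,
    default_walk_pattern,
    simulate_stride_events,
    simulate_study,
    simulate_trajectory,
)
from quadgait.strides import LIMBS, segment_strides


class TestGaitPattern:
    def test_rejects_bad_phase(self):
        with pytest.raises(ValueError, match="phase"):
            GaitPattern(0.25, 5.0, limb_phases={"LH": 0.0, "LF": 1.0, "RH": 0.5, "RF": 0.75})

    def test_rejects_bad_duty(self):
        with pytest.raises(ValueError, match="duty"):
            GaitPattern(0.25, 5.0, duty_factors={limb: 0.0 for limb in LIMBS})

    def test_rejects_nonpositive_duration(self):
        with pytest.raises(ValueError, match="stride_duration"):
            GaitPattern(0.0, 5.0)


class TestSimulateStrideEvents:
    def test_walk_touchdowns_and_contact_length(self, walk):
        events = simulate_stride_events(walk, 2, 200.0)
        lh = sorted(
            (c for c in events if c.limb == "LH"), key=lambda c: c.touchdown_frame
        )
        assert [c.touchdown_frame for c in lh] == [0, 50]
        assert lh[0].duration_frames == 30  # 0.6 * 0.25 s * 200 fps

    def test_full_duty_full_contact(self):
        pattern = default_walk_pattern(duty_factor=1.0)
        events = simulate_stride_events(pattern, 3, 200.0)
        for c in events:
            if c.touchdown_frame + 50 <= 100:  # not the trailing stride
                assert c.duration_frames >= 49  # may be clipped by 1 frame

    def test_zero_frame_contact_errors_with_limb_name(self):
        pattern = GaitPattern(
            0.25, 5.0, duty_factors={"LH": 0.001, "LF": 0.6, "RH": 0.6, "RF": 0.6}
        )
        with pytest.raises(ValueError, match="LH"):
            simulate_stride_events(pattern, 2, 200.0)

    def test_round_trip_49_of_50(self, walk):
        events = simulate_stride_events(walk, 50, 200.0)
        assert len(segment_strides(events, "LH", 200.0)) == 49

    def test_same_limb_intervals_disjoint(self, rng):
        for _ in range(20):
            duty = float(rng.uniform(0.2, 1.0))
            T = float(rng.uniform(0.1, 0.4))
            pattern = GaitPattern(
                T, 5.0, duty_factors={limb: duty for limb in LIMBS}
            )
            events = simulate_stride_events(pattern, 10, 200.0)
            for limb in LIMBS:
                ivals = sorted(
                    (c for c in events if c.limb == limb),
                    key=lambda c: c.touchdown_frame,
                )
                for a, b in zip(ivals, ivals[1:]):
                    assert b.touchdown_frame >= a.liftoff_frame


class TestSimulateTrajectory:
    def test_no_sway_no_noise_is_straight(self):
        pattern = default_walk_pattern(sway_amplitude=0.0)
        track = simulate_trajectory(pattern, 4, 200.0, com_fraction=0.415)
        com = compute_com(track, 0.415)
        # perfectly straight: path length equals net displacement
        n = com.frames[-1]
        straight = np.linalg.norm(com.positions[-1] - com.positions[0])
        assert path_length(com, 0, int(n)) == pytest.approx(straight, rel=1e-12)

    def test_rigid_trunk_cv_zero(self):
        pattern = default_walk_pattern(sway_amplitude=0.2)
        track = simulate_trajectory(pattern, 4, 200.0, com_fraction=0.455)
        assert trunk_length_cv(track) == pytest.approx(0.0, abs=1e-9)

    def test_com_recovery_is_exact(self):
        pattern = default_walk_pattern(sway_amplitude=0.3)
        track = simulate_trajectory(pattern, 4, 200.0, com_fraction=0.415)
        com = compute_com(track, 0.415)
        t = track.frames / 200.0
        expected_x = pattern.speed * t
        np.testing.assert_allclose(com.positions[:, 0], expected_x, atol=1e-9)

    def test_sway_index_matches_quadrature_oracle(self):
        v, T, A = 20.0, 0.25, 0.3
        pattern = default_walk_pattern(
            speed=v, stride_length=v * T, sway_amplitude=A
        )
        track = simulate_trajectory(pattern, 4, 200.0, com_fraction=0.415)
        com = compute_com(track, 0.415)
        omega = 2 * np.pi / T
        arc, _ = integrate.quad(
            lambda s: np.hypot(v, A * omega * np.cos(omega * s)), 0.0, T
        )
        expected = 100.0 * arc / (v * T)
        measured = 100.0 * path_length(com, 0, 50) / np.linalg.norm(
            com.positions[50] - com.positions[0]
        )
        assert measured == pytest.approx(expected, rel=0.01)

    def test_noise_requires_rng(self):
        with pytest.raises(ValueError, match="rng"):
            simulate_trajectory(default_walk_pattern(), 2, noise_sd=0.1)


class TestStudyDesign:
    def test_default_schedule_matches_cohort_plan(self):
        assert DEFAULT_DAY_SCHEDULE == {
            1: (0, 1, 2, 3, 4, 7),
            2: (0, 1, 2, 5, 6, 7),
            3: (0, 3, 4, 5, 6, 7),
        }

    def test_default_has_five_males_four_females(self):
        design = StudyDesign()
        assert design.n_mice("M") == 5
        assert design.n_mice("F") == 4

    def test_rejects_schedule_without_baseline(self):
        with pytest.raises(ValueError, match="baseline"):
            StudyDesign(day_schedule={1: (1, 2, 7), 2: (0, 1, 2, 5, 6, 7), 3: (0, 3, 4, 5, 6, 7)})

    def test_rejects_bad_stride_range(self):
        with pytest.raises(ValueError, match="strides_per_day"):
            StudyDesign(strides_per_day=(0, 5))


class TestSimulateStudy:
    def test_emitted_schedule_matches_design(self, small_study):
        design, dataset = small_study
        meta = dataset.metadata
        for mouse, (gender, cohort) in design.mice.items():
            days = sorted(meta.loc[meta["mouse_id"] == mouse, "day"])
            assert tuple(days) == tuple(sorted(design.day_schedule[cohort]))

    def test_deterministic_given_seed(self):
        design = StudyDesign(seed=42, strides_per_day=(3, 5))
        eff = EffectModel()
        eff.residual_sd["speed"] = 1.0
        a = simulate_study(design, eff)
        b = simulate_study(design, eff)
        assert a.metadata.equals(b.metadata)
        for trial in a.trial_ids():
            assert a.contacts[trial] == b.contacts[trial]
            np.testing.assert_array_equal(a.tracks[trial].nose, b.tracks[trial].nose)

    def test_zero_variation_strides_identical_within_gender(self):
        design = StudyDesign(seed=1, strides_per_day=(4, 4))
        dataset = simulate_study(design, EffectModel())  # all slopes and SDs zero
        metrics = compute_study_metrics(
            dataset.contacts, dataset.tracks, dataset.metadata, PipelineConfig()
        )
        merged = metrics.merge(dataset.metadata, on="trial_id")
        # compare like strides across trials (spline edge effects make the
        # first/last stride of a trial differ slightly from interior ones)
        for (gender, _), grp in merged.groupby(["gender", "stride_index"]):
            assert grp["speed_cm_s"].std() == pytest.approx(0.0, abs=1e-9)
            assert grp["stride_length_cm"].std() == pytest.approx(0.0, abs=1e-9)

    def test_truncation_warning_logged(self, caplog):
        design = StudyDesign(seed=2, strides_per_day=(3, 4))
        eff = EffectModel()
        eff.residual_sd["duty_factor"] = 1.2  # slams into the (0.05, 1] bounds
        import logging

        with caplog.at_level(logging.WARNING, logger="quadgait.simulate"):
            simulate_study(design, eff)
        assert any("truncation" in r.message for r in caplog.records)

    def test_slope_recovery_noise_free(self):
        # with zero noise the fitted gender slopes equal the generating ones
        # up to frame quantization
        design = StudyDesign(seed=5, strides_per_day=(4, 6))
        eff = EffectModel()
        eff.per_day_slopes["M"]["speed"] = -1.25
        eff.per_day_slopes["F"]["speed"] = 0.616
        dataset = simulate_study(design, eff)
        metrics = compute_study_metrics(
            dataset.contacts, dataset.tracks, dataset.metadata, PipelineConfig()
        )
        _, results = run_analysis(metrics, dataset.metadata)
        r = results["ancova"]["speed"]
        assert r["slope_male"] == pytest.approx(-1.25, abs=0.01)
        assert r["slope_female"] == pytest.approx(0.616, abs=0.01)

    def test_slope_recovery_with_noise_is_unbiased(self):
        # parameter-recovery simulation: mean fitted male slope over
        # replicates within Monte-Carlo error of the generating -1.25
        truth = -1.25
        estimates = []
        for rep in range(30):
            design = StudyDesign(seed=900 + rep, strides_per_day=(4, 6))
            eff = EffectModel()
            eff.per_day_slopes["M"]["speed"] = truth
            eff.per_day_slopes["F"]["speed"] = 0.616
            eff.mouse_intercept_sd["speed"] = 0.6
            eff.residual_sd["speed"] = 1.2
            dataset = simulate_study(design, eff)
            metrics = compute_study_metrics(
                dataset.contacts, dataset.tracks, dataset.metadata, PipelineConfig()
            )
            from quadgait.stats import daily_means, fit_gait_ancova

            daily = daily_means(metrics, dataset.metadata)
            estimates.append(fit_gait_ancova(daily, "speed").slope_male)
        estimates = np.asarray(estimates)
        mc_se = estimates.std(ddof=1) / np.sqrt(len(estimates))
        assert abs(estimates.mean() - truth) <= 4 * mc_se + 0.01
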