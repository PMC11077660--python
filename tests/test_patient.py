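"""Virtual patient: profiles, gait/sEMG generation, plant and fatigue."""

import math

import numpy as np
import pytest

from cifes import emg, kinematics, patient, switching
from cifes.patient import (FatigueState, dose_response, generate_gait,
                           generate_semg, make_profile, plant_mean_maxaa,
                           plant_step_response, update_fatigue)


class TestProfiles:
    def test_foot_drop_defaults_carry_unassisted_law(self):
        p = make_profile("foot_drop")
        assert p.maxaa_mean == pytest.approx(105.53)
        assert p.maxaa_var == pytest.approx(28.84)

    def test_healthy_default_mean(self):
        p = make_profile("healthy")
        assert p.maxaa_mean == pytest.approx(100.72)

    def test_override_applies_fieldwise(self):
        p = make_profile("foot_drop", gcd_mean=1.5)
        assert p.gcd_mean == 1.5
        assert p.maxaa_mean == pytest.approx(105.53)

    def test_negative_variance_override_rejected(self):
        with pytest.raises(ValueError):
            make_profile("foot_drop", maxaa_var=-1.0)

    def test_fd_requires_attenuated_affected_ta(self):
        with pytest.raises(ValueError):
            make_profile("foot_drop", ta_burst_amp_affected=0.9, ta_burst_amp=0.8)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            make_profile("sprinter")


class TestGaitGeneration:
    def test_zero_steps_gives_empty_recording(self, fd_profile):
        rec = generate_gait(fd_profile, 0, 1000.0, seed=0)
        assert len(rec.ankle_left) == 0
        assert len(rec.steps) == 0

    def test_same_seed_is_deterministic(self, fd_profile):
        a = generate_gait(fd_profile, 5, 1000.0, seed=3)
        b = generate_gait(fd_profile, 5, 1000.0, seed=3)
        np.testing.assert_array_equal(a.ankle_left.values, b.ankle_left.values)
        sa = generate_semg(fd_profile, a, seed=4)
        sb = generate_semg(fd_profile, b, seed=4)
        np.testing.assert_array_equal(sa.rf_affected.values, sb.rf_affected.values)

    def test_step_count_per_side(self, fd_recording):
        tags = [e.tag for e in fd_recording.steps]
        assert tags.count("left") == 30
        assert tags.count("right") == 30

    def test_imu_reconstruction_identity(self, fd_recording):
        """IMU_up + IMU_down + 90 reproduces the ankle trace exactly."""
        for up, down, ankle in [
            (fd_recording.imu_up_left, fd_recording.imu_down_left,
             fd_recording.ankle_left),
            (fd_recording.imu_up_right, fd_recording.imu_down_right,
             fd_recording.ankle_right),
        ]:
            recon = kinematics.ankle_angle(up, down)
            np.testing.assert_allclose(recon.values, ankle.values, atol=1e-9)

    def test_traces_share_clock(self, fd_recording):
        traces = list(fd_recording.traces().values())
        assert len({t.sampling_rate for t in traces}) == 1
        assert len({len(t) for t in traces}) == 1

    def test_clt_bound_on_percycle_maxima(self, fd_profile):
        """Sample mean of 1000 generated FD maxima stays within 3 SE of the
        profile mean (central-limit bound on the generator's own draws)."""
        rec = generate_gait(fd_profile, 1000, 100.0, seed=7)
        maxima = rec.cycle_truth["left"]["maxaa"]
        se = math.sqrt(fd_profile.maxaa_var / 1000)
        assert abs(maxima.mean() - 105.53) < 3 * se

    def test_feature_extraction_recovers_generator_draws(self, fd_profile):
        """Segmentation applied to a generated recording returns exactly the
        per-cycle draws the generator used (clean, noise-free kinematics)."""
        rec = generate_gait(fd_profile, 40, 1000.0, seed=5)
        feats = kinematics.segment_gait(rec.ankle_left,
                                        min_separation=0.4 * fd_profile.gcd_mean)
        truth = rec.cycle_truth["left"]
        assert len(feats) == 40
        # atol covers the sub-sample quantization of the analytic peak
        np.testing.assert_allclose([f.maxaa for f in feats], truth["maxaa"],
                                   atol=1e-3)
        np.testing.assert_allclose([f.gcd for f in feats], truth["gcd"],
                                   atol=2.0 / 1000.0)


class TestSemg:
    def test_one_activation_per_step(self, fd_recording):
        """The RF burst complex yields exactly one switch activation per
        gait cycle at the default envelope and switch settings."""
        env = emg.envelope(fd_recording.rf_affected)
        _, acts = switching.threshold_switch(env)
        assert len(acts) == 30

    def test_affected_ta_attenuated_every_cycle(self, fd_profile, fd_recording):
        env_a = emg.envelope(fd_recording.ta_affected).values
        env_h = emg.envelope(fd_recording.ta_healthy).values
        fs = fd_recording.ta_affected.sampling_rate
        for e in fd_recording.steps:
            if e.tag != "left":
                continue
            i0, i1 = int(e.onset * fs), int(e.offset * fs)
            assert env_a[i0:i1].max() < env_h.max()
        assert env_a.max() < env_h.max()

    def test_interburst_envelope_below_trigger_threshold(self, fd_recording):
        """The default noise floor keeps the inter-burst envelope below the
        0.15 V trigger threshold, so the switch cannot false-trigger."""
        env = emg.envelope(fd_recording.rf_affected)
        fs = env.sampling_rate
        onsets = [e.onset for e in fd_recording.steps if e.tag == "left"]
        mask = np.ones(len(env), dtype=bool)
        for t0 in onsets:  # blank out burst complexes (+ envelope tail)
            i0 = max(0, int((t0 - 0.35) * fs))
            i1 = min(len(env), int((t0 + 0.45 * 1.6 + 0.55) * fs))
            mask[i0:i1] = False
        assert env.values[mask].max() < 0.15


class TestPlant:
    def test_no_stimulation_draws_unassisted_law(self, fd_profile, rng):
        fresh = FatigueState()
        draws = np.array([plant_step_response(fd_profile, fresh, 0.0, rng)[0]
                          for _ in range(400)])
        assert abs(draws.mean() - 105.53) < 4 * math.sqrt(28.84 / 400)

    def test_mean_maxaa_non_increasing_in_voltage(self, fd_profile):
        fresh = FatigueState()
        grid = np.linspace(0.0, 240.0, 49)
        means = [plant_mean_maxaa(fd_profile, fresh, v) for v in grid]
        assert np.all(np.diff(means) <= 1e-12)
        assert means[-1] >= fd_profile.healthy_maxaa_mean  # never overshoots

    def test_calibration_identity_at_operating_voltage(self, fd_profile):
        """At the 200 V calibration point a fresh plant's MaxAA law is the
        published assisted law: mean 102.81 deg, variance 17.71 deg^2."""
        fresh = FatigueState()
        v_op = patient.CALIBRATION_VOLTAGE
        assert plant_mean_maxaa(fd_profile, fresh, v_op) == pytest.approx(102.81,
                                                                          abs=1e-6)
        frac = dose_response(fd_profile, fresh, v_op) / fd_profile.response_gain
        var = fd_profile.maxaa_var * (1 - fd_profile.variance_shrink * frac)
        assert var == pytest.approx(17.71, abs=1e-6)

    def test_dose_response_saturates_below_gain(self, fd_profile):
        fresh = FatigueState()
        assert dose_response(fd_profile, fresh, 0.0) == 0.0
        for v in (50.0, 140.0, 240.0, 1000.0):
            assert 0.0 < dose_response(fd_profile, fresh, v) < fd_profile.response_gain

    def test_negative_voltage_rejected(self, fd_profile):
        with pytest.raises(ValueError):
            plant_step_response(fd_profile, FatigueState(), -1.0)


class TestFatigue:
    def test_no_exposure_keeps_full_response(self):
        st = FatigueState()
        for _ in range(10):
            st = update_fatigue(st, [0.0], duration=60.0)
        assert st.response_scale == pytest.approx(1.0)

    def test_continuous_900s_drops_response_about_25pct(self):
        st = FatigueState()
        for _ in range(900):
            st = update_fatigue(st, [1.0], duration=1.0)
        assert st.response_scale == pytest.approx(0.75, abs=0.01)

    def test_two_channel_alternation_beats_single_site(self):
        """Splitting the same total charge over two sites keeps the muscle
        fresher than one site taking all of it."""
        single = FatigueState(loads=np.zeros(1))
        dual = FatigueState(loads=np.zeros(2))
        for _ in range(900):
            single = update_fatigue(single, [1.0], duration=1.0)
            dual = update_fatigue(dual, [0.5, 0.5], duration=1.0)
        assert dual.response_scale > single.response_scale

    @pytest.mark.parametrize("total", [10.0, 100.0, 400.0, 1000.0])
    def test_channel_splitting_inequality_on_grid(self, total):
        one = update_fatigue(FatigueState(loads=np.zeros(1)), [total])
        two = update_fatigue(FatigueState(loads=np.zeros(2)),
                             [total / 2, total / 2])
        assert two.response_scale >= one.response_scale

    def test_recovery_returns_to_baseline(self):
        st = update_fatigue(FatigueState(), [300.0])
        assert st.response_scale < 0.9
        st = update_fatigue(st, [0.0], duration=10 * st.tau_recovery)
        assert st.response_scale > 0.99

    def test_negative_exposure_rejected(self):
        with pytest.raises(ValueError):
            update_fatigue(FatigueState(), [-1.0])
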