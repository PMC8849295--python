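"""Withdrawal feature extraction: onset, height/speed, shake, orientation."""

import numpy as np
import pytest

from painscale.errors import (
    DegenerateTrialError,
    FeatureUnavailableError,
    InputError,
    StageError,
)
from painscale.kinematics import (
    KinematicsParams,
    Trajectory,
    detect_lift_onset,
    detect_shake,
    extract_height_speed,
    orientation_order,
    read_trajectory,
    trajectory_to_trial_features,
    write_trajectory,
)
from painscale.synthetic_data import generate_trajectory

FR = 2000.0
DT = 1.0 / FR


def _traj(y, stim_time=0.1, x=None, head=None, fr=FR):
    y = np.asarray(y, dtype=float)
    t = np.arange(y.size) / fr
    return Trajectory(
        t=t, paw_y_mm=y, paw_x_mm=np.zeros_like(y) if x is None else np.asarray(x, float),
        frame_rate_hz=fr, stim_time_s=stim_time, head_orient_deg=head,
    )


class TestTrajectoryValidation:
    def test_channel_length_mismatch(self):
        with pytest.raises(InputError, match="length"):
            Trajectory(t=np.arange(5) * DT, paw_y_mm=np.zeros(4), paw_x_mm=np.zeros(5))

    def test_irregular_spacing_rejected(self):
        t = np.arange(10) * DT
        t[5] += 1e-4
        with pytest.raises(InputError):
            Trajectory(t=t, paw_y_mm=np.zeros(10), paw_x_mm=np.zeros(10))

    def test_small_below_floor_flagged_large_rejected(self):
        y = np.zeros(300)
        y[10] = -0.5
        assert _traj(y).below_floor
        y[10] = -2.0
        with pytest.raises(InputError, match="below -1"):
            _traj(y)


class TestLiftOnset:
    def test_flat_trace_is_no_withdrawal(self):
        assert detect_lift_onset(_traj(np.zeros(600))) is None

    def test_single_frame_spike_fails_persistence(self):
        y = np.zeros(600)
        y[300] = 5.0
        assert detect_lift_onset(_traj(y)) is None

    def test_short_trace_errors(self):
        y = np.zeros(40)  # only 20 ms of pre-stimulus data
        with pytest.raises(InputError, match="baseline"):
            detect_lift_onset(_traj(y, stim_time=0.01), baseline_window_s=0.05)

    def test_noiseless_ramp_onset_within_one_frame(self):
        traj, truth = generate_trajectory(
            onset_s=0.025, apex_height_mm=35.0, rise_time_s=0.04,
            shake_cycles=0, noise_sd_mm=0.0, seed=0,
        )
        onset = detect_lift_onset(traj, delta_mm=1.0)
        assert onset is not None
        assert abs((onset - traj.stim_time_s) - truth.onset_s) <= DT + 1e-12

    def test_time_shift_equivariance(self):
        traj, _ = generate_trajectory(noise_sd_mm=0.1, seed=3)
        shifted = traj.shifted(0.25)
        o1 = detect_lift_onset(traj)
        o2 = detect_lift_onset(shifted)
        assert o2 == pytest.approx(o1 + 0.25, abs=1e-9)
        h1, s1, a1 = extract_height_speed(traj, o1)
        h2, s2, a2 = extract_height_speed(shifted, o2)
        assert a2 == pytest.approx(a1 + 0.25, abs=1e-9)
        assert h2 == pytest.approx(h1, rel=1e-12)
        assert s2 == pytest.approx(s1, rel=1e-9)
        assert detect_shake(shifted, o2, a2) == detect_shake(traj, o1, a1)


class TestHeightSpeed:
    def test_definition_forces_vertical_case(self):
        # onset at y=0, apex 20 mm higher 50 ms later -> 400 mm/s
        y = np.concatenate([np.zeros(220), np.linspace(0, 20, 101)[1:], np.full(200, 20.0)])
        traj = _traj(y)
        onset = 220 * DT
        h, s, apex_t = extract_height_speed(traj, onset)
        assert h == pytest.approx(20.0, abs=1e-9)
        # displacement from the onset sample to the apex over elapsed time
        assert s == pytest.approx(400.0, rel=1e-9)

    def test_three_four_five_triangle(self):
        # 30 mm horizontal, 40 mm vertical over 0.1 s -> 50 mm / 0.1 s = 500 mm/s
        n_rise = 200  # 0.1 s
        y = np.concatenate([np.zeros(220), np.linspace(0, 40, n_rise + 1)[1:], np.full(200, 40.0)])
        x = np.concatenate([np.zeros(220), np.linspace(0, 30, n_rise + 1)[1:], np.full(200, 30.0)])
        traj = _traj(y, x=x)
        h, s, _ = extract_height_speed(traj, 220 * DT)
        assert h == pytest.approx(40.0)
        assert s == pytest.approx(500.0, rel=1e-6)

    def test_vertical_only_mode(self):
        n_rise = 200
        y = np.concatenate([np.zeros(220), np.linspace(0, 40, n_rise + 1)[1:], np.full(200, 40.0)])
        x = np.concatenate([np.zeros(220), np.linspace(0, 30, n_rise + 1)[1:], np.full(200, 30.0)])
        traj = _traj(y, x=x)
        p = KinematicsParams(speed_vertical_only=True)
        _, s, _ = extract_height_speed(traj, 220 * DT, params=p)
        assert s == pytest.approx(400.0, rel=1e-6)

    def test_amplitude_scaling_property(self):
        traj, _ = generate_trajectory(apex_height_mm=20.0, shake_cycles=0, noise_sd_mm=0.0, seed=1)
        onset = detect_lift_onset(traj)
        h1, s1, _ = extract_height_speed(traj, onset)
        scaled = Trajectory(
            t=traj.t, paw_y_mm=3.0 * traj.paw_y_mm, paw_x_mm=traj.paw_x_mm,
            frame_rate_hz=traj.frame_rate_hz, stim_time_s=traj.stim_time_s,
        )
        h2, s2, _ = extract_height_speed(scaled, detect_lift_onset(scaled))
        assert h2 == pytest.approx(3.0 * h1, rel=1e-3)
        assert s2 <= 3.0 * s1 * (1 + 1e-9)  # equality for purely vertical motion

    def test_degenerate_window_errors(self):
        y = np.concatenate([np.zeros(220), np.full(10, 20.0)])
        traj = _traj(y)
        with pytest.raises(DegenerateTrialError):
            extract_height_speed(traj, traj.t[-1])


class TestShake:
    def test_monotone_rise_then_hold_is_no_shake(self):
        y = np.concatenate([np.zeros(220), np.linspace(0, 20, 101)[1:], np.full(700, 20.0)])
        traj = _traj(y)
        onset = detect_lift_onset(traj)
        _, _, apex_t = extract_height_speed(traj, onset)
        assert detect_shake(traj, onset, apex_t) == (0, 0)

    def test_injected_sinusoid_recovered(self):
        traj, truth = generate_trajectory(shake_cycles=4, shake_freq_hz=20.0, noise_sd_mm=0.0, seed=2)
        onset = detect_lift_onset(traj)
        _, _, apex_t = extract_height_speed(traj, onset)
        shake, cycles = detect_shake(traj, onset, apex_t)
        assert shake == 1
        assert abs(cycles - 4) <= 1

    def test_sub_band_noise_is_not_shake(self):
        traj, _ = generate_trajectory(shake_cycles=0, noise_sd_mm=0.2, seed=9)
        onset = detect_lift_onset(traj)
        _, _, apex_t = extract_height_speed(traj, onset)
        shake, _ = detect_shake(traj, onset, apex_t)
        assert shake == 0


class TestOrientation:
    def _head(self, n, cross_at, stim_time=0.1):
        rel = np.arange(n) / FR - stim_time
        return 90.0 * (rel >= cross_at)

    def test_lift_before_look(self):
        y = np.concatenate([np.zeros(220), np.linspace(0, 20, 81), np.full(900, 15.0)])
        traj = _traj(y, head=self._head(y.size, cross_at=0.2))
        onset = detect_lift_onset(traj)
        assert orientation_order(traj, onset) == 1

    def test_look_before_lift(self):
        y = np.concatenate([np.zeros(380), np.linspace(0, 20, 81), np.full(740, 15.0)])
        traj = _traj(y, head=self._head(y.size, cross_at=0.02))
        onset = detect_lift_onset(traj)
        assert orientation_order(traj, onset) == 0

    def test_neither_event_is_none(self):
        y = np.zeros(600)
        traj = _traj(y, head=np.zeros(600))
        assert orientation_order(traj, None) is None

    def test_missing_head_channel_is_error(self):
        traj = _traj(np.zeros(600))
        with pytest.raises(FeatureUnavailableError):
            orientation_order(traj, 0.05)


class TestComposition:
    def test_generator_truth_recovered_end_to_end(self):
        traj, truth = generate_trajectory(
            onset_s=0.03, apex_height_mm=35.0, rise_time_s=0.04,
            shake_cycles=4, shake_freq_hz=20.0, orient_time_s=0.2,
            noise_sd_mm=0.0, seed=4,
        )
        feats = trajectory_to_trial_features(traj)
        assert feats.withdrawal == 1
        assert feats.lift_onset_s == pytest.approx(truth.onset_s, abs=2 * DT)
        assert feats.paw_height_mm == pytest.approx(truth.apex_height_mm, abs=0.1)
        assert feats.paw_speed_mm_per_s == pytest.approx(truth.speed_mm_per_s, rel=0.02)
        assert feats.paw_shake == 1
        assert feats.lift_before_orient == 1  # lift at 30 ms, look at 200 ms

    def test_flat_trace_gives_withdrawal_absent_record(self):
        feats = trajectory_to_trial_features(_traj(np.zeros(600)))
        assert (feats.withdrawal, feats.paw_height_mm, feats.paw_speed_mm_per_s) == (0, 0.0, 0.0)
        assert feats.lift_onset_s is None and feats.paw_shake == 0

    def test_missing_head_channel_staged_error(self):
        traj, _ = generate_trajectory(orient_time_s=None, seed=5)
        with pytest.raises(StageError, match="orientation_order"):
            trajectory_to_trial_features(traj, require_orientation=True)

    def test_trajectory_csv_roundtrip(self, tmp_path):
        traj, _ = generate_trajectory(orient_time_s=0.2, include_eye=True, noise_sd_mm=0.1, seed=6)
        p = write_trajectory(traj, tmp_path / "traj.csv")
        back = read_trajectory(p)
        assert np.array_equal(back.paw_y_mm, traj.paw_y_mm)
        assert np.array_equal(back.head_orient_deg, traj.head_orient_deg)
        assert back.stim_time_s == traj.stim_time_s


class TestParameterRecovery:
    def test_recovery_grid_smoke(self):
        """Small pilot of the recovery property (full grid in acceptance)."""
        rng = np.random.default_rng(11)
        ok = 0
        n = 40
        for i in range(n):
            H = float(rng.uniform(5, 60))
            rise = float(rng.uniform(0.010, 0.100))
            noise = 0.0 if i % 2 == 0 else 0.2
            traj, truth = generate_trajectory(
                onset_s=0.03, apex_height_mm=H, rise_time_s=rise,
                shake_cycles=0, noise_sd_mm=noise, seed=100 + i,
            )
            onset = detect_lift_onset(traj)
            h, _, _ = extract_height_speed(traj, onset)
            ok += (
                abs((onset - traj.stim_time_s) - truth.onset_s) <= 2 * DT + 1e-12
                and abs(h - H) <= max(0.5, 0.02 * H)
            )
        assert ok / n >= 0.9
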