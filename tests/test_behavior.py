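"""Rotation detection from heading angles and AIMs score arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lidpipe import behavior as bh
from lidpipe import synth


def run_detector(traj, lesion="right", frame_rate=None):
    if frame_rate is None:
        frame_rate = traj.attrs.get("frame_rate", 30.0)
    sm = bh.smooth_coordinates(traj, frame_rate=frame_rate)
    return bh.detect_rotations(bh.heading_angle(sm), frame_rate, lesion)


class TestSmoothing:
    def test_constant_position_unchanged(self):
        traj = pd.DataFrame({"front_x": np.full(300, 5.0),
                             "front_y": np.full(300, 7.0),
                             "center_x": np.zeros(300),
                             "center_y": np.zeros(300)})
        out = bh.smooth_coordinates(traj, frame_rate=30.0)
        np.testing.assert_allclose(out["front_x"], 5.0, atol=1e-9)

    def test_fast_jitter_suppressed(self):
        t = np.arange(900) / 30.0
        jitter = 3.0 * np.sin(2 * np.pi * 10.0 * t)
        traj = pd.DataFrame({"front_x": 100 + jitter, "front_y": np.zeros(900),
                             "center_x": np.zeros(900), "center_y": np.zeros(900)})
        out = bh.smooth_coordinates(traj, frame_rate=30.0)
        resid = out["front_x"].to_numpy()[100:-100] - 100
        assert np.std(resid) < 0.2 * np.std(jitter)

    def test_slow_sweep_preserved(self):
        t = np.arange(1800) / 30.0
        sweep = 50.0 * np.sin(2 * np.pi * 0.2 * t)
        traj = pd.DataFrame({"front_x": sweep, "front_y": np.zeros_like(t),
                             "center_x": np.zeros_like(t), "center_y": np.zeros_like(t)})
        out = bh.smooth_coordinates(traj, frame_rate=30.0)
        core = slice(200, -200)
        assert np.max(np.abs(out["front_x"].to_numpy()[core] - sweep[core])) \
            < 0.02 * 50.0

    def test_low_frame_rate_rejected(self):
        traj = pd.DataFrame({c: np.zeros(100) for c in
                             ("front_x", "front_y", "center_x", "center_y")})
        with pytest.raises(ValueError):
            bh.smooth_coordinates(traj, frame_rate=8.0)


class TestHeadingAngle:
    def _traj(self, fx, fy):
        return pd.DataFrame({"front_x": [fx], "front_y": [fy],
                             "center_x": [0.0], "center_y": [0.0]})

    def test_cardinal_conventions(self):
        assert bh.heading_angle(self._traj(1, 0))[0] == pytest.approx(0.0)
        assert bh.heading_angle(self._traj(0, 1))[0] == pytest.approx(np.pi / 2)
        assert bh.heading_angle(self._traj(-1, 0))[0] == pytest.approx(np.pi)

    def test_coincident_points_undefined(self):
        assert np.isnan(bh.heading_angle(self._traj(0, 0))[0])

    def test_uniform_rotation_linear_unwrapped(self):
        t = np.arange(300) / 30.0
        omega = 2 * np.pi / 4.0      # one turn per 4 s
        traj = pd.DataFrame({"front_x": np.cos(omega * t),
                             "front_y": np.sin(omega * t),
                             "center_x": np.zeros_like(t),
                             "center_y": np.zeros_like(t)})
        ang = np.unwrap(bh.heading_angle(traj))
        slope = np.polyfit(t, ang, 1)[0]
        assert slope == pytest.approx(omega, rel=1e-6)


class TestRotationDetection:
    def test_noiseless_ccw_circles_lesion_right(self):
        traj, _ = synth.generate_trajectory(3, 0, seed=1)
        ev = run_detector(traj, "right")
        assert ev.count("contra") == 3 and ev.count("ipsi") == 0

    def test_lesion_side_flips_direction_label(self):
        traj, _ = synth.generate_trajectory(3, 0, seed=1, lesion_side="right")
        ev = run_detector(traj, "left")
        assert ev.count("ipsi") == 3 and ev.count("contra") == 0

    def test_partial_arc_discarded(self):
        traj, _ = synth.generate_trajectory(0, 0, seed=2, n_partial=3)
        ev = run_detector(traj)
        assert len(ev.events) == 0

    def test_mixed_directions(self):
        traj, truth = synth.generate_trajectory(2, 1, seed=3)
        ev = run_detector(traj)
        assert ev.count("contra") == 2 and ev.count("ipsi") == 1

    @given(n_contra=st.integers(0, 6), n_ipsi=st.integers(0, 6),
           n_partial=st.integers(0, 2))
    @settings(deadline=None, max_examples=15)
    def test_exact_counts_property(self, n_contra, n_ipsi, n_partial):
        traj, _ = synth.generate_trajectory(n_contra, n_ipsi, seed=7,
                                            n_partial=n_partial)
        ev = run_detector(traj)
        assert ev.count("contra") == n_contra
        assert ev.count("ipsi") == n_ipsi

    def test_invariance_translation_scaling(self):
        traj, _ = synth.generate_trajectory(4, 2, seed=8)
        moved = traj.copy()
        for c in ("front_x", "center_x"):
            moved[c] = 3.0 * moved[c] + 1000.0
        for c in ("front_y", "center_y"):
            moved[c] = 3.0 * moved[c] - 50.0
        moved.attrs.update(traj.attrs)
        a, b = run_detector(traj), run_detector(moved)
        assert a.count("contra") == b.count("contra")
        assert a.count("ipsi") == b.count("ipsi")

    def test_invariance_frame_rate_doubling(self):
        a, _ = synth.generate_trajectory(4, 2, seed=9, frame_rate=30.0)
        b, _ = synth.generate_trajectory(4, 2, seed=9, frame_rate=60.0)
        ea = run_detector(a, frame_rate=30.0)
        eb = run_detector(b, frame_rate=60.0)
        assert ea.count("contra") == eb.count("contra")
        assert ea.count("ipsi") == eb.count("ipsi")

    def test_noise_robustness(self):
        traj, _ = synth.generate_trajectory(5, 3, seed=10, noise_px=2.0)
        ev = run_detector(traj)
        assert ev.count("contra") == 5 and ev.count("ipsi") == 3

    def test_lesion_side_required(self):
        with pytest.raises(ValueError):
            bh.detect_rotations(np.zeros(100), 30.0, lesion_side="center")

    def test_excess_undefined_frames_rejected(self):
        ang = np.full(100, np.nan)
        with pytest.raises(ValueError):
            bh.detect_rotations(ang, 30.0, "right")


class TestBinning:
    def _events(self, times_min, direction="contra"):
        return bh.RotationEvents(events=[(t * 60.0, direction) for t in times_min],
                                 frame_rate=30.0)

    def test_uniform_peak_window_rate(self):
        ev = bh.bin_rotations(self._events(np.linspace(40.1, 79.9, 12)))
        assert ev.peak_mean == pytest.approx(12 / 40.0)
        assert ev.late_mean == 0.0

    def test_empty_events(self):
        ev = bh.bin_rotations(self._events([]))
        assert ev.bins.sum() == 0

    def test_bin_totals_conserve_counts(self):
        times = [5, 15, 44, 46, 130, 155, 179]
        ev = bh.bin_rotations(self._events(times))
        assert ev.bins.sum() == len(times)

    def test_boundary_event_goes_to_later_bin(self):
        ev = bh.bin_rotations(self._events([10.0]))
        assert ev.bins[1] == 1 and ev.bins[0] == 0

    def test_pre_injection_events_excluded(self):
        ev = bh.bin_rotations(self._events([-5.0, 20.0]))
        assert ev.bins.sum() == 1

    def test_ipsi_not_counted(self):
        ev = bh.bin_rotations(self._events([50.0], direction="ipsi"))
        assert ev.bins.sum() == 0


class TestGlobalAims:
    def _obs(self, triples, t_min=10.0):
        return pd.DataFrame([
            {"t_min": t_min, "subtype": sub, "severity": sev, "amplitude": amp}
            for sub, (sev, amp) in zip(("axial", "limb", "orolingual"), triples)])

    def test_hand_computed_sum(self):
        obs = self._obs([(2, 3), (1, 2), (0, 1)])
        assert bh.global_aims(obs)["global"].iloc[0] == 8.0

    def test_scale_maximum(self):
        obs = self._obs([(2.5, 4)] * 3)
        assert bh.global_aims(obs)["global"].iloc[0] == 30.0

    def test_all_zero(self):
        obs = self._obs([(0, 1)] * 3)
        assert bh.global_aims(obs)["global"].iloc[0] == 0.0

    def test_out_of_scale_named_row(self):
        obs = self._obs([(3, 3), (0, 1), (0, 1)])
        with pytest.raises(ValueError, match="row 0"):
            bh.global_aims(obs)

    def test_window_means(self):
        rows = []
        for t in range(10, 181, 10):
            sev = 2.0 if 40 < t <= 80 else 0.0
            rows += [{"t_min": float(t), "subtype": s, "severity": sev,
                      "amplitude": 2} for s in ("axial", "limb", "orolingual")]
        ga = bh.global_aims(pd.DataFrame(rows))
        assert ga.attrs["peak_mean"] == pytest.approx(12.0)
        assert ga.attrs["late_mean"] == pytest.approx(0.0)

    def test_bounded_additive(self):
        aims = synth.generate_aims_schedule(synth.DrugProfile(), seed=6)
        ga = bh.global_aims(aims)
        assert ga["global"].between(0, 30).all()
        assert len(ga) == 18
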