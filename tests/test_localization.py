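"""Pose estimation from cup rays, track smoothing, gaze resampling."""

import numpy as np
import pandas as pd
import pytest

from gazewalk.geometry import ObserverPose, project_points
from gazewalk.localization import (
    estimate_pose,
    estimate_trial_poses,
    resample_gaze,
    smooth_track,
)
from tests.conftest import random_pose_params


def detections_for(pose, placements, camera, cup_ids=None, noise_sd=0.0, rng=None):
    pts = np.array([p.world_position for p in placements])
    ids = [p.cup_id for p in placements]
    az, el, vis = project_points(pose, camera, pts)
    rows = []
    for j, cid in enumerate(ids):
        if cup_ids is not None and cid not in cup_ids:
            continue
        if not vis[j]:
            continue
        a, e = az[j], el[j]
        if noise_sd > 0:
            a += rng.normal(0, noise_sd)
            e += rng.normal(0, noise_sd)
        rows.append((cid, a, e))
    return pd.DataFrame(rows, columns=["cup_id", "az_deg", "el_deg"])


class TestEstimatePose:
    def test_noiseless_recovery_from_given_pose(self, placements_lrrr, camera):
        true = ObserverPose(0, 10.0, 50.0, 158.0, 2.0, -10.0)
        det = detections_for(true, placements_lrrr, camera)
        est = estimate_pose(det, placements_lrrr, 158.0, camera)
        assert est.status == "ok"
        assert est.pose.x == pytest.approx(10.0, abs=1.0)
        assert est.pose.y == pytest.approx(50.0, abs=1.0)
        assert est.pose.yaw == pytest.approx(2.0, abs=0.1)
        assert est.pose.pitch == pytest.approx(-10.0, abs=0.1)
        assert est.residual_rms < 0.01

    def test_table_cups_only_is_degenerate(self, placements_lrrr, camera):
        true = ObserverPose(0, 0.0, 200.0, 158.0, 0.0, -20.0)
        det = detections_for(true, placements_lrrr, camera,
                             cup_ids=("red", "blue", "purple"))
        est = estimate_pose(det, placements_lrrr, 158.0, camera)
        assert est.status == "degenerate"
        # the constrained fit still gives a usable viewing distance
        assert est.pose is not None
        assert est.pose.y == pytest.approx(200.0, abs=30.0)

    def test_too_few_cups_insufficient(self, placements_lrrr, camera):
        true = ObserverPose(0, 0.0, 50.0, 158.0, 0.0, -10.0)
        det = detections_for(true, placements_lrrr, camera, cup_ids=("blue", "red"))
        est = estimate_pose(det, placements_lrrr, 158.0, camera)
        assert est.status == "insufficient_cups"
        assert est.pose is None

    def test_nonfinite_input_rejected(self, placements_lrrr, camera):
        det = pd.DataFrame({"cup_id": ["blue", "red", "purple", "yellow"],
                            "az_deg": [0.0, np.nan, 1.0, 2.0],
                            "el_deg": [0.0, 0.0, 0.0, -10.0]})
        with pytest.raises(ValueError):
            estimate_pose(det, placements_lrrr, 158.0, camera)

    def test_noisy_recovery_within_10cm(self, placements_lrrr, camera, layout):
        rng = np.random.default_rng(8)
        errs = []
        for _ in range(100):
            x, y, h, yaw, pitch = random_pose_params(rng, layout)
            true = ObserverPose(0, x, y, h, yaw, pitch)
            det = detections_for(true, placements_lrrr, camera,
                                 noise_sd=0.2, rng=rng)
            if not {"red", "blue", "purple"} <= set(det.cup_id):
                continue
            est = estimate_pose(det, placements_lrrr, h, camera)
            if est.status != "ok":
                continue
            errs.append(np.hypot(est.pose.x - x, est.pose.y - y))
        assert len(errs) > 50
        assert np.median(errs) < 10.0

    def test_rmse_monotone_in_detection_noise(self, placements_lrrr, camera, layout):
        rng = np.random.default_rng(12)
        poses = [random_pose_params(rng, layout) for _ in range(80)]
        rmses = []
        for sd in (0.0, 0.5, 1.0, 2.0):
            sub_rng = np.random.default_rng(99)
            errs = []
            for x, y, h, yaw, pitch in poses:
                true = ObserverPose(0, x, y, h, yaw, pitch)
                det = detections_for(true, placements_lrrr, camera,
                                     noise_sd=sd, rng=sub_rng)
                if not {"red", "blue", "purple"} <= set(det.cup_id):
                    continue
                est = estimate_pose(det, placements_lrrr, h, camera)
                if est.status == "ok":
                    errs.append((est.pose.x - x) ** 2 + (est.pose.y - y) ** 2)
            rmses.append(np.sqrt(np.mean(errs)))
        assert all(a <= b + 1e-9 for a, b in zip(rmses, rmses[1:]))


class TestTrialPoses:
    def test_estimated_path_overlays_truth_in_reliable_region(self, noiseless_trial,
                                                              camera, layout):
        filtered = noiseless_trial.detections
        est = estimate_trial_poses(filtered, noiseless_trial.placements,
                                   158.0, camera, layout)
        truth = noiseless_trial.true_poses
        n = min(len(est), len(truth))
        ok = (est.status[:n] == "ok").to_numpy()
        # reliable region: from room entry until the far floor cup leaves
        # the scene (roughly while y < its depth)
        region = ok & (truth.y_cm[:n].to_numpy() > 0) & (truth.y_cm[:n].to_numpy() < 160)
        err = np.hypot(est.x_cm[:n].to_numpy()[region] - truth.x_cm[:n].to_numpy()[region],
                       est.y_cm[:n].to_numpy()[region] - truth.y_cm[:n].to_numpy()[region])
        assert region.sum() > 10
        # pointwise bound implies the discrete Frechet bound
        assert err.max() < 5.0


class TestSmoothTrack:
    @staticmethod
    def _track(x, y):
        n = len(x)
        return pd.DataFrame({"frame": np.arange(n), "t_s": np.arange(n) / 26.0,
                             "x_cm": x, "y_cm": y})

    def test_constant_track_unchanged(self):
        tr = self._track(np.full(100, 7.0), np.full(100, 30.0))
        out = smooth_track(tr)
        np.testing.assert_allclose(out.x_s_cm, 7.0, atol=1e-9)
        np.testing.assert_allclose(out.y_s_cm, 30.0, atol=1e-9)

    def test_quadratic_track_reproduced_exactly(self):
        t = np.arange(120) / 26.0
        x = 3.0 + 2.0 * t - 0.8 * t**2
        tr = self._track(x, np.zeros_like(x) + 1.0)
        out = smooth_track(tr, window_frames=40, poly_order=2)
        np.testing.assert_allclose(out.x_s_cm, x, atol=1e-8)

    def test_noise_variance_reduced(self):
        rng = np.random.default_rng(0)
        t = np.arange(300)
        x = 0.5 * t + rng.normal(0, 2.0, len(t))
        tr = self._track(x, np.zeros_like(x) + 1.0)
        out = smooth_track(tr)
        resid_in = x - 0.5 * t
        resid_out = out.x_s_cm - 0.5 * t
        assert resid_out.std() < resid_in.std()

    def test_short_track_warns_and_passes_through(self):
        tr = self._track(np.arange(10.0), np.arange(10.0))
        with pytest.warns(UserWarning):
            out = smooth_track(tr, window_frames=40)
        np.testing.assert_allclose(out.x_s_cm, tr.x_cm)

    def test_long_gaps_stay_invalid_short_gaps_bridged(self):
        x = np.linspace(0, 100, 200)
        xg = x.copy()
        xg[50:55] = np.nan  # short gap: bridged
        xg[100:160] = np.nan  # long gap: stays invalid
        tr = self._track(xg, np.zeros_like(x) + 1.0)
        out = smooth_track(tr, max_gap=12)
        assert np.isfinite(out.x_s_cm[50:55]).all()
        assert np.isnan(out.x_s_cm[120:140]).all()

    def test_distance_to_target_cup(self, layout):
        tr = self._track(np.full(60, 0.0), np.full(60, 252.0))
        out = smooth_track(tr, layout=layout)
        np.testing.assert_allclose(out.dist_blue_cm, 50.0, atol=1e-6)

    def test_window_must_exceed_order(self):
        with pytest.raises(ValueError):
            smooth_track(self._track(np.arange(5.0), np.arange(5.0)),
                         window_frames=3, poly_order=4)


class TestResampleGaze:
    @staticmethod
    def _gaze(t, az, el=None, valid=None):
        return pd.DataFrame({
            "t_s": t, "az_deg": az,
            "el_deg": az if el is None else el,
            "valid": np.ones(len(t), dtype=bool) if valid is None else valid,
        })

    def test_linear_signal_reproduced(self):
        t = np.arange(0, 1, 1 / 200.0)
        gaze = self._gaze(t, 3.0 + 10.0 * t)
        frames = np.arange(0.1, 0.9, 1 / 26.0)
        out = resample_gaze(gaze, frames)
        assert out.valid.all()
        np.testing.assert_allclose(out.az_deg, 3.0 + 10.0 * frames, atol=1e-9)

    def test_blink_window_marked_invalid(self):
        t = np.arange(0, 1, 1 / 200.0)
        valid = ~((t > 0.45) & (t < 0.60))
        gaze = self._gaze(t, np.zeros_like(t), valid=valid)
        out = resample_gaze(gaze, np.array([0.5, 0.2]))
        assert not out.valid.iloc[0]
        assert out.valid.iloc[1]

    def test_slow_sinusoid_error_small(self):
        t = np.arange(0, 2, 1 / 200.0)
        az = 5.0 * np.sin(2 * np.pi * t / 1.0)  # period 1 s >> 100 ms window
        gaze = self._gaze(t, az)
        frames = np.arange(0.2, 1.8, 1 / 26.0)
        out = resample_gaze(gaze, frames)
        err = np.abs(out.az_deg - 5.0 * np.sin(2 * np.pi * frames))
        assert err.max() < 0.01

    def test_frame_outside_record_invalid(self):
        t = np.arange(0, 1, 1 / 200.0)
        out = resample_gaze(self._gaze(t, np.zeros_like(t)), np.array([2.0, -0.5]))
        assert not out.valid.any()

    def test_decreasing_timestamps_rejected(self):
        with pytest.raises(ValueError):
            resample_gaze(self._gaze(np.array([0.0, 0.1, 0.05]), np.zeros(3)),
                          np.array([0.05]))
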