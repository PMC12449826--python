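"""The synthetic walker: trajectories, gaze, detections, rendering."""

import numpy as np
import pandas as pd
import pytest

from gazewalk.design import Configuration
from gazewalk.geometry import CUP_COLORS, CameraModel, place_cups, project_points
from gazewalk.simulate import (
    GazeScript,
    NoiseModel,
    WalkerProfile,
    default_script,
    render_frames,
    simulate_detections,
    simulate_gaze,
    simulate_pouring_periods,
    simulate_trajectory,
    simulate_trial,
)
from tests.conftest import script_no_blinks


class TestTrajectory:
    def test_around_policy_keeps_clearance_from_floor_cups(self, layout):
        cfg = Configuration("left", "left", "left", "left")
        profile = WalkerProfile(path_policy="around_right", lateral_jitter_sd=0.0)
        poses = simulate_trajectory(profile, cfg, layout, seed=0)
        for p in place_cups(cfg, layout):
            if p.support != "floor":
                continue
            d = np.hypot(poses.x_cm - p.ground_xy[0], poses.y_cm - p.ground_xy[1])
            assert d.min() > 10.0

    def test_between_policy_crosses_midway_between_obstacles(self, layout):
        cfg = Configuration("left", "right", "left", "left")
        profile = WalkerProfile(path_policy="between", lateral_jitter_sd=0.0)
        poses = simulate_trajectory(profile, cfg, layout, seed=0)
        # lateral position when crossing depth 172.5 must lie between the
        # two obstacle lateral positions
        x_mid = np.interp(172.5, poses.y_cm, poses.x_cm)
        assert -27.5 < x_mid < 27.5

    def test_between_policy_infeasible_for_same_side_obstacles(self, layout):
        cfg = Configuration("left", "left", "left", "left")
        profile = WalkerProfile(path_policy="between")
        with pytest.raises(ValueError):
            simulate_trajectory(profile, cfg, layout, seed=0)

    def test_walk_duration_follows_arc_length(self, layout, config_lrrr):
        profile = WalkerProfile(walking_speed=100.0, path_policy="step_over",
                                start_depth=-150.0, lateral_jitter_sd=0.0,
                                table_duration=0.0)
        poses = simulate_trajectory(profile, config_lrrr, layout, seed=0)
        # straight-line distance start -> standing point, divided by speed
        expected = (302.0 - 50.0 + 150.0) / 100.0
        assert poses.walk_T.iloc[0] == pytest.approx(expected, rel=0.05)

    def test_frame_count_matches_duration_and_rate(self, layout, config_lrrr):
        camera = CameraModel(frame_rate=26.0)
        profile = WalkerProfile()
        poses = simulate_trajectory(profile, config_lrrr, layout, seed=0, camera=camera)
        duration = poses.t_s.iloc[-1]
        assert abs(len(poses) - duration * 26.0) <= 1.5

    def test_ends_standing_before_target_cup(self, layout, config_lrrr):
        poses = simulate_trajectory(WalkerProfile(), config_lrrr, layout, seed=4)
        assert poses.y_cm.iloc[-1] == pytest.approx(252.0, abs=1.0)
        assert abs(poses.x_cm.iloc[-1]) < 5.0


class TestGaze:
    def test_degenerate_noise_reproduces_truth(self, placements_lrrr, camera, layout,
                                               config_lrrr):
        poses = simulate_trajectory(WalkerProfile(), config_lrrr, layout, seed=1)
        truth, measured = simulate_gaze(script_no_blinks(), poses, placements_lrrr,
                                        camera, NoiseModel.noiseless(), seed=2)
        assert measured.valid.all()
        np.testing.assert_allclose(measured.az_deg, truth.az_deg, atol=1e-12)
        np.testing.assert_allclose(measured.el_deg, truth.el_deg, atol=1e-12)

    def test_noise_sd_recovered_at_large_n(self, placements_lrrr, camera, layout,
                                           config_lrrr):
        profile = WalkerProfile(table_duration=30.0)
        poses = simulate_trajectory(profile, config_lrrr, layout, seed=1)
        noise = NoiseModel(sd_az=1.8, sd_el=4.0, offset_az=-0.5, offset_el=3.9)
        truth, measured = simulate_gaze(script_no_blinks(), poses, placements_lrrr,
                                        camera, noise, seed=3)
        d_az = measured.az_deg - truth.az_deg
        d_el = measured.el_deg - truth.el_deg
        n = len(d_az)
        assert d_az.std() == pytest.approx(1.8, abs=5 * 1.8 / np.sqrt(n))
        assert d_el.std() == pytest.approx(4.0, abs=5 * 4.0 / np.sqrt(n))
        assert d_az.mean() == pytest.approx(-0.5, abs=5 * 1.8 / np.sqrt(n))

    def test_blink_count_poisson(self, placements_lrrr, camera, config_lrrr, layout):
        profile = WalkerProfile(table_duration=600.0, walking_speed=200.0)
        poses = simulate_trajectory(profile, config_lrrr, layout, seed=1)
        script = GazeScript(segments=((0.0, ("cup", "blue")),), blink_rate=0.2,
                            blink_duration_range=(0.05, 0.05))
        _, measured = simulate_gaze(script, poses, placements_lrrr, camera,
                                    NoiseModel.noiseless(), seed=4)
        invalid = (~measured.valid).to_numpy()
        episodes = np.sum(np.diff(invalid.astype(int)) == 1) + invalid[0]
        expected = 0.2 * (measured.t_s.iloc[-1] - measured.t_s.iloc[0])
        assert episodes == pytest.approx(expected, abs=4 * np.sqrt(expected))

    def test_gaze_sampling_rate(self, noiseless_trial):
        dt = np.diff(noiseless_trial.gaze_measured.t_s)
        assert np.allclose(dt, 1.0 / 200.0)
        assert noiseless_trial.gaze_measured.t_s.is_monotonic_increasing


class TestDetections:
    def test_noiseless_detections_are_exact_projections(self, noiseless_trial,
                                                        camera):
        pts = np.array([p.world_position for p in noiseless_trial.placements])
        ids = [p.cup_id for p in noiseless_trial.placements]
        for frame in (0, 50, 120):
            pose = noiseless_trial.pose_at_frame(frame)
            az, el, vis = project_points(pose, camera, pts)
            got = noiseless_trial.detections.query("frame == @frame")
            assert set(got.cup_id) == {c for c, v in zip(ids, vis) if v}
            for r in got.itertuples():
                j = ids.index(r.cup_id)
                assert r.az_deg == pytest.approx(az[j], abs=1e-9)
                assert r.el_deg == pytest.approx(el[j], abs=1e-9)

    def test_full_dropout_empties_detections(self, placements_lrrr, camera,
                                             noiseless_trial):
        noise = NoiseModel(detection_dropout_p=1.0, false_positive_rate=0.0)
        det = simulate_detections(noiseless_trial.true_poses, placements_lrrr,
                                  camera, noise, seed=0)
        assert len(det) == 0

    def test_false_positive_rate(self, placements_lrrr, config_lrrr, layout):
        # static observer facing the whole room with a near-omniscient
        # field of view, so every injected floor point is visible and the
        # count is plain Bernoulli at the configured rate
        wide = CameraModel(fov=(178.0, 178.0))
        n = 2600
        poses = pd.DataFrame({"t_s": np.arange(n) / 26.0, "x_cm": 0.0,
                              "y_cm": -50.0, "eye_h_cm": 158.0,
                              "yaw_deg": 0.0, "pitch_deg": -20.0})
        noise = NoiseModel(detection_dropout_p=0.0, false_positive_rate=0.05,
                           detection_sd=0.0)
        det = simulate_detections(poses, placements_lrrr, wide, noise, seed=5,
                                  layout=layout)
        n_fp = int(det.is_false_positive.sum())
        assert n_fp == pytest.approx(130, abs=4 * np.sqrt(2600 * 0.05 * 0.95))
        assert (det[det.is_false_positive].cup_id == "yellow").all()


class TestReproducibility:
    def test_trials_bitwise_identical_under_seed(self, config_lrrr):
        a = simulate_trial(config_lrrr, seed=9)
        b = simulate_trial(config_lrrr, seed=9)
        pd.testing.assert_frame_equal(a.true_poses, b.true_poses)
        pd.testing.assert_frame_equal(a.gaze_measured, b.gaze_measured)
        pd.testing.assert_frame_equal(a.detections, b.detections)

    def test_different_seed_changes_measurements(self, config_lrrr):
        a = simulate_trial(config_lrrr, seed=9)
        b = simulate_trial(config_lrrr, seed=10)
        n = min(len(a.gaze_measured), len(b.gaze_measured))
        assert not np.allclose(a.gaze_measured.az_deg[:n], b.gaze_measured.az_deg[:n],
                               equal_nan=True)


class TestPouringSimulation:
    def test_blue_and_purple_close_only_within_periods(self):
        frames = simulate_pouring_periods(1, 3, 20, seed=0)[0]
        from gazewalk.geometry import angular_distance
        sep = angular_distance(frames[["blue_az", "blue_el"]].to_numpy(),
                               frames[["purple_az", "purple_el"]].to_numpy())
        assert (sep < 5.0).sum() == 3 * 20
        assert (sep >= 5.0).sum() == len(frames) - 60

    def test_zero_noise_locks_gaze_on_purple(self):
        frames = simulate_pouring_periods(1, 2, 15, noise=NoiseModel.noiseless(),
                                          seed=0)[0]
        pouring = frames[np.isclose(frames.blue_el, frames.purple_el, atol=5)]
        np.testing.assert_allclose(pouring.gaze_az, pouring.purple_az, atol=1e-9)


class TestRendering:
    def test_visible_cups_render_at_projected_centers(self, noiseless_trial):
        from gazewalk.detection import segment_by_color

        cam = CameraModel(resolution=(640, 640))
        poses = noiseless_trial.true_poses.iloc[60:61]
        frame_idx = 60
        _, img = next(render_frames(poses, noiseless_trial.placements, cam, seed=0))
        cands = segment_by_color(img, cam, CUP_COLORS)
        pose = noiseless_trial.pose_at_frame(frame_idx)
        pts = np.array([p.world_position for p in noiseless_trial.placements])
        az, el, vis = project_points(pose, cam, pts)
        ids = [p.cup_id for p in noiseless_trial.placements]
        assert {c.cup_id for c in cands} == {c for c, v in zip(ids, vis) if v}
        for c in cands:
            j = ids.index(c.cup_id)
            assert abs(c.az - az[j]) < 0.3 and abs(c.el - el[j]) < 0.3

    def test_disk_radius_halves_with_doubled_distance(self, placements_lrrr):
        import pandas as pd

        cam = CameraModel(resolution=(640, 640))
        blue = next(p for p in placements_lrrr if p.cup_id == "blue")

        def disk_area(y):
            poses = pd.DataFrame({"t_s": [0.0], "x_cm": [0.0], "y_cm": [y],
                                  "eye_h_cm": [75.5], "yaw_deg": [0.0],
                                  "pitch_deg": [0.0]})
            _, img = next(render_frames(poses, [blue], cam, seed=0))
            return (img[:, :, 2] > 200).sum()

        near, far = disk_area(302 - 100), disk_area(302 - 200)
        assert np.sqrt(near / far) == pytest.approx(2.0, rel=0.07)
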