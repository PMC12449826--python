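"""Synthetic walking-and-gazing trials.

Generates ground-truth data for the whole pipeline: an observer walking
from a hallway into the room toward the table, head orientation that leads
gaze, scripted gaze targets, blink episodes, gaze measurement noise with
the tracker's reported offsets and spreads, per-frame cup detections with
dropouts and false positives, and (optionally) rendered color frames.

The defaults emulate the study conditions: eye height 158 cm (the cohort
median), start about 3 m outside the door, scene frames at 26 Hz with an
82 deg x 82 deg field of view, gaze samples at about 200 Hz, and a gaze
measurement model with horizontal/vertical offsets of -0.5/+3.9 deg and
standard deviations of 1.8/4.0 deg.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .design import Configuration
from .geometry import (
    CUP_IDS,
    CameraModel,
    CupPlacement,
    ObserverPose,
    RoomLayout,
    place_cups,
    project_points,
    ray_to_pixel,
)

__all__ = [
    "WalkerProfile",
    "GazeScript",
    "NoiseModel",
    "SimulatedTrial",
    "simulate_trajectory",
    "simulate_gaze",
    "simulate_detections",
    "simulate_trial",
    "simulate_pouring_periods",
    "render_frames",
    "default_script",
]

GAZE_RATE_HZ = 200.0


@dataclass(frozen=True)
class WalkerProfile:
    """Walking style of one synthetic participant."""

    eye_height: float = 158.0
    walking_speed: float = 110.0  # cm/s
    start_depth: float = -300.0  # y at trial start (outside the room)
    path_policy: str = "auto"  # auto | around_left | around_right | between | step_over
    lateral_jitter_sd: float = 6.0  # start-position jitter, cm
    table_duration: float = 4.0  # standing phase at the table, s

    def __post_init__(self) -> None:
        if self.eye_height <= 0 or self.walking_speed <= 0:
            raise ValueError("eye height and speed must be positive")
        if self.start_depth > -100:
            raise ValueError("start_depth must be at most -100 cm")


@dataclass(frozen=True)
class GazeScript:
    """Ordered gaze targets as fractions of the trial.

    Each segment is ``(start_fraction, target)`` where target is one of
    ``("cup", cup_id)``, ``("floor_near", cup_id)``, ``("point", (x, y, z))``
    or ``("ahead", None)``. Segments cover [0, 1) without overlap.
    """

    segments: tuple[tuple[float, tuple[str, object]], ...]
    blink_rate: float = 0.25  # episodes per second
    blink_duration_range: tuple[float, float] = (0.1, 0.3)
    floor_offset_sd: float = 20.0  # scatter of floor_near points around a cup, cm

    def __post_init__(self) -> None:
        fracs = [s[0] for s in self.segments]
        if not self.segments or fracs[0] != 0.0 or any(
                b <= a for a, b in zip(fracs, fracs[1:])):
            raise ValueError("segments must start at 0 and be strictly increasing")
        if self.blink_rate < 0 or min(self.blink_duration_range) < 0:
            raise ValueError("blink parameters must be non-negative")

    def target_at(self, frac: float) -> tuple[str, object]:
        idx = 0
        for i, (start, _) in enumerate(self.segments):
            if frac >= start:
                idx = i
        return self.segments[idx][1]


@dataclass(frozen=True)
class NoiseModel:
    """Gaze measurement and detection noise.

    Defaults are the reported precision of the head-mounted tracker
    combined with scene-image cup localization: horizontal/vertical gaze
    offsets of -0.5 and +3.9 deg and standard deviations of 1.8 and
    4.0 deg.
    """

    offset_az: float = -0.5
    offset_el: float = 3.9
    sd_az: float = 1.8
    sd_el: float = 4.0
    detection_dropout_p: float = 0.02
    false_positive_rate: float = 0.05  # extra yellow-labeled blobs per frame
    detection_sd: float = 0.2  # angular jitter of detected cup centers, deg

    def __post_init__(self) -> None:
        if self.sd_az < 0 or self.sd_el < 0 or self.detection_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if not (0 <= self.detection_dropout_p <= 1):
            raise ValueError("dropout probability must be in [0, 1]")

    @classmethod
    def noiseless(cls) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass
class SimulatedTrial:
    """One synthetic trial: ground truth plus simulated measurements."""

    config: Configuration
    placements: list[CupPlacement]
    true_poses: pd.DataFrame  # t_s, x_cm, y_cm, eye_h_cm, yaw_deg, pitch_deg
    gaze_truth: pd.DataFrame  # t_s, az_deg, el_deg, valid, target
    gaze_measured: pd.DataFrame  # t_s, az_deg, el_deg, valid
    detections: pd.DataFrame  # frame, t_s, cup_id, az_deg, el_deg, is_false_positive
    meta: dict = field(default_factory=dict)

    def pose_at_frame(self, i: int, camera_t: float | None = None) -> ObserverPose:
        r = self.true_poses.iloc[i]
        return ObserverPose(r.t_s, r.x_cm, r.y_cm, r.eye_h_cm, r.yaw_deg, r.pitch_deg)


def default_script(rng: np.random.Generator | None = None) -> GazeScript:
    """A gaze script following the commonly observed pattern: table cups
    from the start, the floor near each obstacle while entering the room,
    then the target cup and its neighboring obstacle, finally the
    destination cup."""
    return GazeScript(segments=(
        (0.00, ("cup", "blue")),
        (0.30, ("floor_near", "turquoise")),
        (0.41, ("floor_near", "yellow")),
        (0.52, ("cup", "red")),
        (0.62, ("cup", "blue")),
        (0.80, ("cup", "purple")),
    ))


def _resolve_policy(policy: str, config: Configuration,
                    rng: np.random.Generator) -> str:
    if policy != "auto":
        return policy
    near, far = config.near_floor_side, config.far_floor_side
    if near == far:
        return "around_right" if near == "left" else "around_left"
    # opposite sides: mostly pass between, sometimes step over
    return "between" if rng.random() < 0.8 else "step_over"


def _path_waypoints(policy: str, config: Configuration, layout: RoomLayout,
                    profile: WalkerProfile, rng: np.random.Generator) -> np.ndarray:
    placements = {p.cup_id: p for p in place_cups(config, layout)}
    near = placements["turquoise"].ground_xy
    far = placements["yellow"].ground_xy
    stand_y = layout.door_to_table + layout.target_depth_on_table - 50.0
    x0 = rng.normal(0.0, profile.lateral_jitter_sd)
    pts = [(x0, profile.start_depth), (x0 * 0.4, profile.start_depth / 2), (0.0, 0.0)]
    clearance = 35.0
    if policy == "around_left":
        pts += [(near[0] - clearance, near[1]), (far[0] - clearance, far[1])]
    elif policy == "around_right":
        pts += [(near[0] + clearance, near[1]), (far[0] + clearance, far[1])]
    elif policy == "between":
        if config.near_floor_side == config.far_floor_side:
            raise ValueError("'between' path requires floor obstacles on opposite sides")
        mid_y = (near[1] + far[1]) / 2.0
        pts += [(-np.sign(near[0]) * 12.0, near[1]), ((near[0] + far[0]) / 2.0, mid_y),
                (-np.sign(far[0]) * 12.0, far[1])]
    elif policy == "step_over":
        pts += [(0.0, near[1]), (0.0, far[1])]
    else:
        raise ValueError(f"unknown path policy {policy!r}")
    pts += [(0.0, stand_y)]
    return np.asarray(pts, dtype=float)


def _target_world_point(target: tuple[str, object],
                        placements: dict[str, CupPlacement],
                        floor_offsets: dict[str, np.ndarray]) -> np.ndarray | None:
    kind, arg = target
    if kind == "cup":
        return np.asarray(placements[arg].world_position)  # type: ignore[index]
    if kind == "floor_near":
        gx, gy = placements[arg].ground_xy  # type: ignore[index]
        off = floor_offsets.get(arg, np.zeros(2))  # type: ignore[arg-type]
        return np.array([gx + off[0], gy + off[1], 0.0])
    if kind == "point":
        return np.asarray(arg, dtype=float)
    return None  # straight ahead


def simulate_trajectory(profile: WalkerProfile, config: Configuration,
                        layout: RoomLayout = RoomLayout(),
                        seed: int | np.random.Generator = 0,
                        camera: CameraModel = CameraModel(),
                        script: GazeScript | None = None) -> pd.DataFrame:
    """Simulate the observer's pose series at frame times.

    The ground path runs from the hallway start through obstacle-avoiding
    waypoints to a standing point 50 cm before the target cup, followed by
    a standing phase at the table. Yaw tracks the path tangent blended
    halfway toward the current gaze target (gaze eccentricity in the head
    capped at 40 deg); pitch follows the low-pass filtered target
    elevation.

    Raises ``ValueError`` for an infeasible policy/configuration pair.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    policy = _resolve_policy(profile.path_policy, config, rng)
    wps = _path_waypoints(policy, config, layout, profile, rng)

    # arc-length parameterized smooth path through the waypoints
    chord = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(wps, axis=0), axis=1))])
    spline = CubicSpline(chord, wps, axis=0)
    dense_s = np.linspace(0, chord[-1], 2000)
    dense_xy = spline(dense_s)
    seg = np.linalg.norm(np.diff(dense_xy, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    total_len = arclen[-1]

    walk_T = total_len / profile.walking_speed
    total_T = walk_T + profile.table_duration
    n_frames = int(np.floor(total_T * camera.frame_rate)) + 1
    t = np.arange(n_frames) / camera.frame_rate

    s_of_t = np.minimum(t, walk_T) * profile.walking_speed
    xy = np.column_stack([np.interp(s_of_t, arclen, dense_xy[:, 0]),
                          np.interp(s_of_t, arclen, dense_xy[:, 1])])

    # path tangent heading (deg from +y, positive toward +x)
    ds = 1.0
    ahead = np.column_stack([np.interp(np.minimum(s_of_t + ds, total_len), arclen, dense_xy[:, 0]),
                             np.interp(np.minimum(s_of_t + ds, total_len), arclen, dense_xy[:, 1])])
    tang = ahead - xy
    still = np.linalg.norm(tang, axis=1) < 1e-6
    heading = np.rad2deg(np.arctan2(tang[:, 0], tang[:, 1]))
    heading[still] = 0.0

    # head orientation: blend toward the scripted gaze target
    placements = {p.cup_id: p for p in place_cups(config, layout)}
    script = script or default_script()
    floor_offsets = {cid: rng.normal(0, script.floor_offset_sd, 2)
                     for cid in ("turquoise", "yellow")}
    yaw = np.empty(n_frames)
    target_el = np.empty(n_frames)
    for i in range(n_frames):
        tgt = script.target_at(t[i] / total_T)
        p = _target_world_point(tgt, placements, floor_offsets)
        if p is None:
            yaw[i] = heading[i]
            target_el[i] = 0.0
            continue
        d = p - np.array([xy[i, 0], xy[i, 1], profile.eye_height])
        tgt_az_world = np.rad2deg(np.arctan2(d[0], d[1]))
        tgt_el = np.rad2deg(np.arctan2(d[2], np.hypot(d[0], d[1])))
        y = heading[i] + 0.5 * _wrap(tgt_az_world - heading[i])
        # cap gaze eccentricity in the head at 40 deg
        ecc = _wrap(tgt_az_world - y)
        if abs(ecc) > 40.0:
            y = tgt_az_world - np.sign(ecc) * 40.0
        yaw[i] = y
        target_el[i] = tgt_el
    pitch = _lowpass(0.6 * target_el, camera.frame_rate, cutoff_hz=1.0)
    pitch = np.clip(pitch, -80.0, 80.0)

    return pd.DataFrame({
        "t_s": t, "x_cm": xy[:, 0], "y_cm": xy[:, 1],
        "eye_h_cm": profile.eye_height, "yaw_deg": yaw, "pitch_deg": pitch,
        "policy": policy, "walk_T": walk_T,
    })


def _wrap(angle_deg):
    return (np.asarray(angle_deg) + 180.0) % 360.0 - 180.0


def _lowpass(x: np.ndarray, fs: float, cutoff_hz: float) -> np.ndarray:
    alpha = 1.0 - np.exp(-2 * np.pi * cutoff_hz / fs)
    out = np.empty_like(x)
    acc = x[0]
    for i, v in enumerate(x):
        acc += alpha * (v - acc)
        out[i] = acc
    return out


def _pose_rows(poses: pd.DataFrame) -> Iterable[ObserverPose]:
    for r in poses.itertuples():
        yield ObserverPose(r.t_s, r.x_cm, r.y_cm, r.eye_h_cm, r.yaw_deg, r.pitch_deg)


def simulate_gaze(script: GazeScript, poses: pd.DataFrame,
                  placements: Sequence[CupPlacement], camera: CameraModel,
                  noise: NoiseModel, seed: int | np.random.Generator = 0,
                  gaze_rate: float = GAZE_RATE_HZ,
                  floor_offsets: dict[str, np.ndarray] | None = None,
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate true and measured gaze at the gaze-sampling rate.

    The true gaze ray points at the scripted target each sample (head pose
    linearly interpolated between frames); the measured ray adds the fixed
    offsets plus independent Gaussian azimuth/elevation noise. Blink
    episodes (Poisson onsets, uniform durations) replace samples with
    invalid markers. A target behind the camera falls back to straight
    ahead for that sample.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pmap = {p.cup_id: p for p in placements}
    if floor_offsets is None:
        floor_offsets = {cid: rng.normal(0, script.floor_offset_sd, 2)
                         for cid in ("turquoise", "yellow")}

    t0, t1 = poses.t_s.iloc[0], poses.t_s.iloc[-1]
    tg = np.arange(t0, t1, 1.0 / gaze_rate)
    total_T = t1 - t0

    def interp(col):
        return np.interp(tg, poses.t_s.to_numpy(), poses[col].to_numpy())

    xs, ys, hs = interp("x_cm"), interp("y_cm"), interp("eye_h_cm")
    yaws, pitchs = interp("yaw_deg"), interp("pitch_deg")

    az = np.zeros(len(tg))
    el = np.zeros(len(tg))
    labels = np.empty(len(tg), dtype=object)
    for i, ti in enumerate(tg):
        tgt = script.target_at((ti - t0) / total_T if total_T > 0 else 0.0)
        p = _target_world_point(tgt, pmap, floor_offsets)
        labels[i] = f"{tgt[0]}:{tgt[1]}" if tgt[1] is not None else tgt[0]
        if p is None:
            continue
        pose = ObserverPose(ti, xs[i], ys[i], hs[i], yaws[i], pitchs[i])
        a, e, vis = project_points(pose, camera, p[None, :])
        # behind the camera: fall back to straight ahead
        if abs(a[0]) > 90.0:
            labels[i] = "ahead"
            continue
        az[i], el[i] = a[0], e[0]

    meas_az = az + noise.offset_az + rng.normal(0, noise.sd_az, len(tg))
    meas_el = el + noise.offset_el + rng.normal(0, noise.sd_el, len(tg))

    valid = np.ones(len(tg), dtype=bool)
    if script.blink_rate > 0:
        tb = t0
        lo, hi = script.blink_duration_range
        while True:
            tb += rng.exponential(1.0 / script.blink_rate)
            if tb >= t1:
                break
            dur = rng.uniform(lo, hi)
            valid &= ~((tg >= tb) & (tg < tb + dur))
    meas_az = np.where(valid, meas_az, np.nan)
    meas_el = np.where(valid, meas_el, np.nan)

    truth = pd.DataFrame({"t_s": tg, "az_deg": az, "el_deg": el,
                          "valid": True, "target": labels})
    measured = pd.DataFrame({"t_s": tg, "az_deg": meas_az, "el_deg": meas_el,
                             "valid": valid})
    return truth, measured


def simulate_detections(poses: pd.DataFrame, placements: Sequence[CupPlacement],
                        camera: CameraModel, noise: NoiseModel,
                        seed: int | np.random.Generator = 0,
                        layout: RoomLayout = RoomLayout()) -> pd.DataFrame:
    """Per-frame cup detections: projected rays of visible cups with random
    dropouts, plus yellow-labeled false positives at random floor points."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pts = np.array([p.world_position for p in placements])
    ids = [p.cup_id for p in placements]
    rows = []
    for frame, pose in enumerate(_pose_rows(poses)):
        az, el, vis = project_points(pose, camera, pts)
        for j, cid in enumerate(ids):
            if not vis[j]:
                continue
            if noise.detection_dropout_p > 0 and rng.random() < noise.detection_dropout_p:
                continue
            daz, del_ = az[j], el[j]
            if noise.detection_sd > 0:
                daz += rng.normal(0, noise.detection_sd)
                del_ += rng.normal(0, noise.detection_sd)
            rows.append((frame, pose.t, cid, daz, del_, False))
        if noise.false_positive_rate > 0 and rng.random() < noise.false_positive_rate:
            # light on the floor mistaken for the yellow cup
            fp = np.array([rng.uniform(-layout.room_width / 2, layout.room_width / 2),
                           rng.uniform(0, layout.door_to_table), 0.0])
            faz, fel, fvis = project_points(pose, camera, fp[None, :])
            if fvis[0]:
                rows.append((frame, pose.t, "yellow", faz[0], fel[0], True))
    return pd.DataFrame(rows, columns=["frame", "t_s", "cup_id", "az_deg",
                                       "el_deg", "is_false_positive"])


def simulate_trial(config: Configuration, profile: WalkerProfile | None = None,
                   script: GazeScript | None = None,
                   noise: NoiseModel | None = None,
                   layout: RoomLayout = RoomLayout(),
                   camera: CameraModel = CameraModel(),
                   seed: int = 0) -> SimulatedTrial:
    """Simulate one complete trial (trajectory, gaze, detections)."""
    profile = profile or WalkerProfile()
    script = script or default_script()
    noise = noise if noise is not None else NoiseModel()
    ss = np.random.SeedSequence(seed)
    r_traj, r_gaze, r_det = [np.random.default_rng(s) for s in ss.spawn(3)]

    placements = place_cups(config, layout)
    # one draw of the floor-gaze scatter shared by head model and gaze
    r_shared = np.random.default_rng(ss.spawn(1)[0])
    floor_offsets = {cid: r_shared.normal(0, script.floor_offset_sd, 2)
                     for cid in ("turquoise", "yellow")}

    poses = simulate_trajectory(profile, config, layout, r_traj, camera, script)
    truth, measured = simulate_gaze(script, poses, placements, camera, noise,
                                    r_gaze, floor_offsets=floor_offsets)
    detections = simulate_detections(poses, placements, camera, noise, r_det, layout)
    meta = {
        "seed": seed, "policy": poses["policy"].iloc[0],
        "walk_T": float(poses["walk_T"].iloc[0]),
        "eye_height": profile.eye_height,
    }
    return SimulatedTrial(config, placements, poses.drop(columns=["policy", "walk_T"]),
                          truth, measured, detections, meta)


def simulate_pouring_periods(n_participants: int = 10, n_periods: int = 10,
                             frames_per_period: int = 20,
                             noise: NoiseModel | None = None,
                             seed: int = 0,
                             camera: CameraModel = CameraModel(),
                             layout: RoomLayout = RoomLayout(),
                             gap_frames: int = 15,
                             eye_height: float = 158.0) -> list[pd.DataFrame]:
    """Simulate the at-table pouring phase for precision estimation.

    For each participant, a frame series standing at the table in which
    ``n_periods`` pouring episodes occur: the target (blue) cup is held
    about 3 deg above the destination (purple) cup and gaze is locked on
    the purple cup's center plus the measurement noise. Between episodes
    the blue cup is back on the table (separation well above 5 deg) and
    gaze wanders. Returns one frame DataFrame per participant with the
    columns consumed by the pouring-period detector.
    """
    noise = noise if noise is not None else NoiseModel()
    ss = np.random.SeedSequence(seed)
    out = []
    for rng_seed in ss.spawn(n_participants):
        rng = np.random.default_rng(rng_seed)
        config = Configuration("left", "left", "right", "right")
        placements = {p.cup_id: p for p in place_cups(config, layout)}
        purple = np.asarray(placements["purple"].world_position)
        blue_home = np.asarray(placements["blue"].world_position)
        pose = ObserverPose(0.0, purple[0] * 0.3, layout.door_to_table - 40.0,
                            eye_height, np.rad2deg(np.arctan2(purple[0], 60.0)), -40.0)
        (paz, pel), _ = _project_scalar(pose, camera, purple)
        (haz, hel), _ = _project_scalar(pose, camera, blue_home)
        dist_purple = np.linalg.norm(purple - pose.eye_position)
        # blue cup held just above the purple one while pouring
        held = purple + np.array([0.0, 0.0, np.tan(np.deg2rad(3.0)) * dist_purple])
        (baz, bel), _ = _project_scalar(pose, camera, held)

        rows = []
        frame = 0
        t_frame = 1.0 / camera.frame_rate
        for k in range(n_periods):
            for _ in range(gap_frames):
                rows.append((frame, frame * t_frame, 60.0, haz, hel, paz, pel,
                             paz + rng.uniform(-15, 15), pel + rng.uniform(5, 25), True))
                frame += 1
            for _ in range(frames_per_period):
                gaz = paz + noise.offset_az + rng.normal(0, noise.sd_az)
                gel = pel + noise.offset_el + rng.normal(0, noise.sd_el)
                rows.append((frame, frame * t_frame, 60.0, baz, bel, paz, pel,
                             gaz, gel, True))
                frame += 1
        for _ in range(gap_frames):
            rows.append((frame, frame * t_frame, 60.0, haz, hel, paz, pel,
                         paz + rng.uniform(-15, 15), pel + rng.uniform(5, 25), True))
            frame += 1
        out.append(pd.DataFrame(rows, columns=[
            "frame", "t_s", "distance_to_blue_cm", "blue_az", "blue_el",
            "purple_az", "purple_el", "gaze_az", "gaze_el", "gaze_valid"]))
    return out


def _project_scalar(pose, camera, point):
    az, el, vis = project_points(pose, camera, np.asarray(point)[None, :])
    return (float(az[0]), float(el[0])), bool(vis[0])


def render_frames(poses: pd.DataFrame, placements: Sequence[CupPlacement],
                  camera: CameraModel, seed: int | np.random.Generator = 0,
                  distractor_rate: float = 0.0,
                  background: tuple[int, int, int] = (120, 118, 115)):
    """Render each frame as a color image with cups drawn as filled disks.

    Each visible cup appears as a disk of its nominal color at its
    projected pixel position, with radius set by the angular size of its
    mouth at the current distance. Optional distractor patches (pale
    yellow, emulating light on the floor) are injected at the given rate.
    Yields ``(frame_index, image)`` with images as HxWx3 uint8 arrays.
    """
    from skimage.draw import disk as draw_disk

    if camera.resolution is None:
        camera = CameraModel(camera.fov, camera.frame_rate, (1088, 1088))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w, h = camera.resolution
    fx = (w / 2.0) / np.tan(np.deg2rad(camera.fov[0] / 2.0))
    pts = np.array([p.world_position for p in placements])

    for frame, pose in enumerate(_pose_rows(poses)):
        img = np.empty((h, w, 3), dtype=np.uint8)
        img[:] = background
        az, el, vis = project_points(pose, camera, pts)
        dists = np.linalg.norm(pts - pose.eye_position, axis=1)
        order = np.argsort(-dists)  # draw far cups first
        if distractor_rate > 0 and rng.random() < distractor_rate:
            du, dv = rng.uniform(0.15 * w, 0.85 * w), rng.uniform(0.55 * h, 0.95 * h)
            rr, cc = draw_disk((dv, du), rng.uniform(8, 20), shape=img.shape[:2])
            img[rr, cc] = (228, 214, 80)  # pale light patch, close to yellow
        for j in order:
            if not vis[j]:
                continue
            u, v = ray_to_pixel(camera, az[j], el[j])
            ang_r = np.arctan((placements[j].cup.mouth_diameter / 2.0) / dists[j])
            pix_r = max(2.0, fx * np.tan(ang_r))
            rr, cc = draw_disk((float(v), float(u)), pix_r, shape=img.shape[:2])
            img[rr, cc] = placements[j].cup.color
        yield frame, img
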