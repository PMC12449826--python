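"""Observer localization from detected cup rays and known cup placements.

Each frame, the walker's ground position and camera orientation
``(x, y, yaw, pitch)`` are estimated by minimizing the sum of squared
angular distances between the observed cup rays and the rays predicted by
the forward camera model, with the eye height fixed (known per
participant) and roll fixed at zero. A reliable estimate needs all three
table cups plus at least one floor cup: the table cups alone are nearly
collinear, so viewing distance and viewing angle are confounded
(``degenerate``).

The resulting depth and lateral tracks are smoothed with a Savitzky-Golay
filter (40-frame window), and the ~200 Hz gaze stream is resampled at the
frame times with a local second-order polynomial fit in a 100 ms window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .geometry import (
    FLOOR_CUPS,
    TABLE_CUPS,
    CameraModel,
    CupPlacement,
    ObserverPose,
    RoomLayout,
    ray_unit_vector,
)

__all__ = ["PoseEstimate", "estimate_pose", "estimate_trial_poses",
           "smooth_track", "resample_gaze", "build_track"]

# parameter scales used to normalize convergence checks: cm, cm, deg, deg
_SCALES = np.array([100.0, 100.0, 10.0, 10.0])


@dataclass
class PoseEstimate:
    pose: ObserverPose | None
    residual_rms: float
    n_cups_used: int
    status: str  # ok | insufficient_cups | degenerate | diverged


def _predict_units(params: np.ndarray, pts: np.ndarray, eye_h: float) -> np.ndarray:
    """Unit rays (right, up, forward) of world points for pose params."""
    x, y, yaw_deg, pitch_deg = params
    d = pts - np.array([x, y, eye_h])
    yaw = np.deg2rad(yaw_deg)
    pitch = np.deg2rad(pitch_deg)
    right = np.array([np.cos(yaw), -np.sin(yaw), 0.0])
    fwd0 = np.array([np.sin(yaw), np.cos(yaw), 0.0])
    upw = np.array([0.0, 0.0, 1.0])
    fwd = fwd0 * np.cos(pitch) + upw * np.sin(pitch)
    up = upw * np.cos(pitch) - fwd0 * np.sin(pitch)
    cam = np.column_stack([d @ right, d @ up, d @ fwd])
    return cam / np.linalg.norm(cam, axis=1, keepdims=True)


def _residuals(params, pts, eye_h, obs_units):
    return (_predict_units(params, pts, eye_h) - obs_units).ravel()


def _gauss_newton(params0, pts, eye_h, obs_units, max_iter=100, tol=1e-6,
                  mask: np.ndarray | None = None):
    """Damped Gauss-Newton on the unit-ray residuals. ``mask`` selects the
    free parameters (default: all four). Returns (params, converged flag)."""
    params = np.asarray(params0, dtype=float).copy()
    free = np.arange(4) if mask is None else np.flatnonzero(mask)
    steps = np.array([0.5, 0.5, 0.05, 0.05])  # finite-difference steps
    r = _residuals(params, pts, eye_h, obs_units)
    cost = r @ r
    lam = 1e-4
    for _ in range(max_iter):
        J = np.empty((r.size, len(free)))
        for col, k in enumerate(free):
            dp = np.zeros(4)
            dp[k] = steps[k]
            J[:, col] = (_residuals(params + dp, pts, eye_h, obs_units) - r) / steps[k]
        JtJ = J.T @ J
        g = J.T @ r
        for _ in range(8):  # Levenberg-Marquardt damping backtrack
            try:
                delta = np.linalg.solve(JtJ + lam * np.diag(np.diag(JtJ) + 1e-12), -g)
            except np.linalg.LinAlgError:
                return params, False
            new_params = params.copy()
            new_params[free] += delta
            r_new = _residuals(new_params, pts, eye_h, obs_units)
            c_new = r_new @ r_new
            if c_new <= cost:
                lam = max(lam * 0.3, 1e-8)
                break
            lam *= 10.0
        else:
            return params, True  # cost cannot be reduced further: at a minimum
        step_norm = np.max(np.abs(delta / _SCALES[free]))
        params, r, cost = new_params, r_new, c_new
        if step_norm < 1e-6:
            return params, True
    return params, False


def _coarse_init(pts, eye_h, obs_units, layout: RoomLayout,
                 blue_xy: tuple[float, float] | None = None) -> np.ndarray:
    best, best_cost = None, np.inf
    centroid = pts.mean(axis=0)
    for x in np.linspace(-layout.room_width / 2 + 20, layout.room_width / 2 - 20, 7):
        for y in np.linspace(-250, layout.door_to_table - 30, 9):
            dx, dy = centroid[0] - x, centroid[1] - y
            yaw = np.rad2deg(np.arctan2(dx, dy))
            pitch = np.rad2deg(np.arctan2(centroid[2] - eye_h, np.hypot(dx, dy)))
            p = np.array([x, y, yaw, pitch])
            r = _residuals(p, pts, eye_h, obs_units)
            c = r @ r
            if c < best_cost:
                best, best_cost = p, c
    return best


def _estimate_frame(cup_ids: list[str], az: np.ndarray, el: np.ndarray,
                    pmap: dict[str, np.ndarray], eye_height: float,
                    layout: RoomLayout, init_params: np.ndarray | None,
                    ) -> tuple[np.ndarray | None, float, int, str]:
    """Array-level single-frame estimator shared by the public entry
    points. Returns (params or None, residual_rms_deg, n_cups, status).

    Full fit over (x, y, yaw, pitch) when all three table cups plus a
    floor cup are seen. With only the three near-collinear table cups the
    lateral position is unobservable (distance and viewing angle are
    confounded), so the lateral coordinate is frozen (warm start, else
    the room midline) and only (y, yaw, pitch) are fitted: the result is
    flagged ``degenerate`` and its lateral value should not be trusted.
    """
    if not (np.isfinite(az).all() and np.isfinite(el).all()):
        raise ValueError("non-finite detection input")
    seen = set(cup_ids)
    has_table = all(c in seen for c in TABLE_CUPS)
    n_floor = sum(c in seen for c in FLOOR_CUPS)
    if not has_table:
        return None, np.nan, len(seen), "insufficient_cups"
    degenerate = n_floor == 0

    keep = [i for i, c in enumerate(cup_ids) if c in pmap]
    pts = np.array([pmap[cup_ids[i]] for i in keep])
    obs_units = ray_unit_vector(az[keep], el[keep])

    if init_params is not None:
        p0 = init_params.copy()
    else:
        p0 = _coarse_init(pts, eye_height, obs_units, layout, None)
    mask = np.array([False, True, True, True]) if degenerate else None
    params, converged = _gauss_newton(p0, pts, eye_height, obs_units, mask=mask)
    if init_params is not None and not converged:
        # cold restart before declaring divergence
        p0 = _coarse_init(pts, eye_height, obs_units, layout, None)
        params, converged = _gauss_newton(p0, pts, eye_height, obs_units, mask=mask)
    if not converged or not np.all(np.isfinite(params)):
        return None, np.nan, len(pts), "diverged"

    pred = _predict_units(params, pts, eye_height)
    dots = np.clip(np.sum(pred * obs_units, axis=1), -1, 1)
    rms = float(np.rad2deg(np.sqrt(np.mean(np.arccos(dots) ** 2))))
    params[2] = _wrap(params[2])
    if not (-90 < params[3] < 90):
        return None, rms, len(pts), "diverged"
    return params, rms, len(pts), "degenerate" if degenerate else "ok"


def estimate_pose(detections: pd.DataFrame, placements: list[CupPlacement],
                  eye_height: float, camera: CameraModel = CameraModel(),
                  init: ObserverPose | None = None,
                  layout: RoomLayout = RoomLayout(),
                  t: float = 0.0) -> PoseEstimate:
    """Estimate the observer pose for one frame of detections.

    ``detections`` must hold one row per detected cup (columns ``cup_id``,
    ``az_deg``, ``el_deg``). A reliable (``ok``) estimate requires all
    three table cups and at least one floor cup. Only the three
    (near-collinear) table cups gives ``degenerate`` — a constrained fit
    whose lateral position is frozen and untrustworthy, but whose depth
    supports "at the table" bookkeeping. Any smaller set gives
    ``insufficient_cups``.
    """
    pmap = {p.cup_id: np.asarray(p.world_position, dtype=float) for p in placements}
    init_params = (np.array([init.x, init.y, init.yaw, init.pitch])
                   if init is not None else None)
    params, rms, n, status = _estimate_frame(
        list(detections.cup_id), detections.az_deg.to_numpy(dtype=float),
        detections.el_deg.to_numpy(dtype=float), pmap, eye_height, layout,
        init_params)
    pose = None
    if params is not None:
        pose = ObserverPose(t, params[0], params[1], eye_height,
                            float(params[2]), float(params[3]))
    return PoseEstimate(pose, rms, n, status)


def _wrap(a):
    return (a + 180.0) % 360.0 - 180.0


def estimate_trial_poses(detections: pd.DataFrame, placements: list[CupPlacement],
                         eye_height: float, camera: CameraModel = CameraModel(),
                         layout: RoomLayout = RoomLayout()) -> pd.DataFrame:
    """Estimate the pose for every frame of a trial, warm-starting each
    frame from the previous frame's estimate.

    Returns a table with one row per frame present in ``detections``
    (columns frame, t_s, x_cm, y_cm, yaw_deg, pitch_deg, residual_deg,
    n_cups, status); degenerate frames carry their constrained estimate
    (frozen lateral), other failures carry NaN.
    """
    pmap = {p.cup_id: np.asarray(p.world_position, dtype=float) for p in placements}
    frames = detections["frame"].to_numpy()
    order = np.argsort(frames, kind="stable")
    frames = frames[order]
    ts = detections["t_s"].to_numpy()[order]
    cids = detections["cup_id"].to_numpy()[order]
    az = detections["az_deg"].to_numpy(dtype=float)[order]
    el = detections["el_deg"].to_numpy(dtype=float)[order]
    uniq, starts = np.unique(frames, return_index=True)
    bounds = np.append(starts, len(frames))

    rows = []
    prev: np.ndarray | None = None
    for k, frame in enumerate(uniq):
        a, b = bounds[k], bounds[k + 1]
        t = float(ts[a])
        params, rms, n, status = _estimate_frame(
            list(cids[a:b]), az[a:b], el[a:b], pmap, eye_height, layout, prev)
        if params is not None:
            rows.append((frame, t, params[0], params[1], params[2], params[3],
                         rms, n, status))
            prev = params
        else:
            rows.append((frame, t, np.nan, np.nan, np.nan, np.nan, rms, n, status))
    return pd.DataFrame(rows, columns=["frame", "t_s", "x_cm", "y_cm", "yaw_deg",
                                       "pitch_deg", "residual_deg", "n_cups", "status"])


def smooth_track(track: pd.DataFrame, window_frames: int = 40,
                 poly_order: int = 2, max_gap: int = 12,
                 layout: RoomLayout = RoomLayout()) -> pd.DataFrame:
    """Savitzky-Golay smoothing of the estimated depth and lateral tracks.

    ``track`` needs columns ``x_cm`` and ``y_cm`` (NaN on invalid frames).
    The window is made odd internally. Gaps up to ``max_gap`` frames are
    linearly bridged before smoothing; longer gaps stay invalid. Adds
    smoothed columns ``x_s_cm``, ``y_s_cm`` and ``dist_blue_cm`` (ground
    distance to the target-cup position).
    """
    if window_frames % 2 == 0:
        window_frames += 1
    if window_frames <= poly_order:
        raise ValueError("window must exceed the polynomial order")
    out = track.copy()
    n = len(out)
    if n < window_frames:
        warnings.warn("track shorter than the smoothing window; returned unsmoothed")
        out["x_s_cm"] = out["x_cm"]
        out["y_s_cm"] = out["y_cm"]
    else:
        for col, scol in (("x_cm", "x_s_cm"), ("y_cm", "y_s_cm")):
            v = out[col].to_numpy(dtype=float)
            valid = np.isfinite(v)
            filled, keep = _bridge_gaps(v, valid, max_gap)
            sm = np.full(n, np.nan)
            if keep.any():
                # smooth each contiguous valid run independently
                idx = np.flatnonzero(keep)
                splits = np.flatnonzero(np.diff(idx) > 1)
                for run in np.split(idx, splits + 1):
                    w = min(window_frames, len(run) if len(run) % 2 else len(run) - 1)
                    if w <= poly_order:
                        sm[run] = filled[run]
                    else:
                        sm[run] = savgol_filter(filled[run], w, poly_order)
            out[scol] = sm
    blue_y = layout.door_to_table + layout.target_depth_on_table
    out["dist_blue_cm"] = np.hypot(out["x_s_cm"], out["y_s_cm"] - blue_y)
    return out


def _bridge_gaps(v: np.ndarray, valid: np.ndarray, max_gap: int):
    """Linearly interpolate interior gaps of at most ``max_gap`` samples.

    Returns the filled series and the mask of samples considered usable.
    """
    keep = valid.copy()
    filled = v.copy()
    if valid.sum() < 2:
        return filled, keep
    idx = np.flatnonzero(valid)
    for a, b in zip(idx, idx[1:]):
        gap = b - a - 1
        if 0 < gap <= max_gap:
            filled[a + 1:b] = np.interp(np.arange(a + 1, b), [a, b], [v[a], v[b]])
            keep[a + 1:b] = True
    return filled, keep


def build_track(poses_est: pd.DataFrame, layout: RoomLayout = RoomLayout(),
                window_frames: int = 40) -> pd.DataFrame:
    """Convenience: smooth an estimated pose table into an analysis track."""
    return smooth_track(poses_est, window_frames=window_frames, layout=layout)


def resample_gaze(gaze: pd.DataFrame, frame_times: np.ndarray,
                  window_ms: float = 100.0, poly_order: int = 2,
                  max_invalid_fraction: float = 0.5) -> pd.DataFrame:
    """Resample a ~200 Hz gaze stream at the scene-frame times.

    A local polynomial (Savitzky-Golay style) of order ``poly_order`` is
    fitted to the valid samples inside a ``window_ms`` window centered on
    each frame time and evaluated at that time. A frame whose window
    contains more than ``max_invalid_fraction`` invalid samples — or that
    falls outside the gaze record — is marked invalid, propagating blinks
    to the frame level.
    """
    t = gaze.t_s.to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("gaze timestamps must be strictly increasing")
    az = gaze.az_deg.to_numpy(dtype=float)
    el = gaze.el_deg.to_numpy(dtype=float)
    valid = gaze.valid.to_numpy(dtype=bool) & np.isfinite(az) & np.isfinite(el)
    half = window_ms / 2000.0

    frame_times = np.asarray(frame_times, dtype=float)
    out_az = np.full(len(frame_times), np.nan)
    out_el = np.full(len(frame_times), np.nan)
    out_valid = np.zeros(len(frame_times), dtype=bool)
    lo = np.searchsorted(t, frame_times - half, side="left")
    hi = np.searchsorted(t, frame_times + half, side="right")
    in_record = (frame_times >= t[0]) & (frame_times <= t[-1])
    for i, (a, b) in enumerate(zip(lo, hi)):
        if not in_record[i] or b - a == 0:
            continue
        vmask = valid[a:b]
        if vmask.mean() < (1.0 - max_invalid_fraction) or vmask.sum() <= poly_order:
            continue
        tt = t[a:b][vmask] - frame_times[i]
        order = min(poly_order, vmask.sum() - 1)
        out_az[i] = np.polynomial.polynomial.polyfit(tt, az[a:b][vmask], order)[0]
        out_el[i] = np.polynomial.polynomial.polyfit(tt, el[a:b][vmask], order)[0]
        out_valid[i] = True
    return pd.DataFrame({"t_s": frame_times, "az_deg": out_az,
                         "el_deg": out_el, "valid": out_valid})
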