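"""Frame-by-frame gaze categorization and gaze-measurement precision.

Each scene frame is assigned exactly one of 11 mutually exclusive
categories: one of the five cups (turquoise, yellow, red, blue, purple),
"cups_on_table" (within the cup threshold of two or more table cups),
"table", "floor", "elsewhere", "blink", or "none" (no reliable data).

The decision thresholds are visual angles: gaze counts as on a cup when it
is within 4 deg of the cup's center (about two horizontal standard
deviations of the combined gaze + cup-localization noise); the table/floor
split sits 5 deg below the target (blue) cup's elevation; 20 deg is the
fallback radius around the blue cup when the destination cup is not
visible.

Measurement precision is estimated from pouring periods: runs of at least
10 frames after reaching the table during which the target and destination
cups are less than 5 deg apart in the image — which only happens while
pouring — assuming gaze is then locked on the destination cup.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import (
    CUP_IDS,
    FLOOR_CUPS,
    TABLE_CUPS,
    CameraModel,
    CupPlacement,
    ObserverPose,
    angular_distance,
    project_points,
)

__all__ = [
    "CATEGORIES",
    "PrecisionReport",
    "classify_frame",
    "classify_trial",
    "detect_pouring_periods",
    "estimate_precision",
    "precision_from_periods",
]

CATEGORIES = ("turquoise", "yellow", "red", "blue", "purple",
              "cups_on_table", "table", "floor", "elsewhere", "blink", "none")

#: invalid-gaze runs up to this long count as blinks; longer ones as "none"
BLINK_MAX_S = 0.5
#: "reached the table" = smoothed distance to the target cup at most this
AT_TABLE_CM = 60.0

_D2R = math.pi / 180.0


def _angdist(az1: float, el1: float, az2: float, el2: float) -> float:
    """Scalar great-circle angle in degrees (fast path for the per-frame
    rule evaluation; agrees with :func:`gazewalk.geometry.angular_distance`)."""
    e1, e2 = el1 * _D2R, el2 * _D2R
    dot = math.cos(e1) * math.cos(e2) * math.cos((az1 - az2) * _D2R) \
        + math.sin(e1) * math.sin(e2)
    return math.acos(min(1.0, max(-1.0, dot))) / _D2R


def classify_frame(gaze_az: float, gaze_el: float, gaze_valid: bool,
                   cup_rays: dict[str, tuple[float, float]],
                   blink_flag: bool = False,
                   threshold_deg: float = 4.0, below_deg: float = 5.0,
                   fallback_deg: float = 20.0) -> str:
    """Assign one of the 11 gaze categories to a single frame.

    ``cup_rays`` maps cup ids to angular image positions; absent keys mean
    the cup's center is unavailable this frame. Decision order:

    1. a blink beats everything;
    2. invalid gaze, or no reference for the blue cup, gives "none";
    3. gaze within ``threshold_deg`` of cup centers: two or more table
       cups -> "cups_on_table"; exactly one cup -> that cup; one floor and
       one table cup -> the angularly nearer one;
    4. otherwise, gaze at or above ``below_deg`` below the blue cup and
       closer to the blue than the purple cup (or within ``fallback_deg``
       of the blue cup when the purple cup is missing) -> "table";
    5. otherwise, gaze strictly below that line with no floor cup within
       threshold -> "floor";
    6. anything else -> "elsewhere".

    "Within" is strict: a distance exactly equal to ``threshold_deg`` is
    not on the cup. The table/floor boundary itself classifies as "table".
    """
    if blink_flag:
        return "blink"
    if not gaze_valid or "blue" not in cup_rays:
        return "none"
    dist = {cid: _angdist(gaze_az, gaze_el, ray[0], ray[1])
            for cid, ray in cup_rays.items()}
    near = {cid: d for cid, d in dist.items() if d < threshold_deg}
    near_table = [c for c in TABLE_CUPS if c in near]
    near_floor = [c for c in FLOOR_CUPS if c in near]
    if len(near_table) >= 2:
        return "cups_on_table"
    if len(near) == 1:
        return next(iter(near))
    if len(near) >= 2:
        return min(near, key=near.get)

    blue_el = cup_rays["blue"][1]
    if gaze_el >= blue_el - below_deg:
        if "purple" in cup_rays:
            if dist["blue"] < dist["purple"]:
                return "table"
        elif dist["blue"] < fallback_deg:
            return "table"
        return "elsewhere"
    if not near_floor:
        return "floor"
    return "elsewhere"  # pragma: no cover - unreachable: near_floor implies len(near)>=1


def _blink_flags(gaze_raw: pd.DataFrame, frame_times: np.ndarray) -> np.ndarray:
    """True for frame times inside an invalid-gaze run no longer than
    ``BLINK_MAX_S`` (a blink); longer runs count as unreliable data."""
    t = gaze_raw.t_s.to_numpy(dtype=float)
    invalid = ~gaze_raw.valid.to_numpy(dtype=bool)
    flags = np.zeros(len(frame_times), dtype=bool)
    if not invalid.any():
        return flags
    idx = np.flatnonzero(invalid)
    splits = np.flatnonzero(np.diff(idx) > 1)
    for run in np.split(idx, splits + 1):
        dur = t[run[-1]] - t[run[0]]
        if dur <= BLINK_MAX_S:
            sel = (frame_times >= t[run[0]] - 0.02) & (frame_times <= t[run[-1]] + 0.02)
            flags |= sel
    return flags


def predicted_cup_rays(pose: ObserverPose, placements: list[CupPlacement],
                       camera: CameraModel) -> dict[str, tuple[float, float]]:
    """Cup-center rays predicted from a pose; only cups in the field of
    view are returned."""
    pts = np.array([p.world_position for p in placements])
    az, el, vis = project_points(pose, camera, pts)
    return {p.cup_id: (float(az[i]), float(el[i]))
            for i, p in enumerate(placements) if vis[i]}


def classify_trial(frame_gaze: pd.DataFrame, track: pd.DataFrame,
                   detections: pd.DataFrame, placements: list[CupPlacement],
                   gaze_raw: pd.DataFrame | None = None,
                   camera: CameraModel = CameraModel(),
                   analysis_range_cm: tuple[float, float] = (50.0, 450.0),
                   threshold_deg: float = 4.0) -> pd.DataFrame:
    """Classify every frame of one trial, restricted to the analysis range.

    Per frame the cup-center rays are assembled with observed detections
    preferred and pose-predicted rays as fallback when the pose status is
    "ok"; on degenerate near-table frames the last valid pose's
    predictions are frozen (so the table cups stay classifiable at the
    table). Frames whose smoothed distance to the blue cup falls outside
    ``analysis_range_cm`` are excluded.

    ``track`` is the smoothed pose table (from
    :func:`gazewalk.localization.smooth_track`); ``frame_gaze`` the
    frame-resampled gaze. Returns a frame table with columns ``frame,
    t_s, dist_blue_cm, category, gaze_az, gaze_el``.
    """
    n = len(track)
    frame_ids = track["frame"].to_numpy() if "frame" in track else np.arange(n)
    t_arr = track["t_s"].to_numpy(dtype=float)
    x_arr = track["x_cm"].to_numpy(dtype=float)
    y_arr = track["y_cm"].to_numpy(dtype=float)
    yaw_arr = track["yaw_deg"].to_numpy(dtype=float)
    pitch_arr = track["pitch_deg"].to_numpy(dtype=float)
    dist_arr = track["dist_blue_cm"].to_numpy(dtype=float)
    eye_h = (track["eye_h_cm"].to_numpy(dtype=float)
             if "eye_h_cm" in track else np.full(n, 158.0))
    status_arr = (track["status"].to_numpy()
                  if "status" in track.columns else np.array(["ok"] * n))
    g_valid = frame_gaze["valid"].to_numpy(dtype=bool)
    g_az_arr = frame_gaze["az_deg"].to_numpy(dtype=float)
    g_el_arr = frame_gaze["el_deg"].to_numpy(dtype=float)

    det_by_frame: dict = {}
    if len(detections):
        for fid, cid, daz, del_ in zip(detections["frame"].to_numpy(),
                                       detections["cup_id"].to_numpy(),
                                       detections["az_deg"].to_numpy(dtype=float),
                                       detections["el_deg"].to_numpy(dtype=float)):
            det_by_frame.setdefault(fid, []).append((cid, daz, del_))
    blink = (_blink_flags(gaze_raw, t_arr)
             if gaze_raw is not None else np.zeros(n, dtype=bool))

    frozen_rays: dict[str, tuple[float, float]] | None = None
    rows = []
    for i in range(n):
        fid = frame_ids[i]
        cup_rays: dict[str, tuple[float, float]] = {}
        if status_arr[i] in ("ok", "degenerate") and np.isfinite(x_arr[i]):
            pose = ObserverPose(t_arr[i], x_arr[i], y_arr[i], eye_h[i],
                                yaw_arr[i], pitch_arr[i])
            cup_rays.update(predicted_cup_rays(pose, placements, camera))
            if status_arr[i] == "ok":
                frozen_rays = dict(cup_rays)
        elif frozen_rays is not None and status_arr[i] == "degenerate":
            cup_rays.update(frozen_rays)
        if fid in det_by_frame:  # observed positions override predictions
            for cid, daz, del_ in det_by_frame[fid]:
                cup_rays[cid] = (daz, del_)

        if i >= len(g_valid) or not g_valid[i]:
            cat = "blink" if blink[i] else "none"
            g_az = g_el = np.nan
        else:
            g_az, g_el = g_az_arr[i], g_el_arr[i]
            cat = classify_frame(g_az, g_el, True, cup_rays, blink_flag=bool(blink[i]),
                                 threshold_deg=threshold_deg)
        rows.append((fid, t_arr[i], dist_arr[i], cat, g_az, g_el))

    out = pd.DataFrame(rows, columns=["frame", "t_s", "dist_blue_cm",
                                      "category", "gaze_az", "gaze_el"])
    lo, hi = analysis_range_cm
    in_range = (out.dist_blue_cm >= lo) & (out.dist_blue_cm <= hi)
    return out[in_range.fillna(False)].reset_index(drop=True)


def detect_pouring_periods(frames: pd.DataFrame, min_frames: int = 10,
                           sep_deg: float = 5.0,
                           at_table_cm: float = AT_TABLE_CM) -> list[tuple[int, int]]:
    """Find pouring periods in an at-the-table frame series.

    ``frames`` needs columns ``distance_to_blue_cm`` (smoothed), and per
    frame rays ``blue_az, blue_el, purple_az, purple_el`` (NaN when a cup
    is missing). Returns maximal runs, starting no earlier than the first
    at-table frame, of at least ``min_frames`` consecutive frames whose
    blue-purple separation is strictly below ``sep_deg``; reported as
    ``(start, stop)`` positional index pairs, stop exclusive.
    """
    d = frames.distance_to_blue_cm.to_numpy(dtype=float)
    at_table = np.flatnonzero(d <= at_table_cm)
    if at_table.size == 0:
        return []
    onset = at_table[0]
    a = np.column_stack([frames.blue_az, frames.blue_el])
    b = np.column_stack([frames.purple_az, frames.purple_el])
    with np.errstate(invalid="ignore"):
        sep = angular_distance(a, b)
    close = np.zeros(len(frames), dtype=bool)
    close[onset:] = np.isfinite(sep[onset:]) & (sep[onset:] < sep_deg)
    periods = []
    idx = np.flatnonzero(close)
    if idx.size == 0:
        return []
    splits = np.flatnonzero(np.diff(idx) > 1)
    for run in np.split(idx, splits + 1):
        if run.size >= min_frames:
            periods.append((int(run[0]), int(run[-1]) + 1))
    return periods


@dataclass
class PrecisionReport:
    """Across-participant gaze precision summary (degrees)."""

    offset_az: float
    offset_el: float
    sd_az: float
    sd_el: float
    n_periods_per_participant: list[int]

    def __str__(self) -> str:  # structured text per the output contract
        lines = [
            "gaze precision (pouring periods)",
            f"offset_az_deg: {self.offset_az:.2f}",
            f"offset_el_deg: {self.offset_el:.2f}",
            f"sd_az_deg: {self.sd_az:.2f}",
            f"sd_el_deg: {self.sd_el:.2f}",
            "n_periods: " + ",".join(str(n) for n in self.n_periods_per_participant),
        ]
        return "\n".join(lines)


def precision_from_periods(frames: pd.DataFrame,
                           periods: list[tuple[int, int]]) -> pd.DataFrame:
    """Per-period mean and SD of the gaze-minus-purple azimuth/elevation
    differences for one participant's frame series."""
    stats = []
    for a, b in periods:
        seg = frames.iloc[a:b]
        ok = seg.gaze_valid.astype(bool) & np.isfinite(seg.gaze_az) & np.isfinite(seg.purple_az)
        da = (seg.gaze_az - seg.purple_az)[ok]
        de = (seg.gaze_el - seg.purple_el)[ok]
        if len(da) < 2:
            continue
        stats.append((da.mean(), de.mean(), da.std(ddof=1), de.std(ddof=1), len(da)))
    return pd.DataFrame(stats, columns=["mean_az", "mean_el", "sd_az", "sd_el", "n"])


def estimate_precision(per_participant: list[pd.DataFrame]) -> PrecisionReport:
    """Combine per-period statistics into the study's precision summary.

    Input: one table per participant as returned by
    :func:`precision_from_periods`. Per participant the median over
    periods is taken (robust to periods where the participant briefly
    looked away), then the medians are averaged across participants.
    """
    per_participant = [p for p in per_participant if len(p)]
    if not per_participant:
        raise ValueError("no pouring periods found for any participant")
    med = pd.DataFrame([p[["mean_az", "mean_el", "sd_az", "sd_el"]].median()
                        for p in per_participant])
    return PrecisionReport(
        offset_az=float(med.mean_az.mean()),
        offset_el=float(med.mean_el.mean()),
        sd_az=float(med.sd_az.mean()),
        sd_el=float(med.sd_el.mean()),
        n_periods_per_participant=[len(p) for p in per_participant],
    )
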