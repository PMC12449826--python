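"""Mapping floor-directed gaze to ground coordinates and building
category-occupancy-by-distance summaries.

Only frames categorized as "floor" or one of the floor cups produce floor
points: the world-frame gaze ray from the estimated pose is intersected
with the floor plane exactly. Occupancy curves give, per distance-to-target
bin, the fraction of frames in each of the 11 categories; the stacking
order keeps the floor group (floor, turquoise, yellow) and the table group
(table, cups_on_table, red, blue, purple) contiguous.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classification import CATEGORIES
from .geometry import CameraModel, ObserverPose, ray_floor_intersection

__all__ = ["FLOOR_GROUP", "TABLE_GROUP", "STACK_ORDER",
           "map_floor_gaze", "triangulate_floor_gaze", "occupancy_by_distance"]

FLOOR_GROUP = ("floor", "turquoise", "yellow")
TABLE_GROUP = ("table", "cups_on_table", "red", "blue", "purple")
#: stacked-area plotting order: floor group first, then table group
STACK_ORDER = FLOOR_GROUP + TABLE_GROUP + ("elsewhere", "blink", "none")


def map_floor_gaze(classified: pd.DataFrame, track: pd.DataFrame) -> pd.DataFrame:
    """Ground coordinates of floor-directed gaze.

    ``classified`` is a classified frame table (with ``gaze_az/gaze_el``
    in camera coordinates); ``track`` the smoothed pose table indexed by
    the same frame numbers. Frames with non-descending gaze, or without a
    valid pose, produce no point. Returns columns ``t_s, x_cm, y_cm,
    source_category``.
    """
    pose_by_frame = track.set_index("frame") if "frame" in track else track
    rows = []
    sel = classified[classified.category.isin(FLOOR_GROUP)]
    for r in sel.itertuples():
        if r.frame not in pose_by_frame.index:
            continue
        p = pose_by_frame.loc[r.frame]
        if not (np.isfinite(p.x_s_cm) and np.isfinite(p.yaw_deg)):
            continue
        pose = ObserverPose(r.t_s, p.x_s_cm, p.y_s_cm, p.get("eye_h_cm", 158.0),
                            p.yaw_deg, p.pitch_deg)
        hit = ray_floor_intersection(pose, (r.gaze_az, r.gaze_el))
        if hit is None:
            continue
        rows.append((r.t_s, hit[0], hit[1], r.category))
    return pd.DataFrame(rows, columns=["t_s", "x_cm", "y_cm", "source_category"])


def triangulate_floor_gaze(classified: pd.DataFrame, track: pd.DataFrame,
                           detections: pd.DataFrame,
                           floor_cup_xy: dict[str, tuple[float, float]],
                           camera: CameraModel = CameraModel()) -> pd.DataFrame:
    """Cup-relative floor-gaze variant used as a cross-check.

    Instead of intersecting the gaze ray itself, the gaze point is placed
    relative to the floor cups: each detected floor cup's image ray and
    the gaze ray are both dropped to the floor through the estimated pose,
    and the gaze point is expressed as the cup's known ground position
    plus the floor-plane offset between the two intersections. With two
    cups the estimates are averaged. Agrees with :func:`map_floor_gaze`
    exactly when detections are noiseless.
    """
    pose_by_frame = track.set_index("frame") if "frame" in track else track
    det_by_frame = {f: g for f, g in detections.groupby("frame")}
    rows = []
    sel = classified[classified.category.isin(FLOOR_GROUP)]
    for r in sel.itertuples():
        if r.frame not in pose_by_frame.index or r.frame not in det_by_frame:
            continue
        p = pose_by_frame.loc[r.frame]
        if not (np.isfinite(p.x_s_cm) and np.isfinite(p.yaw_deg)):
            continue
        pose = ObserverPose(r.t_s, p.x_s_cm, p.y_s_cm, p.get("eye_h_cm", 158.0),
                            p.yaw_deg, p.pitch_deg)
        gaze_hit = ray_floor_intersection(pose, (r.gaze_az, r.gaze_el))
        if gaze_hit is None:
            continue
        ests = []
        for d in det_by_frame[r.frame].itertuples():
            if d.cup_id not in floor_cup_xy:
                continue
            cup_hit = ray_floor_intersection(pose, (d.az_deg, d.el_deg))
            if cup_hit is None:
                continue
            cx, cy = floor_cup_xy[d.cup_id]
            ests.append((cx + gaze_hit[0] - cup_hit[0], cy + gaze_hit[1] - cup_hit[1]))
        if not ests:
            continue
        e = np.mean(ests, axis=0)
        rows.append((r.t_s, e[0], e[1], r.category))
    return pd.DataFrame(rows, columns=["t_s", "x_cm", "y_cm", "source_category"])


def occupancy_by_distance(classified_trials: list[pd.DataFrame],
                          bin_width_cm: float = 10.0,
                          range_cm: tuple[float, float] = (50.0, 450.0),
                          participant_ids: list | None = None) -> pd.DataFrame:
    """Fraction of frames in each category per distance-to-target bin.

    Within a participant, frames are pooled unweighted across trials; the
    grand average is the unweighted mean across participants (bins a
    participant never visited are ignored for that participant). Returns a
    table with ``bin_lo_cm, bin_hi_cm`` and one fraction column per
    category; rows with no data have NaN fractions.
    """
    if not classified_trials:
        raise ValueError("need at least one classified trial")
    if participant_ids is None:
        participant_ids = [0] * len(classified_trials)
    lo, hi = range_cm
    edges = np.arange(lo, hi + bin_width_cm, bin_width_cm)
    n_bins = len(edges) - 1

    per_part: dict[object, np.ndarray] = {}
    counts: dict[object, np.ndarray] = {}
    for pid, trial in zip(participant_ids, classified_trials):
        mat = counts.setdefault(pid, np.zeros((n_bins, len(CATEGORIES))))
        d = trial.dist_blue_cm.to_numpy(dtype=float)
        which = np.digitize(d, edges) - 1
        ok = (which >= 0) & (which < n_bins) & np.isfinite(d)
        cat_idx = trial.category.map({c: i for i, c in enumerate(CATEGORIES)}).to_numpy()
        np.add.at(mat, (which[ok], cat_idx[ok]), 1.0)

    fracs = []
    for pid, mat in counts.items():
        tot = mat.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            per_part[pid] = np.where(tot > 0, mat / tot, np.nan)
    stack = np.stack(list(per_part.values()))
    with np.errstate(invalid="ignore"):
        grand = np.nanmean(stack, axis=0)

    out = pd.DataFrame(grand, columns=list(CATEGORIES))
    out.insert(0, "bin_lo_cm", edges[:-1])
    out.insert(1, "bin_hi_cm", edges[1:])
    return out
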