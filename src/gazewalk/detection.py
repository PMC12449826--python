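"""Cup identification in scene frames by color, with plausibility filtering.

Two modes exist. In image mode, rendered color frames are segmented with a
hue-prioritized color distance and the surviving blobs become candidate
detections. In symbolic mode (the default analysis path), the simulator's
detections are taken as candidates directly. Both feed
:func:`plausibility_filter`, which keeps only cups at plausible positions
relative to each other and to their positions on the previous frame —
needed because relying on color alone lets, e.g., light on the floor pass
as the yellow cup.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage.color import rgb2hsv
from skimage.measure import label, regionprops

from .geometry import (
    CUP_IDS,
    FLOOR_CUPS,
    TABLE_CUPS,
    CameraModel,
    CupPlacement,
    ObserverPose,
    angular_distance,
    pixel_to_ray,
)

__all__ = ["segment_by_color", "plausibility_filter", "filter_trial", "Candidate"]

#: Gating radius between consecutive frames, deg. Chosen to exceed the
#: largest inter-frame cup displacement at walking speed.
GATE_DEG = 8.0


class Candidate:
    """A candidate cup detection before plausibility filtering."""

    __slots__ = ("cup_id", "az", "el", "area")

    def __init__(self, cup_id: str, az: float, el: float, area: float | None = None):
        self.cup_id = cup_id
        self.az = float(az)
        self.el = float(el)
        self.area = area

    def __repr__(self) -> str:  # pragma: no cover
        return f"Candidate({self.cup_id}, az={self.az:.2f}, el={self.el:.2f})"


def _hue_distance(h1: np.ndarray, h2: float) -> np.ndarray:
    d = np.abs(h1 - h2)
    return np.minimum(d, 1.0 - d)


def segment_by_color(frame: np.ndarray, camera: CameraModel,
                     palette: dict[str, tuple[int, int, int]],
                     min_area: int = 6, hue_tol: float = 0.06,
                     min_saturation: float = 0.25) -> list[Candidate]:
    """Segment a rendered frame into per-color candidate blobs.

    Pixels are matched to each palette entry by circular hue distance
    (saturation-gated, so the neutral background never matches); connected
    components of at least ``min_area`` pixels are reported with their
    centroid converted to an angular image ray.
    """
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[2] < 3:
        raise ValueError("frame must be an HxWx3 color image")
    if len(palette) != len(set(palette.values())):
        raise ValueError("palette colors must be distinct")
    hsv = rgb2hsv(frame[:, :, :3])
    out: list[Candidate] = []
    for cup_id, rgb in palette.items():
        ph, ps, pv = rgb2hsv(np.asarray(rgb, dtype=np.uint8).reshape(1, 1, 3))[0, 0]
        mask = (_hue_distance(hsv[:, :, 0], ph) < hue_tol) & (hsv[:, :, 1] > min_saturation)
        if not mask.any():
            continue
        for region in regionprops(label(mask)):
            if region.area < min_area:
                continue
            v, u = region.centroid
            az, el = pixel_to_ray(camera, u, v)
            out.append(Candidate(cup_id, float(az), float(el), float(region.area)))
    return out


def _angdist_fast(az1: float, el1: float, az2: float, el2: float) -> float:
    a1, e1, a2, e2 = map(np.deg2rad, (az1, el1, az2, el2))
    dot = np.cos(e1) * np.cos(e2) * np.cos(a1 - a2) + np.sin(e1) * np.sin(e2)
    return float(np.rad2deg(np.arccos(min(1.0, max(-1.0, dot)))))


def _gate_select(cands: list[Candidate], prev_ray: tuple[float, float] | None,
                 gate_deg: float) -> Candidate | None:
    """Pick the best candidate: within the gate of the previous-frame ray
    when one exists; ties broken by angular distance then blob area."""
    if not cands:
        return None
    if prev_ray is not None:
        gated = [(_angdist_fast(c.az, c.el, *prev_ray), c) for c in cands]
        gated = [(d, c) for d, c in gated if d < gate_deg]
        if not gated:
            return None
        gated.sort(key=lambda dc: (dc[0], -(dc[1].area or 0.0)))
        return gated[0][1]
    if len(cands) == 1:
        return cands[0]
    # no history: prefer the largest blob (nearest / most salient)
    return max(cands, key=lambda c: (c.area or 0.0))


def plausibility_filter(candidates: list[Candidate],
                        previous: pd.DataFrame | None,
                        config=None,
                        pose_hint: ObserverPose | None = None,
                        gate_deg: float = GATE_DEG) -> pd.DataFrame:
    """Resolve candidates to at most one detection per cup.

    Rules, mirroring the plausible-positions reasoning:

    * when the cup was seen on the previous frame, the candidate must lie
      within ``gate_deg`` of that ray (ties: smallest angular distance,
      then largest blob area);
    * table-cup rays must lie above floor-cup rays in elevation — for
      every reachable pose in this room the floor cups project below the
      table cups, so a "floor cup" above a table cup is something else
      (e.g., light on the floor);
    * when both floor cups are detected on opposite configured sides, the
      left/right azimuth order must match the configuration (enforced
      when the pose hint is near the room midline, where the apparent
      order is unambiguous).

    Unresolved cups are simply absent from the output; missing is a valid
    outcome.
    """
    prev_rays: dict[str, tuple[float, float]] = {}
    if previous is not None and len(previous):
        for cid, a, e in zip(previous["cup_id"], previous["az_deg"], previous["el_deg"]):
            prev_rays[cid] = (a, e)
    pose_x = None if pose_hint is None else pose_hint.x
    chosen = _filter_frame(candidates, prev_rays, config, pose_x, gate_deg)
    rows = [(cid, c.az, c.el, c.area) for cid, c in chosen.items()]
    return pd.DataFrame(rows, columns=["cup_id", "az_deg", "el_deg", "area"])


def _filter_frame(candidates: list[Candidate], prev_rays: dict, config,
                  pose_x: float | None, gate_deg: float) -> dict[str, Candidate]:
    chosen: dict[str, Candidate] = {}
    for cid in CUP_IDS:
        pick = _gate_select([c for c in candidates if c.cup_id == cid],
                            prev_rays.get(cid), gate_deg)
        if pick is not None:
            chosen[cid] = pick

    # relative geometry: floor cups project below table cups
    table_els = [chosen[c].el for c in TABLE_CUPS if c in chosen]
    if table_els:
        min_table_el = min(table_els)
        for cid in FLOOR_CUPS:
            if cid in chosen and chosen[cid].el >= min_table_el:
                del chosen[cid]

    # left/right ordering of the floor cups against the configuration
    near_midline = pose_x is None or abs(pose_x) < 25.0
    if (config is not None and near_midline
            and "turquoise" in chosen and "yellow" in chosen
            and config.near_floor_side != config.far_floor_side):
        want = 1.0 if config.far_floor_side == "right" else -1.0
        got = np.sign(chosen["yellow"].az - chosen["turquoise"].az)
        if got != 0 and got != want:
            # the far cup is the more error-prone one (light on the floor)
            del chosen["yellow"]
    return chosen


def filter_trial(detections: pd.DataFrame, config=None,
                 gate_deg: float = GATE_DEG) -> pd.DataFrame:
    """Apply :func:`plausibility_filter` frame by frame to a symbolic
    detection table (the simulator's output dialect), carrying each
    frame's result as the next frame's history."""
    cols = ["frame", "t_s", "cup_id", "az_deg", "el_deg", "area"]
    if detections.empty:
        return pd.DataFrame(columns=cols)
    frames = detections["frame"].to_numpy()
    order = np.argsort(frames, kind="stable")
    frames = frames[order]
    ts = detections["t_s"].to_numpy()[order]
    cids = detections["cup_id"].to_numpy()[order]
    az = detections["az_deg"].to_numpy(dtype=float)[order]
    el = detections["el_deg"].to_numpy(dtype=float)[order]

    uniq, starts = np.unique(frames, return_index=True)
    bounds = np.append(starts, len(frames))
    out_rows = []
    # per-cup history (ray, frame seen); a stale entry no longer gates
    history: dict[str, tuple[tuple[float, float], int]] = {}
    max_age = 5  # frames
    for k, frame in enumerate(uniq):
        a, b = bounds[k], bounds[k + 1]
        cands = [Candidate(cids[i], az[i], el[i]) for i in range(a, b)]
        prev_rays = {cid: ray for cid, (ray, f) in history.items()
                     if frame - f <= max_age}
        chosen = _filter_frame(cands, prev_rays, config, None, gate_deg)
        for cid, c in chosen.items():
            history[cid] = ((c.az, c.el), int(frame))
        t = ts[a]
        out_rows.extend((frame, t, cid, c.az, c.el, c.area)
                        for cid, c in chosen.items())
    return pd.DataFrame(out_rows, columns=cols)
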