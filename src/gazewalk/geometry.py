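"""Room, table and cup geometry, and the projection math between world
coordinates, scene-camera rays, and the floor plane.

World frame convention (all lengths in cm, angles in degrees):

* origin at the center of the doorway, on the floor;
* ``+y`` points into the room, toward the table;
* ``+x`` points to the walker's right;
* ``+z`` points up.

Camera rays are represented as angular image coordinates ``(azimuth,
elevation)`` of the 3-D ray in the head/camera frame: azimuth positive
rightward, elevation positive upward. This angular representation is the
canonical one throughout the package; pixel coordinates exist only when
rendering or segmenting images (pinhole tangent mapping, see
:func:`ray_to_pixel`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

__all__ = [
    "RoomLayout",
    "CupSpec",
    "CupPlacement",
    "ObserverPose",
    "CameraModel",
    "ImageRay",
    "CUP_IDS",
    "FLOOR_CUPS",
    "TABLE_CUPS",
    "CUP_SPECS",
    "CUP_COLORS",
    "place_cups",
    "project_to_camera",
    "angular_distance",
    "ray_floor_intersection",
    "ray_to_pixel",
    "pixel_to_ray",
]


@dataclass(frozen=True)
class RoomLayout:
    """Fixed room/table geometry. Defaults reproduce the study room.

    All distances in cm. Depths are measured from the doorway along +y.
    """

    room_width: float = 296.0
    room_depth: float = 480.0
    door_to_table: float = 280.0
    table_width: float = 161.0
    table_depth: float = 80.0
    table_height: float = 71.0
    floor_obstacle_depths: tuple[float, float] = (140.0, 205.0)
    floor_obstacle_lateral_separation: float = 55.0
    target_depth_on_table: float = 22.0
    destination_lateral_offset: float = 66.5
    destination_depth_on_table: float = 11.0
    table_obstacle_offsets: tuple[float, float] = (11.0, 11.0)  # (side, front)

    def __post_init__(self) -> None:
        lengths = [
            self.room_width, self.room_depth, self.door_to_table,
            self.table_width, self.table_depth, self.table_height,
            *self.floor_obstacle_depths, self.floor_obstacle_lateral_separation,
            self.target_depth_on_table, self.destination_lateral_offset,
            self.destination_depth_on_table, *self.table_obstacle_offsets,
        ]
        if any(v <= 0 for v in lengths):
            raise ValueError("all layout lengths must be strictly positive")
        if not all(d < self.door_to_table for d in self.floor_obstacle_depths):
            raise ValueError("floor obstacles must lie between door and table")
        if not (self.target_depth_on_table < self.table_depth
                and self.destination_depth_on_table < self.table_depth):
            raise ValueError("cup depths on table must be less than table depth")


CUP_IDS = ("turquoise", "yellow", "red", "blue", "purple")
FLOOR_CUPS = ("turquoise", "yellow")
TABLE_CUPS = ("red", "blue", "purple")

#: Nominal sRGB colors used for rendering and color segmentation.
CUP_COLORS: dict[str, tuple[int, int, int]] = {
    "turquoise": (64, 224, 208),
    "yellow": (235, 220, 30),
    "red": (220, 30, 30),
    "blue": (30, 60, 220),
    "purple": (140, 40, 160),
}


@dataclass(frozen=True)
class CupSpec:
    """Physical description of one cup (dimensions in cm)."""

    cup_id: str
    height: float
    mouth_diameter: float
    base_diameter: float
    color: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.cup_id not in CUP_IDS:
            raise ValueError(f"unknown cup id {self.cup_id!r}")
        if min(self.height, self.mouth_diameter, self.base_diameter) <= 0:
            raise ValueError("cup dimensions must be positive")


def _default_specs() -> dict[str, CupSpec]:
    specs = {}
    for cid in CUP_IDS:
        if cid == "blue":  # the target cup is the short one
            specs[cid] = CupSpec(cid, 9.0, 8.0, 5.3, CUP_COLORS[cid])
        else:
            specs[cid] = CupSpec(cid, 15.5, 9.0, 6.0, CUP_COLORS[cid])
    return specs


CUP_SPECS: dict[str, CupSpec] = _default_specs()


@dataclass(frozen=True)
class CupPlacement:
    """A cup placed in the world.

    ``world_position`` is the cup's reference point used for projection,
    detection, and angular gaze distances: the cup axis at half cup height.
    """

    cup: CupSpec
    world_position: tuple[float, float, float]
    support: str  # "floor" | "table"

    @property
    def cup_id(self) -> str:
        return self.cup.cup_id

    @property
    def ground_xy(self) -> tuple[float, float]:
        return (self.world_position[0], self.world_position[1])


@dataclass(frozen=True)
class ObserverPose:
    """Scene-camera pose: ground position, eye height, yaw, pitch.

    ``yaw`` is measured from +y (into the room), positive toward +x (the
    walker's right). ``pitch`` is positive upward. Roll is fixed at zero.
    """

    t: float
    x: float
    y: float
    eye_height: float
    yaw: float
    pitch: float

    def __post_init__(self) -> None:
        if not (0 < self.eye_height < 250):
            raise ValueError("eye height outside plausible human range")
        if not (-90 < self.pitch < 90):
            raise ValueError("pitch must lie in (-90, 90) degrees")

    @property
    def eye_position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.eye_height])


@dataclass(frozen=True)
class CameraModel:
    """Scene-camera model: square angular field of view and frame rate."""

    fov: tuple[float, float] = (82.0, 82.0)
    frame_rate: float = 26.0
    resolution: tuple[int, int] | None = None  # (width, height), image mode only

    def __post_init__(self) -> None:
        if not all(0 < f < 180 for f in self.fov):
            raise ValueError("field of view must lie in (0, 180) degrees")
        if self.frame_rate <= 0:
            raise ValueError("frame rate must be positive")


class ImageRay(NamedTuple):
    """Angular image coordinate of a 3-D ray (degrees)."""

    azimuth: float
    elevation: float


def place_cups(config, layout: RoomLayout = RoomLayout(), *,
               constrained: bool = False) -> list[CupPlacement]:
    """Place the five cups for one trial configuration.

    The turquoise (near) and yellow (far) floor obstacles sit at the two
    obstacle depths, laterally at plus/minus half the obstacle separation.
    The blue target cup is central on the table; the purple destination cup
    is offset to the configured side near the table edge; the red table
    obstacle sits one offset to the side of and one offset in front of the
    target cup.

    Parameters
    ----------
    config
        A trial configuration with four binary side choices (see
        :mod:`gazewalk.design`).
    layout
        Room geometry.
    constrained
        When True, the red cup follows the destination side (the physically
        aligned layout); by default the table-obstacle side is an
        independent factor.
    """
    sign = {"left": -1.0, "right": 1.0}
    half_sep = layout.floor_obstacle_lateral_separation / 2.0
    y_table = layout.door_to_table

    def _mid(cid: str, x: float, y: float, support: str) -> CupPlacement:
        spec = CUP_SPECS[cid]
        base_z = 0.0 if support == "floor" else layout.table_height
        return CupPlacement(spec, (x, y, base_z + spec.height / 2.0), support)

    near_x = sign[config.near_floor_side] * half_sep
    far_x = sign[config.far_floor_side] * half_sep
    red_side = config.destination_side if constrained else config.table_obstacle_side

    blue_y = y_table + layout.target_depth_on_table
    side_off, front_off = layout.table_obstacle_offsets
    return [
        _mid("turquoise", near_x, layout.floor_obstacle_depths[0], "floor"),
        _mid("yellow", far_x, layout.floor_obstacle_depths[1], "floor"),
        _mid("red", sign[red_side] * side_off, blue_y - front_off, "table"),
        _mid("blue", 0.0, blue_y, "table"),
        _mid("purple", sign[config.destination_side] * layout.destination_lateral_offset,
             y_table + layout.destination_depth_on_table, "table"),
    ]


def _camera_axes(yaw_deg: float, pitch_deg: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Right, up, forward unit vectors of the camera in world coordinates."""
    yaw = np.deg2rad(yaw_deg)
    pitch = np.deg2rad(pitch_deg)
    right = np.array([np.cos(yaw), -np.sin(yaw), 0.0])
    fwd_level = np.array([np.sin(yaw), np.cos(yaw), 0.0])
    up_world = np.array([0.0, 0.0, 1.0])
    forward = fwd_level * np.cos(pitch) + up_world * np.sin(pitch)
    up = up_world * np.cos(pitch) - fwd_level * np.sin(pitch)
    return right, up, forward


def project_to_camera(pose: ObserverPose, camera: CameraModel, point) -> tuple[ImageRay, bool]:
    """Project a world point into angular image coordinates.

    Returns the ``(azimuth, elevation)`` of the point in the camera frame
    (yaw applied, then pitch) and a visibility flag: True iff the point is
    in front of the camera and both angles are within half the field of
    view.

    Raises
    ------
    ValueError
        If the point coincides with the eye position.
    """
    point = np.asarray(point, dtype=float)
    d = point - pose.eye_position
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite world point")
    if np.linalg.norm(d) < 1e-9:
        raise ValueError("point coincides with the eye position")
    right, up, forward = _camera_axes(pose.yaw, pose.pitch)
    x = float(d @ right)
    y = float(d @ up)
    z = float(d @ forward)
    az = np.rad2deg(np.arctan2(x, z))
    el = np.rad2deg(np.arctan2(y, np.hypot(x, z)))
    visible = z > 0 and abs(az) <= camera.fov[0] / 2 and abs(el) <= camera.fov[1] / 2
    return ImageRay(az, el), visible


def project_points(pose: ObserverPose, camera: CameraModel, points: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized :func:`project_to_camera` over an ``(n, 3)`` array.

    Returns ``(azimuth, elevation, visible)`` arrays.
    """
    points = np.asarray(points, dtype=float)
    d = points - pose.eye_position
    right, up, forward = _camera_axes(pose.yaw, pose.pitch)
    x = d @ right
    y = d @ up
    z = d @ forward
    az = np.rad2deg(np.arctan2(x, z))
    el = np.rad2deg(np.arctan2(y, np.hypot(x, z)))
    visible = (z > 0) & (np.abs(az) <= camera.fov[0] / 2) & (np.abs(el) <= camera.fov[1] / 2)
    return az, el, visible


def ray_unit_vector(azimuth, elevation) -> np.ndarray:
    """Unit 3-vector(s) ``(right, up, forward)`` for angular coordinates."""
    az = np.deg2rad(np.asarray(azimuth, dtype=float))
    el = np.deg2rad(np.asarray(elevation, dtype=float))
    return np.stack([np.cos(el) * np.sin(az), np.sin(el), np.cos(el) * np.cos(az)], axis=-1)


def angular_distance(a, b) -> float | np.ndarray:
    """Great-circle angle (degrees) between two angular image coordinates.

    Accepts ``ImageRay``-like pairs or broadcastable arrays of
    ``(azimuth, elevation)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ua = ray_unit_vector(a[..., 0], a[..., 1])
    ub = ray_unit_vector(b[..., 0], b[..., 1])
    dot = np.sum(ua * ub, axis=-1)
    cross = np.linalg.norm(np.cross(ua, ub), axis=-1)
    ang = np.rad2deg(np.arctan2(cross, dot))  # accurate near 0 and 180
    return float(ang) if ang.ndim == 0 else ang


def ray_floor_intersection(pose: ObserverPose, ray) -> tuple[float, float] | None:
    """Ground point where the world gaze ray crosses the floor plane.

    The ray is given in camera angular coordinates; it is rotated into the
    world frame using the pose's yaw and pitch, then intersected with
    ``z = 0``. Returns None when the ray does not descend.
    """
    az, el = float(ray[0]), float(ray[1])
    u = ray_unit_vector(az, el)
    right, up, forward = _camera_axes(pose.yaw, pose.pitch)
    d_world = u[0] * right + u[1] * up + u[2] * forward
    if d_world[2] >= 0:
        return None
    t = pose.eye_height / -d_world[2]
    return (pose.x + t * d_world[0], pose.y + t * d_world[1])


def _focal_px(camera: CameraModel) -> tuple[float, float]:
    if camera.resolution is None:
        raise ValueError("camera resolution required for pixel mapping")
    w, h = camera.resolution
    fx = (w / 2.0) / np.tan(np.deg2rad(camera.fov[0] / 2.0))
    fy = (h / 2.0) / np.tan(np.deg2rad(camera.fov[1] / 2.0))
    return fx, fy


def ray_to_pixel(camera: CameraModel, azimuth, elevation) -> tuple[np.ndarray, np.ndarray]:
    """Pinhole tangent mapping of angular coordinates to pixel ``(u, v)``.

    ``u`` increases rightward, ``v`` downward; the image center maps the
    optical axis.
    """
    fx, fy = _focal_px(camera)
    w, h = camera.resolution  # type: ignore[misc]
    vec = ray_unit_vector(azimuth, elevation)
    x, y, z = vec[..., 0], vec[..., 1], vec[..., 2]
    u = w / 2.0 + fx * x / z
    v = h / 2.0 - fy * y / z
    return u, v


def pixel_to_ray(camera: CameraModel, u, v) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`ray_to_pixel`; returns ``(azimuth, elevation)``."""
    fx, fy = _focal_px(camera)
    w, h = camera.resolution  # type: ignore[misc]
    x = (np.asarray(u, dtype=float) - w / 2.0) / fx
    y = (h / 2.0 - np.asarray(v, dtype=float)) / fy
    az = np.rad2deg(np.arctan2(x, 1.0))
    el = np.rad2deg(np.arctan2(y, np.hypot(x, 1.0)))
    return az, el
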