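"""Maze geometry, zoning, and frame-wise behavioral features.

The maze is a plus of two closed and two open arms of equal length joined
by a central square platform. The coordinate frame has its origin at the
maze center with axes running along the arms, so every arm is identified
by the signed half-axis it occupies (``+x``, ``-x``, ``+y``, ``-y``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MazeGeometry",
    "Zone",
    "PoseTrack",
    "zone_of",
    "zones_of",
    "compute_kinematics",
    "compute_pose_features",
    "frame_features",
    "heading_histogram",
    "rayleigh_test",
    "ECDF",
    "movement_ecdf",
    "ARMS",
    "CLOSED_REGIONS",
    "OPEN_REGIONS",
]

ARMS = ("+x", "-x", "+y", "-y")
CLOSED_REGIONS = ("closed-proximal", "closed-distal")
OPEN_REGIONS = ("open-proximal", "open-distal")


class Zone(NamedTuple):
    """A maze zone: a region label plus the arm carrying it (None for
    center / off-maze)."""

    region: str
    arm: str | None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.region if self.arm is None else f"{self.region}:{self.arm}"


@dataclass(frozen=True)
class MazeGeometry:
    """Plus-maze dimensions and the zone fractions used for segmentation.

    Parameters
    ----------
    arm_length : float
        Length of each arm in cm.
    center_side : float
        Side of the central square platform in cm.
    closed_axis : {"x", "y"}
        Axis carrying the two closed arms; the other axis carries the
        open arms.
    start_zone_fraction : float
        Distal fraction of a closed arm that forms a sequence start zone.
    proximal_fraction : float
        Proximal fraction of an open arm in which risk-assessment events
        count toward classification.
    stop_threshold_fraction : float
        Fraction of arm length an animal must cross into a non-origin arm
        to terminate a sequence (ties count as crossed).
    """

    arm_length: float = 27.8
    center_side: float = 7.8
    closed_axis: str = "y"
    start_zone_fraction: float = 0.5
    proximal_fraction: float = 0.5
    stop_threshold_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.arm_length <= 0 or self.center_side <= 0:
            raise ValueError("arm_length and center_side must be positive")
        for name in ("start_zone_fraction", "proximal_fraction", "stop_threshold_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.closed_axis not in ("x", "y"):
            raise ValueError("closed_axis must be 'x' or 'y'")

    @property
    def half_center(self) -> float:
        return self.center_side / 2.0

    @property
    def arm_end(self) -> float:
        """Distance from the origin to an arm tip."""
        return self.half_center + self.arm_length

    @property
    def open_axis(self) -> str:
        return "x" if self.closed_axis == "y" else "y"

    def distal_boundary(self, region_kind: str) -> float:
        """Distance from origin at which the distal part of an arm begins.

        For closed arms the start-zone fraction is the *distal* fraction;
        for open arms the proximal fraction is the *proximal* fraction.
        """
        if region_kind == "closed":
            return self.half_center + (1.0 - self.start_zone_fraction) * self.arm_length
        return self.half_center + self.proximal_fraction * self.arm_length

    @property
    def stop_distance(self) -> float:
        """Distance from origin marking the sequence stop threshold."""
        return self.half_center + self.stop_threshold_fraction * self.arm_length

    def arm_of(self, arm: str) -> str:
        """Whether ``arm`` is a closed or open arm."""
        return "closed" if arm[1] == self.closed_axis else "open"


def zone_of(point: Sequence[float], geometry: MazeGeometry) -> Zone:
    """Map a single (x, y) point in cm to its maze zone.

    Points outside the maze footprint are labeled ``off-maze``. Raises on
    non-finite coordinates.
    """
    x, y = float(point[0]), float(point[1])
    if not (math.isfinite(x) and math.isfinite(y)):
        raise ValueError(f"non-finite coordinates: ({x}, {y})")
    hc = geometry.half_center
    if abs(x) <= hc and abs(y) <= hc:
        return Zone("center", None)
    for axis, coord, perp in (("x", x, y), ("y", y, x)):
        if abs(perp) <= hc and hc < abs(coord) <= geometry.arm_end:
            arm = ("+" if coord > 0 else "-") + axis
            kind = geometry.arm_of(arm)
            distal = abs(coord) >= geometry.distal_boundary(kind)
            region = f"{kind}-{'distal' if distal else 'proximal'}"
            return Zone(region, arm)
    return Zone("off-maze", None)


def zones_of(xy: np.ndarray, geometry: MazeGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`zone_of`: returns (region, arm) object arrays."""
    xy = np.asarray(xy, dtype=float)
    if not np.isfinite(xy).all():
        raise ValueError("non-finite coordinates in trajectory")
    x, y = xy[:, 0], xy[:, 1]
    hc = geometry.half_center
    region = np.full(len(xy), "off-maze", dtype=object)
    arm = np.full(len(xy), None, dtype=object)
    center = (np.abs(x) <= hc) & (np.abs(y) <= hc)
    region[center] = "center"
    for axis, coord, perp in (("x", x, y), ("y", y, x)):
        in_arm = (np.abs(perp) <= hc) & (np.abs(coord) > hc) & (np.abs(coord) <= geometry.arm_end)
        in_arm &= ~center
        for sign, mask in (("+", in_arm & (coord > 0)), ("-", in_arm & (coord < 0))):
            if not mask.any():
                continue
            a = sign + axis
            kind = geometry.arm_of(a)
            bound = geometry.distal_boundary(kind)
            distal = mask & (np.abs(coord) >= bound)
            proximal = mask & ~distal
            region[distal] = f"{kind}-distal"
            region[proximal] = f"{kind}-proximal"
            arm[mask] = a
    return region, arm


@dataclass
class PoseTrack:
    """Frame-wise pose: timestamps, keypoints, and bounding box (all cm / s)."""

    time: np.ndarray
    centroid: np.ndarray  # (n, 2)
    head: np.ndarray  # (n, 2)
    tailbase: np.ndarray  # (n, 2)
    bbox_width: np.ndarray
    bbox_height: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        for name in ("centroid", "head", "tailbase"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.bbox_width = np.asarray(self.bbox_width, dtype=float)
        self.bbox_height = np.asarray(self.bbox_height, dtype=float)
        n = len(self.time)
        if any(len(getattr(self, f)) != n for f in ("centroid", "head", "tailbase", "bbox_width", "bbox_height")):
            raise ValueError("all PoseTrack fields must share one length")
        if n > 1 and not (np.diff(self.time) > 0).all():
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.time)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.time,
                "centroid_x": self.centroid[:, 0],
                "centroid_y": self.centroid[:, 1],
                "head_x": self.head[:, 0],
                "head_y": self.head[:, 1],
                "tailbase_x": self.tailbase[:, 0],
                "tailbase_y": self.tailbase[:, 1],
                "bbox_width": self.bbox_width,
                "bbox_height": self.bbox_height,
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PoseTrack":
        return cls(
            time=df["time"].to_numpy(),
            centroid=df[["centroid_x", "centroid_y"]].to_numpy(),
            head=df[["head_x", "head_y"]].to_numpy(),
            tailbase=df[["tailbase_x", "tailbase_y"]].to_numpy(),
            bbox_width=df["bbox_width"].to_numpy(),
            bbox_height=df["bbox_height"].to_numpy(),
        )


def _edge_copy(a: np.ndarray) -> np.ndarray:
    """First-frame edge rule: copy the first defined value backwards."""
    if len(a) > 1:
        a[0] = a[1]
    return a


def compute_kinematics(track: PoseTrack) -> pd.DataFrame:
    """Frame-wise speed, acceleration and horizontal movement.

    Speed is trailing centroid displacement over the frame interval;
    acceleration is the first difference of speed over the interval;
    horizontal movement is the per-frame displacement magnitude. The
    first frame copies the first defined value so the table stays
    rectangular.
    """
    if len(track) < 3:
        raise ValueError("need at least 3 frames for kinematics")
    dt = np.diff(track.time)
    if (dt <= 0).any():
        raise ValueError("duplicate or non-increasing timestamps")
    disp = np.linalg.norm(np.diff(track.centroid, axis=0), axis=1)
    speed = np.empty(len(track))
    speed[1:] = disp / dt
    speed = _edge_copy(speed)
    accel = np.empty(len(track))
    accel[1:] = np.diff(speed) / dt
    accel = _edge_copy(accel)
    hmove = np.empty(len(track))
    hmove[1:] = disp
    hmove = _edge_copy(hmove)
    return pd.DataFrame(
        {"time": track.time, "speed": speed, "acceleration": accel, "horizontal_movement": hmove}
    )


def compute_pose_features(track: PoseTrack) -> pd.DataFrame:
    """Bounding-box area, aspect ratio (height / width), its per-frame
    change, and heading (centroid->head angle, degrees in [0, 360)).

    Frames with a non-positive bounding-box width get NaN aspect values
    and are flagged in the ``aspect_defined`` column rather than dropped.
    """
    width = track.bbox_width
    height = track.bbox_height
    area = width * height
    defined = width > 0
    aspect = np.full(len(track), np.nan)
    aspect[defined] = height[defined] / width[defined]
    d_aspect = np.empty(len(track))
    d_aspect[1:] = np.diff(aspect)
    d_aspect = _edge_copy(d_aspect)
    vec = track.head - track.centroid
    heading = np.degrees(np.arctan2(vec[:, 1], vec[:, 0])) % 360.0
    return pd.DataFrame(
        {
            "time": track.time,
            "bbox_area": area,
            "aspect_ratio": aspect,
            "d_aspect": d_aspect,
            "aspect_defined": defined,
            "heading": heading,
        }
    )


def frame_features(track: PoseTrack, geometry: MazeGeometry) -> pd.DataFrame:
    """Full frame-wise feature table: zones + kinematics + pose features.

    Also carries the centroid coordinates so downstream segmentation can
    evaluate orientation rules without re-reading the track.
    """
    kin = compute_kinematics(track)
    pose = compute_pose_features(track).drop(columns="time")
    region, arm = zones_of(track.centroid, geometry)
    out = pd.concat([kin, pose], axis=1)
    out.insert(1, "zone_region", region)
    out.insert(2, "zone_arm", arm)
    out["centroid_x"] = track.centroid[:, 0]
    out["centroid_y"] = track.centroid[:, 1]
    return out


def heading_histogram(headings: Sequence[float], n_bins: int = 32) -> pd.DataFrame:
    """Polar histogram of heading angles with half-open bins
    ``[k*360/n, (k+1)*360/n)``; densities are per-bin fractions summing
    to 1."""
    h = np.asarray(headings, dtype=float)
    if h.size == 0:
        raise ValueError("empty heading sample")
    if n_bins < 4:
        raise ValueError("n_bins must be >= 4")
    h = np.mod(h, 360.0)
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    idx = np.minimum((h / (360.0 / n_bins)).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    return pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "density": counts / h.size,
        }
    )


def rayleigh_test(headings: Sequence[float]) -> tuple[float, float]:
    """Rayleigh test of circular uniformity on angles in degrees.

    Returns the mean resultant length ``r`` in [0, 1] and the standard
    small-sample corrected approximation of the p-value.
    """
    a = np.radians(np.asarray(headings, dtype=float))
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 angles")
    R = float(np.hypot(np.cos(a).sum(), np.sin(a).sum()))
    r = R / n
    # standard approximation of the Rayleigh p-value
    p = math.exp(math.sqrt(1.0 + 4.0 * n + 4.0 * (n * n - R * R)) - (1.0 + 2.0 * n))
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return r, p


class ECDF:
    """Right-continuous empirical CDF stepping from 0 to 1."""

    def __init__(self, values: Sequence[float]):
        values = np.asarray(values, dtype=float)
        if values.size == 0:
            raise ValueError("empty sample")
        self.values = np.sort(values)
        self.n = values.size

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        out = np.searchsorted(self.values, x, side="right") / self.n
        return float(out) if out.ndim == 0 else out


def movement_ecdf(features: pd.DataFrame, zones: set[str] | Sequence[str]) -> ECDF:
    """ECDF of frame-wise horizontal movement restricted to frames whose
    zone region is in ``zones``."""
    zones = set(zones)
    mask = features["zone_region"].isin(zones)
    vals = features.loc[mask, "horizontal_movement"].to_numpy()
    if vals.size == 0:
        raise ValueError(f"no frames fall in zones {sorted(zones)}")
    return ECDF(vals)
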