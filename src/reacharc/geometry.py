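"""Reach-surface geometry: target placement, crossing detection, angular error.

The task presents targets on an invisible arc at arm's length in front of a
seated participant.  We model the arc as a sector of a vertical cylinder
centred on the calibration-time headset position: radius equal to the
calibrated arm length, a 60 degree azimuth sector (half-width 30 degrees on
either side of straight ahead), extruded indefinitely in the vertical
direction.  A trial ends when the fingertip trajectory crosses the cylinder
from the inside; the outcome measure is the angle at the origin between the
direction to the target centre and the direction to the crossing point, which
folds horizontal and vertical miss into a single degrees-valued error.

Coordinate frame: right-handed, metres; y is up, z is forward from the
origin, x is to the participant's right.  Azimuth is measured in degrees
about the vertical axis from the forward direction (positive toward +x);
elevation is the angle above the horizontal plane through the origin.  All
public angles are degrees; trigonometry is done in radians internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .errors import (
    DegenerateCalibrationError,
    DegenerateGeometryError,
    NoCrossingError,
)

__all__ = [
    "Vec3",
    "ReachSurface",
    "TargetSpec",
    "Crossing",
    "Trajectory",
    "AngularError",
    "calibrate_radius",
    "sample_target",
    "detect_crossing",
    "angular_error",
]


@dataclass(frozen=True)
class Vec3:
    """A 3D position or displacement in metres."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in (self.x, self.y, self.z)):
            raise ValueError(f"Vec3 components must be finite, got {self}")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @classmethod
    def from_array(cls, a: Sequence[float]) -> "Vec3":
        return cls(float(a[0]), float(a[1]), float(a[2]))

    def __add__(self, other: "Vec3") -> "Vec3":
        return Vec3(self.x + other.x, self.y + other.y, self.z + other.z)

    def __sub__(self, other: "Vec3") -> "Vec3":
        return Vec3(self.x - other.x, self.y - other.y, self.z - other.z)

    def norm(self) -> float:
        return math.sqrt(self.x * self.x + self.y * self.y + self.z * self.z)


class AngularError(NamedTuple):
    """Angular endpoint error decomposed into azimuth/elevation components.

    ``total_deg`` is the nonnegative 3D cone angle at the origin between the
    target direction and the crossing direction (0..180 degrees).  The signed
    components are differences in surface coordinates, crossing minus target:
    positive azimuth means the reach landed to the right of the target,
    positive elevation above it.  For small errors
    ``total_deg**2 ~= azimuth_deg**2 + elevation_deg**2``.
    """

    total_deg: float
    azimuth_deg: float
    elevation_deg: float

    def __float__(self) -> float:  # convenient scalar view
        return self.total_deg


@dataclass(frozen=True)
class ReachSurface:
    """The calibrated reach boundary: a vertical cylinder sector.

    Parameters
    ----------
    origin
        Headset position at calibration time; fixed for the whole session.
    radius
        Arm length in metres (cylinder radius).
    azimuth_halfwidth
        Half-width of the target sector in degrees (default 30, i.e. the
        standard 60 degree arc).
    forward_azimuth
        Azimuth of the sector centre in degrees (default 0 = straight ahead).
    """

    origin: Vec3
    radius: float
    azimuth_halfwidth: float = 30.0
    forward_azimuth: float = 0.0

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError(f"radius must be positive, got {self.radius}")
        if not 0 < self.azimuth_halfwidth <= 90:
            raise ValueError(
                "azimuth_halfwidth must be in (0, 90] degrees, got "
                f"{self.azimuth_halfwidth}"
            )

    # -- coordinate transforms -------------------------------------------

    def surface_point(self, azimuth_deg: float, elevation_deg: float) -> Vec3:
        """Cartesian point on the cylinder at the given surface coordinates.

        The point lies at cylindrical distance ``radius`` from the origin's
        vertical axis; its height is ``radius * tan(elevation)`` so that
        ``elevation`` is the true elevation angle of the direction from the
        origin to the point.
        """
        az = math.radians(azimuth_deg)
        el = math.radians(elevation_deg)
        if abs(el) >= math.pi / 2:
            raise DegenerateGeometryError(
                f"elevation {elevation_deg} deg does not intersect the surface"
            )
        return Vec3(
            self.origin.x + self.radius * math.sin(az),
            self.origin.y + self.radius * math.tan(el),
            self.origin.z + self.radius * math.cos(az),
        )

    def angles_of(self, point: Vec3) -> tuple[float, float]:
        """(azimuth_deg, elevation_deg) of a point as seen from the origin."""
        dx = point.x - self.origin.x
        dy = point.y - self.origin.y
        dz = point.z - self.origin.z
        cyl = math.hypot(dx, dz)
        if cyl == 0.0 and dy == 0.0:
            raise DegenerateGeometryError("point coincides with the origin")
        return math.degrees(math.atan2(dx, dz)), math.degrees(math.atan2(dy, cyl))

    def cylindrical_distance(self, point: Vec3) -> float:
        """Horizontal distance of a point from the origin's vertical axis."""
        return math.hypot(point.x - self.origin.x, point.z - self.origin.z)

    def contains_azimuth(self, azimuth_deg: float) -> bool:
        return abs(azimuth_deg - self.forward_azimuth) <= self.azimuth_halfwidth


@dataclass(frozen=True)
class TargetSpec:
    """A target location on the reach surface.

    ``azimuth``/``elevation`` are the surface coordinates in degrees;
    ``cartesian`` is the corresponding point in the session frame.
    """

    azimuth: float
    elevation: float
    cartesian: Vec3


@dataclass(frozen=True)
class Crossing:
    """Where and when the fingertip passed through the reach surface."""

    point: Vec3
    time_ms: float

    def __post_init__(self) -> None:
        if self.time_ms < 0:
            raise ValueError(f"time_ms must be >= 0, got {self.time_ms}")


@dataclass(frozen=True)
class Trajectory:
    """A timestamped fingertip path: ``t_ms`` (n,) and ``xyz`` (n, 3)."""

    t_ms: np.ndarray
    xyz: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t_ms, dtype=float)
        p = np.asarray(self.xyz, dtype=float)
        if t.ndim != 1 or p.shape != (t.size, 3):
            raise ValueError("t_ms must be (n,) and xyz (n, 3)")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        object.__setattr__(self, "t_ms", t)
        object.__setattr__(self, "xyz", p)

    def __len__(self) -> int:
        return int(self.t_ms.size)


def calibrate_radius(headset_pos: Vec3, fingertip_pos: Vec3) -> float:
    """Arm-length calibration: Euclidean headset-to-fingertip distance (m).

    Raises
    ------
    DegenerateCalibrationError
        If the two positions coincide.
    """
    r = (fingertip_pos - headset_pos).norm()
    if r == 0.0:
        raise DegenerateCalibrationError(
            "headset and fingertip positions coincide; cannot calibrate radius"
        )
    return r


def sample_target(
    surface: ReachSurface,
    elevation: float | tuple[float, float] = 0.0,
    rng: np.random.Generator | int | None = None,
) -> TargetSpec:
    """Draw a target uniformly along the azimuth sector.

    ``elevation`` is either a fixed value in degrees or a ``(low, high)``
    range sampled uniformly; either way it must stay within [-60, 60].
    The task only specifies random placement along the arc, so elevation
    defaults to the origin's height (0 degrees).
    """
    gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    az = float(
        gen.uniform(
            surface.forward_azimuth - surface.azimuth_halfwidth,
            surface.forward_azimuth + surface.azimuth_halfwidth,
        )
    )
    if isinstance(elevation, tuple):
        lo, hi = elevation
        if not (-60.0 <= lo <= hi <= 60.0):
            raise ValueError(f"elevation range {elevation} outside [-60, 60]")
        el = float(gen.uniform(lo, hi))
    else:
        el = float(elevation)
        if not -60.0 <= el <= 60.0:
            raise ValueError(f"elevation {el} outside [-60, 60]")
    return TargetSpec(azimuth=az, elevation=el, cartesian=surface.surface_point(az, el))


def detect_crossing(trajectory: Trajectory, surface: ReachSurface) -> Crossing:
    """First passage of the fingertip through the reach surface.

    Scans consecutive samples for the first pair whose cylindrical distances
    from the origin's vertical axis straddle the radius from below, then
    solves the exact segment-cylinder intersection (linear interpolation of
    position in Cartesian coordinates; the returned point sits on the surface
    to machine precision and the timestamp is interpolated with the same
    parameter).

    Raises
    ------
    NoCrossingError
        If no sample pair crosses the radius from inside to outside.
    """
    if len(trajectory) < 2:
        raise NoCrossingError("trajectory has fewer than 2 samples")
    rel = trajectory.xyz - surface.origin.as_array()
    d = np.hypot(rel[:, 0], rel[:, 2])
    r = surface.radius
    inside = d < r
    outside = ~inside
    straddle = np.flatnonzero(inside[:-1] & outside[1:])
    if straddle.size == 0:
        raise NoCrossingError(
            f"trajectory never crossed the surface (max distance {d.max():.4f} m, "
            f"radius {r:.4f} m)"
        )
    i = int(straddle[0])
    # horizontal (x, z) quadratic |a + s*b|^2 = r^2 for s in [0, 1]
    a = rel[i, [0, 2]]
    b = rel[i + 1, [0, 2]] - a
    A = float(b @ b)
    B = 2.0 * float(a @ b)
    C = float(a @ a) - r * r
    if A == 0.0:  # no horizontal motion yet d crosses r: numerically impossible
        raise NoCrossingError("degenerate segment with no horizontal motion")
    disc = B * B - 4.0 * A * C
    s = (-B + math.sqrt(max(disc, 0.0))) / (2.0 * A)
    s = min(max(s, 0.0), 1.0)
    p = trajectory.xyz[i] + s * (trajectory.xyz[i + 1] - trajectory.xyz[i])
    t = trajectory.t_ms[i] + s * (trajectory.t_ms[i + 1] - trajectory.t_ms[i])
    return Crossing(point=Vec3.from_array(p), time_ms=float(t))


def _direction(surface: ReachSurface, point: Vec3) -> np.ndarray:
    v = point.as_array() - surface.origin.as_array()
    n = np.linalg.norm(v)
    if n == 0.0:
        raise DegenerateGeometryError("zero-length direction vector")
    return v / n


def angular_error(
    surface: ReachSurface, target: TargetSpec, crossing: Crossing
) -> AngularError:
    """Angle in degrees between the target and crossing directions.

    The total error is the cone angle at the origin between the two unit
    direction vectors, computed as atan2(|u x v|, u . v) — equivalent to the
    arccos of the dot product but numerically stable near 0 and 180 degrees;
    the signed azimuth and elevation components are differences of surface
    coordinates, crossing minus target.
    """
    u = _direction(surface, target.cartesian)
    v = _direction(surface, crossing.point)
    total = math.degrees(
        math.atan2(float(np.linalg.norm(np.cross(u, v))), float(u @ v))
    )
    az_c, el_c = surface.angles_of(crossing.point)
    return AngularError(
        total_deg=total,
        azimuth_deg=az_c - target.azimuth,
        elevation_deg=el_c - target.elevation,
    )


def cone_angle_deg(az1, el1, az2, el2):
    """Cone angle between two (azimuth, elevation) directions, degrees.

    Vectorised haversine form (numerically stable at small separations);
    used by the simulator's fast path so endpoint errors agree with
    :func:`angular_error` on the surface.
    """
    az1, el1, az2, el2 = (np.radians(np.asarray(a, dtype=float)) for a in (az1, el1, az2, el2))
    h = (
        np.sin((el2 - el1) / 2.0) ** 2
        + np.cos(el1) * np.cos(el2) * np.sin((az2 - az1) / 2.0) ** 2
    )
    return np.degrees(2.0 * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0))))
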