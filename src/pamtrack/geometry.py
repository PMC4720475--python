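"""Array geometry, attitude handling and coordinate conventions.

Frames and conventions used throughout the package
--------------------------------------------------
* **World frame** — local East-North-Up (ENU) tangent plane, flat-earth,
  anchored at a configurable reference origin (by default the midpoint
  between the two acoustic units).  Azimuths facing the user are *compass
  bearings*: degrees clockwise from North, so a direction vector
  ``d = (sin B, cos B, 0)`` has bearing ``B``.
* **Body frame** — fixed to the spar buoy.  Hydrophone pair (H0, H2) lies
  along body *x* at the upper depth, pair (H1, H3) along body *y*, 5 m
  deeper.  Indices are chosen so the contiguous pairs (H0H1, H1H2, H2H3)
  give a non-singular 3x3 system for the plane-wave direction.
* **Attitude** — the tilt-compass reports pitch, roll and compass heading
  independently; the body-to-world rotation is applied intrinsically in the
  order roll (about body x), pitch (about body y), yaw (about z).  Yaw is
  ``-(compass + psi0 + declination)`` in the right-handed ENU sense, i.e.
  a clockwise rotation by the compass angle.
* **Wave direction** — a plane wave propagating towards the array is
  described by the unit vector ``n = (sin th cos ph, sin th sin ph, cos th)``
  (polar angle ``th`` from +z).  The wavefront reaches hydrophone i at
  ``t_i = (H_i . n) / c`` relative to the array origin, so the pairwise time
  difference of arrival is ``dt_ij = t_i - t_j = ((H_i - H_j) . n) / c``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Default sound speed in seawater [m/s]; field calibration (L/c) supersedes
#: this wherever the ratio L/c appears.
SOUND_SPEED = 1500.0

#: The six ordered hydrophone pairs (i, j) for which TDOAs are computed.
PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))

#: Contiguous pairs used by the linear direction solver.
CONTIGUOUS_PAIRS = ((0, 1), (1, 2), (2, 3))


@dataclass(frozen=True)
class ArrayGeometry:
    """Body-frame positions of the four hydrophones.

    Two orthogonal horizontal pairs of spacing ``spacing`` metres, the
    second pair ``depth_offset`` metres below the first.
    """

    positions: np.ndarray = field(
        default_factory=lambda: np.array(
            [
                [-2.5, 0.0, 0.0],   # H0
                [0.0, -2.5, -5.0],  # H1
                [2.5, 0.0, 0.0],    # H2
                [0.0, 2.5, -5.0],   # H3
            ]
        )
    )
    spacing: float = 5.0
    depth_offset: float = 5.0

    def __post_init__(self) -> None:
        p = np.asarray(self.positions, dtype=float)
        if p.shape != (4, 3):
            raise ValueError("ArrayGeometry needs four 3-vectors")
        object.__setattr__(self, "positions", p)
        ax02 = p[2] - p[0]
        ax13 = p[3] - p[1]
        if abs(float(ax02 @ ax13)) > 1e-9 * self.spacing**2:
            raise ValueError("hydrophone pair axes must be orthogonal")

    @classmethod
    def default(cls, spacing: float = 5.0, depth_offset: float = 5.0) -> "ArrayGeometry":
        h = spacing / 2.0
        pos = np.array(
            [
                [-h, 0.0, 0.0],
                [0.0, -h, -depth_offset],
                [h, 0.0, 0.0],
                [0.0, h, -depth_offset],
            ]
        )
        return cls(positions=pos, spacing=spacing, depth_offset=depth_offset)

    @property
    def max_delay(self) -> float:
        """Largest pairwise separation [m] (divide by c for max TDOA)."""
        d = 0.0
        for i, j in PAIRS:
            d = max(d, float(np.linalg.norm(self.positions[i] - self.positions[j])))
        return d


@dataclass(frozen=True)
class Attitude:
    """Instantaneous buoy attitude from the tilt-compass.

    Angles in degrees: ``compass`` in [0, 360), ``pitch``/``roll`` in
    (-90, 90).  ``timestamp`` is UTC seconds.
    """

    pitch: float = 0.0
    roll: float = 0.0
    compass: float = 0.0
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        for a in (self.pitch, self.roll, self.compass):
            if not math.isfinite(a):
                raise ValueError("attitude angles must be finite")
        if not (-90.0 < self.pitch < 90.0 and -90.0 < self.roll < 90.0):
            raise ValueError("pitch and roll must lie in (-90, 90) degrees")
        object.__setattr__(self, "compass", self.compass % 360.0)


@dataclass(frozen=True)
class UnitConfig:
    """Static per-unit configuration (geographic position and calibration).

    ``lc`` is the field-calibrated ratio between hydrophone spacing and
    sound speed [s]; it is the maximum possible TDOA on one pair and
    supersedes the nominal ``spacing / SOUND_SPEED`` wherever it appears.
    ``psi0`` is the compass-to-array azimuth offset [deg] recovered by the
    calibration module.  ``declination`` converts magnetic to true North
    when the compass is magnetic (default 0 = compass already true).
    """

    name: str
    lat: float
    lon: float
    depth: float = 20.0
    lc: float = 5.0 / SOUND_SPEED
    psi0: float = 0.0
    declination: float = 0.0

    def __post_init__(self) -> None:
        if self.lc <= 0:
            raise ValueError("L/c must be positive")
        if self.depth <= 0:
            raise ValueError("array depth must be positive")


@dataclass(frozen=True)
class Bearing:
    """World-frame direction of a source seen from one unit.

    ``azimuth`` is a compass bearing [deg, 0-360), ``elevation`` the polar
    angle from the zenith [deg, 0-180] (90 = horizontal), ``error`` the
    one-sigma angular uncertainty [deg].
    """

    azimuth: float
    elevation: float = 90.0
    error: float = 2.0
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "azimuth", self.azimuth % 360.0)
        if not (0.0 <= self.elevation <= 180.0):
            raise ValueError("elevation must lie in [0, 180] degrees")


def _rot_x(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_y(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rot_z(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def rotation_matrix(attitude: Attitude, psi0: float = 0.0, declination: float = 0.0) -> np.ndarray:
    """Body-to-world rotation for a given attitude.

    Intrinsic roll -> pitch -> yaw; the yaw angle is minus the total compass
    heading (compass + psi0 + declination) because compass bearings grow
    clockwise while ENU angles grow counter-clockwise.
    """
    yaw = -math.radians(attitude.compass + psi0 + declination)
    return _rot_z(yaw) @ _rot_y(math.radians(attitude.pitch)) @ _rot_x(math.radians(attitude.roll))


def body_to_world(v: np.ndarray, attitude: Attitude, psi0: float = 0.0,
                  declination: float = 0.0) -> np.ndarray:
    """Rotate a body-frame vector into the ENU world frame."""
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite input vector")
    return rotation_matrix(attitude, psi0, declination) @ v


def world_to_body(v: np.ndarray, attitude: Attitude, psi0: float = 0.0,
                  declination: float = 0.0) -> np.ndarray:
    """Inverse of :func:`body_to_world` (rotation transpose)."""
    v = np.asarray(v, dtype=float)
    return rotation_matrix(attitude, psi0, declination).T @ v


def wave_unit_vector(azimuth_rad: float, polar_rad: float) -> np.ndarray:
    """Propagation unit vector from wave azimuth and polar angle (radians)."""
    st = math.sin(polar_rad)
    return np.array([st * math.cos(azimuth_rad), st * math.sin(azimuth_rad), math.cos(polar_rad)])


def expected_tdoas(direction: np.ndarray, geometry: ArrayGeometry,
                   c: float = SOUND_SPEED) -> np.ndarray:
    """Theoretical TDOAs [s] of a plane wave at the six ordered pairs.

    ``direction`` is the propagation unit vector n (pointing from the
    source towards the array); ``dt_ij = ((H_i - H_j) . n) / c`` in the
    order of :data:`PAIRS`.
    """
    n = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(n)
    if norm == 0:
        raise ValueError("zero direction vector")
    if c <= 0:
        raise ValueError("sound speed must be positive")
    n = n / norm
    p = geometry.positions
    return np.array([float((p[i] - p[j]) @ n) / c for i, j in PAIRS])


def compass_to_math(bearing_deg: float) -> float:
    """Compass bearing (cw from North) -> math azimuth (ccw from East), deg."""
    return (90.0 - bearing_deg) % 360.0


def math_to_compass(azimuth_deg: float) -> float:
    return (90.0 - azimuth_deg) % 360.0


def vector_to_bearing(v: np.ndarray) -> tuple[float, float]:
    """ENU direction vector -> (compass azimuth deg, polar elevation deg)."""
    v = np.asarray(v, dtype=float)
    r = np.linalg.norm(v)
    if r == 0:
        raise ValueError("zero vector has no bearing")
    az = math.degrees(math.atan2(v[0], v[1])) % 360.0
    el = math.degrees(math.acos(np.clip(v[2] / r, -1.0, 1.0)))
    return az, el


def bearing_to_vector(azimuth_deg: float, elevation_deg: float = 90.0) -> np.ndarray:
    """Inverse of :func:`vector_to_bearing` (unit vector)."""
    el = math.radians(elevation_deg)
    az = math.radians(azimuth_deg)
    return np.array([math.sin(el) * math.sin(az), math.sin(el) * math.cos(az), math.cos(el)])


_EARTH_RADIUS = 6371000.0


def latlon_to_enu(lat: float, lon: float, ref_lat: float, ref_lon: float) -> tuple[float, float]:
    """Flat-earth projection of WGS84 degrees to local ENU metres.

    Adequate over the few-kilometre extent of a coastal study area.
    """
    east = math.radians(lon - ref_lon) * _EARTH_RADIUS * math.cos(math.radians(ref_lat))
    north = math.radians(lat - ref_lat) * _EARTH_RADIUS
    return east, north


def enu_to_latlon(east: float, north: float, ref_lat: float, ref_lon: float) -> tuple[float, float]:
    lat = ref_lat + math.degrees(north / _EARTH_RADIUS)
    lon = ref_lon + math.degrees(east / (_EARTH_RADIUS * math.cos(math.radians(ref_lat))))
    return lat, lon


def angular_difference(a_deg: float, b_deg: float) -> float:
    """Signed smallest difference a - b wrapped to (-180, 180] degrees."""
    return (a_deg - b_deg + 180.0) % 360.0 - 180.0


def circular_mean(angles_deg: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Weighted circular mean of angles in degrees, result in [0, 360)."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    w = np.ones_like(a) if weights is None else np.asarray(weights, dtype=float)
    s = float(np.sum(w * np.sin(a)))
    c = float(np.sum(w * np.cos(a)))
    out = math.degrees(math.atan2(s, c)) % 360.0
    return 0.0 if out == 360.0 else out


def circular_std(angles_deg: np.ndarray) -> float:
    """Circular standard deviation [deg] (Mardia definition)."""
    a = np.radians(np.asarray(angles_deg, dtype=float))
    r = math.hypot(float(np.mean(np.sin(a))), float(np.mean(np.cos(a))))
    r = min(max(r, 1e-12), 1.0)
    return math.degrees(math.sqrt(-2.0 * math.log(r)))
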