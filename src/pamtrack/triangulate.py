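"""Two-unit triangulation with TDOA-hyperbola consistency checking.

Both units are GPS-synchronized, ~1.8 km apart.  A simultaneous pair of
azimuth bearings is intersected in the horizontal ENU plane by least
squares; the inter-unit arrival-time difference of the same event places
the source on a hyperbola with the units as foci, and the distance between
the fix and that hyperbola is reported as a consistency residual.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import Bearing, SOUND_SPEED, angular_difference, bearing_to_vector


@dataclass
class Fix:
    """A triangulated position with its error square and consistency."""

    east: float
    north: float
    time: float = 0.0
    error_side: float = math.nan      # error-square side [m]
    hyperbola_residual: float = math.nan  # [m]
    consistent: bool | None = None    # None = check skipped
    bearings: tuple = ()

    @property
    def position(self) -> np.ndarray:
        return np.array([self.east, self.north])


def intersect_bearings(bearing_a: Bearing, pos_a, bearing_b: Bearing, pos_b,
                       parallel_tol_deg: float = 3.0, time: float = 0.0) -> Fix | None:
    """Least-squares intersection of two azimuth rays in the horizontal plane.

    Returns None (no-fix sentinel) for rays within ``parallel_tol_deg`` of
    parallel or intersecting behind either unit.
    """
    pa = np.asarray(pos_a, dtype=float)[:2]
    pb = np.asarray(pos_b, dtype=float)[:2]
    ua = bearing_to_vector(bearing_a.azimuth)[:2]
    ub = bearing_to_vector(bearing_b.azimuth)[:2]
    cross = ua[0] * ub[1] - ua[1] * ub[0]
    if abs(math.degrees(math.asin(np.clip(abs(cross), 0, 1)))) < parallel_tol_deg:
        return None
    # pa + ta*ua = pb + tb*ub
    A = np.stack([ua, -ub], axis=1)
    rhs = pb - pa
    ta, tb = np.linalg.solve(A, rhs)
    tol = -1e-9 * float(np.linalg.norm(rhs))  # roundoff slack at the units
    if ta < tol or tb < tol:
        return None
    p = pa + ta * ua
    r_mean = 0.5 * (float(np.linalg.norm(p - pa)) + float(np.linalg.norm(p - pb)))
    err = 0.5 * (bearing_a.error + bearing_b.error)
    return Fix(east=float(p[0]), north=float(p[1]), time=time,
               error_side=error_square(r_mean, err),
               bearings=(bearing_a, bearing_b))


def hyperbola_consistency(fix: Fix, dt_ab: float | None, pos_a, pos_b,
                          c: float = SOUND_SPEED, threshold: float = 50.0) -> Fix:
    """Check the fix against the inter-unit arrival-time difference.

    ``dt_ab`` is the arrival time at unit A minus the arrival time at unit
    B of the same event; the residual ``|(r_A - r_B) - c dt_ab|`` (metres)
    measures the distance of the fix from the equal-TDOA hyperbola.  With
    no inter-unit time available the check is skipped and flagged so.
    """
    if dt_ab is None:
        fix.consistent = None
        return fix
    pa = np.asarray(pos_a, dtype=float)[:2]
    pb = np.asarray(pos_b, dtype=float)[:2]
    ra = float(np.linalg.norm(fix.position - pa))
    rb = float(np.linalg.norm(fix.position - pb))
    fix.hyperbola_residual = abs((ra - rb) - c * dt_ab)
    fix.consistent = fix.hyperbola_residual < threshold
    return fix


def error_square(target_range: float, dalpha_deg: float) -> float:
    """Side [m] of the square error area at range r for angular error da."""
    if target_range < 0:
        raise ValueError("range must be non-negative")
    return target_range * math.radians(dalpha_deg)


def match_events(events_a: list, events_b: list, window: float = 3.0,
                 key=lambda e: e.peak_time) -> list[tuple]:
    """Pair events seen by both units within a time window.

    The maximum inter-unit acoustic delay at 1.8 km separation is ~1.2 s;
    the default +-3 s window leaves margin for detection timing jitter.
    Greedy nearest-in-time matching, each event used once.
    """
    pairs = []
    used_b: set[int] = set()
    for ea in events_a:
        best, best_dt = None, window
        for k, eb in enumerate(events_b):
            if k in used_b:
                continue
            dt = abs(key(ea) - key(eb))
            if dt <= best_dt:
                best, best_dt = k, dt
        if best is not None:
            used_b.add(best)
            pairs.append((ea, events_b[best]))
    return pairs


def contour_similarity(contour_a: np.ndarray, contour_b: np.ndarray) -> float:
    """Normalized cross-correlation peak of two whistle frequency contours.

    Used to confirm that the two units detected the same whistle before
    triangulating (threshold 0.7 by default downstream).
    """
    a = np.asarray(contour_a, dtype=float)
    b = np.asarray(contour_b, dtype=float)
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    corr = np.correlate(a, b, mode="full")
    return float(np.max(corr) / denom)
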