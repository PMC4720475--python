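"""Whistle-triggered bearing estimation via the plane-wave TDOA model.

Given a set of measured TDOAs, the direction of the incoming plane wave
``n = (sin th cos ph, sin th sin ph, cos th)`` (body frame) is recovered
two ways:

* ``solve_linear`` — exact inversion of the 3x3 linear system built from
  the contiguous hydrophone pairs (H0H1, H1H2, H2H3):
  ``u dHx + v dHy + w dHz = c dt`` per pair.
* ``grid_search_G`` — least-squares minimization of the functional
  ``G(ph, th) = sum over the six pairs of (dt_meas - dt_theo(ph, th))^2``
  on a coarse grid with local refinement; robust to measurement noise that
  would push the linear solution off the unit sphere.

The body-frame wave direction is then converted to a world-frame source
bearing: source angles are the antipode of the wave angles
(``ph_S = ph_W + pi``, ``th_S = pi - th_W``), rotated by the buoy attitude
(roll, pitch, compass + psi0) and reported as a compass azimuth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .geometry import (
    ArrayGeometry,
    Attitude,
    Bearing,
    CONTIGUOUS_PAIRS,
    PAIRS,
    SOUND_SPEED,
    body_to_world,
    circular_mean,
    vector_to_bearing,
    wave_unit_vector,
)
from .tdoa import TdoaSet


@dataclass
class WaveDirection:
    """Body-frame direction of the incoming plane wave."""

    azimuth_rad: float
    polar_rad: float
    n_hat: np.ndarray
    g_value: float = 0.0
    norm_residual: float = 0.0
    reliable: bool = True


def solve_linear(tdoas: TdoaSet, geometry: ArrayGeometry | None = None,
                 c: float = SOUND_SPEED) -> WaveDirection:
    """Direct linear inversion of the contiguous-pair system.

    The raw solution's deviation from unit length is reported as a quality
    metric; deviations above 0.2 flag the result unreliable (noisy or
    inconsistent TDOAs).
    """
    geometry = geometry or ArrayGeometry.default()
    p = geometry.positions
    A = np.array([p[i] - p[j] for i, j in CONTIGUOUS_PAIRS])
    b = np.array([c * tdoas.tdoa(i, j) for i, j in CONTIGUOUS_PAIRS])
    if abs(np.linalg.det(A)) < 1e-9:
        raise ValueError("singular pair geometry")
    uvw = np.linalg.solve(A, b)
    norm = float(np.linalg.norm(uvw))
    if norm == 0:
        raise ValueError("degenerate TDOA set (all zero)")
    n_hat = uvw / norm
    az = math.atan2(n_hat[1], n_hat[0]) % (2 * math.pi)
    th = math.acos(np.clip(n_hat[2], -1.0, 1.0))
    resid = abs(1.0 - norm)
    return WaveDirection(az, th, n_hat, g_value=0.0, norm_residual=resid,
                         reliable=resid <= 0.2)


def _g_functional(tdoas_meas: np.ndarray, geometry: ArrayGeometry, c: float):
    """Vectorized G(az, th) over arrays of angles."""
    p = geometry.positions
    dh = np.array([p[i] - p[j] for i, j in PAIRS])  # (6, 3)

    def g(az: np.ndarray, th: np.ndarray) -> np.ndarray:
        st = np.sin(th)
        n = np.stack([st * np.cos(az), st * np.sin(az), np.cos(th)], axis=-1)
        theo = (n @ dh.T) / c  # (..., 6)
        return np.sum((tdoas_meas - theo) ** 2, axis=-1)

    return g


def grid_search_G(tdoas: TdoaSet, geometry: ArrayGeometry | None = None,
                  c: float = SOUND_SPEED, coarse_step_deg: float = 2.0,
                  refine_tol_deg: float = 0.1) -> WaveDirection | None:
    """Least-squares grid minimization of the TDOA residual functional.

    Coarse grid over azimuth [0, 360) x polar [0, 180] at
    ``coarse_step_deg``, followed by Nelder-Mead local refinement to
    ``refine_tol_deg``.  Returns None (no-bearing sentinel) when the
    functional surface is flat (undefined or all-zero TDOAs).
    """
    geometry = geometry or ArrayGeometry.default()
    meas = np.asarray(tdoas.tdoas, dtype=float)
    if not np.all(np.isfinite(meas)):
        return None
    g = _g_functional(meas, geometry, c)

    az = np.radians(np.arange(0.0, 360.0, coarse_step_deg))
    th = np.radians(np.arange(0.0, 180.0 + coarse_step_deg, coarse_step_deg))
    azg, thg = np.meshgrid(az, th, indexing="ij")
    surface = g(azg, thg)
    if np.ptp(surface) < 1e-24:
        return None
    k = np.unravel_index(np.argmin(surface), surface.shape)
    x0 = np.array([azg[k], thg[k]])

    res = minimize(
        lambda x: float(g(np.array(x[0]), np.array(np.clip(x[1], 0.0, math.pi)))),
        x0,
        method="Nelder-Mead",
        options={"xatol": math.radians(refine_tol_deg) / 4, "fatol": 1e-24,
                 "maxiter": 400},
    )
    az_opt = float(res.x[0]) % (2 * math.pi)
    th_opt = float(np.clip(res.x[1], 0.0, math.pi))
    n_hat = wave_unit_vector(az_opt, th_opt)
    return WaveDirection(az_opt, th_opt, n_hat, g_value=float(res.fun))


def wave_to_source_bearing(wave: WaveDirection, attitude: Attitude,
                           psi0: float = 0.0, declination: float = 0.0,
                           error_deg: float = 2.0) -> Bearing:
    """World-frame source bearing from a body-frame wave direction.

    The source lies at the antipode of the wave propagation direction; the
    body-frame source vector is rotated to the world frame using the
    attitude and the calibrated compass offset psi0.
    """
    src_body = -wave.n_hat
    src_world = body_to_world(src_body, attitude, psi0, declination)
    az, el = vector_to_bearing(src_world)
    return Bearing(azimuth=az, elevation=el, error=error_deg,
                   timestamp=attitude.timestamp)


def event_bearing(channels: np.ndarray, fs: float, attitude: Attitude,
                  geometry: ArrayGeometry | None = None, c: float = SOUND_SPEED,
                  psi0: float = 0.0, window: float = 0.2,
                  band: tuple = (3000.0, 23000.0)) -> tuple[Bearing, WaveDirection] | None:
    """Bearing of one whistle event from its 4-channel audio extent.

    The event is split into windows; each valid window yields a TdoaSet and
    a grid-search direction, and the event bearing is the correlation-peak
    weighted circular mean of the per-window world bearings.
    """
    from .tdoa import tdoa_set

    geometry = geometry or ArrayGeometry.default()
    n = channels.shape[1]
    win = max(16, int(window * fs))
    bearings, weights, elevations = [], [], []
    best_wave = None
    best_peak = -np.inf
    for start in range(0, max(1, n - win // 2), win):
        seg = channels[:, start:start + win]
        if seg.shape[1] < win // 2:
            break
        ts = tdoa_set(seg, fs, geometry, c, band=band)
        if not ts.valid:
            continue
        wave = grid_search_G(ts, geometry, c)
        if wave is None:
            continue
        b = wave_to_source_bearing(wave, attitude, psi0)
        peak = float(np.max(ts.peaks))
        bearings.append(b.azimuth)
        elevations.append(b.elevation)
        weights.append(peak)
        if peak > best_peak:
            best_peak = peak
            best_wave = wave
    if not bearings:
        return None
    az = circular_mean(np.array(bearings), np.array(weights))
    el = float(np.average(elevations, weights=weights))
    return Bearing(azimuth=az, elevation=el, timestamp=attitude.timestamp), best_wave
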