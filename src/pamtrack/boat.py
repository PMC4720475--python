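"""Continuous boat bearing estimation from the two orthogonal pairs.

Boats are loud and persistent, so no detection trigger is used: the stream
is sliced into short windows (8 ms, twice the maximum pair TDOA) and each
window yields one gated TDOA per orthogonal pair, ``dT20`` on pair (H0,
H2) and ``dT31`` on pair (H1, H3).  With the boat on the sea surface and
the calibrated maximum delay ``Lc = L/c``:

    dT20 = Lc cos(alpha)        dT31 = Lc sin(alpha)

where ``alpha`` is the boat azimuth in the body frame, measured from the
pair-(0,2) axis (+x) towards the pair-(1,3) axis (+y).  Inverting each
equation leaves a mirror ambiguity (``2 pi - alpha_20`` about the x axis,
``pi - alpha_31`` about the y axis) which is resolved by multiplying the
two per-pair probability functions — each a circular mixture of two
Gaussians centred on the real and mirror angles with a standard deviation
of four times the propagated angular error — and taking the argmax.

To match the cosine/sine convention above, the streaming stage reports
``dT20 = t0 - t2`` and ``dT31 = t1 - t3``: with the wave propagating
*towards* the array from azimuth ``alpha``, the hydrophone nearer the boat
(larger projection on the boat direction) receives the wavefront earlier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import ArrayGeometry, SOUND_SPEED, angular_difference
from .tdoa import bandpass, pair_tdoa_gated

#: Sentinel angular error when |tdoa| >= Lc (formula pole).
INF_ERROR = math.inf


@dataclass
class BoatBearingSample:
    """One windowed boat-bearing estimate (body frame unless rotated)."""

    time: float
    alpha_deg: float | None
    error_deg: float
    alpha20_deg: float | None = None
    alpha31_deg: float | None = None
    gated: bool = False


def correlogram_stream(channels: np.ndarray, fs: float, lc: float,
                       window: float = 0.008, hop: float | None = None,
                       n_sigma: float = 4.0, band: tuple = (3000.0, 23000.0),
                       prefiltered: bool = False):
    """Gated per-window TDOA series for the two orthogonal pairs.

    Returns ``(times, dt20, dt31, peaks20, peaks31)`` where gated-out
    windows hold NaN (recorded as no-data, not an error).  Window length
    defaults to 8 ms, twice the maximum pair TDOA at L = 5 m; hop defaults
    to the window (non-overlapping).
    """
    x = np.asarray(channels, dtype=float)
    if x.ndim != 2 or x.shape[0] != 4:
        raise ValueError("need a (4, N) channel array")
    if not prefiltered:
        x = np.stack([bandpass(ch, fs, band) for ch in x])
    hop = window if hop is None else hop
    nwin = int(round(window * fs))
    nhop = int(round(hop * fs))
    max_lag = lc + 2.0 / fs
    n = x.shape[1]
    times, dt20, dt31, pk20, pk31 = [], [], [], [], []
    for start in range(0, n - nwin + 1, nhop):
        seg = x[:, start:start + nwin]
        t = (start + nwin / 2) / fs
        # source-convention TDOAs: t0 - t2 and t1 - t3
        d02, p02 = pair_tdoa_gated(seg[0], seg[2], fs, max_lag, n_sigma)
        d13, p13 = pair_tdoa_gated(seg[1], seg[3], fs, max_lag, n_sigma)
        times.append(t)
        dt20.append(np.nan if d02 is None else d02)
        dt31.append(np.nan if d13 is None else d13)
        pk20.append(p02)
        pk31.append(p13)
    return (np.array(times), np.array(dt20), np.array(dt31),
            np.array(pk20), np.array(pk31))


def angles_from_tdoas(dt20: float, dt31: float, lc: float, fs: float = 100000.0,
                      clip_tol_samples: float = 2.0):
    """Per-pair azimuth candidates (deg) from the two orthogonal TDOAs.

    ``alpha20 = arccos(dT20 / Lc)`` with mirror ``360 - alpha20``;
    ``alpha31 = arcsin(dT31 / Lc)`` with mirror ``180 - alpha31``.
    TDOAs exceeding Lc by up to ``clip_tol_samples`` sample periods are
    clipped to the axis; beyond that the sample is discarded (None).
    """
    tol = clip_tol_samples / fs
    out = []
    for dt in (dt20, dt31):
        if not math.isfinite(dt):
            return None
        if abs(dt) > lc + tol:
            return None
    dt20 = float(np.clip(dt20, -lc, lc))
    dt31 = float(np.clip(dt31, -lc, lc))
    a20 = math.degrees(math.acos(dt20 / lc))
    a31 = math.degrees(math.asin(dt31 / lc))
    return (a20 % 360.0, (360.0 - a20) % 360.0, a31 % 360.0, (180.0 - a31) % 360.0)


def angular_error(tau: float, lc: float, dtau: float) -> float:
    """Propagated angular error of an arccos/arcsin TDOA inversion [rad].

    ``dalpha = dtau / (Lc sqrt(1 - (tau/Lc)^2))``; diverges as |tau| -> Lc
    (pair axis aligned with the source), returning the infinite-error
    sentinel at and beyond the pole.
    """
    if abs(tau) >= lc:
        return INF_ERROR
    return (dtau / lc) / math.sqrt(1.0 - (tau / lc) ** 2)


def _gaussian_mixture(theta_deg: np.ndarray, centers_deg, sigma_deg: float) -> np.ndarray:
    out = np.zeros_like(theta_deg)
    for c in centers_deg:
        d = (theta_deg - c + 180.0) % 360.0 - 180.0
        out += np.exp(-0.5 * (d / sigma_deg) ** 2)
    return out


def resolve_ambiguity(candidates, err20_deg: float, err31_deg: float,
                      grid_step_deg: float = 0.02, sigma_factor: float = 4.0,
                      floor: float = 1e-12):
    """Resolve the left/right mirror ambiguity by probability product.

    Each pair contributes a circular two-Gaussian mixture (real + mirror
    angle) with sigma = ``sigma_factor`` times its propagated angular
    error; the product of the two mixtures is maximized over [0, 360).
    The combined error is the smaller of the two per-pair errors (the
    better-conditioned pair dominates the accuracy).

    Returns ``(alpha_deg, error_deg)`` or None when the product is
    identically negligible (inconsistent pairs).
    """
    if candidates is None:
        return None
    a20, a20m, a31, a31m = candidates
    s20 = max(sigma_factor * err20_deg, 1e-6)
    s31 = max(sigma_factor * err31_deg, 1e-6)
    theta = np.arange(0.0, 360.0, grid_step_deg)
    prod = (_gaussian_mixture(theta, (a20, a20m), min(s20, 1e6)) *
            _gaussian_mixture(theta, (a31, a31m), min(s31, 1e6)))
    k = int(np.argmax(prod))
    if prod[k] < floor:
        return None
    return float(theta[k]), float(min(err20_deg, err31_deg))


def elevation_correction(dt: float, h_pair: float, target_range: float) -> float:
    """Undo the elevation foreshortening of a measured extremal TDOA.

    A surface target at range R seen from a pair at depth h subtends an
    elevation ``beta = arctan(h / R)``; the measured TDOA is shortened by
    ``cos(beta)``, so the corrected value is ``dt / cos(beta)``.  Used in
    calibration where the target range is known; no-op for h = 0 or
    R -> infinity.
    """
    if target_range <= 0:
        raise ValueError("target range must be positive")
    beta = math.atan(abs(h_pair) / target_range)
    return dt / math.cos(beta)


def track_boat(channels: np.ndarray, fs: float, lc: float,
               compass_deg: float = 0.0, psi0: float = 0.0,
               window: float = 0.008, n_sigma: float = 4.0,
               dtau: float | None = None) -> list[BoatBearingSample]:
    """Windowed boat bearings in the world frame (compass convention).

    The body-frame azimuth ``alpha`` grows counter-clockwise from the
    pair-(0,2) axis (body x).  At zero heading the body frame coincides
    with ENU (body x = East, bearing 90 deg), and a heading of
    ``compass + psi0`` rotates the array clockwise, so the compass bearing
    of the target is ``90 + compass + psi0 - alpha``.
    """
    dtau = (1.0 / fs) if dtau is None else dtau
    times, dt20, dt31, _, _ = correlogram_stream(channels, fs, lc, window,
                                                 n_sigma=n_sigma)
    samples = []
    for t, d20, d31 in zip(times, dt20, dt31):
        cand = angles_from_tdoas(d20, d31, lc, fs)
        if cand is None:
            samples.append(BoatBearingSample(t, None, INF_ERROR, gated=True))
            continue
        e20 = math.degrees(angular_error(d20, lc, dtau)) if abs(d20) < lc else 90.0
        e31 = math.degrees(angular_error(d31, lc, dtau)) if abs(d31) < lc else 90.0
        res = resolve_ambiguity(cand, e20, e31)
        if res is None:
            samples.append(BoatBearingSample(t, None, INF_ERROR, gated=True))
            continue
        alpha, err = res
        world = (90.0 + compass_deg + psi0 - alpha) % 360.0
        samples.append(BoatBearingSample(t, world, err, cand[0], cand[2]))
    return samples


def median_bearing_per_second(samples: list[BoatBearingSample]):
    """Per-second circular median-like aggregate of windowed bearings."""
    by_sec: dict[int, list[BoatBearingSample]] = {}
    for s in samples:
        if s.alpha_deg is None:
            continue
        by_sec.setdefault(int(s.time), []).append(s)
    out = []
    for sec in sorted(by_sec):
        group = by_sec[sec]
        ref = group[0].alpha_deg
        unwrapped = [ref + angular_difference(g.alpha_deg, ref) for g in group]
        med = float(np.median(unwrapped)) % 360.0
        err = float(np.median([g.error_deg for g in group]))
        out.append(BoatBearingSample(float(sec), med, err))
    return out
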