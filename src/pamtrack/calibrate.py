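"""On-field calibration: the pair delay ratio L/c and the compass offset.

Two parameters must be measured at sea rather than assumed:

* ``Lc = L / c`` — hydrophone spacing over sound speed, the maximum
  possible TDOA of a pair.  A boat circling the unit at known range R
  produces a sinusoid-like TDOA series on each pair; its extrema occur when
  the boat crosses the pair axis and equal ``Lc cos(beta)`` with
  ``beta = arctan(h / R)`` the pair's elevation angle to the surface
  target.  Averaging the elevation-corrected |extrema| over both pairs and
  all laps estimates Lc.
* ``psi0`` — the fixed offset between the compass indicator and the array
  axes (the turret was mounted after the array was deployed, so the
  mechanical alignment is unknown).  Comparing tracked bearings of the
  circling boat against bearings derived from its GPS track gives psi0 as
  the circular mean of the differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .boat import elevation_correction
from .geometry import angular_difference, circular_mean, circular_std


class CalibrationError(RuntimeError):
    """Raised when a calibration recording cannot constrain the parameter."""


@dataclass
class LcEstimate:
    lc: float
    n_extrema: int
    per_pair: dict


def _extrema(series: np.ndarray, min_separation: int) -> np.ndarray:
    """Indices of local maxima of |series| (maxima and minima of series)."""
    hi, _ = signal.find_peaks(series, distance=min_separation)
    lo, _ = signal.find_peaks(-series, distance=min_separation)
    return np.sort(np.concatenate([hi, lo]))


def estimate_lc(times: np.ndarray, dt20: np.ndarray, dt31: np.ndarray,
                target_range: float, h02: float = -20.0, h13: float = -25.0,
                lowpass_hz: float = 0.05) -> LcEstimate:
    """Recover L/c from the TDOA series of a boat circling at known range.

    Each pair's series is low-pass filtered (default cutoff 0.05 Hz, well
    above the lap frequency but below window-level jitter), its local
    extrema located, each |extremum| corrected for the pair's elevation
    angle, and all corrected extrema averaged.

    Raises :class:`CalibrationError` with fewer than two extrema in total
    (less than a full lap recorded).
    """
    times = np.asarray(times, dtype=float)
    if len(times) < 8:
        raise CalibrationError("TDOA series too short")
    fs = 1.0 / float(np.median(np.diff(times)))
    values = []
    per_pair = {}
    for name, series, h in (("pair02", dt20, h02), ("pair13", dt31, h13)):
        s = np.asarray(series, dtype=float)
        good = np.isfinite(s)
        if good.sum() < 8:
            continue
        s = np.interp(times, times[good], s[good])
        if 0 < lowpass_hz < fs / 2:
            sos = signal.butter(4, lowpass_hz, btype="low", fs=fs, output="sos")
            s = signal.sosfiltfilt(sos, s)
        # extrema of interest are slower than the lowpass cutoff
        min_sep = max(1, int(fs / (4.0 * max(lowpass_hz, 1e-6))))
        idx = _extrema(s, min_sep)
        # drop extrema at the filtered record edges (transient artefacts)
        idx = idx[(idx > 2) & (idx < len(s) - 3)]
        corrected = [abs(elevation_correction(float(s[k]), h, target_range))
                     for k in idx]
        if corrected:
            per_pair[name] = float(np.mean(corrected))
            values.extend(corrected)
    if len(values) < 2:
        raise CalibrationError("fewer than two TDOA extrema found")
    return LcEstimate(lc=float(np.mean(values)), n_extrema=len(values),
                      per_pair=per_pair)


@dataclass
class Psi0Estimate:
    psi0: float
    dispersion: float
    n: int


def gps_bearings(times: np.ndarray, east: np.ndarray, north: np.ndarray,
                 unit_pos) -> np.ndarray:
    """Compass bearing of the boat from the unit at each GPS sample."""
    e = np.asarray(east, dtype=float) - float(unit_pos[0])
    n = np.asarray(north, dtype=float) - float(unit_pos[1])
    return np.degrees(np.arctan2(e, n)) % 360.0


def estimate_psi0(track_times: np.ndarray, tracked_deg: np.ndarray,
                  gps_times: np.ndarray, gps_deg: np.ndarray,
                  match_tol: float = 1.0, max_dispersion: float = 20.0) -> Psi0Estimate:
    """Compass offset: circular mean of (GPS bearing - tracked bearing).

    Tracked bearings must have been computed with psi0 = 0; the recovered
    offset then absorbs any static misalignment (including mean magnetic
    declination).  Samples are matched nearest-in-time within
    ``match_tol`` seconds (GPS rate is 1 Hz).  A circular dispersion above
    ``max_dispersion`` degrees rejects the calibration.
    """
    track_times = np.asarray(track_times, dtype=float)
    tracked = np.asarray(tracked_deg, dtype=float)
    gps_times = np.asarray(gps_times, dtype=float)
    gps = np.asarray(gps_deg, dtype=float)
    diffs = []
    for t, b in zip(track_times, tracked):
        if not math.isfinite(b):
            continue
        k = int(np.argmin(np.abs(gps_times - t)))
        if abs(gps_times[k] - t) > match_tol:
            continue
        diffs.append(angular_difference(gps[k], b))
    if len(diffs) < 4:
        raise CalibrationError("too few matched bearing samples")
    diffs = np.asarray(diffs)
    disp = circular_std(diffs)
    if disp > max_dispersion:
        raise CalibrationError(
            f"bearing-difference dispersion {disp:.1f} deg exceeds {max_dispersion} deg")
    mean = circular_mean(diffs)
    psi0 = mean if mean <= 180.0 else mean - 360.0
    return Psi0Estimate(psi0=float(psi0), dispersion=float(disp), n=len(diffs))
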