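"""Pairwise time-difference-of-arrival measurement by cross-correlation.

TDOAs are measured on the whistle-band bandpassed signals (3-23 kHz by
default, mirroring the analog front-end filter of the acoustic unit), with
sub-sample refinement by parabolic interpolation around the correlation
peak: at 100 kHz sampling and 5 m spacing one sample corresponds to ~3 deg
of bearing, so sub-sample care is required for a 2 deg accuracy target.

Sign convention: the six TDOAs of a set follow the arrival-time convention
``dt_ij = t_i - t_j`` used by the plane-wave model (see geometry module),
so they are directly comparable with ``expected_tdoas``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .geometry import ArrayGeometry, PAIRS, SOUND_SPEED

#: Closure triples (i, j, k): dt_ij + dt_jk = dt_ik must hold.
TRIPLES = ((0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3))

_PAIR_INDEX = {p: k for k, p in enumerate(PAIRS)}


@dataclass
class TdoaSet:
    """Six pairwise TDOAs with consistency metadata."""

    tdoas: np.ndarray              # [s], ordered as geometry.PAIRS
    peaks: np.ndarray              # correlation peak values per pair
    residual: float                # worst closure residual [s]
    valid: bool
    timestamp: float = 0.0

    def tdoa(self, i: int, j: int) -> float:
        if i == j:
            return 0.0
        if (i, j) in _PAIR_INDEX:
            return float(self.tdoas[_PAIR_INDEX[(i, j)]])
        return -float(self.tdoas[_PAIR_INDEX[(j, i)]])


def bandpass(x: np.ndarray, fs: float, band: tuple = (3000.0, 23000.0),
             order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth bandpass (the hardware front-end band)."""
    sos = signal.butter(order, band, btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def cross_correlation_tdoa(x_ref: np.ndarray, x_delayed: np.ndarray, fs: float,
                           max_lag: float) -> tuple[float | None, float]:
    """Delay [s] of the second channel relative to the first.

    The lag of the cross-correlation maximum within ``+-max_lag`` is
    refined to sub-sample precision by fitting a parabola through the peak
    and its two neighbours.  Positive result = second argument arrives
    later.  All-zero input yields ``(None, 0.0)``.
    """
    x = np.asarray(x_ref, dtype=float)
    y = np.asarray(x_delayed, dtype=float)
    if len(x) != len(y):
        raise ValueError("windows must have equal length")
    if not (np.any(x) and np.any(y)):
        return None, 0.0
    max_lag_samples = int(math.ceil(max_lag * fs))
    corr = signal.correlate(y, x, mode="full", method="fft")
    lags = signal.correlation_lags(len(y), len(x), mode="full")
    sel = np.abs(lags) <= max_lag_samples
    corr, lags = corr[sel], lags[sel]
    k = int(np.argmax(corr))
    # tie between equal peaks: smallest |lag| wins
    ties = np.flatnonzero(corr == corr[k])
    if len(ties) > 1:
        k = int(ties[np.argmin(np.abs(lags[ties]))])
    peak = float(corr[k])
    lag = float(lags[k])
    if 0 < k < len(corr) - 1:
        c0, c1, c2 = corr[k - 1], corr[k], corr[k + 1]
        denom = c0 - 2.0 * c1 + c2
        if denom != 0:
            lag += 0.5 * (c0 - c2) / denom
    return lag / fs, peak


def adaptive_peak_gate(corr: np.ndarray, n_sigma: float = 4.0) -> float:
    """Keep the correlation peak only if it stands above the window noise.

    Returns the peak value if ``peak > n_sigma * std(corr)``, else 0.  With
    ``n_sigma = 0`` the peak always survives.
    """
    corr = np.asarray(corr, dtype=float)
    if corr.size == 0:
        raise ValueError("empty correlation window")
    peak = float(np.max(np.abs(corr)))
    if n_sigma <= 0:
        return peak
    sigma = float(np.std(corr))
    return peak if peak > n_sigma * sigma else 0.0


def _pair_candidates(x_ref: np.ndarray, x_delayed: np.ndarray, fs: float,
                     max_lag: float, k_top: int = 13):
    """Top local correlation maxima of a pair as (lags [s], peak values).

    Near-periodic signals (a flat whistle is almost a pure tone) produce a
    comb of correlation peaks one carrier cycle apart; keeping the top few
    lets the closure identities select the consistent combination.
    """
    x = np.asarray(x_ref, dtype=float)
    y = np.asarray(x_delayed, dtype=float)
    if not (np.any(x) and np.any(y)):
        return None
    max_lag_samples = int(math.ceil(max_lag * fs))
    corr = signal.correlate(y, x, mode="full", method="fft")
    lags = signal.correlation_lags(len(y), len(x), mode="full")
    sel = np.abs(lags) <= max_lag_samples
    corr, lags = corr[sel], lags[sel]
    pk, _ = signal.find_peaks(corr)
    if len(pk) == 0:
        pk = np.array([int(np.argmax(corr))])
    top = pk[np.argsort(corr[pk])[::-1][:k_top]]
    out_lags, out_vals = [], []
    for k in top:
        lag = float(lags[k])
        if 0 < k < len(corr) - 1:
            c0, c1, c2 = corr[k - 1], corr[k], corr[k + 1]
            denom = c0 - 2.0 * c1 + c2
            if denom != 0:
                lag += 0.5 * (c0 - c2) / denom
        out_lags.append(lag / fs)
        out_vals.append(float(corr[k]))
    return np.array(out_lags), np.array(out_vals)


def tdoa_set(channels: np.ndarray, fs: float, geometry: ArrayGeometry | None = None,
             c: float = SOUND_SPEED, band: tuple = (3000.0, 23000.0),
             max_lag: float | None = None, residual_tol_samples: float = 2.0,
             timestamp: float = 0.0, prefiltered: bool = False) -> TdoaSet:
    """Measure all six TDOAs of a synchronized 4-channel window.

    The primary estimate per pair is the global correlation maximum.  When
    the resulting set violates the closure identities (e.g.
    ``dt01 + dt12 = dt02``) — typical for near-periodic tonal signals,
    whose correlation peaks repeat every carrier cycle — the redundancy of
    the six pairs is used to disambiguate: candidate peak combinations of
    the three contiguous pairs are enumerated and the combination whose
    implied derived TDOAs land on candidate peaks of the other three pairs
    with the highest total correlation wins.

    The set is flagged invalid if any pair yields no defined TDOA or if
    the worst closure residual still exceeds ``residual_tol_samples``
    sample periods.
    """
    geometry = geometry or ArrayGeometry.default()
    if max_lag is None:
        max_lag = geometry.max_delay / c + 2.0 / fs
    x = np.asarray(channels, dtype=float)
    if x.ndim != 2 or x.shape[0] != 4:
        raise ValueError("need a (4, N) channel array")
    if not prefiltered:
        x = np.stack([bandpass(ch, fs, band) for ch in x])

    cands = {}
    for (i, j) in PAIRS:
        # dt_ij = t_i - t_j: delay of channel i relative to channel j
        cands[(i, j)] = _pair_candidates(x[j], x[i], fs, max_lag)
    if any(v is None for v in cands.values()):
        return TdoaSet(tdoas=np.full(6, np.nan), peaks=np.zeros(6),
                       residual=math.inf, valid=False, timestamp=timestamp)

    tdoas = np.array([cands[p][0][0] for p in PAIRS])
    peaks = np.array([cands[p][1][0] for p in PAIRS])
    residual = _worst_closure(tdoas)
    tol = residual_tol_samples / fs

    if residual > tol or _plane_wave_g(tdoas, geometry, c) > 6 * tol**2:
        best = _disambiguate(cands, tol, geometry, c)
        if best is not None:
            tdoas, peaks = best
            residual = _worst_closure(tdoas)

    return TdoaSet(tdoas=tdoas, peaks=peaks, residual=residual,
                   valid=residual <= tol, timestamp=timestamp)


def _worst_closure(tdoas: np.ndarray) -> float:
    worst = 0.0
    for i, j, k in TRIPLES:
        worst = max(worst, abs(_get(tdoas, i, j) + _get(tdoas, j, k)
                               - _get(tdoas, i, k)))
    return worst


_BASE_PAIRS = ((0, 1), (1, 2), (2, 3))
_DERIVED = {  # derived pair -> base-pair coefficient triple
    (0, 2): (1, 1, 0),   # dt02 = dt01 + dt12
    (1, 3): (0, 1, 1),   # dt13 = dt12 + dt23
    (0, 3): (1, 1, 1),   # dt03 = dt01 + dt12 + dt23
}


def _plane_wave_g(tdoas: np.ndarray, geometry: ArrayGeometry, c: float) -> float:
    """Residual of the best-fit plane wave explaining all six TDOAs [s^2].

    The direction is solved in closed form from the contiguous pairs and
    renormalized; the summed squared TDOA misfit over all six pairs
    measures physical (not just closure) consistency, which separates the
    true peak combination from narrowband grating-lobe combinations.
    """
    p = geometry.positions
    A = np.array([p[i] - p[j] for i, j in _BASE_PAIRS])
    b = np.array([c * _get(tdoas, i, j) for i, j in _BASE_PAIRS])
    try:
        uvw = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:  # pragma: no cover
        return math.inf
    norm = np.linalg.norm(uvw)
    if norm == 0:
        return math.inf
    n_hat = uvw / norm
    dh = np.array([p[i] - p[j] for i, j in PAIRS])
    theo = dh @ n_hat / c
    return float(np.sum((tdoas - theo) ** 2))


def _disambiguate(cands: dict, tol: float, geometry: ArrayGeometry, c: float):
    """Closure- and plane-wave-consistent candidate selection.

    Enumerates candidate peaks of the three contiguous pairs, requires the
    implied derived TDOAs to land on candidate peaks of the remaining
    pairs, and among surviving combinations minimizes the plane-wave
    residual (correlation total as tie-break).
    """
    base = [cands[p] for p in _BASE_PAIRS]
    best_key, best = None, None
    for a, va in zip(*base[0]):
        for b, vb in zip(*base[1]):
            for d, vd in zip(*base[2]):
                tdoas = dict(zip(_BASE_PAIRS, (a, b, d)))
                vals = dict(zip(_BASE_PAIRS, (va, vb, vd)))
                ok = True
                for pair, coefs in _DERIVED.items():
                    implied = coefs[0] * a + coefs[1] * b + coefs[2] * d
                    lags, pv = cands[pair]
                    k = int(np.argmin(np.abs(lags - implied)))
                    if abs(lags[k] - implied) > tol:
                        ok = False
                        break
                    tdoas[pair] = lags[k]
                    vals[pair] = pv[k]
                if not ok:
                    continue
                arr = np.array([tdoas[p] for p in PAIRS])
                g = _plane_wave_g(arr, geometry, c)
                key = (round(g / tol**2, 1), -sum(vals.values()))
                if best_key is None or key < best_key:
                    best_key = key
                    best = (arr, np.array([vals[p] for p in PAIRS]))
    return best


def _get(tdoas: np.ndarray, i: int, j: int) -> float:
    if (i, j) in _PAIR_INDEX:
        return float(tdoas[_PAIR_INDEX[(i, j)]])
    return -float(tdoas[_PAIR_INDEX[(j, i)]])


def pair_tdoa_gated(x_i: np.ndarray, x_j: np.ndarray, fs: float, max_lag: float,
                    n_sigma: float = 4.0) -> tuple[float | None, float]:
    """TDOA ``t_i - t_j`` for one pair with the adaptive peak gate applied.

    Returns ``(None, 0.0)`` when the correlation peak does not rise
    ``n_sigma`` standard deviations above the correlation window.
    """
    x = np.asarray(x_j, dtype=float)
    y = np.asarray(x_i, dtype=float)
    if not (np.any(x) and np.any(y)):
        return None, 0.0
    max_lag_samples = int(math.ceil(max_lag * fs))
    corr = signal.correlate(y, x, mode="full", method="fft")
    lags = signal.correlation_lags(len(y), len(x), mode="full")
    sel = np.abs(lags) <= max_lag_samples
    corr, lags = corr[sel], lags[sel]
    gated = adaptive_peak_gate(corr, n_sigma)
    if gated == 0.0:
        return None, 0.0
    k = int(np.argmax(corr))
    lag = float(lags[k])
    if 0 < k < len(corr) - 1:
        c0, c1, c2 = corr[k - 1], corr[k], corr[k + 1]
        denom = c0 - 2.0 * c1 + c2
        if denom != 0:
            lag += 0.5 * (c0 - c2) / denom
    return lag / fs, float(corr[k])
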