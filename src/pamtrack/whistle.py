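"""Whistle detection on single-channel spectrograms.

Pipeline: short-time spectrogram (1024-point FFT, Hann window, 75 %
overlap) -> click suppression by the negative second derivative of each
spectrum column -> per-column frequency track M(i) of the sharpest tonal
peak in the 5-15 kHz band -> a linearity detection function W(m) built
from the smoothness of the first derivative of M -> thresholding and run
merging into candidate events -> robust slope / duration measurement and a
slope-duration gate that rejects the dominant false positives (mooring
cable screech, which mimics a flat whistle, and small-boat tonals).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

try:  # point-in-polygon for the slope/duration gate
    from shapely.geometry import Point, Polygon
    _HAVE_SHAPELY = True
except Exception:  # pragma: no cover
    _HAVE_SHAPELY = False


@dataclass(frozen=True)
class SpectrogramParams:
    nfft: int = 1024
    overlap: float = 0.75
    fs: float = 100000.0
    window: str = "hann"

    def __post_init__(self) -> None:
        if not (0 <= self.overlap < 1):
            raise ValueError("overlap must lie in [0, 1)")
        if self.nfft & (self.nfft - 1):
            raise ValueError("FFT size must be a power of two")

    @property
    def hop(self) -> int:
        return int(self.nfft * (1.0 - self.overlap))

    @property
    def df(self) -> float:
        return self.fs / self.nfft


@dataclass
class Spectrogram:
    times: np.ndarray
    freqs: np.ndarray
    power: np.ndarray  # (n_freqs, n_times)
    params: SpectrogramParams


@dataclass
class WhistleDetection:
    """One candidate whistle event."""

    start: float
    end: float
    peak_time: float
    peak_freq: float
    slope: float = math.nan        # Hz/s
    duration: float = math.nan     # s, from the contour run
    w_peak: float = 0.0
    accepted: bool = True
    truncated: bool = False
    channel: int = 0

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("event end before start")


@dataclass
class DetectorConfig:
    """Tunable detector parameters (all exposed in the config file).

    ``l_threshold_bins`` is the tolerated jump of the track first
    derivative in frequency bins, ``window_p`` the linearity window length
    P, ``w_threshold`` the boolean threshold on W (default 0.8^2: at most
    two violations inside the window).
    """

    band: tuple = (5000.0, 15000.0)
    l_threshold_bins: float = 2.0
    window_p: int = 10
    w_low: float = 0.8
    w_threshold: float = 0.8 ** 2
    min_event_columns: int = 3
    slope_window: int = 40
    equalize: bool = False
    gate: "GateConfig" = None  # filled in __post_init__

    def __post_init__(self) -> None:
        if self.gate is None:
            self.gate = GateConfig()


def compute_spectrogram(waveform: np.ndarray, params: SpectrogramParams | None = None) -> Spectrogram:
    """Magnitude-squared spectrogram with the detector's standard framing."""
    params = params or SpectrogramParams()
    x = np.asarray(waveform, dtype=float)
    if len(x) < params.nfft:
        raise ValueError("waveform shorter than one FFT frame")
    freqs, times, power = signal.spectrogram(
        x,
        fs=params.fs,
        window=params.window,
        nperseg=params.nfft,
        noverlap=params.nfft - params.hop,
        mode="psd",
        detrend=False,
    )
    return Spectrogram(times=times, freqs=freqs, power=power, params=params)


def equalize_spectrogram(spec: Spectrogram) -> Spectrogram:
    """Optional per-bin median normalization (flattens stationary noise)."""
    med = np.median(spec.power, axis=1, keepdims=True)
    med[med == 0] = 1.0
    return Spectrogram(spec.times, spec.freqs, spec.power / med, spec.params)


def click_suppress(spec: Spectrogram, band: tuple = (5000.0, 15000.0)) -> tuple[np.ndarray, np.ndarray]:
    """Per-column tonal-peak frequency track after click suppression.

    The sharpness indicator ``D_i(f) = 2 P_i(f) - (P_i(f-df) + P_i(f+df))``
    peaks on narrow-band ridges and stays low for broadband clicks; the
    argmax frequency of D in the band is the track M(i).

    Returns ``(M_hz, M_bins)``: the track in Hz and in band-relative bin
    indices.
    """
    lo, hi = band
    sel = (spec.freqs >= lo) & (spec.freqs <= hi)
    if not np.any(sel):
        raise ValueError("band outside the spectrogram range")
    p = spec.power
    d = 2.0 * p - (np.roll(p, 1, axis=0) + np.roll(p, -1, axis=0))
    d = d[sel, :]
    bins = np.argmax(d, axis=0)
    freqs_band = spec.freqs[sel]
    return freqs_band[bins], bins


def detection_function(m_bins: np.ndarray, p: int = 10, threshold: float = 2.0,
                       w_low: float = 0.8) -> tuple[np.ndarray, np.ndarray]:
    """Linearity detection function W(m) over the frequency track.

    ``M'(k) = M(k+2) - M(k)``; ``L(j)`` is the difference of consecutive
    M' values; each of the P window positions contributes 1 if
    ``|L| <= threshold`` else ``w_low``; W is their product, hence bounded
    in ``[w_low**P, 1]``.

    Returns ``(W, centers)`` where ``centers[m]`` is the track index at the
    middle of window m (for time stamping).
    """
    m_arr = np.asarray(m_bins, dtype=float)
    if len(m_arr) < p + 3:
        raise ValueError("track shorter than the linearity window")
    mp = m_arr[2:] - m_arr[:-2]          # M'(k), k = 0 .. N-3
    dl = np.abs(np.diff(mp))             # |L|, length N-3
    viol = (dl > threshold).astype(float)
    counts = np.convolve(viol, np.ones(p), mode="valid")
    w = w_low ** counts
    centers = np.arange(len(w)) + (p + 3) // 2
    return w, centers


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as (start, stop) index pairs (stop exclusive)."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(idx[0::2], idx[1::2]))


def threshold_events(w: np.ndarray, centers: np.ndarray, times: np.ndarray,
                     w_threshold: float, min_columns: int = 3) -> list[dict]:
    """Boolean detection: W >= threshold, contiguous runs merged to events."""
    mask = w >= w_threshold
    events = []
    for a, b in _runs(mask):
        if b - a < min_columns:
            continue
        # ties at the maximum (e.g. W = 1 throughout) centre on the run
        at_max = a + np.flatnonzero(w[a:b] == np.max(w[a:b]))
        peak_m = int(at_max[len(at_max) // 2])
        events.append(
            {
                "start_col": int(centers[a]),
                "end_col": int(centers[b - 1]),
                "peak_col": int(centers[peak_m]),
                "w_peak": float(w[peak_m]),
                "start": float(times[centers[a]]),
                "end": float(times[centers[b - 1]]),
                "peak_time": float(times[centers[peak_m]]),
            }
        )
    return events


def measure_slope_duration(peak_col: int, m_hz: np.ndarray, times: np.ndarray,
                           window: int = 40, deviation: float = 0.25,
                           sigma_clip: float = 3.0) -> tuple[float, float, bool]:
    """Robust frequency slope [Hz/s] and contour duration [s] of an event.

    Slope: bisquare (Tukey) iteratively-reweighted linear fit of the track
    over ``window`` columns centred on the detection-function peak, after
    excluding samples beyond ``sigma_clip`` standard deviations of the
    initial least-squares residual.  Duration: extent of the maximal run of
    consecutive track samples within ``deviation`` (fractional) of the
    frequency at the peak, containing the peak.

    Returns ``(slope, duration, truncated)`` where ``truncated`` flags a
    window clipped at the record edge.
    """
    n = len(m_hz)
    half = window // 2
    a = max(0, peak_col - half)
    b = min(n, peak_col + half)
    truncated = (b - a) < window
    t = times[a:b] - times[peak_col]
    y = m_hz[a:b]

    slope = _bisquare_slope(t, y, sigma_clip)

    f_peak = m_hz[peak_col]
    within = np.abs(m_hz - f_peak) <= deviation * f_peak
    lo = peak_col
    while lo > 0 and within[lo - 1]:
        lo -= 1
    hi = peak_col
    while hi < n - 1 and within[hi + 1]:
        hi += 1
    hop_dt = float(times[1] - times[0]) if len(times) > 1 else 0.0
    duration = (hi - lo + 1) * hop_dt
    return float(slope), float(duration), truncated


def _bisquare_slope(t: np.ndarray, y: np.ndarray, sigma_clip: float,
                    iters: int = 10) -> float:
    """Tukey-bisquare IRLS slope of y vs t with 3-sigma pre-clipping."""
    if len(t) < 3:
        return math.nan
    coef = np.polyfit(t, y, 1)
    resid = y - np.polyval(coef, t)
    sd = np.std(resid)
    keep = np.abs(resid) <= sigma_clip * sd if sd > 0 else np.ones_like(resid, bool)
    if keep.sum() < 3:
        keep = np.ones_like(resid, bool)
    t, y = t[keep], y[keep]
    w = np.ones_like(y)
    for _ in range(iters):
        sw = np.sqrt(w)
        A = np.stack([t * sw, sw], axis=1)
        coef, *_ = np.linalg.lstsq(A, y * sw, rcond=None)
        r = y - (coef[0] * t + coef[1])
        s = np.median(np.abs(r)) / 0.6745 or np.std(r) or 1.0
        u = r / (4.685 * s)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        if w.sum() < 3:
            break
    return float(coef[0])


@dataclass
class GateConfig:
    """Slope/duration acceptance region.

    ``polygon`` is a list of (duration s, slope Hz/s) vertices; a detection
    is accepted iff its point lies inside.  The default region covers the
    whistle population produced by the scene simulator (durations 0.05 to
    1.5 s, |slope| up to 60 kHz/s) and carves out the near-zero-slope,
    long-duration corner where mooring-cable screech lands.  ``enabled``
    False passes everything through.
    """

    enabled: bool = True
    polygon: list = field(default_factory=lambda: [
        (0.05, 800.0), (0.05, 60000.0), (1.5, 60000.0), (1.5, 800.0),
        (1.2, 800.0), (1.2, -800.0), (1.5, -800.0), (1.5, -60000.0),
        (0.05, -60000.0), (0.05, -800.0),
    ])


def false_positive_gate(slope: float, duration: float,
                        gate: GateConfig | None = None) -> bool:
    """Accept a detection iff (duration, slope) falls in the whistle region."""
    gate = gate or GateConfig()
    if not gate.enabled:
        return True
    if not (math.isfinite(slope) and math.isfinite(duration)):
        return False
    if _HAVE_SHAPELY:
        return Polygon(gate.polygon).covers(Point(duration, slope))
    return _point_in_polygon(duration, slope, gate.polygon)  # pragma: no cover


def _point_in_polygon(x: float, y: float, poly: list) -> bool:  # pragma: no cover
    inside = False
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        if (y1 > y) != (y2 > y) and x < (x2 - x1) * (y - y1) / (y2 - y1) + x1:
            inside = not inside
    return inside


def detect_whistles(waveform: np.ndarray, config: DetectorConfig | None = None,
                    params: SpectrogramParams | None = None,
                    channel: int = 0) -> list[WhistleDetection]:
    """Full single-channel detection pipeline."""
    config = config or DetectorConfig()
    params = params or SpectrogramParams()
    spec = compute_spectrogram(waveform, params)
    if config.equalize:
        spec = equalize_spectrogram(spec)
    m_hz, m_bins = click_suppress(spec, config.band)
    if len(m_bins) < config.window_p + 3:
        return []
    w, centers = detection_function(m_bins, config.window_p,
                                    config.l_threshold_bins, config.w_low)
    raw = threshold_events(w, centers, spec.times, config.w_threshold,
                           config.min_event_columns)
    out = []
    for ev in raw:
        slope, duration, truncated = measure_slope_duration(
            ev["peak_col"], m_hz, spec.times, config.slope_window)
        accepted = false_positive_gate(slope, duration, config.gate)
        out.append(WhistleDetection(
            start=ev["start"], end=ev["end"], peak_time=ev["peak_time"],
            peak_freq=float(m_hz[ev["peak_col"]]), slope=slope,
            duration=duration, w_peak=ev["w_peak"], accepted=accepted,
            truncated=truncated, channel=channel,
        ))
    return out


def detect_multichannel(audio: np.ndarray, config: DetectorConfig | None = None,
                        params: SpectrogramParams | None = None) -> list[WhistleDetection]:
    """Run the detector per channel and fuse overlapping events.

    An event is reported once, from the channel with the highest detection
    function peak among channels seeing it at overlapping times.
    """
    per_ch: list[WhistleDetection] = []
    for ch in range(audio.shape[0]):
        per_ch.extend(detect_whistles(audio[ch], config, params, channel=ch))
    per_ch.sort(key=lambda d: d.start)
    fused: list[WhistleDetection] = []
    for det in per_ch:
        merged = False
        for k, kept in enumerate(fused):
            if det.start <= kept.end and kept.start <= det.end:
                if det.w_peak > kept.w_peak:
                    fused[k] = det
                merged = True
                break
        if not merged:
            fused.append(det)
    return fused
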