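"""Passive sonar budget, ambient-noise band levels and radio-link planning.

The passive sonar equation budgets the received signal-to-noise ratio

    L_SN(r) = SL - (TL(r) + NL + BW)

against a detection threshold DT: a whistle of source level SL [dB re 1 uPa
@ 1 m] is detectable at range r while ``L_SN(r) >= DT``.  Transmission loss
is ``TL(r) = k log10(r) + alpha * r`` (spreading + absorption), the ambient
noise NL comes from Wenz-curve spectral levels integrated over the signal
band, and DT follows from the detection index d read off ROC curves for the
chosen detection / false-alarm probabilities.

The radio-link helpers size the shore link of an offshore unit: geometric
radio horizon, first Fresnel-zone radius, free-space path loss and the raw
acoustic stream bandwidth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.optimize import brentq

#: Sentinel returned by :func:`detection_range` when the budget never closes.
UNDETECTABLE = None


@dataclass(frozen=True)
class SonarParams:
    """Inputs of the passive sonar budget.

    Defaults are the coastal-dolphin design point: 160 dB whistle in the
    5-15 kHz band, spherical spreading (k = 20), 0.72 dB/km absorption at
    the band centroid, 100 kHz sampling, detection index d = 9 and a 5 dB
    safety detection threshold.
    """

    source_level: float = 160.0
    f_min: float = 5000.0
    f_max: float = 15000.0
    spreading_k: float = 20.0
    absorption_db_km: float = 0.72
    detection_threshold_db: float = 5.0
    f_sampl: float = 100000.0
    detection_index: float = 9.0

    def __post_init__(self) -> None:
        if not (self.f_max > self.f_min > 0):
            raise ValueError("need f_max > f_min > 0")
        if self.spreading_k <= 0 or self.absorption_db_km < 0:
            raise ValueError("invalid spreading/absorption")


@dataclass(frozen=True)
class NoiseModel:
    """Wenz ambient-noise spectral levels as a small editable table.

    ``table[sea_state][freq_hz]`` holds spectral density levels
    [dB re 1 uPa / sqrt(Hz)].  The table is configuration data because the
    published values are read off curves; only the two levels at the band
    centroid are canonical.  ``wideband_offset`` is an additive measured
    correction [dB] applied uniformly (e.g. a site survey finding the sea
    a few dB noisier than the canonical curves).
    """

    table: dict = field(default_factory=lambda: {0: {8660.0: 29.0}, 4: {8660.0: 48.0}})
    wideband_offset: float = 0.0

    def spectral_level(self, f_hz: float, sea_state: int) -> float:
        """Spectral level at ``f_hz`` (log-frequency interpolation)."""
        if sea_state not in self.table:
            raise KeyError(f"no noise entry for sea state {sea_state}")
        entries = sorted(self.table[sea_state].items())
        freqs = [math.log10(f) for f, _ in entries]
        lvls = [l for _, l in entries]
        x = math.log10(f_hz)
        if x <= freqs[0]:
            lvl = lvls[0]
        elif x >= freqs[-1]:
            lvl = lvls[-1]
        else:
            for k in range(len(freqs) - 1):
                if freqs[k] <= x <= freqs[k + 1]:
                    t = (x - freqs[k]) / (freqs[k + 1] - freqs[k])
                    lvl = lvls[k] + t * (lvls[k + 1] - lvls[k])
                    break
        return lvl + self.wideband_offset

    def band_level(self, sea_state: int, f_min: float, f_max: float) -> float:
        """Band-integrated noise level in [f_min, f_max] (flat-band)."""
        fc = band_centroid(f_min, f_max)
        return band_noise_level(self.spectral_level(fc, sea_state), f_min, f_max)


def band_centroid(f_min: float, f_max: float) -> float:
    """Geometric-mean centroid of a frequency band [Hz]."""
    if f_min <= 0 or f_max < f_min:
        raise ValueError("need f_max >= f_min > 0")
    return math.sqrt(f_min * f_max)


def snr0(detection_index: float, f_sampl: float, f_max: float) -> float:
    """Required per-sample SNR ``S/N0 = d / m`` with ``m = f_sampl / f_max``."""
    if detection_index <= 0:
        raise ValueError("detection index must be positive")
    m = f_sampl / f_max
    if m <= 0:
        raise ValueError("sample ratio m must be positive")
    return detection_index / m


def detection_threshold(detection_index: float, f_sampl: float, f_max: float) -> float:
    """Detection threshold DT = 10 log10(d/m) [dB]."""
    return 10.0 * math.log10(snr0(detection_index, f_sampl, f_max))


def transmission_loss(r: float, k: float = 20.0, alpha_db_km: float = 0.72) -> float:
    """One-way transmission loss TL(r) = k log10(r) + alpha r [dB], r in m.

    Undefined below the 1 m reference distance.
    """
    if r < 1.0:
        raise ValueError("transmission loss undefined below the 1 m reference")
    return k * math.log10(r) + alpha_db_km * (r / 1000.0)


def band_noise_level(spectral_level_db: float, f_min: float, f_max: float) -> float:
    """Band level = spectral level + 10 log10(bandwidth) [dB]."""
    b = f_max - f_min
    if b <= 0:
        raise ValueError("empty frequency band")
    return spectral_level_db + 10.0 * math.log10(b)


def detection_range(params: SonarParams, nl_band: float,
                    r_max: float = 100000.0, tol: float = 0.1):
    """Maximum detection range [m]: root of SL - TL(r) - NL = DT.

    TL is strictly increasing in r so the root is unique; solved by a
    bracketed search on [1 m, ``r_max``] to ``tol`` metres.  Returns
    :data:`UNDETECTABLE` (None) when the budget is negative already at the
    1 m reference, and ``r_max`` when it never closes within the bracket.
    """
    budget = params.source_level - nl_band - params.detection_threshold_db

    def excess(r: float) -> float:
        return budget - transmission_loss(r, params.spreading_k, params.absorption_db_km)

    if budget < 0:
        return UNDETECTABLE
    if budget == 0:
        return 1.0
    if excess(r_max) > 0:
        return r_max
    return float(brentq(excess, 1.0, r_max, xtol=tol))


# --- radio-link planning -------------------------------------------------

def radio_horizon(h_m: float, earth_radius_km: float = 6371.0) -> float:
    """Geometric line-of-sight horizon D = sqrt(2 R h) [km] for antenna
    height ``h_m`` metres (h << R approximation)."""
    if h_m < 0:
        raise ValueError("antenna height must be non-negative")
    return math.sqrt(2.0 * earth_radius_km * (h_m / 1000.0))


def fresnel_radius(d1_km: float, d2_km: float, f_ghz: float, d_km: float) -> float:
    """First Fresnel-zone radius r = 17.31 sqrt(d1 d2 / (f d)) [m]."""
    if f_ghz <= 0:
        raise ValueError("frequency must be positive")
    if d1_km < 0 or d2_km < 0 or d_km <= 0:
        raise ValueError("distances must be positive")
    return 17.31 * math.sqrt(d1_km * d2_km / (f_ghz * d_km))


def free_space_loss(d_km: float, f_mhz: float) -> float:
    """Free-space path loss L_FS = 32.45 + 20 log D + 20 log f [dB]."""
    if d_km < 0.001:
        raise ValueError("distance below 1 m")
    return 32.45 + 20.0 * math.log10(d_km) + 20.0 * math.log10(f_mhz)


def link_budget(p_tx_dbm: float, cable_loss_tx: float, g_tx: float,
                l_fs: float, g_rx: float, cable_loss_rx: float) -> float:
    """Received power P_RX = P_TX - C_LS + G_TX - L_FS + G_RX - C_LS [dBm]."""
    return p_tx_dbm - cable_loss_tx + g_tx - l_fs + g_rx - cable_loss_rx


def link_margin(p_rx_dbm: float, rx_sensitivity_dbm: float) -> float:
    """Margin of the link above the receiver sensitivity [dB]."""
    return p_rx_dbm - rx_sensitivity_dbm


def min_stream_bandwidth(f_sampl: float, n_channels: int, bits: int) -> float:
    """Raw acoustic stream rate f_sampl * channels * bits [bit/s]."""
    if f_sampl <= 0 or n_channels <= 0 or bits <= 0:
        raise ValueError("all factors must be positive")
    return float(f_sampl) * n_channels * bits
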