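"""File I/O: 4-channel PCM WAV, attitude/GPS CSV logs, JSON lines.

Audio is exchanged as RIFF WAV, PCM 16-bit, 100 kHz, 4 channels; the
mapping between pressure [uPa] and digital full scale is a configurable
``full_scale_db`` (dB re 1 uPa of a full-scale peak), default 135 dB so
that a 160 dB whistle received at ~1 km sits well above both the sea-state
0 noise floor and the quantization floor.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

DEFAULT_FULL_SCALE_DB = 135.0


def pressure_to_int16(audio: np.ndarray, full_scale_db: float = DEFAULT_FULL_SCALE_DB) -> np.ndarray:
    """Map pressure [uPa] to int16 counts, clipping at full scale."""
    fs_pa = 10.0 ** (full_scale_db / 20.0)
    scaled = np.clip(np.asarray(audio, dtype=float) / fs_pa, -1.0, 1.0)
    return np.round(scaled * 32767.0).astype(np.int16)


def int16_to_pressure(counts: np.ndarray, full_scale_db: float = DEFAULT_FULL_SCALE_DB) -> np.ndarray:
    fs_pa = 10.0 ** (full_scale_db / 20.0)
    return np.asarray(counts, dtype=float) / 32767.0 * fs_pa


def write_wav(path, audio: np.ndarray, fs: float,
              full_scale_db: float = DEFAULT_FULL_SCALE_DB) -> None:
    """Write (n_channels, N) pressure audio as 16-bit PCM WAV."""
    data = pressure_to_int16(audio, full_scale_db)
    if data.ndim == 2:
        data = data.T  # scipy expects (N, channels)
    wavfile.write(str(path), int(fs), data)


def read_wav(path, full_scale_db: float = DEFAULT_FULL_SCALE_DB):
    """Read a PCM WAV back to (n_channels, N) pressure and sample rate."""
    fs, data = wavfile.read(str(path))
    if data.ndim == 1:
        data = data[:, None]
    audio = int16_to_pressure(data.T, full_scale_db)
    return audio, float(fs)


def write_attitude_csv(path, log: pd.DataFrame) -> None:
    """Attitude log with header timestamp,pitch_deg,roll_deg,compass_deg."""
    cols = ["timestamp", "pitch_deg", "roll_deg", "compass_deg"]
    log[cols].to_csv(str(path), index=False)


def read_attitude_csv(path) -> pd.DataFrame:
    df = pd.read_csv(str(path))
    if "timestamp" in df and df["timestamp"].dtype == object:
        df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True).astype(np.int64) / 1e9
    return df


def read_gps_csv(path) -> pd.DataFrame:
    """GPS track CSV with header timestamp,lat,lon."""
    df = pd.read_csv(str(path))
    if df["timestamp"].dtype == object:
        df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True).astype(np.int64) / 1e9
    return df


def write_jsonl(path, records: list) -> None:
    with open(str(path), "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec, default=_default) + "\n")


def read_jsonl(path) -> list:
    out = []
    with open(str(path)) as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(json.loads(line))
    return out


def _default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    return str(o)


def detections_to_frame(detections: list) -> pd.DataFrame:
    """Whistle detections as a CSV-ready table (one row per event)."""
    rows = [
        {
            "start_s": d.start,
            "end_s": d.end,
            "peak_time_s": d.peak_time,
            "peak_freq_hz": d.peak_freq,
            "slope_hz_per_s": d.slope,
            "duration_s": d.duration,
            "w_peak": d.w_peak,
            "accepted": d.accepted,
            "channel": d.channel,
        }
        for d in detections
    ]
    return pd.DataFrame(rows)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
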