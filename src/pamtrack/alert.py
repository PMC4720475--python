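"""Sector-based alarm state machine and detection reports.

The study area is divided into a small number of rectangular sectors
(five of ~2 km side in the reference deployment).  Each sector carries a
colour state: green (no dolphins), yellow (dolphins detected within the
hold time), red (dolphins and boats simultaneously present).  Red takes
precedence over yellow over green; every transition is timestamped and
logged, and replaying the same event log reproduces the same history.
"""

from __future__ import annotations

import base64
import io as _io
import json
import math
from dataclasses import dataclass, field

import numpy as np

GREEN, YELLOW, RED = "green", "yellow", "red"
OUTSIDE = "outside"


@dataclass(frozen=True)
class Sector:
    """Axis-aligned rectangle in local ENU metres."""

    id: str
    east_min: float
    east_max: float
    north_min: float
    north_max: float

    def contains(self, east: float, north: float) -> bool:
        return (self.east_min <= east <= self.east_max
                and self.north_min <= north <= self.north_max)


def default_grid(side: float = 2000.0, n: int = 5, origin=(-5000.0, 0.0)) -> list[Sector]:
    """A documented example layout: a row of n square sectors along shore."""
    e0, n0 = origin
    return [Sector(str(k + 1), e0 + k * side, e0 + (k + 1) * side, n0, n0 + side)
            for k in range(n)]


@dataclass
class SectorGrid:
    sectors: list = field(default_factory=default_grid)

    def assign_position(self, east: float, north: float) -> str:
        for s in self.sectors:
            if s.contains(east, north):
                return s.id
        return OUTSIDE

    def assign_bearing(self, unit_pos, bearing_deg: float,
                       max_range: float = 3700.0) -> list[str]:
        """Sectors intersected by a bearing ray within detection range.

        For a bearing-only detection (no triangulation) the dolphin may be
        anywhere along the ray out to the unit's detection range.
        """
        e0, n0 = float(unit_pos[0]), float(unit_pos[1])
        de = math.sin(math.radians(bearing_deg))
        dn = math.cos(math.radians(bearing_deg))
        hits = []
        for s in self.sectors:
            if _ray_hits_rect(e0, n0, de, dn, s, max_range):
                hits.append(s.id)
        return hits


def _ray_hits_rect(e0, n0, de, dn, s: Sector, max_range: float) -> bool:
    """Slab test of the ray segment [0, max_range] against the rectangle."""
    t0, t1 = 0.0, max_range
    for p, d, lo, hi in ((e0, de, s.east_min, s.east_max),
                         (n0, dn, s.north_min, s.north_max)):
        if abs(d) < 1e-12:
            if not (lo <= p <= hi):
                return False
            continue
        ta, tb = (lo - p) / d, (hi - p) / d
        if ta > tb:
            ta, tb = tb, ta
        t0, t1 = max(t0, ta), min(t1, tb)
        if t0 > t1:
            return False
    return True


def assign_sector(grid: SectorGrid, position=None, unit_pos=None,
                  bearing_deg=None, max_range: float = 3700.0):
    """Sector id(s) for a fix or a bearing-only detection."""
    if position is not None:
        return grid.assign_position(float(position[0]), float(position[1]))
    if unit_pos is not None and bearing_deg is not None:
        return grid.assign_bearing(unit_pos, bearing_deg, max_range)
    raise ValueError("need a position or a unit position + bearing")


@dataclass
class SectorStateMachine:
    """Per-sector colour states with a transition log."""

    grid: SectorGrid = field(default_factory=SectorGrid)
    hold_time: float = 600.0  # seconds a detection keeps its sector alight
    states: dict = field(init=False)
    log: list = field(init=False, default_factory=list)

    def __post_init__(self) -> None:
        self.states = {s.id: GREEN for s in self.grid.sectors}

    def update(self, now: float, dolphin_events: list, boat_events: list) -> dict:
        """Recompute all sector colours at time ``now``.

        Events are dicts with keys ``time`` and ``sectors`` (list of ids).
        Yellow: a dolphin event within the hold time; red: additionally a
        boat event in the same sector within the hold time.
        """
        recent_d = _recent_sectors(dolphin_events, now, self.hold_time)
        recent_b = _recent_sectors(boat_events, now, self.hold_time)
        for sid in self.states:
            if sid in recent_d and sid in recent_b:
                new = RED
            elif sid in recent_d:
                new = YELLOW
            else:
                new = GREEN
            if new != self.states[sid]:
                self.log.append({"time": now, "sector": sid,
                                 "from": self.states[sid], "to": new})
                self.states[sid] = new
        return dict(self.states)


def _recent_sectors(events: list, now: float, hold: float) -> set:
    out = set()
    for ev in events:
        if 0.0 <= now - ev["time"] <= hold:
            out.update(ev.get("sectors", []))
    return out


def update_state(machine: SectorStateMachine, now: float,
                 dolphin_events: list, boat_events: list) -> dict:
    """Functional wrapper over :meth:`SectorStateMachine.update`."""
    return machine.update(now, dolphin_events, boat_events)


def detection_report(event: dict, out_path=None, spectrogram=None,
                     correlograms=None, tracking: dict | None = None) -> dict:
    """Self-contained report of one detection event.

    Contains the event date-time, the whistle spectrogram, a snapshot of
    the cross-correlation plots and the tracking results; missing products
    are marked absent rather than failing.  Returns the report dict and,
    when ``out_path`` is given, also writes JSON (and HTML with embedded
    figures if matplotlib figures were supplied).
    """
    report = {
        "datetime": event.get("datetime", event.get("time", "absent")),
        "spectrogram": "attached" if spectrogram is not None else "absent",
        "cross_correlation": "attached" if correlograms is not None else "absent",
        "tracking": tracking if tracking is not None else "absent",
        "event": {k: v for k, v in event.items() if _jsonable(v)},
    }
    if out_path is not None:
        out_path = str(out_path)
        with open(out_path if out_path.endswith(".json") else out_path + ".json",
                  "w") as fh:
            json.dump(report, fh, indent=2, default=str)
        html = _render_html(report, spectrogram, correlograms)
        base = out_path[:-5] if out_path.endswith(".json") else out_path
        with open(base + ".html", "w") as fh:
            fh.write(html)
    return report


def _jsonable(v) -> bool:
    return isinstance(v, (str, int, float, bool, list, dict, type(None)))


def _fig_to_data_uri(fig) -> str:
    buf = _io.BytesIO()
    fig.savefig(buf, format="png", dpi=80)
    return "data:image/png;base64," + base64.b64encode(buf.getvalue()).decode()


def _render_html(report: dict, spectrogram, correlograms) -> str:
    parts = [
        "<html><head><title>Detection report</title></head><body>",
        f"<h1>Detection {report['datetime']}</h1>",
        f"<h2>Tracking</h2><pre>{json.dumps(report['tracking'], indent=2, default=str)}</pre>",
    ]
    for title, fig in (("Spectrogram", spectrogram),
                       ("Cross-correlation", correlograms)):
        parts.append(f"<h2>{title}</h2>")
        if fig is None:
            parts.append("<p><em>absent</em></p>")
        else:
            parts.append(f'<img src="{_fig_to_data_uri(fig)}"/>')
    parts.append("</body></html>")
    return "\n".join(parts)
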