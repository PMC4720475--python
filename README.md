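# pamtrack

Passive acoustic monitoring (PAM) toolkit for coastal dolphin
conservation: detect bottlenose-dolphin whistles, estimate the direction
of dolphins and boats from a four-hydrophone array, and triangulate their
position from two moored acoustic units — with a bundled acoustic-scene
simulator so the whole pipeline is testable without sea data.

## Who this is for

Bioacousticians and conservation engineers building or studying fixed
PAM stations of the "two buoys, four hydrophones each" kind: two
orthogonal 5 m hydrophone pairs at different depths per unit, 100 kHz /
16-bit synchronized sampling, a wi-fi link to shore, and a sector-based
dolphin/boat alarm for a marine protected area.

## What it computes

**Design budgets.** The passive sonar equation
`L_SN(r) = SL − (TL(r) + NL + 10 log₁₀B) ≥ DT` with
`TL(r) = k log₁₀ r + αr`, Wenz-table ambient noise, and the detection
threshold `DT = 10 log₁₀(d/m)`; plus radio-link planning (horizon
`√(2Rh)`, Fresnel radius `17.31√(d₁d₂/fd)`, free-space loss
`32.45 + 20 log D + 20 log f`, stream bandwidth).

**Whistle detection.** Spectrogram (1024-pt FFT, Hann, 75 % overlap) →
click suppression by the negative second derivative of each spectrum →
tonal-track extraction M(i) → a linearity detection function
`W(m) = Π w(j)` with `w = 1` for smooth track steps and `0.8` for jumps →
thresholding, then a robust (bisquare) slope fit and a slope/duration
gate that rejects mooring-cable screech and small-boat tonals.

**Direction finding.** Six pairwise times-of-arrival differences (TDOA)
by cross-correlation with sub-sample parabolic refinement and
closure-identity consistency checking (`Δt₀₁ + Δt₁₂ = Δt₀₂`), then the
plane-wave direction by closed-form linear solve and by least-squares
grid minimization of `G(φ,θ) = Σ(Δt_meas − Δt_theo)²`; body-to-world
rotation by the buoy's tilt-compass attitude and the calibrated offset
ψ₀.  Boats are tracked continuously from the two orthogonal pairs
(`ΔT₂₀ = Lc cos α`, `ΔT₃₁ = Lc sin α`) with mirror-ambiguity resolution
by probability-function product.

**Triangulation, calibration, alerting.** Two-unit bearing intersection
with an error square of side `range × Δα` and a TDOA-hyperbola
consistency residual; recovery of the field parameters L/c and ψ₀ from a
circling-boat run; and a green/yellow/red sector state machine with
self-contained detection reports.

## Worked example

Simulate a scene, detect the whistle, and print the design budget:

```bash
$ pamtrack budget
band centroid        : 8.66 kHz
detection threshold  : 1.3 dB (safety 5 dB)
sea state 0: band NL  69.0 dB -> detection range    9260 m
sea state 4: band NL  88.0 dB -> detection range    1911 m
radio horizon (40 m) : 22.6 km
stream bandwidth     : 6.4 Mbit/s
free-space loss 1.7km@5.47GHz: 111.8 dB
Fresnel radius mid-link 1.7km: 4.8 m
```

The detection ranges are the roots of the sonar budget at sea states 0
and 4 (a 160 dB whistle is detectable to ~9.3 km in calm water but only
~1.9 km at the safe-shipping limit — which is why the two units sit
1.8 km apart), the horizon and Fresnel numbers size the shore link, and
6.4 Mbit/s is the raw 4 × 100 kS/s × 16 bit acoustic stream.

```bash
$ pamtrack simulate --seed 3 --out scene/ --duration 4
scene written to scene
$ pamtrack detect --in scene/unit_west.wav --out detections.jsonl
1 events -> detections.jsonl
```

The simulator writes each unit's 4-channel 100 kHz WAV, an attitude CSV
and a ground-truth JSONL; the detector reports one event per whistle
with its time extent, peak frequency, slope, duration and gate decision.

In Python, the full chain from rendered audio to a world-frame bearing:

```python
import numpy as np
from pamtrack.geometry import ArrayGeometry, UnitConfig
from pamtrack.synth import Scene, SceneSource, WhistleSpec, render_scene
from pamtrack.tdoa import tdoa_set
from pamtrack.dolphin import grid_search_G, wave_to_source_bearing

geom = ArrayGeometry.default()
unit = UnitConfig("west", 44.2965, 9.1980, depth=20.0, psi0=30.0)
scene = Scene(duration=1.5, seed=1, sources=[
    SceneSource("whistle", WhistleSpec(shape="rise", duration=0.5),
                start=0.1, position=np.array([1000.0, 0.0, 0.0]))])
res = render_scene(scene, [unit], geom,
                   unit_positions={"west": np.array([0.0, 0.0, -20.0])})["west"]
ts = tdoa_set(res.audio[:, 70000:125000], 100000.0, geom)
wave = grid_search_G(ts, geom)
bearing = wave_to_source_bearing(wave, res.truth[0]["attitude"], psi0=30.0)
print(round(bearing.azimuth, 2), round(res.truth[0]["bearing_deg"], 2))
# 90.0 90.0  — the simulated whistle due East is recovered to <0.01 deg
```

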