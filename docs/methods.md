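# Methods

`pamtrack` re-implements, as a testable library, a two-unit passive
acoustic monitoring (PAM) pipeline for coastal bottlenose dolphins: each
unit is a moored spar buoy carrying four hydrophones in two orthogonal
5 m pairs, 5 m apart in depth, sampled simultaneously at 100 kHz / 16 bit.
This note documents the models, conventions, numerical choices and the
limits of what the synthetic-data tests demonstrate.

## Sonar and link budgets

Detectability of a whistle at range r follows the passive sonar equation
`L_SN(r) = SL − (TL(r) + NL + 10 log10 B)` with `TL(r) = k log10 r + α r`.
Defaults are the coastal design point: SL = 160 dB re 1 µPa @ 1 m over
5–15 kHz, spherical spreading (k = 20), α = 0.72 dB/km at the band
centroid √(f_min f_max) ≈ 8.66 kHz, and a detection threshold whose
lower bound `DT = 10 log10(d/m)` ≈ 1.3 dB (detection index d = 9 for
P(D) = 0.9, P(FA) = 0.05; m = f_sampl/f_max) is raised to a 5 dB safety
value because a passive system never knows the source waveform.  The
ambient-noise model is a small editable table of Wenz-curve spectral
levels keyed by (frequency, sea state) — 29 and 48 dB re 1 µPa/√Hz at
8.66 kHz for sea states 0 and 4 — because those levels are read off
curves, not computed; an additive wide-band offset represents a
site-survey correction.  `detection_range` root-solves the budget by
bracketed bisection on [1 m, 100 km] to 0.1 m; TL is strictly increasing
so the root is unique.  The radio-link helpers (√(2Rh) horizon,
17.31 √(d1 d2/(f d)) Fresnel radius, 32.45 + 20 log D + 20 log f free-space
loss, sample-rate × channels × bits stream bandwidth) are implemented
exactly as those printed formulas.

## Frames and the plane-wave model

World frame: local flat-earth ENU; user-facing azimuths are compass
bearings (clockwise from North).  Body frame: pair (H0, H2) along body x
at the upper depth, (H1, H3) along body y, 5 m deeper; this indexing makes
the contiguous pairs (H0H1, H1H2, H2H3) a non-singular basis for the
linear direction solve.  Attitude is applied intrinsically roll → pitch →
yaw, yaw being minus the total heading (compass + ψ0 + declination),
since the tilt-compass reports the three angles independently.  A plane
wave with unit propagation vector n̂ reaches hydrophone i at
`t_i = (H_i·n̂)/c`, so `Δt_ij = ((H_i − H_j)·n̂)/c`; sources beyond ~100 m
satisfy the plane-wave assumption for this geometry.  Default
c = 1500 m/s; wherever the ratio L/c appears, the field-calibrated value
supersedes it.

## Scene simulator

The generator renders what each unit records: whistles (seven stylized
contour templates — flat, rise, fall, concave, convex, sine, multi-loop —
parameterized by start/end frequency in 5–15 kHz, duration, and a
curvature depth), broadband click trains (differentiated-Gaussian
kernels), boat engines (1/k harmonic comb over a broadband floor), and
Gaussian ambient noise with flat spectral density equal to the Wenz table
entry, which reproduces the configured band level by construction.
Sources are delayed per hydrophone by bulk travel time plus the
plane-wave offset using 64-tap Kaiser-windowed-sinc interpolation (the
window is evaluated continuously, centred on the interpolation point, so
integer delays are exact); amplitudes scale with spherical-spreading TL.
Moving sources interpolate position, gain and delay from 100 ms knots
with per-sample sinc resampling.  Pressure maps to 16-bit WAV with a
configurable full scale (135 dB re 1 µPa peak by default, placing a
160 dB source at 1 km ~30 dB above the sea-state-0 noise floor and well
above the quantization floor).

One deliberate modelling choice: the "flat" template drifts by 400 Hz
(configurable; zero restores an ideal tone).  A strictly periodic tone
cannot be unambiguously localized by a 5 m array — its correlation comb
and the array's grating lobes are a physical, not algorithmic, ambiguity —
and published constant-type whistle contours do drift by a few hundred
hertz.  Not modelled: multipath and surface reflection, Doppler, whistle
directivity, nonstationary or shipping-shaped noise spectra.  Passing
tests therefore demonstrate correctness of the algorithms under the
stated propagation model, not field performance; the deployed system's
field statistics are not reproducible without the sea data.

## Whistle detector

Per channel: 1024-point FFT spectrogram (Hann, 75 % overlap; 97.7 Hz ×
2.56 ms bins), then click suppression via the negative second derivative
of each spectrum column, `D_i(f) = 2P_i(f) − P_i(f−df) − P_i(f+df)`,
whose argmax in 5–15 kHz forms the per-column track M(i): sharp tonal
ridges maximize D, broadband clicks do not.  The detection function
tests the linearity of the track's first derivative
`M′(k) = M(k+2) − M(k)`: over windows of P = 10 columns each step
contributes 1 if `|L| ≤ 2` bins and 0.8 otherwise, and their product W(m)
(bounded in [0.8^P, 1]) is thresholded at 0.8² (at most two violations).
Candidate runs shorter than 3 columns are discarded.  The peak column of
a run with tied W values is taken at the run centre, which keeps the
slope window on the whistle body.  Slope is a Tukey-bisquare IRLS line
fit over 40 columns centred on the W peak after excluding >3σ residuals
of an initial least-squares fit; duration is the maximal run of
consecutive track samples within ±25 % of the peak-column frequency.
The slope/duration gate is a point-in-polygon test; the default region
spans durations 0.05–1.5 s and |slope| ≤ 60 kHz/s, minus the
near-zero-slope corner beyond 1.2 s where mooring-cable screech (which
mimics a long flat whistle) lands.  The 40-column window is honoured as
a sample count; at a 2.56 ms hop it spans ~102 ms.  Optional per-bin
median equalization is off by default.

## TDOA measurement

TDOAs are measured on 3–23 kHz bandpassed signals (the analog front-end
band), as the lag of the cross-correlation maximum refined by parabolic
interpolation — at 100 kHz and L = 5 m one sample is ~3° of bearing, so
sub-sample refinement is required for the 2° accuracy target.  Ties
between equal peaks resolve to the smallest |lag|.  The six pairwise
TDOAs are checked against the closure identities (Δt01 + Δt12 = Δt02
etc.); because tonal signals are near-periodic, the correlation maximum
can sit one carrier cycle off, so on closure failure the redundancy is
used constructively: the top 13 correlation peaks per pair are
enumerated over the three contiguous pairs, combinations must place the
implied derived TDOAs on candidate peaks of the remaining pairs, and
survivors are ranked by the residual of the best-fit single plane wave
(closed-form solve, all six pairs), with total correlation as
tie-break.  A set is invalid if any pair is undefined or the worst
closure residual exceeds 2 samples.  The streaming (boat) path gates
each 8 ms window's correlation peak at n_sigma = 4 standard deviations
of the correlation values (chosen for a <5 % false-keep rate on noise),
and window length 8 ms is twice the maximum pair TDOA.

## Dolphin bearing estimation

Two independent solvers recover the body-frame wave direction from a
TdoaSet: a closed-form 3×3 solve over the contiguous pairs (renormalized;
deviation of the raw norm from 1 is a quality flag at 0.2), and a
least-squares grid search minimizing `G(φ, θ) = Σ (Δt_meas − Δt_theo)²`
over all six pairs on a 2° coarse grid — matching the stated accuracy —
refined by Nelder–Mead to 0.1° (a 2-D simplex refinement was preferred
over two 1-D golden-section passes; same termination).  The source lies
at the antipode of the wave direction (φ_S = φ_W + π, θ_S = π − θ_W) and
is rotated to the world frame by the attitude and ψ0.  For multi-window
events the bearing is the correlation-peak-weighted circular mean.  The
3-D (non-coplanar) array makes the G minimum generically unique; the
up/down mirror of a planar array does not arise.

## Boat tracking

Boats are tracked continuously from the two orthogonal pairs with the
surface-plane convention ΔT20 = Lc cos α, ΔT31 = Lc sin α, where α grows
counter-clockwise from the pair-(0,2) axis; the streaming stage reports
ΔT20 = t0 − t2 and ΔT31 = t1 − t3 so that the hydrophone nearer the
source leads.  (The source's two printed TDOA conventions disagree
between the tracking and calibration sections; the cos/sin assignment
that the arccos/arcsin inversions presuppose is used throughout, with
this axis mapping.)  Each inversion leaves a mirror solution (2π − α20;
π − α31); both pairs contribute a circular two-Gaussian mixture with
σ = 4·Δα — Δα = Δτ/(Lc √(1 − (τ/Lc)²)) propagated from the one-sample
default timing resolution — and the product of the two mixtures is
maximized on a 0.02° grid.  The combined error is the smaller per-pair
Δα: near a pair's axis (τ → Lc) its error diverges and the orthogonal
pair dominates.  Elevation is assumed zero (sea surface) in streaming;
the cos(arctan(h/R)) foreshortening correction is applied only where the
range is known (calibration).  World bearing = 90° + compass + ψ0 − α.

## Calibration

`estimate_lc` consumes the per-pair TDOA series of a boat circling at
known range R (~150 m): the series is a sinusoid whose extrema equal
Lc cos β per pair (β = arctan(h/R), h = −20 / −25 m; correction ~0.9 %).
The series is low-pass filtered at 0.05 Hz (well above the ~1/120 Hz lap
frequency, below window jitter), extrema are located with a minimum
separation of a quarter cutoff period, edge artefacts dropped, each
|extremum| divided by cos β and all averaged; fewer than two extrema is
a calibration failure.  `estimate_psi0` is the circular mean of
(GPS-derived bearing − bearing tracked with ψ0 = 0), matched
nearest-in-time within 1 s (GPS at 1 Hz); a circular dispersion above
20° rejects the run.  The recovered offset absorbs mean magnetic
declination by construction.

## Triangulation and alerting

Simultaneous bearings from the two units (1.8 km apart) are intersected
in the horizontal plane by a linear solve; rays within 3° of parallel or
intersecting behind a unit yield a no-fix sentinel.  The error square
side is range × Δα(rad) — 2° at 3700 m gives ≈130 m — using the mean of
the two unit ranges.  The inter-unit arrival-time difference of a
matched event (±3 s window; maximum acoustic delay at this baseline is
~1.2 s; contours compared by normalized cross-correlation ≥ 0.7) places
the source on a hyperbola with the units as foci; the fix-to-hyperbola
residual is reported in metres and flagged against a 50 m default
threshold.  Sector alerting divides the study area into configurable
rectangles (five of ~2 km side in the reference layout): a sector is
yellow if a dolphin event fell in it within the hold time (default
10 min), red if a boat event coincides, green otherwise; every
transition is timestamped and replay of the same event log reproduces
the same history.  Detection reports bundle the event time, spectrogram
and correlogram snapshots and the tracking results into JSON + HTML,
marking missing products absent.

## Validation studies and problem sizes

The `validate` module drives the end-to-end studies used by the test
suite and `scripts/acceptance.py`: 100 single-whistle scenes (all seven
shapes, 0.5–3 km from both units, sea state 0, wobbling attitudes with
per-unit ψ0 of +30°/−80°) for bearing RMSE and error-square coverage;
60 whistles at 15 dB band SNR plus 10 minutes of noise-only records for
detector rates; forward-simulated three-lap TDOA series (25 Hz, one
sample of timing noise) for L/c and ψ0 recovery; and a full 360° TDOA
sweep (2° steps, excluding ±5° around the degenerate pair axes) for the
boat tracker.  Calibration and the boat sweep are exercised at the TDOA
level — the quantity those estimators actually consume — while audio-level
TDOA fidelity is verified separately on rendered scenes; this keeps the
whole suite within a few minutes on one CPU without changing what is
tested.

## Known limitations

Single source per trigger window (first peak only); no multi-boat
separation or engine-signature classification; no near-field spherical
model or depth estimation; flat-earth geodesy (adequate ≤5 km); noise is
white within the band rather than Wenz-shaped across it; detector
channel fusion keeps the single best channel per event.
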