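# Methods and conventions

This note records how the model is integrated and measured, how the
image-quantification steps are defined, what the synthetic data emulate, and
the choices made where a published description leaves the design open.

## The cell-chain model

### Equations and boundary conditions

The chain couples junction mechanics, a strain-to-ERK relaxation, and an
ERK-to-force relaxation (see the README for the equations). The base
junction (i = 1) is held fixed; the tip junction obeys
`η_c dx_{N+1}/dt = −k ε_N + F_tip` (the last spring resists, the tip force
propels). The motile force of cell j acts at its rear junction i = j,
pulling it toward the cell front.

The elastic term is the standard spring-chain force balance
`k (ε_i − ε_{i−1})`. The index-flipped variant `k (ε_i − ε_{i+1})` is
anti-diffusive in the continuum limit; integrated with the default
parameters it violates junction ordering within ~13 simulated minutes, and
is retained only as `orientation="flipped"` for demonstration.

### Integration

Forward Euler with dt = 0.01 min, all times in minutes. Each step updates
positions from the current force balance, refreshes strain from the new
positions, then applies the ERK relaxation (driven by the fresh strain) and
the force relaxation (driven by the fresh ERK), in that order; `euler_step`
and the `run` integrator implement the identical sequence. Halving dt
changes the measured lags by well under one recording interval.

With the default parameters the saturated coupled wave trains intermittently
drive a single cell through zero length (a junction inversion). The event is
dt-independent — it is a property of the dynamics, which have no excluded
volume — and the forward-Euler update integrates through it; the pattern
recovers within a wave period. `run(strict=True)` instead raises
`ChainInstabilityError` at the first inversion, carrying the failure time.

### Initial conditions

The equations do not fix an initial state. Starting exactly at rest, waves
are seeded only by F_tip and invade from the tip at the wave speed, covering
under a fifth of a 1000-cell chain in 2000 min and leaving the statistics of
any per-cell measurement non-stationary. `run` therefore seeds the coupled
regime with small Gaussian noise on E (sd 0.02, seeded generator): the
feedback amplifies it into retrograde wave trains across the whole chain,
saturating by t ≈ 1000 min, after which per-cell lag statistics are
stationary (drift < 0.5 min between 2000-min windows). The uncoupled regime
starts at rest; its ERK field is prescribed.

### The imposed wave

`E(X,t) = 0.5 (sin(π (X + v t)/w) + 1)` is evaluated at the current cell
centres `(x_j + x_{j+1})/2`. The phase convention makes the spatial period
2w = 168 µm and moves crests toward the base at v = 0.42 µm/min. Because the
imposed E is non-negative (mean 0.5), the relaxed forces have a nonzero mean
and the fixed-base chain creeps and stretches secularly; the measured lag is
nevertheless stable across analysis windows.

### Lag measurement

The extension-shrinkage rate follows its strain-rate-tensor definition: per
cell, the junction-velocity difference over the current cell length,
`(v_{j+1} − v_j)/(x_{j+1} − x_j) = d ln(1+ε_j)/dt` (`kind="strain_rate"`;
plain dε/dt is available as `kind="eps_rate"`). The ERK activity rate is
dE_j/dt. Both are central differences on a 1-min recording grid, smoothed
with a centred 60-min moving average — the physical timescale of the
span-5 smoothing applied to the 12-min-sampled experimental series.

Cross-correlation uses z-scored series and the constant-denominator
normalization (as in MATLAB's `xcorr` with `coeff`), with the grid-peak lag
and ties broken toward zero. Per-cell peak lags are collected over ~64
interior cells whose ERK temporal sd exceeds a quarter of the chain maximum
(excluding quiescent stretches and 20 boundary cells), and summarized by
their median. The analysis window is 4000 min (coupled: duration 5000,
discard 1000; uncoupled: 4400/400), long enough that the correlation
estimator's triangular-envelope bias — which shifts slow-oscillation peaks
by O(period²/window) — is below half a minute.

Under these conventions the coupled regime yields a lag of −25 min (median;
per-cell sd ≈ 1 min; stable across seeds) and the uncoupled regime −3 min.
Two caveats bound the precision of such numbers. First, the emergent coupled
oscillation is a strongly nonlinear relaxation waveform (E swings ±0.97
through tanh saturation); a small-amplitude wave of the same period
(~450 min) would put the lag at atan(ω η_E)/ω ≈ 28 min, and correlating the
ε and E levels instead of rates gives −27 min, so the rate-based figure sits
a few minutes below its linear-response counterpart. Second, the uncoupled
lag is smaller than the phase equivalent of half a cell length
(≈ 6 min at v = 0.42 µm/min), so it is sensitive to evaluation-point
conventions: imposing the wave on material rather than current coordinates,
for example, moves it to −10 min. Lags on the minute scale should be read as
"a few minutes", in contrast to the tens of minutes of the feedback regime.

Station-based (Eulerian) lag variants were evaluated and rejected: the sharp
stripe waveform aliases against the station spacing, swinging the measured
lag between −21 and −34 min for spacings between 12.5 and 50 µm.

## Image quantification

* **FRET ratio** — per frame and channel: 3×3 median filter, background
  subtraction, then FRET/CFP per pixel; pixels whose background-subtracted
  CFP is ≤ 0 are NaN. The default background is the mean of the darkest 1%
  of pixels per frame, which presumes a dark non-tissue region in the field
  of view; scalars or a region mask can be supplied instead (and must be,
  for images that are tissue wall-to-wall — see the synthetic-data caveat).
* **PIV** — 40-px interrogation windows (≈ 25 µm, 4–5 cell diameters) at 50%
  overlap; each window is matched by normalized cross-correlation against a
  search region extended by window/3 px per side, with 3-point Gaussian
  sub-pixel refinement. The window grid is placed so the full symmetric
  search range fits in the frame; correlation peaks on a clipped search
  border are flagged invalid, as are windows without texture. Vector fields
  are median-filtered componentwise over the 3×3 window neighbourhood
  (invalid vectors are replaced by their neighbourhood median). Validated to
  < 0.05 px on integer translations and < 0.2 px at quarter-pixel shifts.
* **Elongation speed and extension-shrinkage rate** — window velocities are
  projected on the local tangent of the apex–base polyline (positive toward
  the apex); windows within one grid spacing of the line are used, and
  windows projecting to the same arc position are band-averaged. The rate
  between adjacent windows is Δspeed/Δarc (min⁻¹), reported at midpoints;
  a span-5 moving average is the default smoothing and the raw rate is also
  returned (its arc integral telescopes exactly to the end-speed
  difference).
* **Windowed ERK series** — per window and frame, Otsu's threshold on the
  CFP window isolates the cytoplasmic region; activity is the mean ratio
  over that mask, NaN frames are interpolated when isolated, and the rate is
  the central-difference time derivative.
* **Kymograph** — activity sampled every 10 px of arc (half the PIV grid
  spacing) and averaged over a 20-px band perpendicular to the line.
* **Wave speed** — the kymograph is clipped to its 1–99 percentile range
  (ratio outliers), lightly smoothed (σ = 1 sample), per-frame activity
  maxima are linked into ridges with a constant-velocity-predictive nearest
  association (gating on the last position instead biases fast ridges slow),
  boundary-censored samples are dropped, each ridge is fitted with a line in
  (position, time), and the speed is the length-weighted median of |slope|
  over ridges (± their sd). Validated to ≤ 5% for 0.1–1.0 µm/min at SNR 5;
  a static ridge gives speed 0.

## Geometry

Traced layers are handled in µm in the image plane. The medial curve is the
skeleton (iterative thinning) of the rasterized ribbon between the apical
and basal contours at 1 µm/px, ordered from the apex end; curves are
resampled every 15 µm of arc and fitted with interpolating cubic splines —
parametric in the chord-length parameter (the coiled duct is not a graph),
natural ends for open curves, periodic for closed phantoms. Signed curvature
is the parametric formula, or the per-interval graph formula
`κ = (6a t + 2b)/(1+(3a t²+2b t+c)²)^{3/2}` in graph mode; the sign is
positive where the centre of curvature lies toward the declared lumen side.
Total curvature integrates κ against the normalized arc length (trapezoid).
Thickness at a sampling point is the normal chord through the point clipped
by the two contours, with a nearest-distance fallback (flagged) when a
normal misses. Local edge curvature samples four points at ±0.5 and ±1.5
× 19 µm around the reference, fits a single parametric cubic (not-a-knot),
and averages the curvature at the two flanking knots — accurate to ~1% at
R = 50 µm; natural ends were rejected here (15% bias from the zero-second-
derivative constraint two knots away).

Accuracy oracles: closed-circle curvature |κ·R − 1| < 0.1% for R between 25
and 200 µm; annulus thickness within 2%; open-curve profiles carry a
natural-end bias confined to roughly one knot interval per end (≈ 2% on a
semicircle's total curvature).

## EdU mapping

Z-stacks split at the middle slice (odd counts: middle slice to the floor
half). Projections: max, sum, or in-duct mean (per-pixel denominator = the
number of z-samples inside the duct mask). The duct mask is Otsu ∘ closing
(3-px disk) ∘ hole fill ∘ largest component. The perimeter is split at the
apex landmark into medial and lateral curves (each ending at its landmark),
21 arc-equidistant marks per curve are joined by chords, and each chord is
split into 10, giving the 20×10 region grid indexed from the apex and the
medial side. Pixels are assigned to the first containing quadrilateral in
index order (shared edges go to the lower index); in-mask pixels missed by
the straight-edged quads along the curved perimeter attach to the nearest
region centroid, so the assigned pixels tile the counted area exactly.
Region values are mean 8-bit EdU intensity / 255. Cell density divides the
mediolateral axis into five equal sections and reports counts per supplied
(or rectangle-derived) section areas.

## Synthetic data

`make_wave_movie` renders a band-limited random texture (Gaussian-filtered
white noise, grain 3 px) advected by an analytic displacement field —
uniform flow toward the apex plus an optional traveling sinusoidal
modulation — via sub-pixel linear interpolation, and multiplies the FRET
channel by a cosine wave traveling toward the base whose activity rate lags
the local strain rate by a set delay. Defaults mirror the measured study
conditions: 0.625 µm/px, 12-min frames, flow 0.24 µm/min, wave 0.42 µm/min,
wavelength 168 µm, lag 24 min. Noise is additive Gaussian. What the movie
does not emulate: photon statistics, bleaching, drift, out-of-plane motion,
cell-scale texture evolution, and — importantly — a dark non-tissue
background region, so ratio analyses of these movies should pass the true
background (zero) rather than use the darkest-percentile estimate. Passing
pipeline tests on these movies therefore demonstrates correctness of the
measurement chain, not robustness to every real-image artefact.

Phantoms (circles, annuli, Archimedean spirals, straight and bent duct
masks with pointed apex tips, gradient volumes, Poisson point fields) carry
closed-form ground truth. All generators are bit-deterministic given their
spec and seed.

## Known limitations

* The model chain has no excluded volume; transient cell inversions occur in
  the saturated coupled regime (integrated through, see above).
* The uncoupled regime's mean imposed force stretches the fixed-base chain
  without bound; runs much longer than ~5000 min leave the near-base cells
  unphysically long.
* Minute-scale lags are convention-limited (± a few minutes), as detailed
  above.
* Natural spline ends bias open-curve curvature near the first and last
  knot; analyses of open layers should discount one sampling interval at
  each end.
* The ridge-based wave-speed estimator assumes a dominant traveling
  component; superposed counter-propagating waves of similar amplitude are
  not resolved.
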