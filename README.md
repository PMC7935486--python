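# cochleaflow

Quantitative tools for studying how the murine cochlear duct elongates and
coils: a 1D mechanochemical model of ERK activation waves coupled to
collective cell flow, together with the image-quantification pipeline used
on FRET time-lapse movies of the developing duct — ratiometric ERK maps,
particle image velocimetry (PIV) of tissue flow, kymography and wave-speed
estimation, deformation–ERK cross-correlation lag analysis, cubic-spline
curvature/thickness morphometry of traced epithelial layers, and regional
EdU-intensity mapping. Because raw two-photon movies of this system are not
distributable, the package ships seeded synthetic-data generators that
emulate every input class with known ground truth, so the entire pipeline is
testable end to end.

It is written for developmental-biology labs quantifying collective cell
migration and kinase activity waves in epithelia, and for modellers probing
mechanochemical feedback.

## The model

Cells `j = 1..N` form a chain of springs whose junctions `i = 1..N+1` move
through viscous friction η_c. Each cell carries a strain ε_j, an ERK
activity E_j, and a motile force F_j exerted at its rear junction:

    η_c dx_i/dt = k (ε_i − ε_{i−1}) + F_{j=i},   ε_j = (x_{j+1} − x_j)/L − 1
    η_E dE_j/dt = tanh(α ε_j) − E_j
    η_F dF_j/dt = λ E_j − F_j

The base junction is fixed; the apical tip is propelled by a constant force
F_tip. Stretch activates ERK after a delay η_E; ERK builds contractile force
after a delay η_F; the force pulls the rear neighbour and stretches it in
turn. This closed loop (the *coupled* regime) self-organises trains of ERK
waves that travel tip→base while the cells flow base→tip — the retrograde
pattern seen in live imaging. In the *uncoupled* control regime the
strain→ERK arm is severed and ERK is prescribed as a retrograde traveling
wave `E(X,t) = 0.5 (sin(π (X + v t)/w) + 1)` of half-wavelength `w = 84 µm`
and speed `v = 0.42 µm/min`.

The signature that separates the two regimes is the peak cross-correlation
lag between the extension-shrinkage rate (the diagonal strain-rate
component) and the ERK activity rate, measured per cell: tens of minutes
with feedback, a few minutes without.

Default parameters: η_c = 40 nN·min/µm, k = 20 nN, F_tip = 6 nN, α = 3,
η_E = 30 min, η_F = 10 min, λ = 9 nN, L = 5 µm, N = 1000, forward Euler with
dt = 0.01 min.

## Worked example

```python
import numpy as np
import cochleaflow as cf

# 1. coupled-regime simulation and lag analysis
params = cf.default_params("coupled")
traj = cf.run(params, duration=5000, record_interval=1.0, discard=1000, seed=1)
res = cf.rate_lag_analysis(traj)
print(f"coupled lag: {res['median_lag']:.0f} min "
      f"(mean {res['mean_lag']:.1f}, sd {res['sd_lag']:.1f}, "
      f"n={len(res['lags'])} cells)")

# 2. synthetic FRET/CFP movie through the imaging pipeline
spec = cf.WaveMovieSpec(noise_sd=0.01)     # flow 0.24 µm/min, wave 0.42 µm/min
fret, cfp, truth = cf.make_wave_movie(spec)
ratio = cf.fret_ratio(fret, cfp, background=(0.0, 0.0))
line = cf.ApexBaseLine(
    points=np.column_stack([np.full(40, 64.0), np.linspace(0, 511, 40)]),
    pixel_size=spec.pixel_size)
field = cf.median_filter_field(cf.piv_pair(
    cfp.frames[0], cfp.frames[1], window_size=40,
    pixel_size=spec.pixel_size, frame_interval=spec.frame_interval))
pos, speed, _ = cf.project_onto_line(field, line)
est = cf.wave_speed(cf.kymograph(ratio, line, band_width=20))
print(f"tissue flow toward apex: {speed.mean():.3f} um/min (truth 0.240)")
print(f"ERK wave: {est.speed:.3f} um/min, {est.direction} (truth 0.420)")
print(f"wave speed in cell diameters: {cf.cells_per_hour(est.speed, 4.0):.1f} cells/h")
```

prints

```
coupled lag: -25 min (mean -24.9, sd 0.8, n=67 cells)
tissue flow toward apex: 0.240 um/min (truth 0.240)
ERK wave: 0.421 um/min, apex_to_base (truth 0.420)
wave speed in cell diameters: 6.3 cells/h
```

The negative lag says local tissue deformation precedes ERK activation by
about 25 minutes — the fingerprint of closed mechanochemical feedback. The
pipeline recovers the movie's built-in flow (toward the apex) and ERK wave
(toward the base, the opposite direction) to within a percent.

A command-line interface exposes the same steps:

```bash
cochleaflow simulate --mode coupled --out out/sim
cochleaflow reproduce --out out/repro          # both regimes + lag report
cochleaflow synth wave-movie --seed 1 --out out/movie
cochleaflow quantify-flow --fret out/movie/fret.tif --cfp out/movie/cfp.tif \
    --meta out/movie/meta.json --line line.csv --out out/flow
cochleaflow kymo --ratio out/flow/ratio.tif --meta out/movie/meta.json \
    --line line.csv --out out/kymo
cochleaflow curvature --apical apical.csv --basal basal.csv --out out/geom
cochleaflow edu-map --stack stack.tif --landmarks lm.json --out out/edu
```

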