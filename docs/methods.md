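# Methods

## Signal model

The simulator integrates the Bloch-McConnell equations for a bulk-water
pool exchanging with dilute solute pools under continuous-wave (CW)
saturation. In the rotating frame of the pulse the system is linear and
time-invariant, dM/dt = A·M + b, so no ODE stepper is needed: the response
to a finite pulse is the matrix exponential of the augmented homogeneous
system, and the steady state is the linear solve A·M = −b. The two routes
are algebraically independent and cross-check each other (they agree within
1.5×10⁻⁶ at t_sat = 20 s over the whole CEST sweep). The single-pool limit
reproduces the closed form z = R₁(Δ²+R₂²)/(R₁(Δ²+R₂²)+ω₁²R₂) exactly.

Exchange is base-catalyzed: each solute's rate follows
k(pH) = k₀·10^(s·(pH−7)), with k₀ the rate at pH 7.0 and s the decadic
slope (1 for amide/amine, 0 for the optional magnetization-transfer pool).
Exchange conserves magnetization component-wise, with the water→solute
rate equal to f·k for proton fraction f.

### Default pool system (9.4 T, water at 400.22 MHz)

| pool  | shift (ppm) | T1 (s) | T2 (ms) | fraction | k₀ (s⁻¹) | s |
|-------|------------|--------|---------|----------|----------|---|
| water | 0          | 2.0    | 60      | —        | —        | — |
| amide | +3.5       | 1.0    | 10      | 7×10⁻⁴   | 30       | 1 |
| amine | +2.75      | 1.0    | 5       | 5×10⁻⁴   | 1500     | 1 |

These are literature-plausible brain-like stand-ins, not values fitted to
any tissue: amide exchange is slow, amine fast/intermediate relative to
ω₁ ≈ 401 rad/s at 1.5 μT, which places AACID on its inverse pH
relationship (strictly decreasing over pH 6.2–7.6, R² = 0.975 against a
line). Solute T1 is not critical (longitudinal relaxation of a dilute pool
is dominated by exchange); 1.0 s is a conventional choice. The water
resonance frequency 400.22 MHz (42.5764 MHz/T × 9.4 T) carries every
ppm↔Hz conversion, including the 1-Hz evaluation grid (≈0.0025 ppm). An
optional broad MT pool exists but is off by default — one fewer
unconstrained component.

Because the default pools are generic, the simulator's AACID-per-pH
sensitivity (≈2.2 AACID units per pH unit around pH 7) is much steeper
than the mouse-brain calibration slope of 0.25. Absolute calibrated pH on
phantoms is therefore offset from scripted pH; all recovery claims are
made either through the simulator's own AACID–pH curve (known exactly) or
as self-consistency of the linear conversion.

## Phantoms

A phantom is a 2-D grid of disjoint tissue classes (background plus
ellipse/rectangle regions), each with its own intracellular pH and
optionally its own pool system. Per voxel, the spectrum is computed with
that voxel's pH-resolved exchange rates, frequency-shifted by its B0
offset, and scaled by its B1 multiplier; the ±1000 ppm reference frames
carry the (essentially unsaturated) signal the normalization divides by.

* **B0 fields** are low-order polynomial surfaces plus optional Gaussian
  jitter, capped at ±0.3 ppm so the ±0.6 ppm WASSR window always brackets
  the water minimum, and quantized to 0.001 ppm; the quantized field is
  what the data encode and is returned as ground truth. Spectra are cached
  per (class, quantized B0, quantized B1), which is what makes grids
  affordable.
* **Noise** is Rician on magnitude images, v → √((v+g₁)²+g₂²) with
  g ~ N(0, σ²) and σ expressed relative to the unsaturated signal
  (σ = 0.02 ≙ SNR 50). Draws are independent per repeat from streams
  spawned off one master seed; fixed seeds give bit-identical phantoms.
  Subject seed and noise seed are separate so a multi-timepoint scenario
  keeps its B0 field while renewing the noise.

What the generator does **not** emulate: k-space/RARE readout and its
artifacts, motion, partial-volume mixing at region boundaries, spatially
correlated noise, B0 drift between repeats, realistic tissue heterogeneity
(semisolid MT, NOE pools), or any pharmacokinetics — drug effects are
scripted pH steps. Passing tests therefore demonstrate correctness of the
processing chain and statistics under the stated noise model, not
performance on in vivo data.

## Processing

Order of operations: reference-normalize each repeat → average repeats →
spline-fit per voxel → WASSR B0 correction. (Whether averaging precedes
correction is a free choice when B0 is static between repeats, as it is
here.)

* Normalization divides by the mean of a voxel's reference frames; a
  non-positive reference flags the voxel invalid (NaN sentinel plus mask)
  rather than failing the stack.
* The smoothing spline uses generalized cross-validation (GCV) by default
  for noisy data and exact cubic interpolation (`smoothing=0`) for
  noiseless data; a fixed penalty may be passed instead. The continuous
  spectrum is evaluated on a 1-Hz grid snapped inside the sampled domain.
* The B0 estimate is the argmin of the 1-Hz-interpolated WASSR spectrum;
  among minima within 10⁻⁴ of the global one, the candidate nearest 0 ppm
  wins. A minimum at the domain boundary means the water line is not
  bracketed and the voxel is flagged invalid. Sign convention: a voxel
  whose water center appears at +Δ ppm gets shift +Δ and its CEST spectrum
  is read at ω+Δ; the convention is pinned by the round-trip test (AACID
  restored within 2% for |Δ| ≤ 0.12 ppm; estimator bias ≈ 1.5×10⁻⁴ ppm and
  SD ≈ 1×10⁻³ ppm at σ = 0.01 over 500 voxels).
* Mz readouts take the nearest 1-Hz grid point (≤ half a step,
  ≈0.00125 ppm, from the requested frequency) rather than re-fitting a
  local model. Degenerate AACID denominators and out-of-domain readouts
  flag the voxel, never raise out of the map loop.

Two numerical caveats are documented deliberately. First, at WASSR power
the water line is only a few 0.03 ppm sampling steps wide, so cubic
interpolation error on its flanks reaches ~0.1 in z; this does not harm
the argmin (see the bias figures above) but means a pointwise
spline-vs-simulator bound of 5×10⁻³ only holds away from the line (and
everywhere on the much smoother CEST spectrum). Second, GCV shrinks sharp
CEST dips slightly under noise, compressing ΔAACID by roughly 10% at
SNR 50; after inversion through the AACID–pH curve this contributes only
~0.03 pH to the recovery error and is accepted in exchange for
variance reduction.

## ROI analysis and statistics

ROI statistics (mean, SD, SEM = SD/√n over valid voxels), percent change
versus baseline, ΔpH = slope·ΔAACID, tumor volume as voxel count × voxel
volume on the anatomical grid, and ordered time courses are straight
implementations; ROIs come from phantom truth masks (a threshold tool on
the label image exists for demonstration only). Percent changes are
computed per subject and then averaged, matching the repeated-measures
structure of the ANOVA.

The statistics battery mirrors a GraphPad-style analysis of region-mean
values: Shapiro-Wilk normality screening (scipy's implementation), a
two-way fully-within repeated-measures ANOVA in the univariate
decomposition with each effect tested against its own subject-interaction
error term, Greenhouse-Geisser correction always applied (sphericity is
never assumed; ε̂ = tr(M)²/(d·tr(M²)) on the contrast-transformed
covariance, exactly 1 for two-level factors), Tukey post-hoc comparisons
on the studentized-range distribution using the factor×subject mean
square, and a textbook paired t-test. All of it is validated against
pingouin, scipy and frozen `car::Anova` (R, type-III repeated measures)
oracle values to 10⁻⁶. Under a null simulation sized like the cohort
design it serves (10 subjects × 2 sides × 3 sessions), the GG-corrected
time effect rejects at 3–4% for nominal α = 5%; at very small subject
counts (n = 6) the correction is conservative (~1–2%), a known property of
the ε̂ estimator rather than a defect.

## Problem sizes and determinism

Tests and the acceptance script run on deliberately small phantoms
(8×8–12×12 grids, 1–3 repeats, 6-subject cohorts, 500-replicate null
simulations); the processing cost is dominated by per-voxel GCV spline
fits and scales linearly in voxels, so larger grids change runtimes, not
conclusions. Every random quantity descends from an explicit seed
(`numpy.random.SeedSequence` spawning), and the pipeline writes a
provenance log (config hash, package versions, seed) sufficient to re-run
bit-identically.

## Known limitations

* Absolute pH accuracy is not claimed anywhere: the linear calibration is
  taken as given, and the synthetic pools are not fitted to it.
* No B1 correction (a B1 scale exists only as a simulator perturbation),
  no MT-asymmetry analysis, no motion or registration handling, no outlier
  rule (none is specified for the analysis this mirrors), and no DICOM or
  vendor raw-format IO.
* The WASSR estimator is the spline-minimum variant; maximum-symmetry
  center finding is out of scope.
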