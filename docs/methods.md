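# Methods

`mwtomo` implements a complete two-dimensional microwave-tomography chain
for a cylindrical imaging tank: a TM-polarized FDTD forward model with
single-pole Debye dispersion, an acquisition emulator producing multistatic
transmission sweeps with empty-tank calibration, and a distorted Born
iterative method (DBIM) inversion with TwIST and CGLS linear solvers and a
frequency-hopping schedule.  This note records the models, the numerical
choices, and what the synthetic experiments do and do not demonstrate.

## Conventions

Time dependence is `e^{+jωt}`; complex relative permittivity is written
`ε = ε′ − jε″` with `ε″ ≥ 0` for loss; outgoing cylindrical waves are
Hankel functions of the second kind.  Coordinates are tank-centered
Cartesian, meters internally and millimeters in user-facing files.
Antenna 1 sits on the +x axis; numbering proceeds counter-clockwise.

## Dispersive media

All media are single-pole Debye with a static-conductivity term,

    ε(ω) = ε∞ + Δε / (1 + jωτ) − j σ_s / (ω ε0).

`fit_debye` estimates (ε∞, Δε, τ, σ_s) from a tabulated (f, ε′, ε″) curve
by bounded trust-region least squares on the joint real/imaginary misfit,
with a deterministic multi-start over τ ∈ {10, 20, 50, 100} ps because the
fit has known local minima when τ falls outside the sampled band.  With
noise-free data from a Debye medium the fit is exact to < 1e-6; at 1%
multiplicative noise ε∞ (the small term of a large sum) is only
identifiable in ensemble mean, not per draw.

The shipped material library anchors three liquids to measured complex
permittivities at 1.2 GHz: 90% glycerine–water (ε′ = 14.2, ε″ = 13.3),
water (78.6, 4.8) and salt–water at 10 mg/mL (77.5, 30.5).  Only those
anchor values are measured ground truth.  The dispersion *shape* away from
1.2 GHz is a documented assumption chosen as physically plausible Debye
behaviour: the glycerine mixture relaxes slowly (τ = 120 ps, σ_s = 0.1 S/m,
giving ε′ falling from ≈ 25 at DC to ≈ 4 at 3.5 GHz and attenuation rising
with frequency), water uses the textbook τ = 9 ps with σ_s = 0 (the
anchored fit then lands near the textbook ε∞ ≈ 8, Δε ≈ 71), and the salt
mixture adds ionic conductivity σ_s = 1.71 S/m to the water pole — the
value implied by the measured ε″ split, and typical for ~10 g/L NaCl.
Users with measured dispersion curves should fit their own media through
the `DispersionTable` pathway rather than rely on these shapes.

## Geometry and rasterization

The scenario mirrors the experimental rig: concentric 100/200 mm tanks, an
8-antenna ring of 130 mm diameter (a 16-antenna/150 mm variant is one
constructor argument away), a 120 mm reconstruction ring 10 mm inside the
array to keep antenna artifacts out of the unknowns, and 16 mm cylindrical
targets.  The default single target sits 30 mm from the tank center along
the first-quadrant diagonal; the two-target scenario adds the point-mirrored
twin in the third quadrant.  Exact experimental target coordinates are
never available, so recovery experiments use these self-consistent
synthetic positions.

Rasterization is center-in staircase without sub-cell averaging: a cell
takes the target medium iff its center falls inside the disk.  This keeps
the forward and inverse representations identical (blocky 2 mm pixels) at
the cost of a quantized target area (±15% at 2 mm for a 16 mm disk,
converging as dx → 0).  The acrylic tank walls are not modelled; the
entire grid outside targets is homogeneous immersion liquid, as in the
2-D forward model the inversion itself assumes.

## FDTD forward solver

TM-z Yee scheme (Ez, Hx, Hy) with vertical monopoles modelled as soft
line-current sources at the nearest grid cell; the same cells serve as
probes, which makes the discrete system exactly reciprocal.  Debye
dispersion uses one auxiliary polarization state per cell (trapezoidal
ADE); PEC targets are cells whose update coefficients are zeroed.

* Excitation: Gaussian-modulated sine, center 2.0 GHz, envelope width
  0.32 ns, delay 4.5 widths — spectral amplitude at 0.5 and 3.5 GHz stays
  above 10% of peak (validated at run time).
* Time step: 0.95 of the 2-D stability bound dx/(c√2).  A blow-up guard
  raises a divergence error; the resolution precondition requires ≥ 10
  cells per background wavelength at the highest requested frequency.
* Frequency extraction: running DFT of Ez (full raster and probes)
  accumulated over the whole run; the injected current is DFT-ed over the
  same window so field/current transfer ratios are self-consistent.
* Run length: auto-extended in 400-step chunks until the trailing-window
  peak |Ez| falls below 1e-8 of the global peak.  The very lossy immersion
  leaves a slowly decaying quasi-static tail, so this threshold (rather
  than a fixed step count) controls the DFT truncation error (≈ 3e-4
  relative at the weakest probe).  All sources of one sweep are then
  topped up to a common horizon, which restores exact (≈ 1e-14) discrete
  reciprocity.
* Boundaries: 10-cell convolutional PML, cubic grading, κ = 1, α = 0.05.
  The σ_max profile is scaled by √ε_r of the background — the usual
  vacuum-referenced optimum under-absorbs by the factor ε_r in a
  high-permittivity medium.  The grid pads the tank by 40 mm of background
  before the PML for data generation; with the absorber within ~λ/4 of the
  probe ring the 1.0 GHz field shape errs by several percent.  The
  inversion's internal model uses a leaner 12 mm pad and a 1e-7 ring-down
  threshold for speed; model and Jacobian stay mutually consistent, and
  empty-tank calibration absorbs the resulting per-channel factors.

Validation: the scattered field of a 16 mm water cylinder against the
line-source/cylinder eigenfunction series agrees within 5% relative L2
over the probe ring at 1.0/1.5/2.0 GHz on the 1 mm grid, with errors
decreasing from the 2 mm grid.  The analytic series itself is checked
against a brute-force Born volume integral in the weak-contrast limit,
which pins the line-source normalization constant independently.
Raw probe values at dx = 1 mm vs 2 mm can differ by up to ~30% on the
weakest (diametral, ≈ −80 dB) channels — numerical-dissipation differences
integrated over a very lossy path.  This is the documented channel factor
that multiplicative empty-tank calibration exists to cancel.

## Acquisition emulation and calibration

A sweep records complex Ez at every receiving antenna for every
transmitter (n×(n−1) transmission entries per frequency; monostatic
entries are excluded as dominated by unmodelled antenna internals).
Receiver noise is circular complex Gaussian with RMS amplitude
`ref_amp(f) · 10^(floor_dB/20)`, where `ref_amp` is the line-source field
one cell from the source — the same reference used by the dB signal-
strength convention.  Absolute port-calibrated dB levels of a physical VNA
are out of scope; only relative levels and shapes are meaningful.

Calibration is multiplicative per channel:
`E_total_cal = (measured_with / measured_empty) · model_empty`, scattered
= total − model_empty.  It is exactly invariant to any per-channel complex
factor common to the two measured sweeps, and channels whose empty-tank
magnitude falls below a floor are flagged and excluded rather than
divided.

## DBIM inversion

At each iteration, one FDTD run per antenna on the current background
provides both the transmitter fields and (by reciprocity) the background
Green's function; the distorted-Born sensitivity of probe (m, n) to voxel
k is `k0² A_vox E^m(r_k) E^n(r_k) / (−jωμ0 I(ω))`.  A finite-difference
check on a 16-voxel patch agrees to ≈ 0.1% at δε′ = 0.1.  The complex
update equation is solved as a real block system in two unknowns per voxel
— δε′ and δε″ = δσ/(ωε0) at the working frequency — applied to the ε∞ and
σ_s rasters with Δε and τ held at background values (the schedule's maps
are therefore Debye-parameter maps; any report frequency can be evaluated
from them).  ε′ is clamped to [1, 90] and σ ≥ 0.

Solvers.  TwIST uses the standard two-step recursion with soft-threshold
denoising, monotone fallback to a plain IST step, and internal spectral-
norm normalization of the operator.  The regularization weight defaults to
the data-driven rule λ = 0.02·max|Aᵀy| on the normalized system — there is
no canonical published value for these solver knobs in this setting, so the
default was fixed once on the package's own recovery experiments and is
exposed in `TwISTConfig` along with (α, β) = the usual lam1 = 1e-4 recipe.
CGLS regularizes by early stopping (default 30 iterations per linear
solve).

Outer loop.  Frequency hopping 1.2 → 1.5 → 1.8 → 2.1 → 2.4 GHz, 20
iterations per frequency, each hop warm-starting from the previous maps;
within a hop each linear solve starts from a zero update.  Updates are
relaxed by 0.5, and a monotone safeguard rolls back any update that raises
the data residual by more than 2% and halves the step — near the noise/
model-error floor an undamped Born step otherwise oscillates.  The
recorded residual history is that of the accepted backgrounds, hence
non-increasing up to the guard tolerance.

## Synthetic experiments: what they show

The standard battery (see `mwtomo.experiments`, run by
`scripts/acceptance.py`) generates measurement data on a 1 mm grid and
inverts on the 2 mm voxel grid, so the inversion never sees its own
discretization, and adds receiver noise at the −100 dB floor of the
physical VNA.  Problem sizes were chosen so the whole battery runs in
roughly a quarter hour on one core: the recovery experiment is 100 DBIM
iterations × 8 FDTD runs on a ~117² grid.

* A 16 mm target of moderate contrast (ε′ 1.5× the background at 1.2 GHz,
  emulating a weaker glycerine dilution; `moderate_contrast_medium`) is
  localized to within one voxel of its true center and its footprint-mean
  ε′ is recovered to ≈ −9%.  The single-voxel peak value overshoots by
  ~25% — the ℓ1 solution concentrates the recovered contrast in a blob
  smaller than the true disk — which is why the footprint mean is the
  stable quantitative readout.
* Two point-symmetric moderate-contrast targets at a single 2.2 GHz
  frequency are resolved as two distinct maxima at the true locations by
  both TwIST and CGLS.

Known limitations.  These experiments emulate the 2-D line-source world
the inversion assumes; they do not probe 3-D antenna effects, cable
coupling, tank-wall reflections or drift, so passing them bounds
algorithmic correctness, not hardware fidelity.  At the full ~10:1
contrast of water-filled targets, a single-frequency 2.2 GHz inversion is
beyond the distorted-Born regime of this chain: the excess phase through
the cylinder (~4 rad) wraps, and both solvers return two point-symmetric
extrema displaced radially outward by 30–60% of the target radius —
detected and resolved, but not quantitatively localized.  High-contrast
targets need the full low-to-high frequency-hopping schedule, and even
then recovered values saturate well below water's ε′ ≈ 78.  The
reconstruction-quality figures of merit are all defined on the 1.2 GHz
maps evaluated from the reconstructed Debye rasters.
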