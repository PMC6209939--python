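# mwtomo

2-D microwave tomography for a cylindrical immersion tank: an FDTD forward
model with single-pole Debye dispersion, a multistatic acquisition emulator
with empty-tank calibration, and a DBIM inversion with TwIST and CGLS
linear solvers and frequency hopping.

## The problem

Microwave tomography (MWT) estimates the spatial complex-permittivity
distribution `ε(r) = ε′ − jε″` of a region from multistatic scattering
measurements — an antenna ring immersed in a lossy coupling liquid
(here 90% glycerine–water, ε′ = 14.2, ε″ = 13.3 at 1.2 GHz) transmits from
each element in turn and records the transmission at every other element.
Detecting a dielectric discontinuity (a tumour surrogate, a hemorrhage)
then becomes a nonlinear inverse-scattering problem.  This package models
an 8-element printed-monopole ring of 130 mm diameter inside concentric
100/200 mm tanks and reconstructs cylindrical targets from synthetic
sweeps of that rig.

## The method

**Forward model.** Vertical monopoles are treated as 2-D line sources: a
TM-z FDTD solver (Yee grid, auxiliary-differential-equation Debye media,
convolutional PML, Gaussian pulse covering 0.5–3.5 GHz) yields
frequency-domain fields `E(r; ω)` by running DFT.  An analytic
line-source/cylinder eigenfunction series (Bessel–Hankel expansion)
serves as an independent oracle.

**Inversion.** The distorted Born iterative method linearizes scattering
about the current background estimate `ε_b`:

    E_s(rx; tx) ≈ k0² Σ_k A_vox · E_b^tx(r_k) · G_b(rx, r_k) · δε_k

with the background Green's function `G_b` obtained from receiver-sourced
FDTD runs via reciprocity.  Each iteration solves the linear system for
per-voxel updates (δε′, δσ/(ωε0)) with either TwIST (two-step iterative
shrinkage-thresholding, ℓ1 regularization) or CGLS (early stopping), and
updates the background.  A frequency-hopping schedule (1.2, 1.5, 1.8, 2.1,
2.4 GHz; 20 iterations each) uses each lower-frequency reconstruction as
the initial guess for the next — the low-frequency prior that stabilizes
the high-frequency inversion.  Measured sweeps enter the model's frame via
multiplicative empty-tank calibration,
`E_cal = (S_with / S_empty) · E_model_empty`.

## Worked example

Simulate a measurement campaign of a 16 mm water cylinder, calibrate, and
reconstruct (the `mwtomo` console script wraps the same library calls):

```
mwtomo simulate --dx-mm 1 --freqs "1.2e9 1.5e9 1.8e9 2.1e9 2.4e9" \
    --noise-floor-db -100 --seed 7 --out-prefix run
mwtomo reconstruct --data run_target.csv --empty run_empty.csv \
    --scenario scen.json --solver twist --out recon.h5
```

or in Python, using the packaged recovery experiment (1 mm data grid, 2 mm
inversion voxels, −100 dB receiver noise floor):

```python
from mwtomo.experiments import single_target_recovery_experiment
rec = single_target_recovery_experiment(noise_seed=11)
print(f"peak offset      : {rec['peak_offset_m']*1e3:.1f} mm")
print(f"recovered eps'   : {rec['disk_mean_eps1']:.1f} (truth {rec['truth_eps1']:.1f})")
print(f"max residual rise: {rec['residual_max_rel_increase']*100:.1f} %")
```

which prints (about nine minutes on one core):

```
peak offset      : 1.7 mm
recovered eps'   : 19.4 (truth 21.3)
max residual rise: 1.5 %
```

The target — a moderate-contrast dielectric (ε′ 1.5× the glycerine–water
background at 1.2 GHz) 30 mm from the tank center — is localized to within
one 2 mm voxel, its footprint-mean ε′ is recovered to about −9%, and the
per-frequency data residual is non-increasing to within the 2% rollback
guard.  `ReconResult.eps_map(1.2e9)` returns the complex-permittivity
raster evaluated from the reconstructed Debye parameters;
`mwtomo.plotting.plot_recon_map` renders it.

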