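"""Canned validation and parameter-recovery experiments.

These functions define the package's standard self-validation battery:
forward-solver comparison against the analytic cylinder series, reciprocity
on randomized scenes, a finite-difference Jacobian check, linear-solver
oracles, and the single- and two-target reconstruction experiments (data
generated at 1 mm, inverted at 2 mm, so the inversion never sees its own
discretization).  Both the test suite and ``scripts/acceptance.py`` run
them; keeping them here guarantees the two surfaces measure the same thing.
"""

from __future__ import annotations

import numpy as np

from .acquisition import MultistaticDataset, add_noise, calibrate, simulate_dataset
from .forward import SimConfig, analytic_cylinder_fields, line_source_field, run_array
from .inversion import (
    DBIMConfig,
    TwISTConfig,
    cgls_solve,
    dbim_reconstruct,
    twist_solve,
)
from .media import MATERIALS, DebyeMedium, moderate_contrast_medium
from .scenario import (
    CylinderTarget,
    Scenario,
    antenna_positions,
    make_grid,
    rasterize,
)

__all__ = [
    "forward_oracle_experiment",
    "reciprocity_experiment",
    "jacobian_fd_experiment",
    "solver_oracle_experiment",
    "single_target_recovery_experiment",
    "two_target_resolution_experiment",
    "calibration_experiment",
    "counting_experiment",
    "HOP_SCHEDULE",
    "default_recovery_target",
]

HOP_SCHEDULE = (1.2e9, 1.5e9, 1.8e9, 2.1e9, 2.4e9)

# leaner forward settings for the inversion-side model (2 mm voxel grid)
INV_SIM = SimConfig(dx=2e-3, convergence_rtol=1e-7, margin=0.012)
DATA_SIM = SimConfig(dx=1e-3)


def default_recovery_target(center=None, diameter: float = 0.016) -> CylinderTarget:
    """The canonical moderate-contrast cylinder for recovery experiments:
    eps' 1.5x the immersion background (a weaker glycerine dilution)."""
    bg = MATERIALS["glycerine_water_90"]
    if center is None:
        r = 0.030 / np.sqrt(2.0)
        center = (r, r)
    return CylinderTarget(
        center=center, diameter=diameter, medium=moderate_contrast_medium(bg)
    )


def forward_oracle_experiment(freqs=(1.0e9, 1.5e9, 2.0e9), dxs=(2e-3, 1e-3)) -> dict:
    """Relative L2 error of the FDTD scattered field against the analytic
    Bessel-Hankel series over the 8-probe ring, per frequency and grid.

    A 16 mm water cylinder sits at the tank center in the glycerine-water
    immersion; the analytic solution is scaled by the single complex factor
    that best matches the simulated incident field (the line-source
    normalization), so the comparison probes the scattering physics.
    """
    bg = MATERIALS["glycerine_water_90"]
    water = MATERIALS["water"]
    scen = Scenario().with_targets(
        CylinderTarget(center=(0.0, 0.0), diameter=0.016, medium=water)
    )
    ants = antenna_positions(scen)
    out = {}
    for dx in dxs:
        cfg = SimConfig(dx=dx)
        grid = make_grid(scen, dx, margin=cfg.margin)
        props_t = rasterize(scen, grid)
        props_e = rasterize(scen.without_targets(), grid)
        fs_t = run_array(props_t, ants, [0], list(freqs), cfg, store_rasters=False)
        fs_e = run_array(props_e, ants, [0], list(freqs), cfg, store_rasters=False)
        xc, yc = grid.x_centers(), grid.y_centers()
        snap = np.array([[xc[i], yc[j]] for i, j in fs_t.probe_cells])
        src_xy, probes = snap[0], snap[1:]
        for fi, f in enumerate(freqs):
            scat_fdtd = fs_t.probes[0, fi, 1:] - fs_e.probes[0, fi, 1:]
            inc_fdtd = fs_e.probes[0, fi, 1:]
            inc_an = line_source_field(bg.eval(f), f, src_xy, probes)
            c = np.vdot(inc_an, inc_fdtd) / np.vdot(inc_an, inc_an)
            scat_an, _ = analytic_cylinder_fields(
                bg.eval(f), water.eval(f), 0.008, f, src_xy, probes
            )
            out[(dx, f)] = float(
                np.linalg.norm(scat_fdtd - c * scat_an) / np.linalg.norm(c * scat_an)
            )
    return out


def _random_scene(seed: int) -> Scenario:
    rng = np.random.default_rng(seed)
    targets = []
    for _ in range(3):
        ang = rng.uniform(0, 2 * np.pi)
        r = rng.uniform(0, 0.035)
        targets.append(
            CylinderTarget(
                center=(r * np.cos(ang), r * np.sin(ang)),
                diameter=rng.uniform(0.008, 0.018),
                medium=DebyeMedium(
                    eps_inf=rng.uniform(2, 30),
                    delta_eps=rng.uniform(0, 40),
                    tau=rng.uniform(8, 150) * 1e-12,
                    sigma_s=rng.uniform(0, 1.5),
                ),
            )
        )
    return Scenario().with_targets(*targets)


def reciprocity_experiment(seed: int = 7, freqs=(1.5e9, 2.0e9)) -> float:
    """Worst relative tx/rx interchange error on a randomized heterogeneous
    scene simulated on a single grid."""
    ds = simulate_dataset(_random_scene(seed), list(freqs), INV_SIM)
    worst = 0.0
    for (f, tx, rx), v in ds.entries.items():
        if tx < rx:
            w = ds.get(f, rx, tx)
            worst = max(worst, abs(v - w) / abs(v))
    return worst


def jacobian_fd_experiment(freq: float = 1.5e9, d_eps: float = 0.1) -> float:
    """Finite-difference check of the distorted-Born sensitivity matrix on a
    16-voxel patch: relative error of J * d_eps against the actual forward
    probe perturbation."""
    from .inversion import assemble_jacobian

    scen = Scenario()
    grid = make_grid(scen, INV_SIM.dx, margin=INV_SIM.margin)
    props = rasterize(scen, grid)
    ants = antenna_positions(scen)
    fields = run_array(props, ants, list(range(8)), [freq], INV_SIM, store_rasters=True)
    i0, j0 = grid.index_of(0.010, 0.005)
    voxels = np.array([(i0 + a, j0 + b) for a in range(4) for b in range(4)])
    pairs = [(m, n) for m in range(8) for n in range(8) if m != n]
    J = assemble_jacobian(fields, fields, voxels, freq, pairs)
    props2 = props.copy()
    for i, j in voxels:
        props2.eps_inf[i, j] += d_eps
    f2 = run_array(props2, ants, list(range(8)), [freq], INV_SIM, store_rasters=False)
    delta = np.array([f2.probes[m, 0, n] - fields.probes[m, 0, n] for m, n in pairs])
    pred = J @ (d_eps * np.ones(len(voxels)))
    return float(np.linalg.norm(delta - pred) / np.linalg.norm(pred))


def solver_oracle_experiment(seed: int = 0) -> dict:
    """TwIST and CGLS against closed-form/direct oracles."""
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((20, 30))
    y = rng.standard_normal(20)
    x = twist_solve(A, y, TwISTConfig(lambda_reg=1e-12, max_inner_iters=20000, tolerance=0.0))
    x_pinv = np.linalg.pinv(A) @ y
    minnorm_err = float(np.linalg.norm(x - x_pinv) / np.linalg.norm(x_pinv))

    x_scalar = twist_solve(
        np.array([[1.0]]), np.array([3.0]),
        TwISTConfig(lambda_reg=1.0, max_inner_iters=1000, tolerance=0.0),
    )[0]

    A5 = rng.standard_normal((5, 5)) + 5 * np.eye(5)
    y5 = rng.standard_normal(5)
    x5 = cgls_solve(A5, y5, max_iters=200, tolerance=1e-16)
    ref = np.linalg.solve(A5, y5)
    cgls_err = float(np.linalg.norm(x5 - ref) / np.linalg.norm(ref))
    return {
        "twist_minnorm_rel_err": minnorm_err,
        "twist_scalar_solution": float(x_scalar),
        "cgls_direct_rel_err": cgls_err,
    }


def single_target_recovery_experiment(
    noise_seed: int = 11,
    noise_floor_db: float = -100.0,
    datasets: tuple | None = None,
) -> dict:
    """Full-chain parameter recovery of one moderate-contrast 16 mm target.

    Data are generated on a 1 mm grid, perturbed by receiver noise at the
    given floor, calibrated against the 2 mm model frame, and inverted with
    the default frequency-hopping DBIM-TwIST schedule (1.2...2.4 GHz, 20
    iterations each).  ``datasets`` may carry pre-simulated (with, empty,
    model_empty) sweeps to skip the data generation.
    """
    target = default_recovery_target()
    scen = Scenario().with_targets(target)
    sched = list(HOP_SCHEDULE)
    if datasets is None:
        ds_t = simulate_dataset(scen, sched, DATA_SIM)
        ds_e = simulate_dataset(scen.without_targets(), sched, DATA_SIM)
        model_e = simulate_dataset(scen.without_targets(), sched, INV_SIM)
    else:
        ds_t, ds_e, model_e = datasets
    ds_t = add_noise(ds_t, noise_floor_db, seed=noise_seed)
    ds_e = add_noise(ds_e, noise_floor_db, seed=noise_seed + 1)
    cal = calibrate(ds_t, ds_e, model_e)
    cfg = DBIMConfig(freq_schedule=tuple(sched), sim=INV_SIM)
    res = dbim_reconstruct(cal, scen.without_targets(), cfg)

    truth_eps1 = target.medium.eval(1.2e9).real
    peak = res.peak_summary()
    peak_err = float(
        np.hypot(peak["peak_xy_m"][0] - target.center[0], peak["peak_xy_m"][1] - target.center[1])
    )
    disk_mean = res.mean_eps_in_disk(target.center, target.diameter).real
    max_inc = 0.0
    for f in sched:
        r = res.residuals_at(f)
        if len(r) > 1:
            max_inc = max(max_inc, float(np.max(np.diff(r) / r[:-1])))
    return {
        "result": res,
        "target": target,
        "truth_eps1": float(truth_eps1),
        "peak_offset_m": peak_err,
        "peak_eps1": peak["peak_eps1"],
        "disk_mean_eps1": float(disk_mean),
        "disk_mean_rel_err": float(abs(disk_mean - truth_eps1) / truth_eps1),
        "residual_max_rel_increase": max_inc,
    }


def two_target_resolution_experiment(
    freq: float = 2.2e9,
    datasets: tuple | None = None,
    solvers=("twist", "cgls"),
) -> dict:
    """Single-frequency reconstruction of two point-symmetric moderate-
    contrast 16 mm targets with both linear solvers (TwIST vs CGLS
    comparison harness).  Returns, per solver, the two strongest local
    maxima and their distances to the true centers."""
    t1 = default_recovery_target()
    t2 = CylinderTarget(
        center=(-t1.center[0], -t1.center[1]), diameter=t1.diameter, medium=t1.medium
    )
    scen = Scenario(recon_ring_diam=0.100).with_targets(t1, t2)
    if datasets is None:
        ds_t = simulate_dataset(scen, [freq], DATA_SIM)
        ds_e = simulate_dataset(scen.without_targets(), [freq], DATA_SIM)
        model_e = simulate_dataset(scen.without_targets(), [freq], INV_SIM)
    else:
        ds_t, ds_e, model_e = datasets
    cal = calibrate(ds_t, ds_e, model_e)
    centers = [t1.center, t2.center]
    out = {"centers": centers, "solvers": {}}
    for solver in solvers:
        cfg = DBIMConfig(
            freq_schedule=(freq,), recon_ring_diam=0.100, solver=solver, sim=INV_SIM
        )
        res = dbim_reconstruct(cal, scen.without_targets(), cfg)
        peaks = res.local_maxima(freq, min_separation=0.02)[:2]
        # greedy assignment of the two maxima to the two true centers
        dists = []
        used = set()
        for px, py, _ in peaks:
            best = min(
                (k for k in range(2) if k not in used),
                key=lambda k: np.hypot(px - centers[k][0], py - centers[k][1]),
            )
            used.add(best)
            dists.append(float(np.hypot(px - centers[best][0], py - centers[best][1])))
        out["solvers"][solver] = {
            "peaks": peaks,
            "distances_m": dists,
            "result": res,
        }
    return out


def calibration_experiment(ds_with: MultistaticDataset, ds_empty: MultistaticDataset) -> dict:
    """Self-calibration identity error and port-factor scale invariance."""
    cal_a = calibrate(ds_with, ds_empty, ds_empty)
    ident = max(
        abs(cal_a.total[k] - ds_with.entries[k]) / abs(ds_with.entries[k])
        for k in cal_a.total
    )
    factor = 2.7 * np.exp(1.2j)
    cal_b = calibrate(ds_with.scaled(factor), ds_empty.scaled(factor), ds_empty)
    scale_err = max(
        abs(cal_a.total[k] - cal_b.total[k]) / abs(cal_a.total[k]) for k in cal_a.total
    )
    return {"self_calibration_rel_err": float(ident), "scale_invariance_rel_err": float(scale_err)}


def counting_experiment() -> dict:
    """Sweep-size invariants for the 8- and 16-antenna arrays."""
    ds8 = simulate_dataset(Scenario(), list(HOP_SCHEDULE), INV_SIM)
    ds16 = simulate_dataset(
        Scenario(n_antennas=16, array_diam=0.150), [1.5e9], INV_SIM
    )
    return {
        "entries_8ant_5freq": len(ds8),
        "entries_16ant_per_freq": len(ds16),
    }
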