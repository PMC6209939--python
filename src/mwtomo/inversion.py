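"""Distorted Born iterative method (DBIM) with TwIST and CGLS linear solvers.

At each DBIM iteration the nonlinear scattering problem is linearized about
the current background estimate: with background fields ``E_b`` (per
transmitter) and the background Green's function ``G_b`` (obtained from
receiver-sourced runs by reciprocity), the change in the field at receiver
``n`` due to a permittivity perturbation ``d_eps`` in voxel ``k`` is

    d Ez(rx_n; tx_m) = k0^2 A_vox * E_b^m(r_k) * E_b^n(r_k) / (-j omega mu0 I(omega)) * d_eps_k

where ``I(omega)`` is the spectrum of the injected line current.  The
resulting linear system is solved for complex ``d_eps = d_eps' - j d_eps''``
as a real-valued block system in the two unknowns per voxel
(``d_eps'`` and the conductivity-equivalent ``d_eps'' = d_sigma/(omega eps0)``),
and the update is applied to the per-voxel Debye rasters (eps_inf and
sigma_s free; delta_eps and tau held at their background values).  A
frequency-hopping schedule warm-starts each frequency from the previous
one's reconstruction.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.constants import epsilon_0, mu_0

from .acquisition import CalibratedScatteredData, _freq_key
from .forward import DFTFieldSet, SimConfig, run_array
from .scenario import (
    Grid2D,
    PropertyMap,
    Scenario,
    antenna_positions,
    make_grid,
    rasterize,
)

__all__ = [
    "TwISTConfig",
    "DBIMConfig",
    "ReconResult",
    "TwISTDivergenceError",
    "twist_solve",
    "cgls_solve",
    "assemble_jacobian",
    "dbim_reconstruct",
]


# ---------------------------------------------------------------------------
# Linear solvers
# ---------------------------------------------------------------------------


class TwISTDivergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class TwISTConfig:
    """Two-step IST solver parameters.

    ``lam1`` is the assumed ratio of the smallest to largest eigenvalue of
    A^T A, from which the two-step relaxation parameters are derived
    (alpha = 2/(1 + sqrt(1 - rho^2)), beta = 2 alpha/(1 + lam1) with
    rho = (1 - lam1)/(1 + lam1)) unless alpha/beta are given explicitly.
    ``lambda_reg=None`` selects the default data-driven rule
    ``lambda = lambda_rel * max|A^T y|``.
    """

    lambda_reg: float | None = None
    lambda_rel: float = 0.02
    lam1: float = 1e-4
    alpha: float | None = None
    beta: float | None = None
    max_inner_iters: int = 400
    tolerance: float = 1e-6

    def relaxation(self) -> tuple[float, float]:
        if self.alpha is not None and self.beta is not None:
            return self.alpha, self.beta
        rho = (1.0 - self.lam1) / (1.0 + self.lam1)
        alpha = 2.0 / (1.0 + np.sqrt(1.0 - rho**2))
        beta = alpha * 2.0 / (1.0 + self.lam1)
        return alpha, beta


def _soft(x, thr):
    return np.sign(x) * np.maximum(np.abs(x) - thr, 0.0)


def twist_solve(A, y, cfg: TwISTConfig | None = None, x0=None):
    """Solve ``min 1/2 ||y - A x||^2 + lambda ||x||_1`` by monotone TwIST.

    The operator is normalized internally so its spectral norm is <= 1
    (required for IST-type convergence); the reported solution is on the
    original scale.  Raises :class:`TwISTDivergenceError` if the objective
    grows persistently despite the monotone fallback.
    """
    cfg = cfg or TwISTConfig()
    A = np.asarray(A, dtype=float)
    y = np.asarray(y, dtype=float).ravel()

    # normalization: spectral norm via a few power iterations (deterministic)
    s = _spectral_norm(A)
    if s == 0.0:
        return np.zeros(A.shape[1])
    An = A / s
    yn = y / s
    if cfg.lambda_reg is None:
        # data-driven default, expressed in the normalized problem: a fixed
        # fraction of the largest gradient magnitude at x = 0
        lam_n = cfg.lambda_rel * float(np.max(np.abs(An.T @ yn)))
    else:
        lam_n = cfg.lambda_reg / (s * s)

    alpha, beta = cfg.relaxation()
    x_prev = np.zeros(An.shape[1]) if x0 is None else np.asarray(x0, dtype=float).copy()
    r = yn - An @ x_prev
    x_curr = _soft(x_prev + An.T @ r, lam_n)

    def objective(x):
        return 0.5 * np.sum((yn - An @ x) ** 2) + lam_n * np.sum(np.abs(x))

    obj_curr = objective(x_curr)
    best_obj = obj_curr
    growth_count = 0
    for _ in range(cfg.max_inner_iters):
        grad_step = x_curr + An.T @ (yn - An @ x_curr)
        x_twist = (1.0 - alpha) * x_prev + (alpha - beta) * x_curr + beta * _soft(grad_step, lam_n)
        obj_twist = objective(x_twist)
        if obj_twist <= obj_curr:
            x_new, obj_new = x_twist, obj_twist
        else:
            # monotone fallback: plain IST step never increases the objective
            x_new = _soft(grad_step, lam_n)
            obj_new = objective(x_new)
        if obj_new > obj_curr * (1.0 + 1e-10) and obj_new > best_obj * 1.05:
            growth_count += 1
            if growth_count > 10:
                raise TwISTDivergenceError(
                    "TwIST objective is growing; operator normalization "
                    f"(spectral norm scaling {s:.3e}) may be inconsistent"
                )
        best_obj = min(best_obj, obj_new)
        done = obj_curr - obj_new <= cfg.tolerance * max(obj_curr, 1e-300)
        x_prev, x_curr, obj_curr = x_curr, x_new, obj_new
        if done:
            break
    return x_curr


def _spectral_norm(A: np.ndarray, n_iter: int = 60) -> float:
    if A.size == 0:
        return 0.0
    v = np.ones(A.shape[1]) / np.sqrt(A.shape[1])
    s = 0.0
    for _ in range(n_iter):
        w = A.T @ (A @ v)
        nw = np.linalg.norm(w)
        if nw == 0.0:
            return 0.0
        s_new = np.sqrt(nw)
        v = w / nw
        if abs(s_new - s) <= 1e-12 * max(s_new, 1.0):
            s = s_new
            break
        s = s_new
    # 5% safety headroom so the normalized operator norm is surely <= 1
    return s * 1.05


def cgls_solve(A, y, max_iters: int = 200, tolerance: float = 1e-12, x0=None):
    """Conjugate gradient on the normal equations ``A^T A x = A^T y``.

    Early stopping (``max_iters``) is the regularization knob.  Returns the
    iterate when ``||A^T (y - A x)||`` drops below ``tolerance * ||A^T y||``
    or the iteration cap is reached.
    """
    A = np.asarray(A, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    x = np.zeros(A.shape[1]) if x0 is None else np.asarray(x0, float).copy()
    r = y - A @ x
    s = A.T @ r
    p = s.copy()
    gamma = float(s @ s)
    gamma0 = gamma
    if gamma0 == 0.0:
        return x
    for _ in range(max_iters):
        q = A @ p
        qq = float(q @ q)
        if qq == 0.0:
            break
        alpha = gamma / qq
        x += alpha * p
        r -= alpha * q
        s = A.T @ r
        gamma_new = float(s @ s)
        if gamma_new <= tolerance**2 * gamma0:
            break
        p = s + (gamma_new / gamma) * p
        gamma = gamma_new
    return x


# ---------------------------------------------------------------------------
# Jacobian assembly
# ---------------------------------------------------------------------------


def assemble_jacobian(
    background_fields: DFTFieldSet,
    adjoint_fields: DFTFieldSet,
    voxels: np.ndarray,
    freq: float,
    pairs: list,
) -> np.ndarray:
    """Distorted-Born sensitivity matrix, rows = (tx, rx) pairs, cols = voxels.

    ``voxels`` is an (nvox, 2) array of grid indices; ``pairs`` a list of
    (tx, rx) tuples.  Both field sets must be computed on the same grid and
    background: per pair (m, n) and voxel k the entry is

        k0^2 * A_vox * E^m(r_k) * E^n(r_k) / (-j omega mu0 I(omega))

    with E^m from ``background_fields`` (transmitter-sourced) and E^n from
    ``adjoint_fields`` (receiver-sourced; identical runs here since every
    antenna is a transceiver — reciprocity supplies G_b).
    """
    if background_fields.grid != adjoint_fields.grid:
        raise ValueError("background and adjoint fields live on different grids")
    grid = background_fields.grid
    fi_b = int(np.argmin(np.abs(background_fields.freqs - freq)))
    fi_a = int(np.argmin(np.abs(adjoint_fields.freqs - freq)))
    if abs(background_fields.freqs[fi_b] - freq) > 1.0:
        raise ValueError(f"frequency {freq} not present in background fields")
    omega = 2.0 * np.pi * freq
    k0sq = omega**2 / 299792458.0**2
    dA = grid.dx**2
    I_omega = background_fields.source_spectrum[fi_b]
    scale = k0sq * dA / (-1j * omega * mu_0 * I_omega)

    vi = voxels[:, 0]
    vj = voxels[:, 1]
    # cached per-source field samples at the voxel centers
    cache_b = {
        s: background_fields.rasters[background_fields.source_indices.index(s), fi_b][vi, vj]
        for s in background_fields.source_indices
    }
    cache_a = {
        s: adjoint_fields.rasters[adjoint_fields.source_indices.index(s), fi_a][vi, vj]
        for s in adjoint_fields.source_indices
    }
    J = np.empty((len(pairs), len(voxels)), dtype=complex)
    for row, (m, n) in enumerate(pairs):
        J[row] = scale * cache_b[m] * cache_a[n]
    return J


def _real_block(J: np.ndarray) -> np.ndarray:
    """Real block system for d_eps = u' - j u'':  [[Jr, Ji], [Ji, -Jr]]."""
    Jr, Ji = J.real, J.imag
    top = np.hstack([Jr, Ji])
    bot = np.hstack([Ji, -Jr])
    return np.vstack([top, bot])


# ---------------------------------------------------------------------------
# DBIM outer loop
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DBIMConfig:
    """DBIM reconstruction configuration.

    Defaults mirror the experimental protocol: frequency hopping at 1.2,
    1.5, 1.8, 2.1 and 2.4 GHz with 20 iterations per frequency, 2.0 mm
    voxels, and a 120 mm reconstruction ring.
    """

    freq_schedule: tuple = (1.2e9, 1.5e9, 1.8e9, 2.1e9, 2.4e9)
    iters_per_freq: int = 20
    voxel_size: float = 2.0e-3
    recon_ring_diam: float = 0.120
    solver: str = "twist"  # "twist" | "cgls"
    twist: TwISTConfig = field(default_factory=TwISTConfig)
    cgls_iters: int = 30
    sim: SimConfig | None = None
    step_scale: float = 0.5  # relaxation applied to each Born update
    sigma_step_scale: float = 1.0  # extra relaxation on the conductivity unknowns
    # monotone safeguard: an update that raises the data residual by more
    # than this fraction is rolled back and the step halved (0 disables)
    monotone_guard: float = 0.02
    eps1_bounds: tuple = (1.0, 90.0)
    early_exit_rtol: float = 0.0  # e.g. 1e-4 to stop a hop early
    report_freq: float | None = None  # None -> first schedule frequency

    def __post_init__(self) -> None:
        if list(self.freq_schedule) != sorted(self.freq_schedule):
            raise ValueError("freq_schedule must be increasing")
        if self.iters_per_freq < 1:
            raise ValueError("iters_per_freq must be >= 1")
        if self.solver not in ("twist", "cgls"):
            raise ValueError("solver must be 'twist' or 'cgls'")


@dataclass
class ReconResult:
    """DBIM output: per-hop snapshots, final maps, residual history."""

    grid: Grid2D
    voxels: np.ndarray  # (nvox, 2) indices inside the reconstruction ring
    props: PropertyMap  # final background estimate
    hop_snapshots: list  # [(freq, PropertyMap), ...]
    residual_history: list  # [(freq, iteration, residual_norm), ...]
    config: DBIMConfig = None
    report_freq: float = None
    diverged: bool = False
    diagnostics: dict = field(default_factory=dict)

    def eps_map(self, freq: float | None = None) -> np.ndarray:
        """Complex permittivity raster at the report frequency."""
        return self.props.complex_permittivity(freq or self.report_freq)

    def residuals_at(self, freq) -> np.ndarray:
        fk = _freq_key(freq)
        return np.array([r for (f, _, r) in self.residual_history if _freq_key(f) == fk])

    def peak_summary(self, freq: float | None = None) -> dict:
        """Peak recovered eps' location/value inside the reconstruction ring."""
        eps = self.eps_map(freq)
        vi, vj = self.voxels[:, 0], self.voxels[:, 1]
        vals = eps[vi, vj].real
        k = int(np.argmax(vals))
        x = self.grid.x_centers()[vi[k]]
        y = self.grid.y_centers()[vj[k]]
        return {
            "peak_eps1": float(vals[k]),
            "peak_eps2": float(-eps[vi[k], vj[k]].imag),
            "peak_xy_m": (float(x), float(y)),
        }

    def mean_eps_in_disk(self, center, diameter: float, freq: float | None = None) -> complex:
        """Mean recovered permittivity over a disk footprint (a stable
        readout of an extended target's recovered properties)."""
        eps = self.eps_map(freq)
        X, Y = self.grid.meshgrid()
        mask = (X - center[0]) ** 2 + (Y - center[1]) ** 2 <= (diameter / 2.0) ** 2
        return complex(eps[mask].mean())

    def local_maxima(self, freq: float | None = None, min_separation: float = 0.01) -> list:
        """Local maxima of the recovered eps' map inside the reconstruction
        ring, strongest first, suppressing neighbors within min_separation."""
        eps = self.eps_map(freq)
        vi, vj = self.voxels[:, 0], self.voxels[:, 1]
        vals = eps[vi, vj].real
        xs = self.grid.x_centers()
        ys = self.grid.y_centers()
        order = np.argsort(vals)[::-1]
        peaks = []
        for k in order:
            x, y, v = xs[vi[k]], ys[vj[k]], vals[k]
            if any(np.hypot(x - px, y - py) < min_separation for px, py, _ in peaks):
                continue
            peaks.append((float(x), float(y), float(v)))
        return peaks

    def centroid_estimate(self, freq: float | None = None, quantile: float = 0.95) -> tuple:
        """Contrast-weighted centroid of the strongest recovered voxels."""
        eps = self.eps_map(freq)
        vi, vj = self.voxels[:, 0], self.voxels[:, 1]
        contrast = eps[vi, vj].real - np.median(eps[vi, vj].real)
        contrast = np.maximum(contrast, 0.0)
        thr = np.quantile(contrast, quantile)
        w = np.where(contrast >= thr, contrast, 0.0)
        if w.sum() == 0:
            return (0.0, 0.0)
        x = self.grid.x_centers()[vi]
        y = self.grid.y_centers()[vj]
        return (float((w * x).sum() / w.sum()), float((w * y).sum() / w.sum()))


def _ring_voxels(grid: Grid2D, ring_diam: float, pec: np.ndarray) -> np.ndarray:
    X, Y = grid.meshgrid()
    inside = (X**2 + Y**2) <= (ring_diam / 2.0) ** 2
    inside &= ~pec
    idx = np.argwhere(inside)
    return idx


def dbim_reconstruct(
    data: CalibratedScatteredData,
    scenario: Scenario,
    cfg: DBIMConfig | None = None,
    progress: bool = False,
) -> ReconResult:
    """Run the frequency-hopped DBIM reconstruction.

    ``scenario`` is the target-free prior: its homogeneous background
    medium fills the imaging domain at the start of the 1st hop; each later
    hop warm-starts from the previous hop's maps.  Unknowns are the per-
    voxel perturbations of eps' and sigma at the working frequency, applied
    to the eps_inf and sigma_s rasters.
    """
    cfg = cfg or DBIMConfig()
    # inversion-grid forward runs trade a little open-domain fidelity for
    # speed: leaner padding and a slightly looser ring-down threshold than
    # the data-generation defaults
    sim = cfg.sim or SimConfig(dx=cfg.voxel_size, convergence_rtol=1e-7, margin=0.012)
    if abs(sim.dx - cfg.voxel_size) > 1e-12:
        sim = replace(sim, dx=cfg.voxel_size)
    data_freqs = set(data.freqs())
    for f in cfg.freq_schedule:
        if _freq_key(f) not in data_freqs:
            raise ValueError(f"frequency {f/1e9:.2f} GHz missing from calibrated data")

    grid = make_grid(scenario.without_targets(), sim.dx, margin=sim.margin)
    props = rasterize(scenario.without_targets(), grid)
    ants = antenna_positions(scenario)
    n_ant = scenario.n_antennas
    voxels = _ring_voxels(grid, cfg.recon_ring_diam, props.pec)
    vi, vj = voxels[:, 0], voxels[:, 1]
    nvox = len(voxels)

    residual_history = []
    hop_snapshots = []
    diverged = False
    diagnostics = {"solver": cfg.solver, "iters": []}

    try:
        for freq in cfg.freq_schedule:
            omega = 2.0 * np.pi * freq
            keys = data.keys_at(freq)
            pairs = [(tx, rx) for (_, tx, rx) in keys]
            d_total = np.array([data.total[k] for k in keys])
            prev_res = None
            accepted = None  # last accepted background (for the monotone guard)
            step_local = cfg.step_scale
            for it in range(cfg.iters_per_freq):
                t_iter = time.perf_counter()
                fields = run_array(
                    props, ants, list(range(n_ant)), [freq], sim, store_rasters=True
                )
                model = np.array(
                    [fields.probes[tx, 0, rx] for (tx, rx) in pairs], dtype=complex
                )
                r = d_total - model
                res_norm = float(np.linalg.norm(r))
                if (
                    cfg.monotone_guard > 0
                    and prev_res is not None
                    and res_norm > prev_res * (1.0 + cfg.monotone_guard)
                ):
                    # the last update overshot: roll back, damp, try again
                    props = accepted.copy()
                    step_local *= 0.5
                    residual_history.append((freq, it, prev_res))
                    diagnostics["iters"].append(
                        {
                            "freq_hz": float(freq),
                            "iter": it,
                            "residual": prev_res,
                            "rolled_back": True,
                            "step_scale": step_local,
                            "seconds": time.perf_counter() - t_iter,
                        }
                    )
                    continue
                accepted = props.copy()
                res_before = prev_res
                prev_res = res_norm
                residual_history.append((freq, it, res_norm))

                J = assemble_jacobian(fields, fields, voxels, freq, pairs)
                A = _real_block(J)
                y = np.concatenate([r.real, r.imag])
                if cfg.solver == "twist":
                    u = twist_solve(A, y, cfg.twist)
                else:
                    u = cgls_solve(A, y, max_iters=cfg.cgls_iters)
                d_eps1 = step_local * u[:nvox]
                d_eps2 = step_local * cfg.sigma_step_scale * u[nvox:]

                props.eps_inf[vi, vj] = np.clip(
                    props.eps_inf[vi, vj] + d_eps1, cfg.eps1_bounds[0], cfg.eps1_bounds[1]
                )
                props.sigma_s[vi, vj] = np.maximum(
                    props.sigma_s[vi, vj] + omega * epsilon_0 * d_eps2, 0.0
                )
                diagnostics["iters"].append(
                    {
                        "freq_hz": float(freq),
                        "iter": it,
                        "residual": res_norm,
                        "update_norm": float(np.linalg.norm(u)),
                        "seconds": time.perf_counter() - t_iter,
                    }
                )
                if progress:  # pragma: no cover
                    print(
                        f"[dbim] {freq/1e9:.2f} GHz iter {it + 1}/{cfg.iters_per_freq} "
                        f"residual {res_norm:.4e}"
                    )
                if (
                    cfg.early_exit_rtol > 0
                    and res_before is not None
                    and abs(res_before - res_norm) < cfg.early_exit_rtol * res_before
                ):
                    break
            hop_snapshots.append((freq, props.copy()))
    except TwISTDivergenceError as exc:
        warnings.warn(f"DBIM aborted: {exc}; returning partial result", RuntimeWarning)
        diverged = True
        diagnostics["abort"] = str(exc)

    return ReconResult(
        grid=grid,
        voxels=voxels,
        props=props,
        hop_snapshots=hop_snapshots,
        residual_history=residual_history,
        config=cfg,
        report_freq=cfg.report_freq or cfg.freq_schedule[0],
        diverged=diverged,
        diagnostics=diagnostics,
    )
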