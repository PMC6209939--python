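"""Numba time-stepping kernel for the 2-D TM-z FDTD solver.

Yee grid, single-pole Debye media via an auxiliary polarization state per
cell, convolutional PML on all four edges, soft line-current source, and
running DFT accumulation of Ez (full raster and probe cells).

The per-cell update is derived from Ampere's law with a Debye polarization
current:

    eps0 eps_inf dE/dt + sigma_s E + dP/dt = curl H - J_src
    tau dP/dt + P = eps0 delta_eps E

Trapezoidal discretization of the P equation gives
``P^{n+1} = A P^n + B (E^{n+1} + E^n)``; eliminating P^{n+1} from Ampere's
law yields the three-coefficient update
``E^{n+1} = ca E + cp P + cb (curl H - J_src)``.  PEC cells carry
ca = cp = cb = 0 so Ez stays identically zero there.
"""

import numba
import numpy as np

__all__ = ["run_fdtd_kernel"]


@numba.njit(cache=True, fastmath=True)
def run_fdtd_kernel(
    Ez,
    P,
    Hx,
    Hy,
    ca,
    cp,
    cb,
    Apol,
    Bpol,
    chy,  # dt / (mu0 * dx)
    dt_over_mu0,
    dx,
    dt,
    npml,
    be_x,
    ce_x,
    be_y,
    ce_y,
    bh_x,
    ch_x,
    bh_y,
    ch_y,
    psi_ezx,
    psi_ezy,
    psi_hxy,
    psi_hyx,
    src_i,
    src_j,
    s_half,  # source current waveform sampled at (n + 1/2) dt
    inv_dA,
    omegas,
    acc_raster,  # (nf, nx, ny) complex128 (1x1x1 dummy when unused)
    store_raster,
    acc_probe,  # (nf, nprobe) complex128
    probe_i,
    probe_j,
    n_start,
    n_min,
    max_steps,
    chunk,
    rtol,
    blowup_abs,
    peak_in,
):
    """Run the time loop from step ``n_start``; returns
    (n_done, peak, trailing_ratio, status).

    status: 0 = converged, 1 = hit max_steps unconverged, 2 = diverged.
    Passing ``rtol < 0`` disables the convergence stop (used to top up a
    resumed run to a prescribed step count); ``peak_in`` carries the peak
    amplitude across resumed segments.
    """
    nx, ny = Ez.shape
    nf = omegas.shape[0]
    nprobe = probe_i.shape[0]

    peak = peak_in
    chunk_max = 0.0
    trailing_ratio = 1.0
    status = 1
    n_done = n_start

    for n in range(n_start, max_steps):
        # CPML psi for H (uses Ez at time n): y strips act on Hx, x on Hy
        for j in range(npml):
            for i in range(nx):
                d = (Ez[i, j + 1] - Ez[i, j]) / dx
                psi_hxy[i, j] = bh_y[j] * psi_hxy[i, j] + ch_y[j] * d
        for j in range(ny - 1 - npml, ny - 1):
            for i in range(nx):
                d = (Ez[i, j + 1] - Ez[i, j]) / dx
                psi_hxy[i, j] = bh_y[j] * psi_hxy[i, j] + ch_y[j] * d
        for i in range(npml):
            for j in range(ny):
                d = (Ez[i + 1, j] - Ez[i, j]) / dx
                psi_hyx[i, j] = bh_x[i] * psi_hyx[i, j] + ch_x[i] * d
        for i in range(nx - 1 - npml, nx - 1):
            for j in range(ny):
                d = (Ez[i + 1, j] - Ez[i, j]) / dx
                psi_hyx[i, j] = bh_x[i] * psi_hyx[i, j] + ch_x[i] * d

        # ---- H update (leapfrog half step) --------------------------------
        for i in range(nx):
            for j in range(ny - 1):
                Hx[i, j] -= chy * (Ez[i, j + 1] - Ez[i, j]) + dt_over_mu0 * psi_hxy[i, j]
        for i in range(nx - 1):
            for j in range(ny):
                Hy[i, j] += chy * (Ez[i + 1, j] - Ez[i, j]) + dt_over_mu0 * psi_hyx[i, j]

        # CPML psi for Ez (uses fresh H)
        for i in range(1, npml + 1):
            for j in range(1, ny - 1):
                d = (Hy[i, j] - Hy[i - 1, j]) / dx
                psi_ezx[i, j] = be_x[i] * psi_ezx[i, j] + ce_x[i] * d
        for i in range(nx - 1 - npml, nx - 1):
            for j in range(1, ny - 1):
                d = (Hy[i, j] - Hy[i - 1, j]) / dx
                psi_ezx[i, j] = be_x[i] * psi_ezx[i, j] + ce_x[i] * d
        for j in range(1, npml + 1):
            for i in range(1, nx - 1):
                d = (Hx[i, j] - Hx[i, j - 1]) / dx
                psi_ezy[i, j] = be_y[j] * psi_ezy[i, j] + ce_y[j] * d
        for j in range(ny - 1 - npml, ny - 1):
            for i in range(1, nx - 1):
                d = (Hx[i, j] - Hx[i, j - 1]) / dx
                psi_ezy[i, j] = be_y[j] * psi_ezy[i, j] + ce_y[j] * d

        # ---- Ez + polarization update (single fused pass) -----------------
        src = s_half[n] * inv_dA
        cmax = 0.0
        for i in range(1, nx - 1):
            for j in range(1, ny - 1):
                curl = (
                    (Hy[i, j] - Hy[i - 1, j]) - (Hx[i, j] - Hx[i, j - 1])
                ) / dx + psi_ezx[i, j] + psi_ezy[i, j]
                if i == src_i and j == src_j:
                    curl -= src
                ez_old = Ez[i, j]
                ez_new = ca[i, j] * ez_old + cp[i, j] * P[i, j] + cb[i, j] * curl
                P[i, j] = Apol[i, j] * P[i, j] + Bpol[i, j] * (ez_new + ez_old)
                Ez[i, j] = ez_new
                a = abs(ez_new)
                if a > cmax:
                    cmax = a

        if cmax > blowup_abs:
            status = 2
            n_done = n + 1
            break

        # ---- running DFT ---------------------------------------------------
        t = (n + 1) * dt
        for f in range(nf):
            c = np.cos(omegas[f] * t)
            s = np.sin(omegas[f] * t)
            ph = complex(c, -s) * dt
            if store_raster:
                for i in range(nx):
                    for j in range(ny):
                        acc_raster[f, i, j] += Ez[i, j] * ph
            for p in range(nprobe):
                acc_probe[f, p] += Ez[probe_i[p], probe_j[p]] * ph

        if cmax > peak:
            peak = cmax
        if cmax > chunk_max:
            chunk_max = cmax
        n_done = n + 1
        if rtol >= 0.0 and (n + 1) % chunk == 0:
            if peak > 0.0:
                trailing_ratio = chunk_max / peak
            if n + 1 >= n_min and (peak == 0.0 or trailing_ratio < rtol):
                status = 0
                break
            chunk_max = 0.0

    return n_done, peak, trailing_ratio, status
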