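"""2-D TM-z FDTD forward solver and analytic cylinder-scattering oracle.

Vertical monopoles are modelled as soft line-current sources on a 2-D grid
(Ez, Hx, Hy).  Media are single-pole Debye (auxiliary-differential-equation
formulation); a 10-cell convolutional PML terminates the grid.  Fields are
extracted in the frequency domain by a running DFT accumulated over the
whole run; the run is auto-extended until the trailing-window field
amplitude falls below a configurable fraction of the peak.

Phasor convention: ``e^{+j omega t}``; outgoing waves are Hankel functions
of the second kind; lossy permittivity is ``eps' - j eps''``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.constants import c as c0
from scipy.constants import epsilon_0, mu_0
from scipy.special import h2vp, hankel2, jv, jvp

from ._fdtd_kernel import run_fdtd_kernel
from .scenario import Grid2D, PropertyMap

__all__ = [
    "PulseSpec",
    "SimConfig",
    "DFTFieldSet",
    "FDTDDivergenceError",
    "run_fdtd",
    "run_array",
    "analytic_cylinder_fields",
    "line_source_field",
    "received_signal_strength",
]


class FDTDDivergenceError(RuntimeError):
    """Field magnitude blew up: the configuration is unstable (dt too large)."""


@dataclass(frozen=True)
class PulseSpec:
    """Gaussian-modulated sine excitation.

    Defaults give usable spectral content across 0.5-3.5 GHz: center 2.0 GHz
    and an envelope width such that the band-edge spectral amplitude is at
    least 10% of the peak.
    """

    center_freq: float = 2.0e9
    width: float = 0.32e-9  # Gaussian envelope 1/e half-width, seconds
    delay: float | None = None  # None -> 4.5 * width
    amplitude: float = 1.0

    @property
    def t0(self) -> float:
        return 4.5 * self.width if self.delay is None else self.delay

    def waveform(self, t):
        """Source current I(t) in arbitrary units."""
        t = np.asarray(t, dtype=float)
        u = (t - self.t0) / self.width
        return self.amplitude * np.exp(-(u**2)) * np.sin(
            2.0 * np.pi * self.center_freq * (t - self.t0)
        )

    def spectral_amplitude(self, freq) -> np.ndarray:
        """|FT| of the envelope-shifted carrier (analytic, up to a constant)."""
        f = np.asarray(freq, dtype=float)
        return self.amplitude * np.exp(-((np.pi * (f - self.center_freq) * self.width) ** 2))

    def validate_band(self, f_lo: float = 0.5e9, f_hi: float = 3.5e9) -> None:
        peak = self.spectral_amplitude(self.center_freq)
        for f in (f_lo, f_hi):
            if self.spectral_amplitude(f) < 0.1 * peak:
                raise ValueError(
                    f"pulse spectral amplitude at {f/1e9:.2f} GHz is below 10% of peak; "
                    "widen the band by shortening `width`"
                )


@dataclass(frozen=True)
class SimConfig:
    """FDTD run configuration.

    courant is the fraction of the 2-D stability limit dx/(c sqrt(2)) used
    for the time step.  The run length is first estimated from the pulse
    delay plus a few domain crossings at the slowest background speed, then
    extended in chunks until the trailing-window peak |Ez| falls below
    ``convergence_rtol`` times the global peak.
    """

    dx: float = 2.0e-3
    courant: float = 0.95
    pml_cells: int = 10
    margin: float = 0.040  # background padding beyond the tank wall, m
    pulse: PulseSpec = field(default_factory=PulseSpec)
    convergence_rtol: float = 1e-8
    chunk_steps: int = 400
    max_steps: int = 60000
    crossings: float = 3.0  # initial run-length estimate, in domain crossings
    min_cells_per_wavelength: float = 10.0

    @property
    def dt(self) -> float:
        return self.courant * self.dx / (c0 * np.sqrt(2.0))


@dataclass
class DFTFieldSet:
    """Frequency-domain Ez fields from one or more FDTD source runs.

    ``rasters[s, f]`` is the complex Ez map for source index ``s`` at
    ``freqs[f]``; ``probes[s, f, p]`` the Ez value at probe cell ``p``
    (nearest grid cell to each antenna position).  ``source_spectrum[f]`` is
    the DFT of the injected current waveform over the same run, so that
    field/current transfer ratios are internally consistent.
    """

    grid: Grid2D
    freqs: np.ndarray
    source_indices: list
    probes_xy: np.ndarray  # (nprobe, 2) meters
    probe_cells: np.ndarray  # (nprobe, 2) int
    probes: np.ndarray  # (nsrc, nf, nprobe) complex
    rasters: np.ndarray | None  # (nsrc, nf, nx, ny) complex or None
    source_spectrum: np.ndarray  # (nf,) complex
    converged: np.ndarray  # (nsrc,) bool
    n_steps: np.ndarray  # (nsrc,) int
    config: SimConfig = None

    def probe_value(self, source_index, freq, probe_index) -> complex:
        s = self.source_indices.index(source_index)
        f = int(np.argmin(np.abs(self.freqs - freq)))
        if abs(self.freqs[f] - freq) > 1.0:
            raise KeyError(f"frequency {freq} not in field set")
        return complex(self.probes[s, f, probe_index])

    def raster(self, source_index, freq) -> np.ndarray:
        if self.rasters is None:
            raise ValueError("rasters were not stored for this run")
        s = self.source_indices.index(source_index)
        f = int(np.argmin(np.abs(self.freqs - freq)))
        if abs(self.freqs[f] - freq) > 1.0:
            raise KeyError(f"frequency {freq} not in field set")
        return self.rasters[s, f]


def _cpml_coeffs(n: int, npml: int, dx: float, dt: float, eps_edge: float, half: bool):
    """1-D CPML b/c coefficient profiles along one axis.

    Cubic-graded sigma with the standard optimal maximum scaled by the edge
    refractive index; linearly graded kappa-free (kappa = 1) with a small
    alpha for late-time stability.
    """
    m = 3.0
    eta0 = np.sqrt(mu_0 / epsilon_0)
    # the optimal profile maximum scales with the medium's refractive index
    # (wave impedance eta0/sqrt(eps) drops, so sigma must rise to keep the
    # one-way attenuation exponent ~0.8 * n_cells)
    sigma_max = 0.8 * (m + 1.0) * np.sqrt(eps_edge) / (eta0 * dx)
    a_max = 0.05
    b = np.zeros(n)
    c = np.zeros(n)
    for i in range(n):
        # depth into the PML, normalized to (0, 1]; 0 outside
        off = 0.5 if half else 0.0
        d_lo = (npml - i - off) / npml
        d_hi = (i + off - (n - 1 - npml)) / npml
        d = max(d_lo, d_hi)
        if d <= 0.0:
            continue
        d = min(d, 1.0)
        sig = sigma_max * d**m
        a = a_max * (1.0 - d)
        b[i] = np.exp(-(sig + a) * dt / epsilon_0)
        c[i] = sig * (b[i] - 1.0) / (sig + a) if (sig + a) > 0 else 0.0
    return b, c


def _debye_coeffs(props: PropertyMap, dt: float):
    """Per-cell update coefficients (ca, cp, cb, Apol, Bpol)."""
    tau = props.tau
    th = dt / (2.0 * tau)
    A = (1.0 - th) / (1.0 + th)
    B = epsilon_0 * props.delta_eps * th / (1.0 + th)
    denom = epsilon_0 * props.eps_inf / dt + props.sigma_s / 2.0 + B / dt
    ca = (epsilon_0 * props.eps_inf / dt - props.sigma_s / 2.0 - B / dt) / denom
    cp = (1.0 - A) / (dt * denom)
    cb = 1.0 / denom
    pec = props.pec
    for arr in (ca, cp, cb):
        arr[pec] = 0.0
    return ca, cp, cb, A, B


def _check_resolution(props: PropertyMap, freqs, config: SimConfig) -> None:
    # background permittivity from a corner cell (rasterization fills the
    # region outside the tank with the homogeneous background)
    from .media import DebyeMedium

    bg = DebyeMedium(
        eps_inf=float(props.eps_inf[0, 0]),
        delta_eps=float(props.delta_eps[0, 0]),
        tau=float(props.tau[0, 0]),
        sigma_s=float(props.sigma_s[0, 0]),
    )
    fmax = float(np.max(freqs))
    n_bg = np.sqrt(max(1.0, bg.eval(fmax).real))
    lam = c0 / (fmax * n_bg)
    if lam / config.dx < config.min_cells_per_wavelength:
        raise ValueError(
            f"grid under-resolves the background wavelength at {fmax/1e9:.2f} GHz: "
            f"{lam/config.dx:.1f} cells/wavelength < {config.min_cells_per_wavelength}"
        )


def run_fdtd(
    props: PropertyMap,
    antennas_xy: np.ndarray,
    source_index: int,
    freqs,
    config: SimConfig | None = None,
    store_rasters: bool = True,
) -> DFTFieldSet:
    """Run one line-source FDTD simulation and return its DFT fields.

    ``antennas_xy`` are all antenna positions (m); the source is placed at
    ``antennas_xy[source_index]`` and every antenna cell is probed.
    """
    fs = run_array(props, antennas_xy, [source_index], freqs, config, store_rasters)
    return fs


def run_array(
    props: PropertyMap,
    antennas_xy: np.ndarray,
    source_indices,
    freqs,
    config: SimConfig | None = None,
    store_rasters: bool = True,
) -> DFTFieldSet:
    """Run one FDTD simulation per requested source on a shared grid."""
    config = config or SimConfig()
    grid = props.grid
    if abs(grid.dx - config.dx) > 1e-12:
        config = replace(config, dx=grid.dx)
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    _check_resolution(props, freqs, config)
    config.pulse.validate_band()

    dt = config.dt
    dx = grid.dx
    nx, ny = grid.shape
    npml = config.pml_cells
    omegas = 2.0 * np.pi * freqs

    antennas_xy = np.asarray(antennas_xy, dtype=float)
    probe_cells = np.array([grid.index_of(x, y) for x, y in antennas_xy], dtype=np.int64)

    ca, cp, cb, Apol, Bpol = _debye_coeffs(props, dt)
    eps_edge = float(props.eps_inf[0, 0] + 0.5 * props.delta_eps[0, 0])
    be_x, ce_x = _cpml_coeffs(nx, npml, dx, dt, eps_edge, half=False)
    be_y, ce_y = _cpml_coeffs(ny, npml, dx, dt, eps_edge, half=False)
    bh_x, ch_x = _cpml_coeffs(nx - 1, npml, dx, dt, eps_edge, half=True)
    bh_y, ch_y = _cpml_coeffs(ny - 1, npml, dx, dt, eps_edge, half=True)

    # initial run-length estimate: pulse delay + a few domain crossings at
    # the slowest in-band background speed
    f_lo = min(0.5e9, float(np.min(freqs)))
    from .media import DebyeMedium

    bg = DebyeMedium(
        eps_inf=float(props.eps_inf[0, 0]),
        delta_eps=float(props.delta_eps[0, 0]),
        tau=float(props.tau[0, 0]),
        sigma_s=float(props.sigma_s[0, 0]),
    )
    n_slow = np.sqrt(max(1.0, bg.eval(f_lo).real))
    diag = np.hypot(nx * dx, ny * dx)
    t_est = config.pulse.t0 + config.crossings * diag * n_slow / c0
    n_min = int(np.ceil(t_est / dt))
    chunk = config.chunk_steps
    n_min = ((n_min + chunk - 1) // chunk) * chunk

    times_half = (np.arange(config.max_steps) + 0.5) * dt
    s_half = config.pulse.waveform(times_half)

    nf = len(freqs)
    nprobe = len(antennas_xy)
    nsrc = len(source_indices)
    probes = np.zeros((nsrc, nf, nprobe), dtype=np.complex128)
    rasters = (
        np.zeros((nsrc, nf, nx, ny), dtype=np.complex128) if store_rasters else None
    )
    converged = np.zeros(nsrc, dtype=bool)
    n_steps = np.zeros(nsrc, dtype=np.int64)
    blowup = 1e12 * max(config.pulse.amplitude, 1e-300)

    pi = probe_cells[:, 0].copy()
    pj = probe_cells[:, 1].copy()
    states = []
    peaks = np.zeros(nsrc)
    for s_idx, src in enumerate(source_indices):
        si, sj = probe_cells[src]
        state = {
            "Ez": np.zeros((nx, ny)),
            "P": np.zeros((nx, ny)),
            "Hx": np.zeros((nx, ny - 1)),
            "Hy": np.zeros((nx - 1, ny)),
            "psi_ezx": np.zeros((nx, ny)),
            "psi_ezy": np.zeros((nx, ny)),
            "psi_hxy": np.zeros((nx, ny - 1)),
            "psi_hyx": np.zeros((nx - 1, ny)),
        }
        states.append(state)
        acc_r = rasters[s_idx] if store_rasters else np.zeros((1, 1, 1), dtype=np.complex128)
        acc_p = probes[s_idx]

        n_done, peak, trailing, status = run_fdtd_kernel(
            state["Ez"], state["P"], state["Hx"], state["Hy"],
            ca, cp, cb, Apol, Bpol,
            dt / (mu_0 * dx), dt / mu_0, dx, dt, npml,
            be_x, ce_x, be_y, ce_y, bh_x, ch_x, bh_y, ch_y,
            state["psi_ezx"], state["psi_ezy"], state["psi_hxy"], state["psi_hyx"],
            si, sj, s_half, 1.0 / (dx * dx),
            omegas, acc_r, store_rasters, acc_p, pi, pj,
            0, n_min, config.max_steps, chunk, config.convergence_rtol, blowup, 0.0,
        )
        if status == 2:
            raise FDTDDivergenceError(
                f"FDTD field blow-up at step {n_done} (peak {peak:.3e}); "
                "reduce the time step (courant) or check material parameters"
            )
        if status == 1 and peak > 0.0:
            warnings.warn(
                f"FDTD run for source {src} stopped at max_steps={config.max_steps} "
                f"with trailing/peak amplitude {trailing:.2e} above "
                f"{config.convergence_rtol:.1e}; DFT fields may not be fully converged",
                RuntimeWarning,
                stacklevel=2,
            )
        converged[s_idx] = status == 0 or peak == 0.0
        n_steps[s_idx] = n_done
        peaks[s_idx] = peak

    # Top up every run to the longest executed horizon so all sources share
    # one time window: the discrete system is then exactly reciprocal and
    # DFT values of (tx, rx) and (rx, tx) agree to rounding error.
    n_sync = int(np.max(n_steps)) if nsrc else 0
    for s_idx, src in enumerate(source_indices):
        if n_steps[s_idx] >= n_sync:
            continue
        si, sj = probe_cells[src]
        state = states[s_idx]
        acc_r = rasters[s_idx] if store_rasters else np.zeros((1, 1, 1), dtype=np.complex128)
        run_fdtd_kernel(
            state["Ez"], state["P"], state["Hx"], state["Hy"],
            ca, cp, cb, Apol, Bpol,
            dt / (mu_0 * dx), dt / mu_0, dx, dt, npml,
            be_x, ce_x, be_y, ce_y, bh_x, ch_x, bh_y, ch_y,
            state["psi_ezx"], state["psi_ezy"], state["psi_hxy"], state["psi_hyx"],
            si, sj, s_half, 1.0 / (dx * dx),
            omegas, acc_r, store_rasters, probes[s_idx], pi, pj,
            int(n_steps[s_idx]), n_sync, n_sync, chunk, -1.0, blowup, peaks[s_idx],
        )
        n_steps[s_idx] = n_sync
    del states

    # DFT of the injected current over the longest executed run (the source
    # waveform is zero well before any run ends, so any run's horizon works)
    n_ref = int(np.max(n_steps)) if nsrc else 0
    spec = np.zeros(nf, dtype=np.complex128)
    if n_ref > 0:
        th = times_half[:n_ref]
        sh = s_half[:n_ref]
        for fi, om in enumerate(omegas):
            spec[fi] = np.sum(sh * np.exp(-1j * om * th)) * dt

    return DFTFieldSet(
        grid=grid,
        freqs=freqs,
        source_indices=list(source_indices),
        probes_xy=antennas_xy,
        probe_cells=probe_cells,
        probes=probes,
        rasters=rasters,
        source_spectrum=spec,
        converged=converged,
        n_steps=n_steps,
        config=config,
    )


# ---------------------------------------------------------------------------
# Analytic line-source + circular-cylinder series oracle
# ---------------------------------------------------------------------------


def _wavenumber(eps_complex: complex, freq: float) -> complex:
    """k = omega sqrt(eps)/c with the decaying branch (Im k <= 0)."""
    k = 2.0 * np.pi * freq * np.sqrt(complex(eps_complex)) / c0
    if k.imag > 0:
        k = -k
    return k


def line_source_field(eps_b: complex, freq: float, source_xy, probe_xy, current: complex = 1.0):
    """Ez of a line current I in a homogeneous medium: -(omega mu0 / 4) I H0^(2)(k rho)."""
    omega = 2.0 * np.pi * freq
    k = _wavenumber(eps_b, freq)
    probe_xy = np.atleast_2d(np.asarray(probe_xy, dtype=float))
    rho = np.hypot(probe_xy[:, 0] - source_xy[0], probe_xy[:, 1] - source_xy[1])
    return -(omega * mu_0 / 4.0) * current * hankel2(0, k * rho)


def _auto_order(k_b: complex, k_c, a: float) -> int:
    x = abs(k_b) * a
    if k_c is not None:
        x = max(x, abs(k_c) * a)
    return int(np.ceil(x + 6.0 * x ** (1.0 / 3.0) + 12.0))


def analytic_cylinder_fields(
    eps_b: complex,
    eps_c,  # complex permittivity of the cylinder, or the string "PEC"
    radius: float,
    freq: float,
    source_xy,
    probes_xy,
    n_terms: int | None = None,
    current: complex = 1.0,
):
    """Eigenfunction-series scattering of a line source by a circular cylinder.

    The cylinder is centered at the origin; source and probes must lie
    outside it.  Returns ``(scattered, total)`` complex Ez arrays at the
    probes.  TM polarization: Ez and dEz/dr continuous across the boundary
    (PEC: Ez = 0 on the surface).
    """
    source_xy = np.asarray(source_xy, dtype=float)
    probes_xy = np.atleast_2d(np.asarray(probes_xy, dtype=float))
    r_s = np.hypot(*source_xy)
    if r_s <= radius:
        raise ValueError("source must lie outside the cylinder")
    r_p = np.hypot(probes_xy[:, 0], probes_xy[:, 1])
    if np.any(r_p <= radius):
        raise ValueError("probes inside the cylinder are not supported")

    omega = 2.0 * np.pi * freq
    k_b = _wavenumber(eps_b, freq)
    is_pec = isinstance(eps_c, str) and eps_c.upper() == "PEC"
    k_c = None if is_pec else _wavenumber(complex(eps_c), freq)

    if n_terms is None:
        n_terms = _auto_order(k_b, k_c, radius)

    phi_s = np.arctan2(source_xy[1], source_xy[0])
    phi_p = np.arctan2(probes_xy[:, 1], probes_xy[:, 0])
    amp = -(omega * mu_0 / 4.0) * current

    xb = k_b * radius
    scattered = np.zeros(len(probes_xy), dtype=complex)
    for n in range(-n_terms, n_terms + 1):
        if is_pec:
            an = -jv(n, xb) / hankel2(n, xb)
        else:
            xc = k_c * radius
            num = k_c * jvp(n, xc) * jv(n, xb) - k_b * jv(n, xc) * jvp(n, xb)
            den = k_c * jvp(n, xc) * hankel2(n, xb) - k_b * jv(n, xc) * h2vp(n, xb)
            an = -num / den
        scattered += (
            an
            * hankel2(n, k_b * r_s)
            * hankel2(n, k_b * r_p)
            * np.exp(1j * n * (phi_p - phi_s))
        )
    scattered *= amp
    incident = line_source_field(eps_b, freq, source_xy, probes_xy, current)
    return scattered, incident + scattered


# ---------------------------------------------------------------------------
# Received signal strength
# ---------------------------------------------------------------------------


def received_signal_strength(dataset, tx: int, freq: float, ref: float | None = None):
    """Per-receiver signal strength in dB for one transmitter and frequency.

    ``20 log10(|value| / ref)``.  For a :class:`MultistaticDataset` the
    reference defaults to the dataset's recorded per-frequency source
    reference amplitude (the line-source field one cell from the source in
    the homogeneous background); pass ``ref`` explicitly to override.

    Returns ``(rx_ids, strength_db)`` sorted by receiver id.
    """
    entries = dataset.at_freq_tx(freq, tx)  # {rx: complex}
    if not entries:
        raise KeyError(f"no entries for tx={tx} at {freq/1e9:.3f} GHz")
    if ref is None:
        ref = dataset.reference_amplitude(freq)
    rx_ids = np.array(sorted(entries.keys()))
    vals = np.array([entries[r] for r in rx_ids])
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(np.abs(vals) / ref)
    return rx_ids, db
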