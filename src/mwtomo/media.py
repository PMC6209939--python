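"""Single-pole Debye dispersive media: evaluation, fitting, and a material library.

Conventions (fixed package-wide)
--------------------------------
Time dependence ``e^{+j omega t}``; complex relative permittivity is written
``eps = eps' - j eps''`` with ``eps'' >= 0`` for lossy media.  The single-pole
Debye law with a static-conductivity term is

    eps(omega) = eps_inf + delta_eps / (1 + j omega tau) - j sigma_s / (omega eps0)

where ``eps_inf`` is the optical (infinite-frequency) relative permittivity,
``delta_eps`` the dispersion strength, ``tau`` the relaxation time in seconds
and ``sigma_s`` the static conductivity in S/m.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.constants import epsilon_0
from scipy.optimize import least_squares

__all__ = [
    "DebyeMedium",
    "DispersionTable",
    "DebyeFitResult",
    "eval_debye",
    "fit_debye",
    "sigma_from_eps2",
    "eps2_from_sigma",
    "MATERIALS",
    "load_material_library",
    "save_material_library",
]


@dataclass(frozen=True)
class DebyeMedium:
    """Single-pole Debye medium.

    Parameters
    ----------
    eps_inf : float
        Relative permittivity at infinite frequency (>= 1).
    delta_eps : float
        Dispersion strength (static minus optical permittivity, >= 0).
    tau : float
        Relaxation time in seconds (> 0).
    sigma_s : float
        Static conductivity in S/m (>= 0).
    """

    eps_inf: float
    delta_eps: float = 0.0
    tau: float = 1e-11
    sigma_s: float = 0.0

    def __post_init__(self) -> None:
        if not self.eps_inf >= 1.0:
            raise ValueError(f"eps_inf must be >= 1, got {self.eps_inf}")
        if not self.delta_eps >= 0.0:
            raise ValueError(f"delta_eps must be >= 0, got {self.delta_eps}")
        if not self.tau > 0.0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if not self.sigma_s >= 0.0:
            raise ValueError(f"sigma_s must be >= 0, got {self.sigma_s}")

    def eval(self, freq):
        """Complex relative permittivity ``eps' - j eps''`` at ``freq`` (Hz)."""
        return eval_debye(self, freq)

    def to_dict(self) -> dict:
        return {
            "eps_inf": self.eps_inf,
            "delta_eps": self.delta_eps,
            "tau": self.tau,
            "sigma_s": self.sigma_s,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DebyeMedium":
        return cls(
            eps_inf=float(d["eps_inf"]),
            delta_eps=float(d.get("delta_eps", 0.0)),
            tau=float(d.get("tau", 1e-11)),
            sigma_s=float(d.get("sigma_s", 0.0)),
        )


def eval_debye(medium: DebyeMedium, freq):
    """Evaluate a single-pole Debye medium at frequency ``freq`` (Hz).

    Returns the complex relative permittivity ``eps' - j eps''``.  ``freq``
    may be a scalar or array; all entries must be positive.
    """
    f = np.asarray(freq, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be positive")
    omega = 2.0 * np.pi * f
    eps = (
        medium.eps_inf
        + medium.delta_eps / (1.0 + 1j * omega * medium.tau)
        - 1j * medium.sigma_s / (omega * epsilon_0)
    )
    eps = np.asarray(eps)
    return eps if eps.ndim else complex(eps)


def sigma_from_eps2(eps2, freq):
    """Convert loss factor eps'' to an equivalent conductivity (S/m).

    ``sigma = omega * eps0 * eps''`` — the bridge between a conductivity
    axis and the ``eps' - j eps''`` loss convention.
    """
    eps2 = np.asarray(eps2, dtype=float)
    f = np.asarray(freq, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be positive")
    if np.any(eps2 < 0):
        raise ValueError("eps'' must be non-negative")
    out = 2.0 * np.pi * f * epsilon_0 * eps2
    return out if out.ndim else float(out)


def eps2_from_sigma(sigma, freq):
    """Inverse of :func:`sigma_from_eps2`: ``eps'' = sigma / (omega eps0)``."""
    sigma = np.asarray(sigma, dtype=float)
    f = np.asarray(freq, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be positive")
    if np.any(sigma < 0):
        raise ValueError("conductivity must be non-negative")
    out = sigma / (2.0 * np.pi * f * epsilon_0)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class DispersionTable:
    """Tabulated complex permittivity ``eps' - j eps''`` versus frequency.

    ``freqs`` must be strictly increasing; the loss convention is positive
    ``eps''`` for loss.
    """

    freqs: np.ndarray
    eps_complex: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        e = np.asarray(self.eps_complex, dtype=complex)
        if f.shape != e.shape or f.ndim != 1:
            raise ValueError("freqs and eps_complex must be 1-D arrays of equal length")
        if np.any(np.diff(f) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(f <= 0):
            raise ValueError("freqs must be positive")
        if np.any(e.real < 1.0):
            raise ValueError("eps' must be >= 1")
        if np.any(-e.imag < -1e-12):
            raise ValueError("eps'' must be >= 0 (loss convention eps' - j eps'')")
        object.__setattr__(self, "freqs", f)
        object.__setattr__(self, "eps_complex", e)

    def __len__(self) -> int:
        return len(self.freqs)

    @classmethod
    def from_csv(cls, path) -> "DispersionTable":
        """Read a ``freq_hz,eps1,eps2`` CSV (comma or tab delimited)."""
        df = pd.read_csv(path, sep=None, engine="python")
        required = {"freq_hz", "eps1", "eps2"}
        if not required.issubset(df.columns):
            raise ValueError(f"dispersion CSV must have columns {sorted(required)}")
        return cls(
            freqs=df["freq_hz"].to_numpy(float),
            eps_complex=df["eps1"].to_numpy(float) - 1j * df["eps2"].to_numpy(float),
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "freq_hz": self.freqs,
                "eps1": self.eps_complex.real,
                "eps2": -self.eps_complex.imag,
            }
        ).to_csv(path, index=False)


@dataclass
class DebyeFitResult:
    """Fit diagnostics returned alongside the fitted medium."""

    medium: DebyeMedium
    residuals: np.ndarray  # complex misfit per table point
    residual_norm: float
    converged: bool
    message: str = ""


class DebyeFitError(RuntimeError):
    """Raised when the Debye fit cannot be performed or did not converge."""


# Deterministic multi-start grid over the relaxation time: the Debye fit has
# known local minima when tau is far outside the sampled band.
_TAU_STARTS_PS = (10.0, 20.0, 50.0, 100.0)


def fit_debye(
    table: DispersionTable,
    weights: np.ndarray | None = None,
) -> tuple[DebyeMedium, DebyeFitResult]:
    """Fit a single-pole Debye medium to a dispersion table.

    Bounded nonlinear least squares on (eps_inf, delta_eps, tau, sigma_s) with
    a deterministic multi-start over tau; the best start wins.  Real and
    imaginary parts of the tabulated permittivity are fitted jointly.

    Parameters
    ----------
    table : DispersionTable
        At least 3 points, spanning at least one octave in frequency.
    weights : array, optional
        Per-point non-negative weights (default: uniform).

    Returns
    -------
    (DebyeMedium, DebyeFitResult)

    Raises
    ------
    DebyeFitError
        Fewer than 3 points, insufficient frequency span, or non-convergence.
    """
    if len(table) < 3:
        raise DebyeFitError("Debye fit needs at least 3 table points")
    if table.freqs[-1] / table.freqs[0] < 2.0:
        raise DebyeFitError("Debye fit needs a table spanning at least one octave")
    w = np.ones(len(table)) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != table.freqs.shape or np.any(w < 0):
        raise DebyeFitError("weights must be non-negative, one per table point")

    f = table.freqs
    target = table.eps_complex
    scale = max(1.0, float(np.max(np.abs(target))))

    def residual(p):
        m = DebyeMedium(eps_inf=p[0], delta_eps=p[1], tau=p[2], sigma_s=p[3])
        r = (eval_debye(m, f) - target) * w / scale
        return np.concatenate([r.real, r.imag])

    lo = [1.0, 0.0, 1e-13, 0.0]
    hi = [200.0, 200.0, 1e-9, 50.0]
    eps1_hi = float(np.max(target.real))
    eps1_lo = float(np.min(target.real))
    best = None
    for tau0_ps in _TAU_STARTS_PS:
        x0 = [
            max(1.0, eps1_lo * 0.8),
            max(1e-3, eps1_hi - eps1_lo),
            tau0_ps * 1e-12,
            max(1e-4, sigma_from_eps2(max(0.0, -target.imag[0]), f[0])),
        ]
        sol = least_squares(
            residual,
            x0,
            bounds=(lo, hi),
            method="trf",
            x_scale=[10.0, 10.0, 1e-11, 0.5],
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    assert best is not None
    if not best.success:
        raise DebyeFitError(f"Debye fit did not converge: {best.message}")

    medium = DebyeMedium(
        eps_inf=float(best.x[0]),
        delta_eps=float(best.x[1]),
        tau=float(best.x[2]),
        sigma_s=float(best.x[3]),
    )
    res = eval_debye(medium, f) - target
    result = DebyeFitResult(
        medium=medium,
        residuals=res,
        residual_norm=float(np.linalg.norm(res)),
        converged=bool(best.success),
        message=str(best.message),
    )
    return medium, result


def _anchored_debye(freq: float, eps1: float, eps2: float, tau: float, sigma_s: float) -> DebyeMedium:
    """Construct a Debye medium that reproduces (eps1, eps2) exactly at ``freq``.

    The relaxation time and static conductivity are prescribed; eps_inf and
    delta_eps are solved from the two anchor equations.
    """
    omega = 2.0 * np.pi * freq
    x = omega * tau
    # eps'' = delta_eps * x / (1 + x^2) + sigma_s/(omega eps0)
    eps2_pole = eps2 - sigma_s / (omega * epsilon_0)
    if eps2_pole < 0:
        raise ValueError("sigma_s alone exceeds the anchored eps''")
    delta_eps = eps2_pole * (1.0 + x * x) / x
    eps_inf = eps1 - delta_eps / (1.0 + x * x)
    return DebyeMedium(eps_inf=eps_inf, delta_eps=delta_eps, tau=tau, sigma_s=sigma_s)


def _build_materials() -> dict[str, DebyeMedium]:
    """Shipped material library.

    The 1.2 GHz complex permittivities are measured anchor values:
    90% glycerine-water eps'=14.2, eps''=13.3; water eps'=78.6, eps''=4.8;
    salt-water (10 mg/mL) eps'=77.5, eps''=30.5.  The dispersion *shape*
    away from 1.2 GHz (relaxation time, conductivity split) is a plausible
    Debye assumption, not a measured curve: glycerine-rich mixtures relax
    slowly (~100 ps class) with a sizeable ionic-conduction floor, water
    relaxes at ~9 ps with negligible static conductivity, and dissolved salt
    adds ionic conductivity without moving the relaxation time much.
    """
    lib = {
        "glycerine_water_90": _anchored_debye(
            1.2e9, 14.2, 13.3, tau=120e-12, sigma_s=0.10
        ),
        "water": _anchored_debye(1.2e9, 78.6, 4.8, tau=9e-12, sigma_s=0.0),
        "salt_water_10mgml": _anchored_debye(1.2e9, 77.5, 30.5, tau=9e-12, sigma_s=1.71),
        "vacuum": DebyeMedium(eps_inf=1.0),
    }
    return lib


MATERIALS: dict[str, DebyeMedium] = _build_materials()


def moderate_contrast_medium(
    background: DebyeMedium,
    eps1_ratio: float = 1.5,
    pole_scale: float = 1.3,
    anchor_freq: float = 1.2e9,
) -> DebyeMedium:
    """A moderate-contrast dielectric target medium, emulating a weaker
    glycerine dilution: the Debye pole strength is scaled by ``pole_scale``
    (raising the loss mildly along with the dispersion) and eps_inf is set
    so that eps' at ``anchor_freq`` is exactly ``eps1_ratio`` times the
    background's.  Same relaxation time and static conductivity as the
    background."""
    x = 2.0 * np.pi * anchor_freq * background.tau
    de = background.delta_eps * pole_scale
    eps1_target = eps1_ratio * eval_debye(background, anchor_freq).real
    eps_inf = eps1_target - de / (1.0 + x * x)
    return DebyeMedium(
        eps_inf=eps_inf, delta_eps=de, tau=background.tau, sigma_s=background.sigma_s
    )


def save_material_library(path, library: dict[str, DebyeMedium] | None = None) -> None:
    """Write a material library as a JSON document keyed by material name."""
    library = MATERIALS if library is None else library
    doc = {name: m.to_dict() for name, m in library.items()}
    Path(path).write_text(json.dumps(doc, indent=2))


def load_material_library(path) -> dict[str, DebyeMedium]:
    doc = json.loads(Path(path).read_text())
    return {name: DebyeMedium.from_dict(d) for name, d in doc.items()}
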