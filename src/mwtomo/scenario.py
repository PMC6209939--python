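"""Imaging geometry: tanks, antenna ring, cylindrical targets, grids, rasters.

Coordinates are tank-centered Cartesian, meters internally (user-facing JSON
uses millimeters).  Antenna 1 sits on the +x axis and numbering proceeds
counter-clockwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.constants import c as c0

from .media import MATERIALS, DebyeMedium

__all__ = [
    "PEC",
    "CylinderTarget",
    "Scenario",
    "Grid2D",
    "PropertyMap",
    "antenna_positions",
    "suggest_num_antennas",
    "rasterize",
    "make_grid",
]


class _PECMarker:
    """Sentinel marking a perfect-electric-conductor target."""

    def __repr__(self) -> str:  # pragma: no cover
        return "PEC"


PEC = _PECMarker()


@dataclass(frozen=True)
class CylinderTarget:
    """Infinite dielectric (or PEC) cylinder, axis normal to the imaging plane."""

    center: tuple[float, float]  # m, tank-centered
    diameter: float  # m
    medium: DebyeMedium | _PECMarker

    def __post_init__(self) -> None:
        if not self.diameter > 0:
            raise ValueError("target diameter must be positive")

    @property
    def is_pec(self) -> bool:
        return isinstance(self.medium, _PECMarker)


@dataclass(frozen=True)
class Scenario:
    """Tank + antenna-ring + target geometry with a background immersion medium.

    Defaults mirror the experimental rig: concentric 100/200 mm tanks, an
    8-antenna ring of 130 mm diameter, a 120 mm reconstruction ring, and 90%
    glycerine-water immersion.
    """

    tank_inner_diam: float = 0.100
    tank_outer_diam: float = 0.200
    array_diam: float = 0.130
    n_antennas: int = 8
    background: DebyeMedium = field(
        default_factory=lambda: MATERIALS["glycerine_water_90"]
    )
    targets: tuple[CylinderTarget, ...] = ()
    recon_ring_diam: float = 0.120
    antenna_angles: tuple[float, ...] | None = None  # radians; None = even spacing

    def __post_init__(self) -> None:
        if self.n_antennas < 2:
            raise ValueError("need at least 2 antennas")
        if not self.array_diam < self.tank_outer_diam:
            raise ValueError("antenna ring must fit inside the outer tank")
        if not self.recon_ring_diam < self.array_diam:
            raise ValueError("reconstruction ring must lie inside the antenna ring")
        if self.antenna_angles is not None and len(self.antenna_angles) != self.n_antennas:
            raise ValueError("antenna_angles length must equal n_antennas")
        object.__setattr__(self, "targets", tuple(self.targets))
        r_ring = self.recon_ring_diam / 2.0
        for t in self.targets:
            if np.hypot(*t.center) + t.diameter / 2.0 > r_ring + 1e-12:
                raise ValueError(
                    f"target at {t.center} extends outside the reconstruction ring"
                )

    def with_targets(self, *targets: CylinderTarget) -> "Scenario":
        return replace(self, targets=tuple(targets))

    def without_targets(self) -> "Scenario":
        return replace(self, targets=())

    # -- JSON serialization (mm in files, m in memory) -----------------------

    def to_dict(self) -> dict:
        def medium_doc(m):
            if isinstance(m, _PECMarker):
                return "PEC"
            for name, lib in MATERIALS.items():
                if lib == m:
                    return name
            return m.to_dict()

        return {
            "schema": "mwtomo/scenario/1",
            "tank_inner_diam_mm": self.tank_inner_diam * 1e3,
            "tank_outer_diam_mm": self.tank_outer_diam * 1e3,
            "array_diam_mm": self.array_diam * 1e3,
            "n_antennas": self.n_antennas,
            "recon_ring_diam_mm": self.recon_ring_diam * 1e3,
            "background": medium_doc(self.background),
            "antenna_angles_deg": None
            if self.antenna_angles is None
            else [np.degrees(a) for a in self.antenna_angles],
            "targets": [
                {
                    "center_mm": [t.center[0] * 1e3, t.center[1] * 1e3],
                    "diameter_mm": t.diameter * 1e3,
                    "medium": medium_doc(t.medium),
                }
                for t in self.targets
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        def medium_from(doc):
            if doc == "PEC":
                return PEC
            if isinstance(doc, str):
                return MATERIALS[doc]
            return DebyeMedium.from_dict(doc)

        angles = d.get("antenna_angles_deg")
        return cls(
            tank_inner_diam=d["tank_inner_diam_mm"] / 1e3,
            tank_outer_diam=d["tank_outer_diam_mm"] / 1e3,
            array_diam=d["array_diam_mm"] / 1e3,
            n_antennas=int(d["n_antennas"]),
            recon_ring_diam=d["recon_ring_diam_mm"] / 1e3,
            background=medium_from(d["background"]),
            antenna_angles=None if angles is None else tuple(np.radians(a) for a in angles),
            targets=tuple(
                CylinderTarget(
                    center=(t["center_mm"][0] / 1e3, t["center_mm"][1] / 1e3),
                    diameter=t["diameter_mm"] / 1e3,
                    medium=medium_from(t["medium"]),
                )
                for t in d.get("targets", ())
            ),
        )

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path) -> "Scenario":
        return cls.from_dict(json.loads(Path(path).read_text()))


def default_single_target(
    medium: DebyeMedium | _PECMarker = None, diameter: float = 0.016
) -> CylinderTarget:
    """The default off-center target: 16 mm cylinder, 30 mm from the tank
    center along the first-quadrant diagonal (configurable convention)."""
    if medium is None:
        medium = MATERIALS["water"]
    r = 0.030 / np.sqrt(2.0)
    return CylinderTarget(center=(r, r), diameter=diameter, medium=medium)


def symmetric_pair(
    medium: DebyeMedium | _PECMarker = None, diameter: float = 0.016
) -> tuple[CylinderTarget, CylinderTarget]:
    """Two identical targets placed point-symmetrically about the tank center
    (first and third quadrants)."""
    t1 = default_single_target(medium, diameter)
    t2 = CylinderTarget(
        center=(-t1.center[0], -t1.center[1]), diameter=diameter, medium=t1.medium
    )
    return t1, t2


def antenna_positions(scenario: Scenario) -> np.ndarray:
    """Antenna (x, y) positions in meters, shape (n_antennas, 2).

    Points lie on the circle of diameter ``array_diam``; antenna 1 at angle 0
    (+x axis), numbering counter-clockwise, unless explicit angles override.
    """
    r = scenario.array_diam / 2.0
    if scenario.antenna_angles is not None:
        ang = np.asarray(scenario.antenna_angles, dtype=float)
    else:
        ang = 2.0 * np.pi * np.arange(scenario.n_antennas) / scenario.n_antennas
    return np.column_stack([r * np.cos(ang), r * np.sin(ang)])


def suggest_num_antennas(background: DebyeMedium, freq: float, imaging_radius: float) -> int:
    """Degrees-of-freedom antenna count ``ceil(2 beta a)``.

    ``beta`` is the real wavenumber ``2 pi f sqrt(eps') / c`` in the
    background (real part of the permittivity; the loss part does not add
    spatial degrees of freedom) and ``a`` the imaging-domain radius.
    A minimum of 1 is returned in the degenerate small-domain limit.
    """
    if freq <= 0 or imaging_radius <= 0:
        raise ValueError("freq and imaging_radius must be positive")
    eps1 = background.eval(freq).real
    beta = 2.0 * np.pi * freq * np.sqrt(eps1) / c0
    return max(1, int(np.ceil(2.0 * beta * imaging_radius)))


@dataclass(frozen=True)
class Grid2D:
    """Uniform square-cell grid; ``origin`` is the center of cell (0, 0)."""

    nx: int
    ny: int
    dx: float
    origin: tuple[float, float]

    def __post_init__(self) -> None:
        if self.nx < 8 or self.ny < 8:
            raise ValueError("grid must be at least 8x8")
        if not self.dx > 0:
            raise ValueError("dx must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nx, self.ny)

    def x_centers(self) -> np.ndarray:
        return self.origin[0] + self.dx * np.arange(self.nx)

    def y_centers(self) -> np.ndarray:
        return self.origin[1] + self.dx * np.arange(self.ny)

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.x_centers(), self.y_centers(), indexing="ij")

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """Nearest cell index to physical point (x, y)."""
        i = int(round((x - self.origin[0]) / self.dx))
        j = int(round((y - self.origin[1]) / self.dx))
        if not (0 <= i < self.nx and 0 <= j < self.ny):
            raise ValueError(f"point ({x}, {y}) outside grid")
        return i, j


def make_grid(scenario: Scenario, dx: float, margin: float = 0.040) -> Grid2D:
    """Tank-covering grid centered on the tank, cell size ``dx``.

    ``margin`` of background padding is added beyond the outer tank wall.
    The absorbing boundary layer occupies the outermost cells, so a generous
    margin keeps it well clear of the antenna ring; within a wavelength of
    the ring it would otherwise perturb the low-frequency fields.
    """
    half = scenario.tank_outer_diam / 2.0 + margin
    n = 2 * int(np.ceil(half / dx)) + 1  # odd: a cell center at the tank center
    origin = (-(n - 1) / 2.0 * dx, -(n - 1) / 2.0 * dx)
    return Grid2D(nx=n, ny=n, dx=dx, origin=origin)


@dataclass
class PropertyMap:
    """Per-cell single-pole-Debye rasters plus a PEC mask on a ``Grid2D``."""

    grid: Grid2D
    eps_inf: np.ndarray
    delta_eps: np.ndarray
    tau: np.ndarray
    sigma_s: np.ndarray
    pec: np.ndarray  # bool

    def __post_init__(self) -> None:
        shape = self.grid.shape
        for name in ("eps_inf", "delta_eps", "tau", "sigma_s", "pec"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"raster {name} shape {arr.shape} != grid {shape}")

    def copy(self) -> "PropertyMap":
        return PropertyMap(
            grid=self.grid,
            eps_inf=self.eps_inf.copy(),
            delta_eps=self.delta_eps.copy(),
            tau=self.tau.copy(),
            sigma_s=self.sigma_s.copy(),
            pec=self.pec.copy(),
        )

    def complex_permittivity(self, freq: float) -> np.ndarray:
        """Per-cell eps' - j eps'' at ``freq`` (PEC cells returned as NaN)."""
        from scipy.constants import epsilon_0

        omega = 2.0 * np.pi * freq
        eps = (
            self.eps_inf
            + self.delta_eps / (1.0 + 1j * omega * self.tau)
            - 1j * self.sigma_s / (omega * epsilon_0)
        )
        eps = eps.astype(complex)
        eps[self.pec] = np.nan
        return eps


def uniform_property_map(grid: Grid2D, medium: DebyeMedium) -> PropertyMap:
    shape = grid.shape
    return PropertyMap(
        grid=grid,
        eps_inf=np.full(shape, medium.eps_inf),
        delta_eps=np.full(shape, medium.delta_eps),
        tau=np.full(shape, medium.tau),
        sigma_s=np.full(shape, medium.sigma_s),
        pec=np.zeros(shape, dtype=bool),
    )


def rasterize(scenario: Scenario, grid: Grid2D) -> PropertyMap:
    """Staircase-rasterize the scenario onto ``grid``.

    Cells whose centers fall inside a target disk take the target medium
    (center-in/center-out, no sub-cell averaging — consistent with the blocky
    inversion pixels); everything else is the homogeneous background.  The
    acrylic tank walls are not modelled as a dielectric layer.
    """
    half_extent_x = grid.origin[0] + grid.dx * (grid.nx - 1)
    if (
        grid.origin[0] > -scenario.tank_outer_diam / 2
        or half_extent_x < scenario.tank_outer_diam / 2
    ):
        raise ValueError("grid does not cover the tank interior")
    pm = uniform_property_map(grid, scenario.background)
    X, Y = grid.meshgrid()
    r_wall = scenario.tank_inner_diam / 2.0
    for t in scenario.targets:
        if np.hypot(*t.center) + t.diameter / 2.0 > r_wall + 1e-12:
            raise ValueError(f"target at {t.center} overlaps the inner tank wall")
        mask = (X - t.center[0]) ** 2 + (Y - t.center[1]) ** 2 <= (t.diameter / 2.0) ** 2
        if t.is_pec:
            pm.pec[mask] = True
        else:
            m = t.medium
            pm.eps_inf[mask] = m.eps_inf
            pm.delta_eps[mask] = m.delta_eps
            pm.tau[mask] = m.tau
            pm.sigma_s[mask] = m.sigma_s
    return pm
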