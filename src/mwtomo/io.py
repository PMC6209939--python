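"""HDF5 and CSV persistence for field sets and reconstruction results."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .forward import DFTFieldSet, SimConfig
from .inversion import ReconResult
from .scenario import Grid2D, PropertyMap

__all__ = [
    "save_fieldset",
    "load_fieldset",
    "save_recon_result",
    "load_recon_maps",
    "probe_traces_to_csv",
    "raster_to_csv",
]


def _grid_attrs(g, grid: Grid2D) -> None:
    g.attrs["nx"] = grid.nx
    g.attrs["ny"] = grid.ny
    g.attrs["dx_m"] = grid.dx
    g.attrs["origin_m"] = grid.origin


def _grid_from_attrs(g) -> Grid2D:
    return Grid2D(
        nx=int(g.attrs["nx"]),
        ny=int(g.attrs["ny"]),
        dx=float(g.attrs["dx_m"]),
        origin=tuple(g.attrs["origin_m"]),
    )


def save_fieldset(path, fs: DFTFieldSet) -> None:
    with h5py.File(path, "w") as h:
        _grid_attrs(h, fs.grid)
        h.create_dataset("freqs_hz", data=fs.freqs)
        h.create_dataset("source_indices", data=np.asarray(fs.source_indices))
        h.create_dataset("probes_xy_m", data=fs.probes_xy)
        h.create_dataset("probe_cells", data=fs.probe_cells)
        h.create_dataset("probes", data=fs.probes)
        if fs.rasters is not None:
            h.create_dataset("rasters", data=fs.rasters, compression="gzip")
        h.create_dataset("source_spectrum", data=fs.source_spectrum)
        h.create_dataset("converged", data=fs.converged)
        h.create_dataset("n_steps", data=fs.n_steps)


def load_fieldset(path) -> DFTFieldSet:
    with h5py.File(path, "r") as h:
        return DFTFieldSet(
            grid=_grid_from_attrs(h),
            freqs=h["freqs_hz"][:],
            source_indices=[int(s) for s in h["source_indices"][:]],
            probes_xy=h["probes_xy_m"][:],
            probe_cells=h["probe_cells"][:],
            probes=h["probes"][:],
            rasters=h["rasters"][:] if "rasters" in h else None,
            source_spectrum=h["source_spectrum"][:],
            converged=h["converged"][:],
            n_steps=h["n_steps"][:],
            config=SimConfig(dx=float(h.attrs["dx_m"])),
        )


def save_recon_result(path, result: ReconResult) -> None:
    """Persist maps + residual trace (HDF5)."""
    with h5py.File(path, "w") as h:
        _grid_attrs(h, result.grid)
        h.attrs["report_freq_hz"] = result.report_freq
        h.attrs["diverged"] = result.diverged
        h.create_dataset("voxels", data=result.voxels)
        for name in ("eps_inf", "delta_eps", "tau", "sigma_s"):
            h.create_dataset(f"maps/{name}", data=getattr(result.props, name))
        h.create_dataset("maps/pec", data=result.props.pec.astype(np.uint8))
        eps = result.eps_map()
        h.create_dataset("maps/eps_report", data=eps)
        rh = np.array(
            [(f, i, r) for (f, i, r) in result.residual_history], dtype=float
        ).reshape(-1, 3)
        h.create_dataset("residual_history", data=rh)
        for hop_i, (f, pm) in enumerate(result.hop_snapshots):
            grp = h.create_group(f"hops/{hop_i}")
            grp.attrs["freq_hz"] = f
            grp.create_dataset("eps_inf", data=pm.eps_inf)
            grp.create_dataset("sigma_s", data=pm.sigma_s)


def load_recon_maps(path) -> dict:
    with h5py.File(path, "r") as h:
        out = {
            "grid": _grid_from_attrs(h),
            "report_freq_hz": float(h.attrs["report_freq_hz"]),
            "eps_report": h["maps/eps_report"][:],
            "eps_inf": h["maps/eps_inf"][:],
            "sigma_s": h["maps/sigma_s"][:],
            "residual_history": h["residual_history"][:],
        }
    return out


def probe_traces_to_csv(path, fs: DFTFieldSet) -> None:
    rows = []
    for s_pos, src in enumerate(fs.source_indices):
        for fi, f in enumerate(fs.freqs):
            for p in range(fs.probes.shape[2]):
                v = fs.probes[s_pos, fi, p]
                rows.append((f, src, p, v.real, v.imag))
    pd.DataFrame(rows, columns=["freq_hz", "tx", "rx", "re", "im"]).to_csv(
        path, index=False, float_format="%.17g"
    )


def raster_to_csv(path, raster: np.ndarray) -> None:
    """Flat CSV dump of a 2-D raster (row index i, column index j, value)."""
    r = np.asarray(raster)
    ii, jj = np.meshgrid(np.arange(r.shape[0]), np.arange(r.shape[1]), indexing="ij")
    cols = {"i": ii.ravel(), "j": jj.ravel()}
    if np.iscomplexobj(r):
        cols["re"] = r.real.ravel()
        cols["im"] = r.imag.ravel()
    else:
        cols["value"] = r.ravel()
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")
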