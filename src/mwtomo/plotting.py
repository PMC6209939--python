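"""Signal-strength curves and reconstruction-map figures.

Figures are secondary artifacts; every plot also writes its numbers as a
CSV twin, which is the machine-checkable surface.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .forward import received_signal_strength

__all__ = ["plot_curves", "plot_difference_curves", "plot_recon_map"]


def plot_curves(datasets: dict, tx: int, freqs, out_png, out_csv=None):
    """Received signal strength vs receiver number, one curve per
    (dataset label, frequency).

    ``datasets`` maps label -> MultistaticDataset.  Returns the DataFrame of
    plotted numbers (also written to ``out_csv`` when given).
    """
    rows = []
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for label, ds in datasets.items():
        for f in np.atleast_1d(freqs):
            rx, db = received_signal_strength(ds, tx, f)
            ax.plot(rx + 1, db, marker="o", label=f"{label} @ {f/1e9:.1f} GHz")
            rows.extend(
                {"dataset": label, "freq_hz": float(f), "tx": tx, "rx": int(r), "strength_db": float(d)}
                for r, d in zip(rx, db)
            )
    ax.set_xlabel("receiver number")
    ax.set_ylabel("received signal strength (dB)")
    ax.legend(fontsize=8)
    ax.grid(alpha=0.3)
    fig.tight_layout()
    fig.savefig(out_png, dpi=150)
    plt.close(fig)
    df = pd.DataFrame(rows)
    if out_csv:
        df.to_csv(out_csv, index=False)
    return df


def plot_difference_curves(ds_empty, ds_target, tx: int, freqs, out_png, out_csv=None):
    """Difference in dB (no target - with target) vs receiver number.

    Positive values mean the received signal is reduced by the target.
    """
    rows = []
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for f in np.atleast_1d(freqs):
        rx_e, db_e = received_signal_strength(ds_empty, tx, f)
        rx_t, db_t = received_signal_strength(ds_target, tx, f)
        if not np.array_equal(rx_e, rx_t):
            raise ValueError("datasets have different receiver sets")
        diff = db_e - db_t
        ax.plot(rx_e + 1, diff, marker="s", label=f"{f/1e9:.1f} GHz")
        rows.extend(
            {"freq_hz": float(f), "tx": tx, "rx": int(r), "difference_db": float(d)}
            for r, d in zip(rx_e, diff)
        )
    ax.set_xlabel("receiver number")
    ax.set_ylabel("difference, no target - with target (dB)")
    ax.legend(fontsize=8)
    ax.grid(alpha=0.3)
    fig.tight_layout()
    fig.savefig(out_png, dpi=150)
    plt.close(fig)
    df = pd.DataFrame(rows)
    if out_csv:
        df.to_csv(out_csv, index=False)
    return df


def plot_recon_map(result, out_png, freq=None):
    """Real/imaginary permittivity maps of a reconstruction result."""
    eps = result.eps_map(freq)
    grid = result.grid
    extent = [
        grid.origin[0] * 1e3,
        (grid.origin[0] + grid.dx * (grid.nx - 1)) * 1e3,
        grid.origin[1] * 1e3,
        (grid.origin[1] + grid.dx * (grid.ny - 1)) * 1e3,
    ]
    fig, axes = plt.subplots(1, 2, figsize=(10, 4.2))
    for ax, data, title in (
        (axes[0], eps.real, "eps'"),
        (axes[1], -eps.imag, "eps''"),
    ):
        im = ax.imshow(data.T, origin="lower", extent=extent, cmap="viridis")
        ax.set_title(title)
        ax.set_xlabel("x (mm)")
        ax.set_ylabel("y (mm)")
        fig.colorbar(im, ax=ax, shrink=0.85)
    fig.tight_layout()
    fig.savefig(out_png, dpi=150)
    plt.close(fig)
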