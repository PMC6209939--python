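"""Multistatic measurement emulation and empty-tank calibration.

A measurement campaign is a complete tx-by-rx transmission sweep of the
antenna ring at a set of frequencies, once for the target-free ("empty
tank") configuration and once with targets.  Monostatic (tx == rx) entries
are not recorded: reflection data is dominated by antenna internals the
2-D model cannot express.

Calibration is the standard multiplicative empty-tank procedure: per
(freq, tx, rx) channel,

    E_total_cal = (measured_with / measured_empty) * model_empty
    E_scat_cal  = E_total_cal - model_empty

which cancels any per-channel complex port factor common to the two
measured sweeps.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.constants import mu_0

from .forward import SimConfig, line_source_field, run_array
from .scenario import Scenario, antenna_positions, make_grid, rasterize

__all__ = [
    "MultistaticDataset",
    "CalibratedScatteredData",
    "simulate_dataset",
    "add_noise",
    "calibrate",
    "BAND",
]

BAND = (0.5e9, 3.5e9)  # valid acquisition band, Hz


def _freq_key(freq: float) -> float:
    """Frequencies are keyed rounded to 1 Hz to make float lookups robust."""
    return round(float(freq), 0)


@dataclass
class MultistaticDataset:
    """Complex transmission values indexed by (freq Hz, tx, rx), tx != rx."""

    entries: dict = dc_field(default_factory=dict)
    metadata: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        for (f, tx, rx) in self.entries:
            self._validate_key(f, tx, rx)

    @staticmethod
    def _validate_key(f, tx, rx) -> None:
        if not (BAND[0] <= f <= BAND[1]):
            raise ValueError(f"frequency {f} outside acquisition band {BAND}")
        if tx == rx:
            raise ValueError("monostatic (tx == rx) entries are not allowed")

    def set(self, freq, tx, rx, value) -> None:
        self._validate_key(_freq_key(freq), tx, rx)
        self.entries[(_freq_key(freq), int(tx), int(rx))] = complex(value)

    def get(self, freq, tx, rx) -> complex:
        key = (_freq_key(freq), int(tx), int(rx))
        if key not in self.entries:
            raise KeyError(f"no entry for freq={freq}, tx={tx}, rx={rx}")
        return self.entries[key]

    def freqs(self) -> list:
        return sorted({f for (f, _, _) in self.entries})

    def at_freq_tx(self, freq, tx) -> dict:
        fk = _freq_key(freq)
        return {rx: v for (f, t, rx), v in self.entries.items() if f == fk and t == tx}

    def reference_amplitude(self, freq) -> float:
        refs = self.metadata.get("ref_amp", {})
        key = str(int(_freq_key(freq)))
        if key not in refs:
            raise KeyError(f"no reference amplitude recorded for {freq} Hz")
        return float(refs[key])

    def __len__(self) -> int:
        return len(self.entries)

    def subset(self, freqs) -> "MultistaticDataset":
        """Entries restricted to the given frequencies."""
        wanted = {_freq_key(f) for f in np.atleast_1d(freqs)}
        return MultistaticDataset(
            entries={k: v for k, v in self.entries.items() if k[0] in wanted},
            metadata=dict(self.metadata),
        )

    def scaled(self, factor: complex) -> "MultistaticDataset":
        return MultistaticDataset(
            entries={k: v * factor for k, v in self.entries.items()},
            metadata=dict(self.metadata),
        )

    # -- CSV + JSON-sidecar persistence -------------------------------------

    def to_csv(self, path, meta_path=None) -> None:
        path = Path(path)
        keys = sorted(self.entries)
        df = pd.DataFrame(
            {
                "freq_hz": [k[0] for k in keys],
                "tx": [k[1] for k in keys],
                "rx": [k[2] for k in keys],
                "re": [self.entries[k].real for k in keys],
                "im": [self.entries[k].imag for k in keys],
            }
        )
        df.to_csv(path, index=False, float_format="%.17g")
        meta_path = Path(meta_path) if meta_path else path.with_suffix(".meta.json")
        meta_path.write_text(json.dumps(self.metadata, indent=2, default=str))

    @classmethod
    def from_csv(cls, path, meta_path=None) -> "MultistaticDataset":
        path = Path(path)
        try:
            df = pd.read_csv(path, sep=None, engine="python")
        except Exception as exc:  # pragma: no cover - pandas message passthrough
            raise ValueError(f"{path}: malformed dataset CSV: {exc}") from exc
        required = ["freq_hz", "tx", "rx", "re", "im"]
        if list(df.columns[:5]) != required and not set(required).issubset(df.columns):
            raise ValueError(f"{path}: expected columns {required}, got {list(df.columns)}")
        for col in required:
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            if len(bad):
                raise ValueError(
                    f"{path}: malformed value in column {col!r} at data line {bad[0] + 2}"
                )
        entries = {}
        for row_num, row in enumerate(df.itertuples(index=False), start=2):
            key = (_freq_key(row.freq_hz), int(row.tx), int(row.rx))
            if key in entries:
                raise ValueError(f"{path}: duplicate (freq, tx, rx) key at data line {row_num}")
            entries[key] = complex(float(row.re), float(row.im))
        meta_path = Path(meta_path) if meta_path else path.with_suffix(".meta.json")
        metadata = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(entries=entries, metadata=metadata)


def _scenario_hash(scenario: Scenario) -> str:
    doc = json.dumps(scenario.to_dict(), sort_keys=True)
    return hashlib.sha256(doc.encode()).hexdigest()[:16]


def simulate_dataset(
    scenario: Scenario,
    freqs,
    sim_config: SimConfig | None = None,
    store_rasters: bool = False,
) -> MultistaticDataset:
    """Emulate a full multistatic sweep of the scenario's antenna ring.

    Runs one FDTD simulation per transmitter and records the complex Ez at
    every other antenna for each requested frequency:
    n_antennas x (n_antennas - 1) transmission entries per frequency.
    """
    sim_config = sim_config or SimConfig()
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    grid = make_grid(scenario, sim_config.dx, margin=sim_config.margin)
    props = rasterize(scenario, grid)
    ants = antenna_positions(scenario)
    n = scenario.n_antennas
    fields = run_array(props, ants, list(range(n)), freqs, sim_config, store_rasters)

    ds = MultistaticDataset()
    for tx in range(n):
        for fi, f in enumerate(freqs):
            for rx in range(n):
                if rx == tx:
                    continue
                ds.set(f, tx, rx, fields.probes[tx, fi, rx])

    # dB reference: line-source field amplitude one cell from the source in
    # the homogeneous background, with this run's source spectrum
    ref = {}
    for fi, f in enumerate(freqs):
        e1 = line_source_field(
            scenario.background.eval(f), f, (0.0, 0.0), [(grid.dx, 0.0)],
            current=fields.source_spectrum[fi],
        )[0]
        ref[str(int(_freq_key(f)))] = float(np.abs(e1))

    ds.metadata = {
        "scenario_hash": _scenario_hash(scenario),
        "scenario": scenario.to_dict(),
        "with_target": bool(scenario.targets),
        "grid_dx_m": grid.dx,
        "grid_shape": list(grid.shape),
        "n_antennas": n,
        "freqs_hz": [float(f) for f in freqs],
        "ref_amp": ref,
        "noise_floor_db": None,
        "vna_settings": {"points": 201, "averaging": 5, "if_bandwidth_hz": 200},
    }
    return ds


def add_noise(dataset: MultistaticDataset, noise_floor_db: float, seed: int) -> MultistaticDataset:
    """Add circular complex Gaussian receiver noise set by a dB noise floor.

    The floor is on the dataset's dB scale, ``20 log10(|value| / ref_amp)``:
    the per-entry noise RMS amplitude is ``ref_amp(f) * 10^(floor/20)``.  An
    entry whose strength sits S dB above the floor is perturbed by a
    relative amount of about ``10^(-S/20)``.
    """
    out = MultistaticDataset(entries=dict(dataset.entries), metadata=dict(dataset.metadata))
    out.metadata["noise_floor_db"] = noise_floor_db
    out.metadata["noise_seed"] = seed
    if np.isneginf(noise_floor_db):
        return out
    rng = np.random.default_rng(seed)
    for key in sorted(out.entries):
        f = key[0]
        sigma = dataset.reference_amplitude(f) * 10.0 ** (noise_floor_db / 20.0)
        noise = (rng.standard_normal() + 1j * rng.standard_normal()) * sigma / np.sqrt(2.0)
        out.entries[key] = out.entries[key] + noise
    return out


@dataclass
class CalibratedScatteredData:
    """Calibrated total and scattered fields in the forward model's frame."""

    total: dict  # (freq, tx, rx) -> complex calibrated total field
    scattered: dict  # (freq, tx, rx) -> complex calibrated scattered field
    excluded: set  # keys flagged out (empty-tank value below floor)
    empty_reference: dict  # metadata of the empty-tank pair used

    def freqs(self) -> list:
        return sorted({f for (f, _, _) in self.total})

    def keys_at(self, freq) -> list:
        fk = _freq_key(freq)
        return sorted(k for k in self.total if k[0] == fk and k not in self.excluded)


class CalibrationError(ValueError):
    pass


def calibrate(
    measured_with_target: MultistaticDataset,
    measured_empty: MultistaticDataset,
    model_empty: MultistaticDataset,
    floor_threshold: float | None = None,
) -> CalibratedScatteredData:
    """Empty-tank (multiplicative, per-channel) calibration.

    All three datasets must share their (freq, tx, rx) keys.  Channels whose
    empty-tank measurement magnitude falls below ``floor_threshold``
    (default: 1e-12 of the largest empty-tank magnitude) are flagged and
    excluded rather than divided.
    """
    kw = set(measured_with_target.entries)
    ke = set(measured_empty.entries)
    km = set(model_empty.entries)
    if kw != ke or kw != km:
        raise CalibrationError(
            "datasets are not aligned: "
            f"{len(kw ^ ke)} with/empty key mismatches, {len(kw ^ km)} with/model"
        )
    max_empty = max((abs(v) for v in measured_empty.entries.values()), default=0.0)
    if floor_threshold is None:
        floor_threshold = 1e-12 * max_empty
    total, scattered, excluded = {}, {}, set()
    for key in sorted(kw):
        e_meas = measured_empty.entries[key]
        if abs(e_meas) <= floor_threshold:
            excluded.add(key)
            continue
        t = measured_with_target.entries[key] / e_meas * model_empty.entries[key]
        total[key] = t
        scattered[key] = t - model_empty.entries[key]
    return CalibratedScatteredData(
        total=total,
        scattered=scattered,
        excluded=excluded,
        empty_reference={
            "measured_empty_meta": dict(measured_empty.metadata),
            "model_empty_meta": dict(model_empty.metadata),
            "floor_threshold": floor_threshold,
        },
    )
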