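"""File formats and run configuration.

Criterion records travel as CSV with the column layout
``signal_number, imat, sat, cr1..cr6`` (percent for the fat fractions; m/s,
dB/cm and relative units for the criteria).  Waveform containers use HDF5:
one group per signal train holding the three waveform arrays with sample
rate, path length, offset and truth attributes.  Run configurations and
surface fits serialise to JSON.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .ann import NetworkConfig
from .features import CRITERION_COLUMNS
from .phantoms import AcousticModel, DatasetManifest, SignalTrain

__all__ = [
    "RECORD_COLUMNS",
    "read_records",
    "write_records",
    "save_trains",
    "load_trains",
    "RunConfig",
]

RECORD_COLUMNS = ["signal_number", "imat", "sat", *CRITERION_COLUMNS]


def write_records(records: pd.DataFrame, path) -> None:
    """Write criterion records as CSV (>= 9 significant digits, lossless
    for round-tripping)."""
    df = records.copy()
    if "signal_number" not in df:
        df.insert(0, "signal_number", np.arange(1, len(df) + 1))
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"records are missing columns: {missing}")
    extra = [c for c in df.columns if c not in RECORD_COLUMNS]
    df[RECORD_COLUMNS + extra].to_csv(path, index=False, float_format="%.12g")


def read_records(path) -> pd.DataFrame:
    """Read a criterion-record CSV, validating schema and cell types."""
    df = pd.read_csv(path)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    for col in RECORD_COLUMNS:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            rows = (df.index[bad] + 2).tolist()     # 1-based + header line
            raise ValueError(f"{path}: non-numeric value(s) in column "
                             f"{col!r} at line(s) {rows}")
        df[col] = pd.to_numeric(df[col])
    return df


def save_trains(trains, path, manifest: DatasetManifest | None = None) -> None:
    """Write signal trains into an HDF5 container (one group per train)."""
    with h5py.File(path, "w") as f:
        if manifest is not None:
            f.attrs["manifest"] = manifest.to_json()
        for k, tr in enumerate(trains):
            g = f.create_group(f"train_{k:05d}")
            g.create_dataset("waveform_08", data=tr.waveform_08)
            g.create_dataset("waveform_22", data=tr.waveform_22)
            g.create_dataset("waveform_sweep", data=tr.waveform_sweep)
            g.attrs["sample_rate_msps"] = tr.sample_rate_msps
            g.attrs["path_length_mm"] = tr.path_length_mm
            g.attrs["transducer_offset_us"] = tr.transducer_offset_us
            g.attrs["phantom_id"] = tr.phantom_id
            g.attrs["repeat_index"] = tr.repeat_index
            if tr.truth is not None:
                g.attrs["truth_sat_pct"] = tr.truth[0]
                g.attrs["truth_imat_pct"] = tr.truth[1]


def load_trains(path) -> list[SignalTrain]:
    """Read signal trains back from an HDF5 container."""
    trains = []
    with h5py.File(path, "r") as f:
        for name in sorted(k for k in f.keys() if k.startswith("train_")):
            g = f[name]
            truth = None
            if "truth_sat_pct" in g.attrs:
                truth = (float(g.attrs["truth_sat_pct"]),
                         float(g.attrs["truth_imat_pct"]))
            trains.append(SignalTrain(
                waveform_08=g["waveform_08"][()],
                waveform_22=g["waveform_22"][()],
                waveform_sweep=g["waveform_sweep"][()],
                sample_rate_msps=float(g.attrs["sample_rate_msps"]),
                path_length_mm=float(g.attrs["path_length_mm"]),
                transducer_offset_us=float(g.attrs["transducer_offset_us"]),
                phantom_id=str(g.attrs["phantom_id"]),
                repeat_index=int(g.attrs["repeat_index"]),
                truth=truth,
            ))
    return trains


@dataclass
class RunConfig:
    """Everything needed to reproduce a full pipeline run."""

    seed: int = 0
    repeats: int = 15
    levels: tuple[float, ...] = (0.0, 12.5, 25.0, 37.5, 50.0)
    path_length_mm: float = 80.0
    model: AcousticModel = field(default_factory=AcousticModel)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    run_ann: bool = True
    out_dir: str = "results"

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        if "model" in d:
            d["model"] = AcousticModel(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in d["model"].items()})
        if "network" in d:
            net = d["network"]
            if "layer_widths" in net:
                net["layer_widths"] = tuple(net["layer_widths"])
            if "lr_schedule" in net:
                net["lr_schedule"] = tuple(
                    (int(e), float(r)) for e, r in net["lr_schedule"])
            d["network"] = NetworkConfig(**net)
        if "levels" in d:
            d["levels"] = tuple(d["levels"])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        return cls.from_json(Path(path).read_text())

    def manifest(self) -> DatasetManifest:
        from .phantoms import build_phantom_grid
        return DatasetManifest(
            phantoms=build_phantom_grid(self.levels, self.path_length_mm),
            repeats=self.repeats, seed=self.seed, model=self.model)
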