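"""Readers and writers for the package's on-disk formats.

Inertial records travel as delimited text with a fixed header
(t, ax, ay, az [g], gx, gy, gz [deg/s], mx, my, mz [uT]); sensor
specifications as one YAML file per sensor; tremor events as a
(start, end, class) interval table; window corpora as an HDF5 container
for large datasets.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from tremorsim.sensor_model import InertialRecord, SensorSpec
from tremorsim.tremor import TremorEvent
from tremorsim.dataset import LabeledWindowSet

__all__ = [
    "write_record_csv", "read_record_csv", "save_spec_yaml", "load_spec_yaml",
    "write_events_csv", "read_events_csv", "save_windowset_h5",
    "load_windowset_h5",
]

RECORD_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz", "mx", "my", "mz"]


def write_record_csv(record: InertialRecord, path) -> None:
    df = pd.DataFrame(
        np.column_stack([record.t, record.accel.T, record.gyro.T, record.mag.T]),
        columns=RECORD_COLUMNS)
    df.to_csv(path, index=False, float_format="%.9g")


def read_record_csv(path) -> InertialRecord:
    df = pd.read_csv(path)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"record file missing columns: {missing}")
    t = df["t"].to_numpy()
    if len(t) < 2:
        raise ValueError("record needs at least 2 samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError("record time base is not uniform")
    fs = 1.0 / dt[0]
    return InertialRecord(fs,
                          df[["ax", "ay", "az"]].to_numpy().T,
                          df[["gx", "gy", "gz"]].to_numpy().T,
                          df[["mx", "my", "mz"]].to_numpy().T)


def save_spec_yaml(spec: SensorSpec, path) -> None:
    Path(path).write_text(yaml.safe_dump(spec.to_dict(), sort_keys=False))


def load_spec_yaml(path) -> SensorSpec:
    return SensorSpec.from_dict(yaml.safe_load(Path(path).read_text()))


def write_events_csv(events: list[TremorEvent], tremor_class: str, path) -> None:
    pd.DataFrame({
        "start_s": [ev.start for ev in events],
        "end_s": [ev.end for ev in events],
        "class": tremor_class,
    }).to_csv(path, index=False)


def read_events_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_windowset_h5(ws: LabeledWindowSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("windows", data=ws.windows, compression="gzip")
        f.create_dataset("labels", data=ws.labels)
        f.attrs["fs"] = ws.fs
        f.attrs["window_s"] = ws.window_s
        f.attrs["channel_names"] = [str(c) for c in ws.channel_names]
        g = f.create_group("provenance")
        for col in ws.provenance.columns:
            vals = ws.provenance[col].to_numpy()
            if vals.dtype == object:
                vals = vals.astype("S")
            g.create_dataset(col, data=vals)


def load_windowset_h5(path) -> LabeledWindowSet:
    with h5py.File(path, "r") as f:
        prov = {}
        for col, ds in f["provenance"].items():
            vals = ds[...]
            if vals.dtype.kind == "S":
                vals = vals.astype(str)
            prov[col] = vals
        return LabeledWindowSet(
            windows=f["windows"][...],
            labels=f["labels"][...],
            fs=float(f.attrs["fs"]),
            window_s=float(f.attrs["window_s"]),
            channel_names=[str(c) for c in f.attrs["channel_names"]],
            provenance=pd.DataFrame(prov),
        )
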