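"""File I/O for the formats the pipeline exchanges.

HDF5 raw recordings (datasets /voltage_uV, /fs_hz; attr div_day, well_id),
CSV spike tables (electrode_id, time_s), CSV fluorescence trace matrices,
two-channel TIFFs, and JSON ground-truth sidecars.  SWC lives in
:mod:`neurodish.morphometry`.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .calcium import CalciumTraceSet
from .mea import RawRecording, SpikeTrainSet

__all__ = [
    "write_raw_h5",
    "read_raw_h5",
    "write_spikes_csv",
    "read_spikes_csv",
    "write_traces_csv",
    "read_traces_csv",
    "write_tiff",
    "read_tiff",
    "write_json",
    "read_json",
]


def write_raw_h5(raw: RawRecording, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("voltage_uV", data=raw.voltage_uV)
        f.create_dataset("fs_hz", data=raw.fs_hz)
        f.attrs["div_day"] = raw.div_day
        f.attrs["well_id"] = raw.well_id


def read_raw_h5(path) -> RawRecording:
    with h5py.File(path, "r") as f:
        return RawRecording(
            voltage_uV=f["voltage_uV"][...],
            fs_hz=float(f["fs_hz"][()]),
            div_day=int(f.attrs.get("div_day", 0)),
            well_id=str(f.attrs.get("well_id", "well0")),
        )


def write_spikes_csv(spikes: SpikeTrainSet, path) -> None:
    df = spikes.to_frame()
    df.insert(0, "duration_s", spikes.duration_s)
    df.to_csv(path, index=False)


def read_spikes_csv(path, duration_s: float | None = None,
                    n_electrodes: int | None = None) -> SpikeTrainSet:
    df = pd.read_csv(path)
    if duration_s is None:
        if "duration_s" not in df.columns:
            raise ValueError("duration_s neither in file nor given")
        duration_s = float(df["duration_s"].iloc[0])
    return SpikeTrainSet.from_frame(df, duration_s=duration_s,
                                    n_electrodes=n_electrodes)


def write_traces_csv(traces: CalciumTraceSet, path) -> None:
    df = pd.DataFrame(traces.F.T)
    df.columns = [f"cell{c}" for c in range(traces.n_cells)]
    df.insert(0, "time_s", np.arange(traces.n_samples) / traces.fs_hz)
    df.to_csv(path, index=False)


def read_traces_csv(path) -> CalciumTraceSet:
    df = pd.read_csv(path)
    t = df.pop("time_s").to_numpy()
    fs = 1.0 / np.median(np.diff(t))
    return CalciumTraceSet(F=df.to_numpy().T, fs_hz=float(fs))


def write_tiff(image: np.ndarray, path, pixel_size_um: float) -> None:
    """Write a (channels, H, W) image with pixel size in the resolution tag."""
    res = 1.0 / pixel_size_um  # pixels per um
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32),
                     resolution=(res, res),
                     metadata={"unit": "um", "pixel_size_um": pixel_size_um})


def read_tiff(path):
    """Read an image and its pixel size (um) from the resolution tag."""
    with tifffile.TiffFile(path) as tf:
        img = tf.asarray()
        page = tf.pages[0]
        tag = page.tags.get("XResolution")
        if tag is None:
            raise ValueError(f"{path}: missing resolution metadata")
        num, den = tag.value
        pixel_size_um = den / num
    return img, pixel_size_um


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        return super().default(o)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder))


def read_json(path):
    return json.loads(Path(path).read_text())
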