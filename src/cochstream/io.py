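"""HDF5 container for neural recordings and small table writers.

Layout of a recording file:

    /waveform          float64 (n_channels, n_samples)
    /schedule/<col>    one dataset per schedule column
    attrs: fs, channel_cfs_khz, t_drug
"""

from __future__ import annotations

import h5py
import numpy as np
import pandas as pd

from .neuro import NeuralRecording

__all__ = ["save_recording", "load_recording"]


def save_recording(path: str, rec: NeuralRecording) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("waveform", data=rec.waveform, compression="gzip")
        f.attrs["fs"] = rec.fs
        f.attrs["channel_cfs_khz"] = rec.channel_cfs_khz
        f.attrs["t_drug"] = rec.t_drug
        g = f.create_group("schedule")
        for col in rec.schedule.columns:
            vals = rec.schedule[col].to_numpy()
            if vals.dtype == object:
                vals = vals.astype("S")
            g.create_dataset(col, data=vals)


def load_recording(path: str) -> NeuralRecording:
    with h5py.File(path, "r") as f:
        cols = {}
        for col, ds in f["schedule"].items():
            v = ds[...]
            if v.dtype.kind == "S":
                v = v.astype(str)
            cols[col] = v
        return NeuralRecording(
            waveform=f["waveform"][...],
            fs=float(f.attrs["fs"]),
            channel_cfs_khz=np.asarray(f.attrs["channel_cfs_khz"]),
            schedule=pd.DataFrame(cols),
            t_drug=float(f.attrs["t_drug"]),
        )
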