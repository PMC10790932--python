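"""Readers and writers: SNIRF (HDF5), CSV dialects, YAML configs.

The SNIRF writer emits a minimal standard-conforming raw-intensity file
(one /nirs/data1 block, dataType 1, one measurementList entry per
channel-wavelength pair); the reader accepts what the writer emits. A
plain CSV matrix dialect (time x channel.wavelength columns) is provided
for dependency-free inspection.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .effectmap import EffectMap
from .preprocess import ConcentrationSeries
from .simdata import OpticalRecording

__all__ = [
    "write_snirf",
    "read_snirf",
    "write_recording_csv",
    "read_recording_csv",
    "write_concentration_csv",
    "write_effectmap_csv",
    "load_yaml_config",
    "dump_yaml_config",
]


def write_snirf(rec: OpticalRecording, path) -> None:
    """Write a raw-intensity recording as a SNIRF/HDF5 file."""
    nc = rec.n_channels
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        data = nirs.create_group("data1")
        # SNIRF stores time x measurement columns
        flat = rec.intensities.reshape(nc * 2, rec.n_samples).T
        data.create_dataset("dataTimeSeries", data=flat)
        data.create_dataset("time", data=rec.times)
        for k in range(nc * 2):
            ch, wl = divmod(k, 2)
            ml = data.create_group(f"measurementList{k + 1}")
            ml.create_dataset("sourceIndex", data=ch + 1)
            ml.create_dataset("detectorIndex", data=ch + 1)
            ml.create_dataset("wavelengthIndex", data=wl + 1)
            ml.create_dataset("dataType", data=1)  # raw CW amplitude
            ml.create_dataset("dataTypeIndex", data=1)
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(rec.wavelengths))


def read_snirf(path) -> OpticalRecording:
    with h5py.File(path, "r") as f:
        data = f["nirs/data1"]
        flat = np.asarray(data["dataTimeSeries"])  # time x (channels*2)
        times = np.asarray(data["time"])
        wavelengths = tuple(np.asarray(f["nirs/probe/wavelengths"]).tolist())
    fs = 1.0 / np.median(np.diff(times))
    nc = flat.shape[1] // 2
    inten = flat.T.reshape(nc, 2, -1)
    labels = [f"CH{ch}" for ch in range(nc)]
    return OpticalRecording(intensities=inten, sampling_rate=float(round(fs, 6)),
                            channel_labels=labels, wavelengths=wavelengths)


def write_recording_csv(rec: OpticalRecording, path) -> None:
    """Time x channel.wavelength CSV matrix dialect."""
    nc = rec.n_channels
    cols = {}
    for ch in range(nc):
        for w, wl in enumerate(rec.wavelengths):
            cols[f"ch{ch}_wl{int(wl)}"] = rec.intensities[ch, w]
    df = pd.DataFrame({"time_s": rec.times, **cols})
    df.to_csv(path, index=False)


def read_recording_csv(path) -> OpticalRecording:
    df = pd.read_csv(path)
    times = df.pop("time_s").to_numpy()
    fs = 1.0 / np.median(np.diff(times))
    names = list(df.columns)
    channels = sorted({int(n.split("_")[0][2:]) for n in names})
    wavelengths = sorted({int(n.split("wl")[1]) for n in names})
    inten = np.stack(
        [
            np.stack([df[f"ch{ch}_wl{wl}"].to_numpy() for wl in wavelengths])
            for ch in channels
        ]
    )
    return OpticalRecording(intensities=inten, sampling_rate=float(round(fs, 6)),
                            channel_labels=[f"CH{c}" for c in channels],
                            wavelengths=tuple(float(w) for w in wavelengths))


def write_concentration_csv(conc: ConcentrationSeries, path_prefix) -> None:
    """Write HbO/HbR as two CSVs plus a JSON rejection report."""
    prefix = Path(path_prefix)
    t = np.arange(conc.n_samples) / conc.sampling_rate
    for name, arr in (("hbo", conc.hbo), ("hbr", conc.hbr)):
        df = pd.DataFrame(arr.T, columns=[f"ch{c}" for c in conc.retained_channels])
        df.insert(0, "time_s", t)
        df.to_csv(f"{prefix}_{name}.csv", index=False)
    report = {
        "retained": [int(c) for c in conc.retained_channels],
        "rejected": {str(k): v for k, v in conc.rejected_channels.items()},
    }
    Path(f"{prefix}_rejection.json").write_text(json.dumps(report, indent=2))


def write_effectmap_csv(em: EffectMap, path) -> None:
    df = pd.DataFrame(
        {
            "channel": em.channel_indices,
            "t": em.t,
            "d": em.d,
            "n_pairs": em.n_pairs,
        }
    )
    df.to_csv(path, index=False)


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_yaml_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
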