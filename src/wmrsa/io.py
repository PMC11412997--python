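"""HDF5 / TSV / JSON persistence for pipeline artifacts."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .models import LayeredModelRSMs
from .rsm import RSMSeries
from .timefreq import EpochedRecording, TFPower

__all__ = [
    "save_tfpower",
    "load_tfpower",
    "save_recording",
    "load_recording",
    "save_rsm_series",
    "load_rsm_series",
    "save_layered_rsms",
    "load_layered_rsms",
    "save_trial_table",
    "load_trial_table",
    "write_json",
    "file_checksum",
]


def _str_ds(values: list[str]) -> np.ndarray:
    return np.asarray(values, dtype=h5py.string_dtype())


def save_tfpower(path: str | Path, power: TFPower) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=power.data, compression="gzip", shuffle=True)
        fh["times"] = np.asarray(power.times)
        fh["frequencies"] = np.asarray(power.frequencies)
        fh["channels"] = _str_ds(power.channels)
        fh["valid"] = power.valid
        if power.sessions is not None:
            fh["sessions"] = np.asarray(power.sessions)
        fh.attrs["zscored"] = bool(power.zscored)
        fh.attrs["zero_variance_cells"] = int(power.zero_variance_cells)


def load_tfpower(path: str | Path) -> TFPower:
    with h5py.File(path, "r") as fh:
        return TFPower(
            data=fh["data"][()],
            times=fh["times"][()],
            frequencies=fh["frequencies"][()],
            channels=[c.decode() for c in fh["channels"][()]],
            sessions=fh["sessions"][()] if "sessions" in fh else None,
            zscored=bool(fh.attrs["zscored"]),
            valid=fh["valid"][()].astype(bool),
            zero_variance_cells=int(fh.attrs["zero_variance_cells"]),
        )


def save_recording(path: str | Path, rec: EpochedRecording) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=rec.data, compression="gzip", shuffle=True)
        fh["times"] = np.asarray(rec.times)
        fh["channels"] = _str_ds(rec.channels)
        fh.attrs["sfreq"] = float(rec.sfreq)
        if rec.sessions is not None:
            fh["sessions"] = np.asarray(rec.sessions)


def load_recording(path: str | Path) -> EpochedRecording:
    with h5py.File(path, "r") as fh:
        return EpochedRecording(
            data=fh["data"][()],
            sfreq=float(fh.attrs["sfreq"]),
            times=fh["times"][()],
            channels=[c.decode() for c in fh["channels"][()]],
            sessions=fh["sessions"][()] if "sessions" in fh else None,
        )


def save_rsm_series(path: str | Path, series: RSMSeries) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("rsms", data=series.rsms, compression="gzip")
        fh["window_times"] = series.window_times
        fh["items"] = np.asarray(series.items)
        fh["categories"] = np.asarray(series.categories)
        fh.attrs["scope"] = series.scope


def load_rsm_series(path: str | Path) -> RSMSeries:
    with h5py.File(path, "r") as fh:
        return RSMSeries(
            rsms=fh["rsms"][()],
            window_times=fh["window_times"][()],
            items=fh["items"][()],
            categories=fh["categories"][()],
            scope=str(fh.attrs["scope"]),
        )


def save_layered_rsms(path: str | Path, stack: LayeredModelRSMs) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["source"] = stack.source
        fh.attrs["layers"] = json.dumps(stack.layers)
        if stack.categories is not None:
            fh["categories"] = np.asarray(stack.categories)
        for li, layer in enumerate(stack.rsms):
            for ti, m in enumerate(layer):
                fh.create_dataset(f"layer{li}/t{ti}", data=m)


def load_layered_rsms(path: str | Path) -> LayeredModelRSMs:
    with h5py.File(path, "r") as fh:
        layers = json.loads(fh.attrs["layers"])
        rsms = []
        for li in range(len(layers)):
            grp = fh[f"layer{li}"]
            rsms.append([grp[f"t{ti}"][()] for ti in range(len(grp))])
        return LayeredModelRSMs(
            rsms=rsms,
            layers=layers,
            source=str(fh.attrs["source"]),
            categories=fh["categories"][()] if "categories" in fh else None,
        )


def save_trial_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def load_trial_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(path: str | Path, payload: dict) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating, np.bool_)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(payload, indent=2, default=default))


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
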