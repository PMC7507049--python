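"""Readers and writers for the package's on-disk formats.

* Trial tables: delimited text (CSV) with header ``subject, group,
  intensity, stim_type, is_target, rt_ms, correct``; misses have an empty
  ``rt_ms`` field.  A generator ground-truth dict travels in a JSON
  sidecar next to the table.
* Epoch containers: HDF5 with a float dataset ``data`` of shape
  (channels, samples, trials) and attributes ``fs_hz``, ``t0_ms``,
  ``channel_names`` and ``condition``.
* PLI tensors and connectivity series: HDF5 datasets with band/condition
  attributes.
* Reports: JSON, numpy-safe.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import h5py
import numpy as np
import pandas as pd

from .connectivity import ConnectivityTimeSeries, EpochArray, PLITensor

__all__ = [
    "write_trial_table",
    "read_trial_table",
    "write_epochs_h5",
    "read_epochs_h5",
    "write_pli_h5",
    "read_pli_h5",
    "write_json",
    "read_json",
]


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_json(obj: Any, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> Any:
    return json.loads(Path(path).read_text())


def write_trial_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a behavioral trial table as CSV; if the table carries a
    ``ground_truth`` attr, drop it next to the table as ``<stem>.truth.json``."""
    path = Path(path)
    table.to_csv(path, index=False)
    truth = table.attrs.get("ground_truth")
    if truth is not None:
        write_json(truth, path.with_suffix(".truth.json"))


def read_trial_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, dtype={"subject": str}, keep_default_na=True)
    table["is_target"] = table["is_target"].astype(bool)
    table["correct"] = table["correct"].astype(bool)
    truth_path = Path(path).with_suffix(".truth.json")
    if truth_path.exists():
        table.attrs["ground_truth"] = read_json(truth_path)
    return table


def write_epochs_h5(epochs: EpochArray, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("data", data=epochs.data)
        ds.attrs["fs_hz"] = epochs.fs
        ds.attrs["t0_ms"] = epochs.t0_ms
        ds.attrs["channel_names"] = list(epochs.channel_names)
        ds.attrs["condition"] = json.dumps(_jsonable(epochs.condition))


def read_epochs_h5(path: str | Path) -> EpochArray:
    with h5py.File(path, "r") as f:
        ds = f["data"]
        condition = json.loads(ds.attrs["condition"])
        return EpochArray(
            data=ds[()],
            fs=float(ds.attrs["fs_hz"]),
            t0_ms=float(ds.attrs["t0_ms"]),
            channel_names=tuple(str(c) for c in ds.attrs["channel_names"]),
            condition=tuple(condition) if condition is not None else None,
        )


def write_pli_h5(
    tensor: PLITensor,
    path: str | Path,
    *,
    series: ConnectivityTimeSeries | None = None,
    condition: Any = None,
) -> None:
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("pli", data=tensor.pli)
        ds.attrs["band"] = tensor.band
        ds.attrs["band_hz"] = list(tensor.band_hz)
        ds.attrs["trimmed"] = tensor.trimmed
        ds.attrs["channel_names"] = list(tensor.channel_names)
        ds.attrs["condition"] = json.dumps(_jsonable(condition))
        f.create_dataset("times_ms", data=tensor.times_ms)
        if series is not None:
            f.create_dataset("mean_pli", data=series.mean_pli)


def read_pli_h5(path: str | Path) -> tuple[PLITensor, ConnectivityTimeSeries | None]:
    with h5py.File(path, "r") as f:
        ds = f["pli"]
        times = f["times_ms"][()]
        tensor = PLITensor(
            pli=ds[()],
            band=str(ds.attrs["band"]),
            band_hz=tuple(float(x) for x in ds.attrs["band_hz"]),
            times_ms=times,
            channel_names=tuple(str(c) for c in ds.attrs["channel_names"]),
            trimmed=bool(ds.attrs["trimmed"]),
        )
        series = None
        if "mean_pli" in f:
            series = ConnectivityTimeSeries(
                mean_pli=f["mean_pli"][()], times_ms=times, band=tensor.band
            )
    return tensor, series
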