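"""File formats: TSV trial tables, HDF5 power tensors, JSON results.

Trial tables round-trip as tab-separated text with one row per trial and
the ten contrast samples as columns s01..s10.  Power tensors use an
HDF5 layout with datasets /power (trial x roi x hemi x freq x time),
/freqs, /times, /rois, /hemis, /trial_ids and a root attribute ``units``
in {raw, pct_change}; the layout is versioned.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import xarray as xr

from .trials import SAMPLE_COLUMNS

__all__ = [
    "read_trials", "write_trials",
    "read_tensor", "write_tensor",
    "read_results", "write_results",
    "SchemaError",
]

TENSOR_SCHEMA_VERSION = 1
TRIAL_COLUMNS = (
    ["subject", "trial"] + SAMPLE_COLUMNS
    + ["sd_level", "trial_mean", "stimulus_category", "choice", "confidence",
       "rt", "correct", "response_hand"]
)


class SchemaError(ValueError):
    """A file does not match the expected on-disk schema."""


def write_trials(trials: pd.DataFrame, path) -> None:
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise SchemaError(f"trial table missing columns: {missing}")
    trials[TRIAL_COLUMNS].to_csv(path, sep="\t", index=False)


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trial table at {path} missing columns: {missing}")
    df["correct"] = df["correct"].astype(bool)
    return df


def write_tensor(power: xr.DataArray, path) -> None:
    power = power.transpose("trial", "roi", "hemi", "freq", "time")
    with h5py.File(path, "w") as f:
        f.create_dataset("power", data=power.values)
        f.create_dataset("freqs", data=np.asarray(power["freq"].values, float))
        f.create_dataset("times", data=np.asarray(power["time"].values, float))
        f.create_dataset("rois", data=np.asarray(power["roi"].values, dtype="S"))
        f.create_dataset("hemis", data=np.asarray(power["hemi"].values, dtype="S"))
        f.create_dataset("trial_ids", data=np.asarray(power["trial"].values, int))
        f.attrs["units"] = power.attrs.get("units", "raw")
        f.attrs["schema_version"] = TENSOR_SCHEMA_VERSION


def read_tensor(path) -> xr.DataArray:
    with h5py.File(path, "r") as f:
        version = f.attrs.get("schema_version")
        if version != TENSOR_SCHEMA_VERSION:
            raise SchemaError(
                f"tensor schema version {version!r} != {TENSOR_SCHEMA_VERSION}")
        for name in ("power", "freqs", "times", "rois", "hemis", "trial_ids"):
            if name not in f:
                raise SchemaError(f"tensor file missing dataset /{name}")
        da = xr.DataArray(
            f["power"][()],
            dims=("trial", "roi", "hemi", "freq", "time"),
            coords={
                "trial": f["trial_ids"][()],
                "roi": [s.decode() for s in f["rois"][()]],
                "hemi": [s.decode() for s in f["hemis"][()]],
                "freq": f["freqs"][()],
                "time": f["times"][()],
            },
            attrs={"units": f.attrs["units"]},
            name="power",
        )
    return da


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _to_jsonable(obj.tolist())
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_results(results: dict, path) -> None:
    Path(path).write_text(json.dumps(_to_jsonable(results), indent=2) + "\n")


def read_results(path) -> dict:
    return json.loads(Path(path).read_text())
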