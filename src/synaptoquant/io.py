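"""Readers/writers for the formats the pipeline exchanges.

Images: single-plane grayscale TIFF (8/16-bit). Traces: CSV with columns
``time_s,value`` or HDF5 with datasets ``/trace`` and ``/fs``. Trees:
7-column SWC. Sweep tables: CSV with ``stim_001..stim_NNN`` columns plus
``rs_mohm`` and ``has_ap`` metadata columns. Group tables: long-format
CSV with ``value,group[,unit]`` columns.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile

from .errors import ContractError
from .morphology import SWC_COLUMNS, NeuronTree

__all__ = [
    "read_image", "write_image",
    "read_trace", "write_trace",
    "read_swc", "write_swc",
    "read_sweep_table", "write_sweep_table",
    "read_group_table", "write_json",
]


def read_image(path) -> np.ndarray:
    img = tifffile.imread(str(path))
    if img.ndim != 2:
        raise ContractError(
            f"{path}: expected a single-plane grayscale image, "
            f"got shape {img.shape}")
    return img


def write_image(path, image: np.ndarray) -> None:
    arr = np.asarray(image)
    out = np.clip(np.rint(arr), 0, 65535).astype(np.uint16)
    tifffile.imwrite(str(path), out)


def read_trace(path) -> tuple[np.ndarray, float]:
    """Returns (samples, fs_hz) from CSV (time_s,value) or HDF5."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            return f["/trace"][:], float(f["/fs"][()])
    df = pd.read_csv(path)
    if "time_s" not in df.columns or "value" not in df.columns:
        raise ContractError(f"{path}: expected columns time_s,value")
    t = df["time_s"].to_numpy()
    if len(t) < 2:
        raise ContractError(f"{path}: trace too short")
    fs = 1.0 / np.median(np.diff(t))
    return df["value"].to_numpy(dtype=np.float64), float(fs)


def write_trace(path, samples: np.ndarray, fs_hz: float) -> None:
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("/trace", data=np.asarray(samples))
            f.create_dataset("/fs", data=float(fs_hz))
    else:
        t = np.arange(len(samples)) / fs_hz
        pd.DataFrame({"time_s": t, "value": samples}).to_csv(
            path, index=False)


def read_swc(path) -> NeuronTree:
    df = pd.read_csv(path, sep=r"\s+", comment="#", header=None,
                     names=SWC_COLUMNS)
    df["id"] = df["id"].astype(int)
    df["type"] = df["type"].astype(int)
    df["parent"] = df["parent"].astype(int)
    return NeuronTree.from_swc(df)


def write_swc(path, nodes: pd.DataFrame) -> None:
    with open(path, "w") as f:
        f.write("# id type x y z radius parent\n")
        for _, r in nodes.iterrows():
            f.write(f"{int(r['id'])} {int(r['type'])} "
                    f"{r['x']:.6f} {r['y']:.6f} {r['z']:.6f} "
                    f"{r['radius']:.3f} {int(r['parent'])}\n")


def write_sweep_table(path, table: np.ndarray, rs_mohm=None,
                      has_ap=None) -> None:
    table = np.atleast_2d(np.asarray(table))
    n_sweeps, n_pulses = table.shape
    df = pd.DataFrame(table,
                      columns=[f"stim_{i:03d}" for i in
                               range(1, n_pulses + 1)])
    df["rs_mohm"] = np.zeros(n_sweeps) if rs_mohm is None else rs_mohm
    df["has_ap"] = (np.zeros(n_sweeps, bool) if has_ap is None
                    else np.asarray(has_ap, bool))
    df.to_csv(path, index=False)


def read_sweep_table(path):
    """Returns (amplitude table, rs_mohm, has_ap) from a sweep CSV."""
    df = pd.read_csv(path)
    stim_cols = sorted(c for c in df.columns if c.startswith("stim_"))
    if not stim_cols:
        raise ContractError(f"{path}: no stim_ columns found")
    table = df[stim_cols].to_numpy(dtype=np.float64)
    rs = (df["rs_mohm"].to_numpy(dtype=np.float64)
          if "rs_mohm" in df.columns else np.zeros(len(df)))
    ap = (df["has_ap"].to_numpy(dtype=bool)
          if "has_ap" in df.columns else np.zeros(len(df), bool))
    return table, rs, ap


def read_group_table(path) -> tuple[np.ndarray, np.ndarray, str]:
    """Long-format CSV with value,group[,unit] -> (group1, group2, unit)."""
    df = pd.read_csv(path)
    for col in ("value", "group"):
        if col not in df.columns:
            raise ContractError(f"{path}: missing required column '{col}'")
    if not np.issubdtype(df["value"].dtype, np.number):
        raise ContractError(f"{path}: column 'value' is not numeric")
    names = list(dict.fromkeys(df["group"]))
    if len(names) != 2:
        raise ContractError(
            f"{path}: expected exactly 2 groups, found {len(names)}")
    g1 = df.loc[df["group"] == names[0], "value"].to_numpy(dtype=np.float64)
    g2 = df.loc[df["group"] == names[1], "value"].to_numpy(dtype=np.float64)
    unit = str(df["unit"].iloc[0]) if "unit" in df.columns else ""
    return g1, g2, unit


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        return super().default(o)


def write_json(path, obj) -> None:
    with open(path, "w") as f:
        json.dump(obj, f, indent=2, cls=_NumpyEncoder)
        f.write("\n")
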