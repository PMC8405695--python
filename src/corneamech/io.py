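"""File I/O: B-scan pair containers, force-trace CSV, cohort CSV.

B-scan pairs are stored as an HDF5 file with groups ``reference`` and
``deformed``, each holding ``real``/``imag`` float planes, plus a JSON
sidecar (same stem, ``.json``) carrying the scan metadata and any
generator ground truth.  Force traces and cohort tables are plain CSV with
the documented headers.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .extensometry import ForceTrace
from .geometry import LoadingGeometry
from .oce import OCEScanPair

TRACE_COLUMNS = ["t_s", "force_N", "travel_um", "segment"]
COHORT_COLUMNS = ["eye_id", "group", "cct_um", "strain_permil", "E_oct_kPa", "E_ext_kPa"]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def save_scan_pair(pair: OCEScanPair, path: str | Path) -> Path:
    """Write a scan pair to ``path`` (.h5) with a JSON metadata sidecar."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        for name, arr in (("reference", pair.b_ref), ("deformed", pair.b_def)):
            g = f.create_group(name)
            g.create_dataset("real", data=arr.real)
            g.create_dataset("imag", data=arr.imag)
    sidecar = {"meta": _jsonable(pair.meta)}
    if pair.truth is not None:
        truth = {k: v for k, v in pair.truth.items() if k != "tissue_mask"}
        sidecar["truth"] = _jsonable(truth)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def load_scan_pair(path: str | Path) -> OCEScanPair:
    """Read a scan pair written by :func:`save_scan_pair`."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        b_ref = f["reference/real"][()] + 1j * f["reference/imag"][()]
        b_def = f["deformed/real"][()] + 1j * f["deformed/imag"][()]
    sidecar = json.loads(path.with_suffix(".json").read_text())
    return OCEScanPair(
        b_ref=b_ref,
        b_def=b_def,
        meta=sidecar["meta"],
        truth=sidecar.get("truth"),
    )


def save_trace(trace: ForceTrace, path: str | Path) -> Path:
    """Write a force trace as CSV with header ``t_s,force_N,travel_um,segment``."""
    path = Path(path)
    trace.to_frame().to_csv(path, index=False)
    return path


def load_trace(
    path: str | Path, geometry: LoadingGeometry | None = None
) -> ForceTrace:
    """Read a force-trace CSV; the segment column is optional."""
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise ValueError(f"trace CSV is missing columns {missing}")
    seg = None
    if "segment" in df.columns and df["segment"].notna().any():
        seg = df["segment"].fillna("").to_numpy(dtype=object)
        if (seg == "").all():
            seg = None
    return ForceTrace(
        df["t_s"].to_numpy(),
        df["force_N"].to_numpy(),
        df["travel_um"].to_numpy(),
        seg,
        geometry,
    )


def save_cohort(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a cohort table as CSV with the documented column order."""
    path = Path(path)
    cols = [c for c in COHORT_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    table[cols].to_csv(path, index=False)
    return path


def load_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV."""
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS[:2] if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV is missing columns {missing}")
    return df
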