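"""File formats: end-tidal trace TSV, NIfTI volumes, regressor TSV.

Traces are tab-separated text with the header columns ``time_s``,
``petco2_mmHg``, ``peto2_mmHg``. BOLD volumes are 4D NIfTI with the TR stored
in the fourth zoom; 3D maps carry their units in the header description and
encode invalid voxels as NaN. Uncompressed ``.nii`` is written so repeated
runs are byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .containers import BoldImage4D, VoxelMap
from .errors import TraceFormatError
from .paradigms import EndTidalTrace

TRACE_COLUMNS = ("time_s", "petco2_mmHg", "peto2_mmHg")


def read_trace(path: str | Path) -> EndTidalTrace:
    """Read an end-tidal trace TSV, validating header and monotonic times."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise TraceFormatError(f"{path}: cannot parse as TSV ({exc})") from exc
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise TraceFormatError(f"{path}: missing column(s) {', '.join(missing)}")
    t = df["time_s"].to_numpy(float)
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        # +2: one for the header line, one for 1-based numbering
        raise TraceFormatError(f"{path}: non-monotonic time at line {bad[0] + 3}")
    return EndTidalTrace(breath_times=t,
                         petco2=df["petco2_mmHg"].to_numpy(float),
                         peto2=df["peto2_mmHg"].to_numpy(float))


def write_trace(trace: EndTidalTrace, path: str | Path) -> Path:
    """Write a trace as TSV (full float precision, round-trip stable)."""
    path = Path(path)
    df = pd.DataFrame({"time_s": trace.breath_times,
                       "petco2_mmHg": trace.petco2,
                       "peto2_mmHg": trace.peto2})
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")
    return path


def write_regressor(times: np.ndarray, values: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"time_s": times, "value": values}).to_csv(
        path, sep="\t", index=False, float_format="%.12g")
    return path


def save_bold(bold: BoldImage4D, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(bold.data.astype(np.float32), bold.affine)
    img.header.set_zooms((1.0, 1.0, 1.0, bold.tr_s))
    img.header["descrip"] = b"BOLD time series"
    nib.save(img, str(path))
    return path


def load_bold(path: str | Path) -> BoldImage4D:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise TraceFormatError(f"{path}: expected a 4D NIfTI")
    tr = float(img.header.get_zooms()[3])
    return BoldImage4D(data=data, tr_s=tr, affine=img.affine)


def save_map(vmap: VoxelMap, path: str | Path) -> Path:
    """Write a 3D map; invalid voxels become NaN, units go in the header."""
    path = Path(path)
    data = vmap.data.astype(np.float32).copy()
    data[~vmap.valid] = np.nan
    img = nib.Nifti1Image(data, np.eye(4))
    img.header["descrip"] = f"units={vmap.units}".encode()
    nib.save(img, str(path))
    return path


def load_map(path: str | Path, units: str | None = None) -> VoxelMap:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if units is None:
        desc = img.header["descrip"].tobytes().rstrip(b"\x00").decode()
        units = desc.split("units=", 1)[1] if "units=" in desc else "dimensionless"
    valid = np.isfinite(data)
    return VoxelMap(data, units, valid)


def save_prob_map(prob: np.ndarray, path: str | Path) -> Path:
    img = nib.Nifti1Image(np.asarray(prob, np.float32), np.eye(4))
    img.header["descrip"] = b"tissue probability"
    nib.save(img, str(path))
    return path


def load_prob_map(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=float)


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    return path
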