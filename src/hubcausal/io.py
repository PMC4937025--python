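"""NIfTI-1 I/O, subjects tables, and motion-parameter files."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .grids import BoldSeries, ScalarMap, VolumeGrid

__all__ = [
    "read_volume",
    "write_volume",
    "read_subjects_table",
    "write_subjects_table",
    "read_motion_trace",
    "write_motion_trace",
]

SUBJECT_COLUMNS = [
    "subject_id",
    "group",
    "age",
    "sex",
    "education",
    "tinnitus_duration",
    "thq",
    "hearing_left",
    "hearing_right",
    "max_translation",
    "max_rotation",
    "excluded",
]


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def read_volume(
    path: str | Path,
    kind: str | None = None,
    tr_seconds: float | None = None,
) -> BoldSeries | ScalarMap:
    """Load a NIfTI file as a :class:`ScalarMap` (3D) or :class:`BoldSeries` (4D).

    The grid comes from the sform affine; TR from ``pixdim[4]`` unless
    overridden.  ``kind`` for 3D maps is taken from, in order: the argument,
    a sidecar JSON written by :func:`write_volume`, a ``gm`` substring in the
    filename (-> ``gm_prob``), else ``scalar``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types for bad payloads
        raise ValueError(f"{path} is not a readable NIfTI file: {exc}") from exc
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim not in (3, 4):
        raise ValueError(f"{path}: expected 3D or 4D volume, got {data.ndim}D")
    grid = VolumeGrid(tuple(data.shape[:3]), np.asarray(img.affine, dtype=float))
    if data.ndim == 4:
        if tr_seconds is None:
            pixdim4 = float(img.header["pixdim"][4])
            tr_seconds = pixdim4 if pixdim4 > 0 else 2.0
        return BoldSeries(grid, data, tr_seconds=tr_seconds)
    if kind is None:
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            kind = json.loads(sidecar.read_text()).get("kind")
        elif "gm" in path.name.lower():
            kind = "gm_prob"
    return ScalarMap(grid, data, kind=kind or "scalar")


def write_volume(
    obj: BoldSeries | ScalarMap,
    path: str | Path,
    sidecar: dict | None = None,
) -> Path:
    """Write a map or BOLD series as NIfTI-1 (optionally with a JSON sidecar)."""
    path = Path(path)
    data = np.asarray(obj.data, dtype=np.float64)
    if not np.all(np.isfinite(data)):
        raise ValueError("refusing to write non-finite voxel data")
    img = nib.Nifti1Image(data, obj.grid.affine)
    img.header.set_sform(obj.grid.affine, code=1)
    img.header.set_qform(obj.grid.affine, code=1)
    meta = dict(sidecar or {})
    if isinstance(obj, BoldSeries):
        img.header["pixdim"][4] = obj.tr_seconds
        img.header.set_xyzt_units("mm", "sec")
    else:
        meta.setdefault("kind", obj.kind)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    if meta:
        _sidecar_path(path).write_text(json.dumps(meta, sort_keys=True))
    return path


def read_subjects_table(path: str | Path) -> pd.DataFrame:
    """Read the subjects CSV (header row, one row per subject)."""
    df = pd.read_csv(path)
    missing = {"subject_id", "group"} - set(df.columns)
    if missing:
        raise ValueError(f"subjects table missing columns: {sorted(missing)}")
    bad = set(df["group"].unique()) - {"tinnitus", "control"}
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    if "excluded" in df.columns:
        df["excluded"] = df["excluded"].astype(bool)
    return df


def write_subjects_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = [c for c in SUBJECT_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df.to_csv(path, index=False, columns=cols)
    return path


def read_motion_trace(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a 6-column motion-parameter file.

    One row per volume: translations (mm, 3 cols) then rotations (deg, 3 cols).
    Returns ``(translations, rotations)`` arrays of shape (T, 3).
    """
    arr = np.loadtxt(path, ndmin=2)
    if arr.shape[1] != 6:
        raise ValueError(f"{path}: expected 6 columns, got {arr.shape[1]}")
    return arr[:, :3], arr[:, 3:]


def write_motion_trace(
    translations: np.ndarray, rotations: np.ndarray, path: str | Path
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.hstack([np.asarray(translations), np.asarray(rotations)])
    np.savetxt(path, arr, fmt="%.6f")
    return path
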