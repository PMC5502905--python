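"""File formats: NIfTI volumes with JSON sidecars, masks, CSV tables.

An echo series is stored as one NIfTI volume per slice with the echo
dimension on the 4th axis, plus a JSON sidecar holding ``echo_times_ms``,
``slice_thickness_mm``, ``voxel_size_mm`` and the generation seed.  Masks
are uint8 NIfTI; parameter maps are float32 NIfTI; tabular outputs are CSV
with documented headers.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np

from .relaxometry import EchoSeries, T2Map
from .segmentation import WallROI

__all__ = [
    "write_echo_series", "read_echo_series",
    "write_mask", "read_mask", "write_roi", "read_roi",
    "write_t2map", "read_t2map", "write_json",
]


def _affine(voxel_size: float, slice_thickness: float) -> np.ndarray:
    return np.diag([voxel_size, voxel_size, slice_thickness, 1.0])


def write_json(obj, path) -> None:
    """Deterministic JSON: sorted keys, fixed float formatting via repr."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_echo_series(series: EchoSeries, path, seed: Optional[int] = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    vol = np.transpose(series.data, (1, 2, 0))[:, :, None, :].astype(np.float32)
    voxel_size = float(np.sqrt(series.voxel_area))
    nib.save(nib.Nifti1Image(vol, _affine(voxel_size, series.slice_thickness)), str(path))
    sidecar = {
        "echo_times_ms": [float(t) for t in series.echo_times],
        "slice_index": int(series.slice_index),
        "slice_thickness_mm": float(series.slice_thickness),
        "voxel_size_mm": voxel_size,
    }
    if seed is not None:
        sidecar["seed"] = int(seed)
    write_json(sidecar, path.parent / (path.name.split(".")[0] + ".json"))


def read_echo_series(path) -> EchoSeries:
    path = Path(path)
    img = nib.load(str(path))
    vol = np.asarray(img.dataobj, dtype=float)
    if vol.ndim == 4:
        vol = vol[:, :, 0, :]
    sidecar_path = path.parent / (path.name.split(".")[0] + ".json")
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    data = np.transpose(vol, (2, 0, 1))
    return EchoSeries(
        data=data,
        echo_times=np.asarray(meta["echo_times_ms"], dtype=float),
        slice_index=int(meta.get("slice_index", 0)),
        voxel_area=float(meta.get("voxel_size_mm", 0.2)) ** 2,
        slice_thickness=float(meta.get("slice_thickness_mm", 2.0)),
    )


def write_mask(mask: np.ndarray, path, voxel_size: float = 0.2,
               slice_thickness: float = 2.0) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(mask, dtype=np.uint8)[:, :, None]
    nib.save(nib.Nifti1Image(arr, _affine(voxel_size, slice_thickness)), str(path))


def read_mask(path) -> np.ndarray:
    vol = np.asarray(nib.load(str(path)).dataobj)
    return np.squeeze(vol).astype(bool)


def write_roi(roi: WallROI, lumen_path, outer_path) -> None:
    vs = float(np.sqrt(roi.voxel_area))
    write_mask(roi.lumen_mask, lumen_path, voxel_size=vs)
    write_mask(roi.outer_mask, outer_path, voxel_size=vs)


def read_roi(lumen_path, outer_path, voxel_area: float = 0.04) -> WallROI:
    return WallROI(lumen_mask=read_mask(lumen_path), outer_mask=read_mask(outer_path),
                   voxel_area=voxel_area)


def write_t2map(t2map: T2Map, stem) -> None:
    """Write t2/s0/rsq/valid maps as ``<stem>_{t2,s0,rsq,valid}.nii.gz``."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    vs = float(np.sqrt(t2map.voxel_area))
    aff = _affine(vs, t2map.slice_thickness)
    for name, arr, dtype in (
        ("t2", t2map.t2, np.float32), ("s0", t2map.s0, np.float32),
        ("rsq", t2map.rsq, np.float32), ("valid", t2map.valid, np.uint8),
        ("reason", t2map.reason, np.uint8),
    ):
        img = nib.Nifti1Image(np.asarray(arr, dtype=dtype)[:, :, None], aff)
        nib.save(img, str(stem.parent / f"{stem.name}_{name}.nii.gz"))


def read_t2map(stem, voxel_area: float = 0.04, slice_thickness: float = 2.0) -> T2Map:
    stem = Path(stem)

    def load(name, dtype):
        arr = np.asarray(nib.load(str(stem.parent / f"{stem.name}_{name}.nii.gz")).dataobj)
        return np.squeeze(arr).astype(dtype)

    return T2Map(
        t2=load("t2", float), s0=load("s0", float), rsq=load("rsq", float),
        valid=load("valid", bool), reason=load("reason", np.uint8),
        voxel_area=voxel_area, slice_thickness=slice_thickness,
    )
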