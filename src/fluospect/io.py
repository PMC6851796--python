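"""On-disk formats: NIfTI volumes/stacks with JSON sidecars.

Volumes keep the package's (x, y, z) axis order; the NIfTI affine encodes the
isotropic voxel size.  Projection stacks are stored as 3D arrays
(frames x rows x cols); motion vector fields as 5D arrays
(bins x nx x ny x nz x 3) with a JSON summary of the per-bin scalar shifts.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["save_volume", "load_volume", "save_stack", "load_stack",
           "save_mvf", "load_mvf"]


def save_volume(path, volume: np.ndarray, voxel_size_mm: float) -> None:
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine),
             str(path))


def load_volume(path):
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), float(img.header.get_zooms()[0])


def save_stack(path, stack: np.ndarray, sidecar: dict | None = None) -> None:
    nib.save(nib.Nifti1Image(np.asarray(stack, dtype=np.float32), np.eye(4)),
             str(path))
    if sidecar is not None:
        Path(str(path).split(".nii")[0] + ".json").write_text(
            json.dumps(sidecar, indent=2))


def load_stack(path):
    data = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    side = Path(str(path).split(".nii")[0] + ".json")
    meta = json.loads(side.read_text()) if side.exists() else {}
    return data, meta


def save_mvf(path, mvf) -> None:
    arr = np.stack([mvf.forward_mm, mvf.inverse_mm])  # (2, B, nx, ny, nz, 3)
    nib.save(nib.Nifti1Image(arr.astype(np.float32), np.eye(4)), str(path))
    summary = {"diaphragm_shift_mm": mvf.diaphragm_shift_mm.tolist(),
               "sternum_shift_mm": mvf.sternum_shift_mm.tolist(),
               "voxel_size_mm": mvf.voxel_size_mm,
               "bin_labels": list(mvf.bin_labels or [])}
    Path(str(path).split(".nii")[0] + ".json").write_text(
        json.dumps(summary, indent=2))


def load_mvf(path):
    from .cbct import MotionVectorField
    arr = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    meta = json.loads(Path(str(path).split(".nii")[0] + ".json").read_text())
    return MotionVectorField(
        forward_mm=arr[0], inverse_mm=arr[1],
        diaphragm_shift_mm=np.asarray(meta["diaphragm_shift_mm"]),
        sternum_shift_mm=np.asarray(meta["sternum_shift_mm"]),
        voxel_size_mm=meta["voxel_size_mm"],
        bin_labels=tuple(meta["bin_labels"]) or None)
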