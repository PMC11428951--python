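"""File I/O: NIfTI volumes, multi-page TIFF projection stacks, weight matrices."""

from __future__ import annotations

import json
import os

import nibabel as nib
import numpy as np
import tifffile

from .forward import ProjectionSet
from .geometry import VoxelGrid


def save_volume_nifti(volume: np.ndarray, grid: VoxelGrid, path: str) -> None:
    """Write a (nz, ny, nx) volume as NIfTI with voxel spacing in the header.

    Data is stored x-fastest (nx, ny, nz) per NIfTI convention.
    """
    data = np.asarray(volume, dtype=np.float32).transpose(2, 1, 0)
    affine = np.diag([grid.dx_mm, grid.dy_mm, grid.dz_mm, 1.0])
    nib.save(nib.Nifti1Image(data, affine), path)


def load_volume_nifti(path: str) -> tuple[np.ndarray, VoxelGrid]:
    img = nib.load(path)
    data = np.asarray(img.dataobj, dtype=float).transpose(2, 1, 0)
    dx, dy, dz = np.abs(np.diag(img.affine)[:3])
    nz, ny, nx = data.shape
    return data, VoxelGrid(nx, ny, nz, float(dx), float(dy), float(dz))


def save_projections_tiff(projections: ProjectionSet, path: str) -> None:
    """One TIFF page per view plus a JSON sidecar with the view angles."""
    tifffile.imwrite(path, projections.images.astype(np.float32))
    with open(path + ".angles.json", "w") as fh:
        json.dump({"angles_deg": projections.angles_deg.tolist()}, fh)


def load_projections_tiff(path: str) -> ProjectionSet:
    images = tifffile.imread(path).astype(float)
    sidecar = path + ".angles.json"
    if os.path.exists(sidecar):
        with open(sidecar) as fh:
            angles = np.asarray(json.load(fh)["angles_deg"], dtype=float)
    else:
        angles = np.arange(len(images)) * (360.0 / len(images))
    return ProjectionSet(images, angles)


def save_weight_matrix(W: np.ndarray, grid: VoxelGrid, n_views: int,
                       detector_pixels: int, path: str) -> None:
    """Compressed container with the index-map metadata needed to reuse W."""
    np.savez_compressed(
        path, W=W.astype(np.float32),
        meta=np.frombuffer(json.dumps({
            "grid": {"nx": grid.nx, "ny": grid.ny, "nz": grid.nz,
                     "dx_mm": grid.dx_mm, "dy_mm": grid.dy_mm, "dz_mm": grid.dz_mm},
            "n_views": n_views, "detector_pixels": detector_pixels,
            "stacking": "view-major, row-major within view",
        }).encode(), dtype=np.uint8))


def load_weight_matrix(path: str) -> tuple[np.ndarray, VoxelGrid, dict]:
    with np.load(path) as data:
        W = data["W"]
        meta = json.loads(bytes(data["meta"]).decode())
    g = meta["grid"]
    return W, VoxelGrid(**g), meta
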