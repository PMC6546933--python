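"""NIfTI and sidecar-config I/O helpers shared by the pipeline stages."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import yaml


def affine_from_voxel_size(voxel_size_mm) -> np.ndarray:
    aff = np.eye(4)
    for i, v in enumerate(voxel_size_mm):
        aff[i, i] = v
    return aff


def write_nifti(path: str | Path, data: np.ndarray, voxel_size_mm) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(
        np.asarray(data, dtype=np.float32), affine_from_voxel_size(voxel_size_mm)
    )
    img.header.set_zooms(tuple(voxel_size_mm) + (1.0,) * (data.ndim - 3))
    nib.save(img, str(path))
    return path


def read_nifti(path: str | Path) -> tuple[np.ndarray, tuple[float, ...]]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, zooms


def save_yaml(path: str | Path, obj: dict) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(obj, sort_keys=True))
    return path


def load_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())
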