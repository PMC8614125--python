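"""NIfTI volume, transform and k-space archive I/O."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .forward_model import RigidTransform

__all__ = [
    "Volume",
    "read_volume",
    "write_volume",
    "save_transforms",
    "load_transforms",
    "save_kspace",
    "load_kspace",
]


@dataclass
class Volume:
    """A 3D (or coil-indexed 4D) volume with voxel spacing in mm."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray | None = None

    def __post_init__(self):
        if self.values.ndim not in (3, 4):
            raise ValueError("expected a 3D volume or a 4D coil-indexed stack")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be strictly positive")

    @property
    def shape(self):
        return self.values.shape


def _default_affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def read_volume(path) -> Volume:
    """Read a NIfTI volume; a 4D file is returned as a coil-indexed stack."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 4:
        data = np.moveaxis(data, -1, 0)  # coil axis first
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(values=data, spacing=spacing, affine=np.asarray(img.affine))


def write_volume(path, vol: Volume) -> None:
    """Write a volume as float32 NIfTI (complex volumes are written as magnitude)."""
    data = vol.values
    if np.iscomplexobj(data):
        data = np.abs(data)
    if data.ndim == 4:
        data = np.moveaxis(data, 0, -1)
    affine = vol.affine if vol.affine is not None else _default_affine(vol.spacing)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    img.header.set_zooms(tuple(vol.spacing) + ((1.0,) if data.ndim == 4 else ()))
    nib.save(img, str(path))


def save_transforms(path, transforms: list[RigidTransform]) -> None:
    Path(path).write_text(json.dumps([t.to_dict() for t in transforms], indent=1))


def load_transforms(path) -> list[RigidTransform]:
    return [RigidTransform.from_dict(d) for d in json.loads(Path(path).read_text())]


def save_kspace(path, **arrays) -> None:
    """Archive complex k-space arrays (and a sampling mask) as an .npz file."""
    np.savez_compressed(str(path), **arrays)


def load_kspace(path) -> dict[str, np.ndarray]:
    with np.load(str(path)) as z:
        return {k: z[k] for k in z.files}
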