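"""Volumetric containers and NIfTI I/O.

A :class:`Volume` is a 3-D scalar grid with physical voxel spacing in mm;
it carries images, fuzzy memberships, signed distance fields and thickness
maps.  A :class:`LabelMap` is an integer-valued volume assigning each voxel
one of the five codes below.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

# Tissue label codes.
BACKGROUND = 0
CSF = 1
GM = 2  # relatively unmyelinated cortical gray matter
MGM = 3  # well-myelinated cortical gray matter
WM = 4  # white matter

TISSUE_CLASSES = (CSF, GM, MGM, WM)
CLASS_NAMES = {
    BACKGROUND: "background",
    CSF: "csf",
    GM: "gm",
    MGM: "mgm",
    WM: "wm",
}


@dataclass
class Volume:
    """3-D scalar grid with voxel spacing and origin in mm."""

    data: np.ndarray
    spacing: tuple = (0.7, 0.7, 0.7)
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3-D, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive mm values, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self):
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def with_data(self, data: np.ndarray) -> "Volume":
        """New volume on the same grid (spacing/origin preserved)."""
        return Volume(np.asarray(data), self.spacing, self.origin)

    def same_grid(self, other: "Volume") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def to_nifti(self, path) -> None:
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine)
        img.header.set_zooms(self.spacing)
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path) -> "Volume":
        img = nib.load(str(path))
        zooms = img.header.get_zooms()[:3]
        origin = tuple(np.asarray(img.affine)[:3, 3])
        return cls(np.asarray(img.get_fdata()), tuple(zooms), origin)


@dataclass
class LabelMap(Volume):
    """Integer volume with codes {0 background, 1 CSF, 2 GM, 3 mGM, 4 WM}."""

    def __post_init__(self):
        super().__post_init__()
        if not np.issubdtype(self.data.dtype, np.integer):
            rounded = np.rint(self.data)
            if not np.allclose(self.data, rounded):
                raise ValueError("LabelMap data must be integer-valued")
            self.data = rounded.astype(np.int16)

    def class_mask(self, code: int) -> np.ndarray:
        return self.data == code

    def with_labels(self, data: np.ndarray) -> "LabelMap":
        return LabelMap(np.asarray(data), self.spacing, self.origin)

    def to_nifti(self, path) -> None:
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.int16), self.affine)
        img.header.set_zooms(self.spacing)
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path) -> "LabelMap":
        vol = Volume.from_nifti(path)
        return cls(np.rint(vol.data).astype(np.int16), vol.spacing, vol.origin)


def require_same_grid(*volumes: Volume, op: str = "operation") -> None:
    """Raise ValueError naming the mismatching shapes, if any."""
    first = volumes[0]
    for v in volumes[1:]:
        if not first.same_grid(v):
            raise ValueError(
                f"{op}: volumes are not on the same grid "
                f"(shapes {first.shape} vs {v.shape}, "
                f"spacings {first.spacing} vs {v.spacing})"
            )
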