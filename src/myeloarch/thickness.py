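"""Signed distance fields and level-set thickness maps.

Three nested tissue boundaries are represented as signed distance (level
set) functions over the volume:

    phi_p  — pial boundary (CSF | cortex),
    phi_m  — outer myelinated boundary (GM | mGM),
    phi_w  — outer white-matter boundary (mGM | WM),

each positive on the deep (white-matter-ward) side, negative on the
superficial (CSF-ward) side, with the zero crossing at the boundary.  For
nested, locally parallel boundaries the thickness maps follow by level-set
subtraction:

    t = phi_p - phi_w      (total cortical thickness)
    d = phi_p - phi_m      (superficial unmyelinated depth)
    m = t - d              (myelinated thickness)

evaluated over the cortical ribbon (GM plus mGM).  Where the boundaries are
not nested the subtraction can go negative; that condition is surfaced as a
warning with a voxel count rather than silently clipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import CLASS_NAMES, CSF, GM, MGM, WM, LabelMap, Volume, require_same_grid

#: deep-side label codes for each named boundary
BOUNDARY_DEEP = {
    "pial": (GM, MGM, WM),
    "outer_myelin": (MGM, WM),
    "outer_white": (WM,),
}


@dataclass
class DistanceField:
    """Signed distances (mm) to one tissue boundary."""

    volume: Volume
    boundary: str

    @property
    def data(self) -> np.ndarray:
        return self.volume.data


@dataclass
class ThicknessSet:
    """Thickness maps t, d, m (mm) over the cortical ribbon."""

    t: Volume
    d: Volume
    m: Volume
    ribbon_mask: Volume


def signed_distance(lab: LabelMap, boundary: str) -> DistanceField:
    """Euclidean signed distance field for one of the three boundaries.

    Computed with physical voxel spacing as the difference of the two
    one-sided unsigned distance transforms, with a half-voxel shift so the
    zero crossing falls on the interface between the two voxel sheets rather
    than on voxel centers.  Deterministic.
    """
    if boundary not in BOUNDARY_DEEP:
        raise ValueError(f"unknown boundary {boundary!r}; choose from {sorted(BOUNDARY_DEEP)}")
    deep_codes = BOUNDARY_DEEP[boundary]
    labels = np.asarray(lab.data)
    deep = np.isin(labels, deep_codes)
    if not deep.any():
        raise ValueError(
            f"boundary {boundary!r}: deep side empty "
            f"(missing {', '.join(CLASS_NAMES[c] for c in deep_codes)})"
        )
    if deep.all():
        raise ValueError(f"boundary {boundary!r}: superficial side empty (no CSF/background)")
    d_deep = ndimage.distance_transform_edt(deep, sampling=lab.spacing)
    d_sup = ndimage.distance_transform_edt(~deep, sampling=lab.spacing)
    raw = d_deep - d_sup  # positive deep, negative superficial
    h = 0.5 * float(np.mean(lab.spacing))
    phi = np.where(raw > 0, raw - h, raw + h)
    return DistanceField(Volume(phi, lab.spacing, lab.origin), boundary)


def ribbon_from_labels(lab: LabelMap) -> Volume:
    """Binary cortical ribbon: GM plus mGM."""
    labels = np.asarray(lab.data)
    return Volume(((labels == GM) | (labels == MGM)).astype(np.uint8),
                  lab.spacing, lab.origin)


def thickness_maps(phi_p: DistanceField, phi_m: DistanceField, phi_w: DistanceField,
                   ribbon: Volume) -> ThicknessSet:
    """Level-set subtraction: t = phi_p - phi_w, d = phi_p - phi_m, m = t - d.

    Values are reported on the ribbon mask (zero elsewhere).  A warning with
    the voxel count is emitted if t <= 0 anywhere on the ribbon, which flags
    a segmentation topology fault (non-nested boundaries).
    """
    require_same_grid(phi_p.volume, phi_m.volume, phi_w.volume, ribbon,
                      op="thickness_maps")
    rib = np.asarray(ribbon.data).astype(bool)
    t = phi_p.data - phi_w.data
    d = phi_p.data - phi_m.data
    m = t - d
    bad = int(np.count_nonzero((t <= 0) & rib))
    if bad:
        warnings.warn(
            f"non-positive cortical thickness at {bad} ribbon voxels "
            "(boundaries are not nested there)",
            RuntimeWarning,
        )
    zero = ~rib
    for arr in (t, d, m):
        arr[zero] = 0.0
    grid = phi_p.volume
    return ThicknessSet(
        t=grid.with_data(t),
        d=grid.with_data(d),
        m=grid.with_data(m),
        ribbon_mask=grid.with_data(rib.astype(np.uint8)),
    )


def cortical_thickness(lab: LabelMap) -> ThicknessSet:
    """Convenience chain: the three distance fields plus the thickness maps."""
    phi_p = signed_distance(lab, "pial")
    phi_m = signed_distance(lab, "outer_myelin")
    phi_w = signed_distance(lab, "outer_white")
    return thickness_maps(phi_p, phi_m, phi_w, ribbon_from_labels(lab))


def gradient_magnitude(df: DistanceField) -> Volume:
    """|grad phi| by central differences with physical spacing.

    A well-formed signed distance field has unit gradient magnitude away
    from the medial axis; useful as a diagnostic.
    """
    grads = np.gradient(df.data, *df.volume.spacing)
    mag = np.sqrt(sum(g**2 for g in grads))
    return df.volume.with_data(mag)
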