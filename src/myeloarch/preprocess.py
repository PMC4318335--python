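"""Repeat combination, FLASH denoising, and the bias-cancelling ratio image.

The T1-weighted and proton-density FLASH channels of the protocol share the
same receive-field profile, so dividing the summed T1w repeats by the
(median-filtered) summed FLASH image cancels the multiplicative field and
leaves myelin-driven tissue contrast.  Only the FLASH denominator is
smoothed; the T1w numerator keeps its full resolution.
"""

from __future__ import annotations

from scipy import ndimage
import numpy as np

from .volume import Volume, require_same_grid


def sum_repeats(repeats) -> Volume:
    """Voxelwise sum of co-registered repeat acquisitions."""
    repeats = list(repeats)
    if not repeats:
        raise ValueError("need at least one repeat")
    require_same_grid(*repeats, op="sum_repeats")
    total = np.zeros(repeats[0].shape, dtype=float)
    for r in repeats:
        total += r.data
    return repeats[0].with_data(total)


def median_filter_3d(vol: Volume, kernel_voxels: int = 3, passes: int = 2) -> Volume:
    """Repeated cubic median filtering with reflect border handling.

    Two passes of a 3-voxel kernel approximate a single larger kernel while
    preserving edges; a constant volume is a fixed point.
    """
    if kernel_voxels < 1 or kernel_voxels % 2 == 0:
        raise ValueError(f"kernel_voxels must be odd and >= 1, got {kernel_voxels}")
    if passes < 0:
        raise ValueError("passes must be non-negative")
    data = np.asarray(vol.data, dtype=float)
    for _ in range(passes):
        data = ndimage.median_filter(data, size=kernel_voxels, mode="reflect")
    return vol.with_data(data)


def ratio_image(t1w_sum: Volume, flash_filtered: Volume, eps: float | None = None,
                mask: np.ndarray | None = None):
    """Voxelwise T1w / FLASH with a guard against a vanishing denominator.

    Voxels where the denominator falls below ``eps`` are set to 0 and
    counted; the count is returned alongside the ratio volume.  ``eps``
    defaults to 1e-6 of the median (in-mask) FLASH intensity, a scale-free
    guard.

    Returns
    -------
    (Volume, int)
        The ratio image and the number of guarded voxels.
    """
    require_same_grid(t1w_sum, flash_filtered, op="ratio_image")
    flash = np.asarray(flash_filtered.data, dtype=float)
    if eps is None:
        ref = flash[mask] if mask is not None else flash
        scale = float(np.median(np.abs(ref)))
        eps = 1e-6 * scale if scale > 0 else 1e-12
    bad = flash < eps
    ratio = np.zeros_like(flash)
    np.divide(np.asarray(t1w_sum.data, dtype=float), flash, out=ratio, where=~bad)
    n_flagged = int(bad.sum()) if mask is None else int((bad & mask).sum())
    return t1w_sum.with_data(ratio), n_flagged


def shift_volume(vol: Volume, shift_voxels) -> Volume:
    """Integer-voxel translation with zero fill (alignment plumbing only)."""
    shift = tuple(int(s) for s in shift_voxels)
    out = np.zeros_like(np.asarray(vol.data, dtype=float))
    src = []
    dst = []
    for n, s in zip(vol.shape, shift):
        src.append(slice(max(0, -s), n - max(0, s)))
        dst.append(slice(max(0, s), n - max(0, -s)))
    out[tuple(dst)] = vol.data[tuple(src)]
    return vol.with_data(out)


def preprocess(t1w_repeats, flash_repeats, kernel_voxels: int = 3, passes: int = 2,
               eps: float | None = None, mask: np.ndarray | None = None):
    """Full preprocessing chain: sum repeats, filter FLASH, form the ratio.

    Returns the ratio volume and the guarded-voxel count.
    """
    t1w = sum_repeats(t1w_repeats)
    flash = sum_repeats(flash_repeats)
    flash = median_filter_3d(flash, kernel_voxels=kernel_voxels, passes=passes)
    return ratio_image(t1w, flash, eps=eps, mask=mask)
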