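"""Fuzzy c-means tissue segmentation of the ratio image.

The masked ratio image is partitioned into four intensity classes — CSF,
unmyelinated gray matter (GM), well-myelinated gray matter (mGM) and white
matter (WM) — by standard fuzzy c-means (FCM).  FCM minimizes

    J = sum_i sum_k  u_ik^q (x_i - c_k)^2,   sum_k u_ik = 1,

by alternating the membership update

    u_ik = 1 / sum_j [ (x_i - c_k)^2 / (x_i - c_j)^2 ]^(1/(q-1))

with the centroid update  c_k = sum_i u_ik^q x_i / sum_i u_ik^q.  Classes
are relabeled by ascending centroid so the CSF < GM < mGM < WM intensity
ordering of the ratio contrast maps onto the label codes.

Memberships are turned into labels by argmax, with one asymmetry: voxels
whose WM membership reaches a low threshold (default 0.1) *and* that are
3-D-connected to the main WM body are relabeled WM, capturing the very thin
WM blades in gyral crowns where partial voluming depresses WM intensity.
Finally, per-class islands disconnected from the largest component are
removed and reassigned by next-highest membership.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import BACKGROUND, CSF, GM, MGM, WM, TISSUE_CLASSES, LabelMap, Volume


@dataclass
class MembershipSet:
    """Per-class fuzzy memberships (each a Volume in [0, 1]) and centroids.

    Classes are ordered by ascending centroid: index 0 is CSF, 3 is WM.
    Memberships sum to 1 at every in-mask voxel and are 0 outside the mask.
    """

    memberships: list
    centroids: np.ndarray
    mask: np.ndarray
    objective_history: list = field(default_factory=list)
    converged: bool = True

    @property
    def n_classes(self) -> int:
        return len(self.memberships)

    def stack(self) -> np.ndarray:
        """Memberships as a (K, *shape) array."""
        return np.stack([m.data for m in self.memberships])


def _connectivity_structure(connectivity: int):
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 18:
        return ndimage.generate_binary_structure(3, 2)
    raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}")


def fuzzy_c_means(vol: Volume, mask: np.ndarray | Volume, n_classes: int = 4,
                  fuzziness: float = 2.0, tol: float = 1e-5, max_iter: int = 300,
                  init: str = "spread", seed: int | None = None) -> MembershipSet:
    """Cluster in-mask intensities into ``n_classes`` fuzzy classes.

    Parameters
    ----------
    init:
        ``"spread"`` (default) places initial centroids evenly between the
        1st and 99th in-mask intensity percentiles, which is robust to
        strongly unbalanced class sizes; ``"quantile"`` uses the
        (2k+1)/(2K) intensity quantiles; ``"random"`` samples in-mask
        intensities (requires ``seed`` for reproducibility).
    tol:
        Relative centroid change (infinity norm over centroids, scaled by
        the intensity range) declaring convergence.

    Voxels whose intensity coincides exactly with a centroid get a one-hot
    membership for that class, the correct limit of the update formula.
    """
    if isinstance(mask, Volume):
        mask = mask.data
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("mask is empty")
    x = np.asarray(vol.data, dtype=float)[mask]
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite intensities inside the mask")
    if np.unique(x).size < n_classes:
        raise ValueError(
            f"only {np.unique(x).size} distinct in-mask intensities for {n_classes} classes"
        )
    if fuzziness <= 1:
        raise ValueError("fuzziness must be > 1")

    lo, hi = np.percentile(x, [1, 99])
    scale = max(hi - lo, np.ptp(x) * 1e-3, 1e-12)
    if init == "spread":
        c = lo + (np.arange(n_classes) + 0.5) / n_classes * (hi - lo)
    elif init == "quantile":
        c = np.quantile(x, (2 * np.arange(n_classes) + 1) / (2 * n_classes))
    elif init == "random":
        rng = np.random.default_rng(seed)
        c = np.sort(rng.choice(x, size=n_classes, replace=False))
    else:
        raise ValueError(f"unknown init {init!r}")
    c = np.asarray(c, dtype=float)

    expo = 1.0 / (fuzziness - 1.0)
    history = []
    converged = False
    u = None
    for _ in range(max_iter):
        u = _memberships(x, c, expo)
        w = u**fuzziness
        d2 = (x[:, None] - c[None, :]) ** 2
        history.append(float(np.sum(w * d2)))
        denom = w.sum(axis=0)
        c_new = (w * x[:, None]).sum(axis=0) / np.where(denom > 0, denom, 1.0)
        shift = np.max(np.abs(c_new - c)) / scale
        c = c_new
        if shift < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"fuzzy_c_means did not converge in {max_iter} iterations; "
            "returning current state",
            RuntimeWarning,
        )
    u = _memberships(x, c, expo)

    order = np.argsort(c)
    c = c[order]
    u = u[:, order]

    vols = []
    for k in range(n_classes):
        full = np.zeros(vol.shape, dtype=float)
        full[mask] = u[:, k]
        vols.append(vol.with_data(full))
    return MembershipSet(vols, c, mask, history, converged)


def _memberships(x: np.ndarray, c: np.ndarray, expo: float) -> np.ndarray:
    d2 = (x[:, None] - c[None, :]) ** 2
    zero = d2 == 0.0
    hit = zero.any(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = d2 ** (-expo)
        u = inv / inv.sum(axis=1, keepdims=True)
    if hit.any():
        u[hit] = 0.0
        # split ties evenly among coincident centroids
        z = zero[hit]
        u[hit] = z / z.sum(axis=1, keepdims=True)
    return u


def threshold_memberships(ms: MembershipSet, level_default: float = 0.5,
                          level_wm: float = 0.1, connectivity: int = 26) -> LabelMap:
    """Convert memberships to labels.

    Every in-mask voxel gets its argmax class (which subsumes thresholding
    the non-WM classes at ``level_default``: a membership above 0.5 is
    necessarily the argmax, and argmax resolves the remaining voxels so the
    labeling is total).  Voxels with WM membership >= ``level_wm`` that are
    3-D-connected to the argmax-WM body are then relabeled WM, recovering
    thin, partial-volumed WM blades.
    """
    u = ms.stack()
    labels = np.zeros(u.shape[1:], dtype=np.int16)
    labels[ms.mask] = np.argmax(u[:, ms.mask], axis=0) + CSF

    wm_u = u[ms.n_classes - 1]
    body = labels == WM
    candidates = (wm_u >= level_wm) & ms.mask & ~body
    if body.any() and candidates.any():
        structure = _connectivity_structure(connectivity)
        comp, n = ndimage.label(body | candidates, structure=structure)
        attached = np.unique(comp[body])
        attached = attached[attached > 0]
        grow = candidates & np.isin(comp, attached)
        labels[grow] = WM

    ref = ms.memberships[0]
    return LabelMap(labels, ref.spacing, ref.origin)


def remove_islands(lab: LabelMap, memberships: MembershipSet | None = None,
                   connectivity: int = 26) -> LabelMap:
    """Keep, per tissue class, only the largest 3-D-connected component.

    Voxels of removed islands are reassigned to their next-highest-membership
    class when a :class:`MembershipSet` is given, otherwise to background.
    """
    structure = _connectivity_structure(connectivity)
    labels = np.asarray(lab.data).copy()
    removed_from = np.zeros_like(labels, dtype=bool)
    removed_class = np.zeros_like(labels)

    for code in TISSUE_CLASSES:
        m = labels == code
        if not m.any():
            warnings.warn(f"class {code} is empty; nothing to de-island", RuntimeWarning)
            continue
        comp, n = ndimage.label(m, structure=structure)
        if n <= 1:
            continue
        sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1  # ties: lowest component id, deterministic
        drop = m & (comp != keep)
        removed_from |= drop
        removed_class[drop] = code

    if not removed_from.any():
        return lab.with_labels(labels)

    if memberships is None:
        labels[removed_from] = BACKGROUND
    else:
        u = memberships.stack()
        idx = np.argwhere(removed_from)
        for z, y, x in idx:
            own = removed_class[z, y, x] - CSF
            vals = u[:, z, y, x].copy()
            vals[own] = -1.0
            best = int(np.argmax(vals))
            labels[z, y, x] = best + CSF if vals[best] > 0 else BACKGROUND
    return lab.with_labels(labels)


def segment(ratio: Volume, mask: np.ndarray | Volume, level_wm: float = 0.1,
            connectivity: int = 26, **fcm_kwargs):
    """Full segmentation chain: FCM, thresholding, island removal.

    Returns ``(LabelMap, MembershipSet)``.
    """
    ms = fuzzy_c_means(ratio, mask, **fcm_kwargs)
    lab = threshold_memberships(ms, level_wm=level_wm, connectivity=connectivity)
    lab = remove_islands(lab, memberships=ms, connectivity=connectivity)
    return lab, ms


def dice_score(a: LabelMap, b: LabelMap, code: int) -> float:
    """Dice overlap of one label class between two label maps."""
    ma = np.asarray(a.data) == code
    mb = np.asarray(b.data) == code
    denom = ma.sum() + mb.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(ma, mb).sum() / denom
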