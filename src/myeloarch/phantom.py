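"""Synthetic two-channel phantoms and cohorts with known ground truth.

Real myelin-sensitive acquisitions of the cortex are rarely shareable, so
every downstream stage of the pipeline is exercised against phantoms that
emulate a 0.7 mm isotropic two-channel protocol: a T1-weighted channel with
four nested tissue classes (CSF, unmyelinated GM, myelinated mGM, WM), a
predominantly proton-density FLASH channel, a smooth multiplicative
receive-field bias shared between the channels, and additive noise per
repeat.  Ground-truth thickness maps (total cortical thickness ``t``,
superficial unmyelinated depth ``d`` and myelinated thickness ``m = t - d``)
are known analytically for each geometry.

Three geometries are provided:

``slab``
    Parallel planar boundaries; thickness maps are spatially constant.
``spherical_shell``
    Concentric spheres; exercises curvature at constant thickness.
``folded_sheet``
    A sinusoidally displaced slab whose deeper boundaries are true offset
    surfaces of the pial sheet (built from a Euclidean distance transform),
    so the normal separations still equal ``d`` and ``t`` wherever the fold
    curvature radius exceeds the cortical thickness.

A cohort generator produces per-subject left/right ROI tables with
controlled percent bilateral asymmetry for the group-statistics module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .stats import bilateral_asymmetry
from .volume import CSF, GM, MGM, WM, CLASS_NAMES, LabelMap, Volume

GEOMETRIES = ("slab", "spherical_shell", "folded_sheet")

# Fixed receive-bump placement (fractions of the field of view) so that a
# given bias_amplitude always produces the same, clearly inhomogeneous field.
_BIAS_CENTER_FRAC = (0.35, 0.40, 0.45)
_BIAS_SIGMA_FRAC = 0.35


@dataclass
class PhantomSpec:
    """Parameters of a synthetic two-channel acquisition.

    Thicknesses are in mm; intensities are arbitrary units.  ``class_means``
    are ordered (CSF, GM, mGM, WM) and must be strictly increasing on the
    T1w channel, matching the myelin-driven contrast ordering of the ratio
    image.  ``bias_amplitude`` is the peak deviation of the shared
    multiplicative receive field around 1.
    """

    geometry: str = "slab"
    voxel_size: float | tuple = 0.7
    shape: tuple = (48, 40, 40)
    t_true: float = 4.5
    d_true: float = 1.5
    class_means_t1w: tuple = (0.2, 0.55, 0.75, 1.0)
    class_means_flash: tuple = (1.0, 1.0, 1.0, 1.0)
    bias_amplitude: float = 0.0
    noise_sigma: float = 0.0
    noise_model: str = "gaussian"
    n_repeats: int = 2
    seed: int = 0
    # geometry details
    pial_offset_frac: float = 0.25
    shell_outer_radius: float | None = None
    fold_amplitude: float = 1.5
    fold_wavelength: float = 20.0

    @property
    def spacing(self) -> tuple:
        if np.isscalar(self.voxel_size):
            return (float(self.voxel_size),) * 3
        return tuple(float(s) for s in self.voxel_size)

    def validate(self) -> None:
        if self.geometry not in GEOMETRIES:
            raise ValueError(f"unknown geometry {self.geometry!r}; choose from {GEOMETRIES}")
        if not (0 < self.d_true < self.t_true):
            raise ValueError("require 0 < d_true < t_true")
        if self.t_true > 6.0:
            raise ValueError("t_true > 6 mm is implausible for cortex")
        means = np.asarray(self.class_means_t1w, dtype=float)
        if means.shape != (4,) or np.any(np.diff(means) <= 0):
            raise ValueError("class_means_t1w must be 4 strictly increasing values (CSF<GM<mGM<WM)")
        if len(self.class_means_flash) != 4:
            raise ValueError("class_means_flash must have 4 entries")
        if not (0 <= self.bias_amplitude < 1):
            raise ValueError("bias_amplitude must lie in [0, 1) to keep the field positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError("noise_model must be 'gaussian' or 'rician'")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        self._check_class_extents()

    def _check_class_extents(self) -> None:
        """Reject geometries where any tissue class is under 2 voxels thick."""
        s = self.spacing
        vmax = max(s)
        if self.d_true < 2 * vmax:
            raise ValueError(f"GM shell thinner than 2 voxels (d_true={self.d_true} mm)")
        if self.t_true - self.d_true < 2 * vmax:
            raise ValueError(
                f"mGM shell thinner than 2 voxels (t_true-d_true={self.t_true - self.d_true} mm)"
            )
        extent0 = self.shape[0] * s[0]
        if self.geometry in ("slab", "folded_sheet"):
            amp = self.fold_amplitude if self.geometry == "folded_sheet" else 0.0
            pial = self._pial_offset()
            if pial - amp < 2 * s[0]:
                raise ValueError("CSF layer thinner than 2 voxels; increase pial_offset_frac")
            if extent0 - (pial + amp) - self.t_true < 2 * s[0]:
                raise ValueError("WM compartment thinner than 2 voxels; enlarge shape along axis 0")
        else:
            R = self._shell_radius()
            half = min(n * sp for n, sp in zip(self.shape, s)) / 2
            if half - R < 2 * vmax:
                raise ValueError("CSF margin outside the shell thinner than 2 voxels")
            if R - self.t_true < 2 * vmax:
                raise ValueError("WM core thinner than 2 voxels; increase shell_outer_radius")

    def _pial_offset(self) -> float:
        # Snap the pial plane to an integer multiple of the axis-0 spacing so
        # that it sits midway between voxel centers (centers at (i+0.5)*s).
        s0 = self.spacing[0]
        return round(self.pial_offset_frac * self.shape[0]) * s0

    def _shell_radius(self) -> float:
        if self.shell_outer_radius is not None:
            return float(self.shell_outer_radius)
        s = self.spacing
        half = min(n * sp for n, sp in zip(self.shape, s)) / 2
        return half - 2.5 * max(s)


@dataclass
class PhantomOutput:
    """Generated channels plus ground truth on a common grid."""

    t1w_repeats: list
    flash_repeats: list
    truth_labels: LabelMap
    truth_t: Volume
    truth_d: Volume
    truth_m: Volume
    brain_mask: Volume
    bias: Volume
    spec: PhantomSpec = None

    @property
    def ribbon(self) -> np.ndarray:
        lab = self.truth_labels.data
        return (lab == GM) | (lab == MGM)


def _axis_coords(shape, spacing):
    """Physical voxel-center coordinates (mm) per axis."""
    return [(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)]


def _depth_field(spec: PhantomSpec) -> np.ndarray:
    """Signed depth below the pial surface (mm, positive deep) at voxel centers."""
    z, y, x = _axis_coords(spec.shape, spec.spacing)
    if spec.geometry == "slab":
        return z[:, None, None] - spec._pial_offset() + np.zeros(spec.shape)
    if spec.geometry == "spherical_shell":
        c = [n * s / 2 for n, s in zip(spec.shape, spec.spacing)]
        r = np.sqrt(
            (z[:, None, None] - c[0]) ** 2
            + (y[None, :, None] - c[1]) ** 2
            + (x[None, None, :] - c[2]) ** 2
        )
        return spec._shell_radius() - r
    # folded_sheet: signed Euclidean distance to the sinusoidal pial surface,
    # so deeper boundaries are true offset surfaces of the pial sheet.
    pial = spec._pial_offset() + spec.fold_amplitude * np.sin(
        2 * np.pi * y / spec.fold_wavelength
    )
    inside = z[:, None, None] >= pial[None, :, None] + np.zeros(spec.shape)
    d_in = ndimage.distance_transform_edt(inside, sampling=spec.spacing)
    d_out = ndimage.distance_transform_edt(~inside, sampling=spec.spacing)
    raw = d_in - d_out
    h = 0.5 * float(np.mean(spec.spacing))  # zero crossing between voxel centers
    return np.where(raw > 0, raw - h, raw + h)


def bias_field(shape, spacing, amplitude: float) -> np.ndarray:
    """Smooth multiplicative receive-field model: 1 + amplitude * Gaussian bump.

    The bump center and width are fixed fractions of the field of view, so the
    field peaks at 1 + amplitude inside the volume and decays toward 1 at the
    far corner.  Strictly positive for amplitude in [0, 1).
    """
    if amplitude == 0:
        return np.ones(shape)
    coords = _axis_coords(shape, spacing)
    extents = [n * s for n, s in zip(shape, spacing)]
    q = np.zeros(shape)
    for ax, (c, ext) in enumerate(zip(coords, extents)):
        mu = _BIAS_CENTER_FRAC[ax] * ext
        sig = _BIAS_SIGMA_FRAC * ext
        sl = [None, None, None]
        sl[ax] = slice(None)
        q = q + (((c - mu) / sig) ** 2)[tuple(sl)]
    return 1.0 + amplitude * np.exp(-0.5 * q)


def make_phantom(spec: PhantomSpec) -> PhantomOutput:
    """Generate channels, labels and ground-truth thickness maps.

    Both channels are the per-class mean intensity times one shared bias
    field, plus independent noise per repeat; identical seeds give
    bit-identical output.
    """
    spec.validate()
    spacing = spec.spacing
    depth = _depth_field(spec)

    labels = np.select(
        [depth < 0, depth < spec.d_true, depth < spec.t_true],
        [CSF, GM, MGM],
        default=WM,
    ).astype(np.int16)
    lab = LabelMap(labels, spacing)

    ribbon = (labels == GM) | (labels == MGM)
    truth_t = np.where(ribbon, spec.t_true, 0.0)
    truth_d = np.where(ribbon, spec.d_true, 0.0)
    truth_m = truth_t - truth_d

    b = bias_field(spec.shape, spacing, spec.bias_amplitude)
    lut_t1w = np.zeros(5)
    lut_t1w[1:] = spec.class_means_t1w
    lut_flash = np.zeros(5)
    lut_flash[1:] = spec.class_means_flash
    clean_t1w = lut_t1w[labels] * b
    clean_flash = lut_flash[labels] * b

    rng = np.random.default_rng(spec.seed)

    def noisy(clean):
        if spec.noise_sigma == 0:
            return clean.copy()
        if spec.noise_model == "gaussian":
            return clean + rng.normal(0.0, spec.noise_sigma, spec.shape)
        n1 = rng.normal(0.0, spec.noise_sigma, spec.shape)
        n2 = rng.normal(0.0, spec.noise_sigma, spec.shape)
        return np.sqrt((clean + n1) ** 2 + n2**2)

    t1w_repeats = [Volume(noisy(clean_t1w), spacing) for _ in range(spec.n_repeats)]
    flash_repeats = [Volume(noisy(clean_flash), spacing) for _ in range(spec.n_repeats)]

    return PhantomOutput(
        t1w_repeats=t1w_repeats,
        flash_repeats=flash_repeats,
        truth_labels=lab,
        truth_t=Volume(truth_t, spacing),
        truth_d=Volume(truth_d, spacing),
        truth_m=Volume(truth_m, spacing),
        brain_mask=Volume(np.ones(spec.shape), spacing),
        bias=Volume(b, spacing),
        spec=spec,
    )


def write_phantom(out: PhantomOutput, outdir) -> None:
    """Write channels, truth maps and a JSON manifest as NIfTI-1 + sidecars."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i, vol in enumerate(out.t1w_repeats):
        vol.to_nifti(outdir / f"t1w_rep{i + 1}.nii.gz")
    for i, vol in enumerate(out.flash_repeats):
        vol.to_nifti(outdir / f"flash_rep{i + 1}.nii.gz")
    out.truth_labels.to_nifti(outdir / "truth_labels.nii.gz")
    out.truth_t.to_nifti(outdir / "truth_t.nii.gz")
    out.truth_d.to_nifti(outdir / "truth_d.nii.gz")
    out.truth_m.to_nifti(outdir / "truth_m.nii.gz")
    out.brain_mask.to_nifti(outdir / "brain_mask.nii.gz")
    spec = out.spec
    manifest = {
        "geometry": spec.geometry,
        "voxel_size_mm": spec.spacing,
        "shape": list(spec.shape),
        "t_true_mm": spec.t_true,
        "d_true_mm": spec.d_true,
        "m_true_mm": spec.t_true - spec.d_true,
        "class_means_t1w": list(spec.class_means_t1w),
        "class_means_flash": list(spec.class_means_flash),
        "bias_amplitude": spec.bias_amplitude,
        "noise_sigma": spec.noise_sigma,
        "noise_model": spec.noise_model,
        "n_repeats": spec.n_repeats,
        "seed": spec.seed,
        "label_codes": {str(k): v for k, v in CLASS_NAMES.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


# ---------------------------------------------------------------------------
# Synthetic cohorts


@dataclass
class CohortSpec:
    """Controlled left/right ROI-mean tables for the asymmetry statistics.

    ``asym_mean``/``asym_sd`` are the target percent bilateral asymmetry of
    each group (scalars, per-group dicts, or per-(group, metric) dicts).
    Defaults reproduce the regime of a small precentral-ROI study: myelinated
    thickness around 3.1-3.4 mm with ~17% asymmetry, cortical thickness
    around 4 mm with 8-15% asymmetry.
    """

    n_per_group: int = 4
    groups: tuple = ("control", "amputee")
    metric_names: tuple = ("myelinated_thickness", "cortical_thickness")
    mean_left: float | dict = field(
        default_factory=lambda: {
            ("control", "myelinated_thickness"): 3.4,
            ("amputee", "myelinated_thickness"): 3.4,
            ("control", "cortical_thickness"): 4.1,
            ("amputee", "cortical_thickness"): 4.4,
        }
    )
    mean_right: float | dict = field(
        default_factory=lambda: {
            ("control", "myelinated_thickness"): 3.2,
            ("amputee", "myelinated_thickness"): 2.8,
            ("control", "cortical_thickness"): 4.2,
            ("amputee", "cortical_thickness"): 3.8,
        }
    )
    asym_mean: float | dict = field(
        default_factory=lambda: {
            ("control", "myelinated_thickness"): 17.0,
            ("amputee", "myelinated_thickness"): 17.0,
            ("control", "cortical_thickness"): 8.0,
            ("amputee", "cortical_thickness"): 15.0,
        }
    )
    asym_sd: float | dict = field(
        default_factory=lambda: {
            ("control", "myelinated_thickness"): 10.0,
            ("amputee", "myelinated_thickness"): 5.0,
            ("control", "cortical_thickness"): 6.0,
            ("amputee", "cortical_thickness"): 6.0,
        }
    )
    between_subject_sd: float = 0.4
    seed: int = 0

    def _lookup(self, param, group, metric) -> float:
        if isinstance(param, dict):
            if (group, metric) in param:
                return float(param[(group, metric)])
            return float(param[group])
        return float(param)

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        for g in self.groups:
            for m in self.metric_names:
                if self._lookup(self.asym_sd, g, m) < 0:
                    raise ValueError("asym_sd must be non-negative")


def make_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw per-subject left/right ROI means with the requested asymmetry.

    Each subject's percent asymmetry is drawn from N(asym_mean, asym_sd)
    truncated to [0, 180); the subject's hemispheric mean is drawn around the
    group's mid value.  The returned table recomputes ``asym_percent`` from
    the generated left/right values, so the recovered group mean/SD converge
    to the request as n grows.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows = []
    for group in spec.groups:
        for i in range(spec.n_per_group):
            sid = f"{group}_{i + 1:03d}"
            for metric in spec.metric_names:
                m_l = spec._lookup(spec.mean_left, group, metric)
                m_r = spec._lookup(spec.mean_right, group, metric)
                a_mu = spec._lookup(spec.asym_mean, group, metric)
                a_sd = spec._lookup(spec.asym_sd, group, metric)
                mid = (m_l + m_r) / 2 + rng.normal(0.0, spec.between_subject_sd)
                mid = max(mid, 0.5)
                a = float(np.clip(rng.normal(a_mu, a_sd), 0.0, 180.0))
                direction = np.sign(m_l - m_r)
                if direction == 0:
                    direction = rng.choice([-1.0, 1.0])
                left = mid * (1 + direction * a / 200)
                right = mid * (1 - direction * a / 200)
                rows.append(
                    {
                        "subject_id": sid,
                        "group": group,
                        "metric": metric,
                        "left": left,
                        "right": right,
                        "asym_percent": bilateral_asymmetry(left, right),
                    }
                )
    return pd.DataFrame(rows)
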