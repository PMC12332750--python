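"""Synthetic cohorts and gray-matter-volume image stacks with planted effects.

Emulates the data shape of a multi-site anxious-depression morphometry
study: three groups (anxious depression AD, non-anxious depression NAD,
healthy controls HC) with Hamilton depression (HAMD-17) and anxiety
(HAMA-14) scores consistent with the diagnostic rule, and per-subject 3D
GMV images on a small MNI-like grid.  Effects (group mean shifts,
covariate slopes, group-dependent seed coupling, a linear GMV-anxiety
signal) are planted with known ground truth so downstream inference can
be validated by recovery.

Group labels follow the clinical convention: an MDD patient with
HAMD-17 >= 17 and HAMA-14 >= 14 is anxious-depressed (AD); with
HAMD-17 >= 17 but HAMA-14 < 14, non-anxious (NAD).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

HAMD17_MAX = 52
HAMA14_MAX = 56
HAMD_CUTOFF = 17
HAMA_CUTOFF = 14

__all__ = [
    "CohortSpec",
    "ImageSpec",
    "PlantedEffect",
    "classify_primary",
    "classify_external",
    "generate_cohort",
    "generate_images",
    "smooth_within_mask",
    "realized_noise_sd",
    "default_image_spec",
    "ellipsoid_mask",
    "box_roi",
]


@dataclass
class CohortSpec:
    """Per-group demographic and clinical score distributions.

    Score and demographic parameters are (mean, SD) pairs per group; scores
    are drawn as truncated normals rounded to integers and rejection-sampled
    against the group's diagnostic constraint.
    """

    n_per_group: int = 89
    group_names: tuple[str, ...] = ("AD", "NAD", "HC")
    # defaults mirror the primary-cohort summary statistics of a
    # three-group anxious-depression VBM study
    age_params: dict = field(
        default_factory=lambda: {
            "AD": (39.93, 14.76),
            "NAD": (29.93, 10.66),
            "HC": (31.44, 11.34),
        }
    )
    edu_params: dict = field(
        default_factory=lambda: {
            "AD": (11.25, 3.55),
            "NAD": (11.75, 3.26),
            "HC": (13.80, 3.51),
        }
    )
    sex_probs: dict = field(
        default_factory=lambda: {"AD": 28 / 89, "NAD": 40 / 89, "HC": 40 / 89}
    )
    n_sites: int = 4
    hamd_params: dict = field(
        default_factory=lambda: {"AD": (22.08, 3.39), "NAD": (21.45, 4.19), "HC": (2.0, 1.5)}
    )
    hama_params: dict = field(
        default_factory=lambda: {"AD": (25.36, 6.79), "NAD": (9.74, 3.18), "HC": (2.0, 1.5)}
    )
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        for params in (self.age_params, self.edu_params, self.hamd_params, self.hama_params):
            for g in self.group_names:
                if params[g][1] <= 0:
                    raise ValueError("all SDs must be > 0")
        for g in self.group_names:
            if not 0.0 <= self.sex_probs[g] <= 1.0:
                raise ValueError("sex_probs must lie in [0, 1]")


@dataclass
class ImageSpec:
    """Geometry and noise model of the synthetic GMV images."""

    grid_shape: tuple[int, int, int]
    voxel_size_mm: float
    affine: np.ndarray
    smoothing_fwhm_mm: float
    noise_sd: float
    baseline_template: np.ndarray
    mask: np.ndarray

    def validate(self) -> None:
        if any(d < 4 for d in self.grid_shape):
            raise ValueError("all grid dimensions must be >= 4")
        if self.smoothing_fwhm_mm < 0:
            raise ValueError("smoothing FWHM must be >= 0")
        if not self.mask.any():
            raise ValueError("mask is empty")
        if self.baseline_template.shape != self.grid_shape or self.mask.shape != self.grid_shape:
            raise ValueError("template/mask shape must match grid")


@dataclass
class PlantedEffect:
    """A ground-truth effect added to the generated images.

    kind:
      ``group_mean_shift``  add `magnitude` inside `roi_mask` for `target_group`
      ``covariate_slope``   add `magnitude` * z-scored covariate inside `roi_mask`
      ``seed_coupling``     one latent N(0,1) factor per subject drives
                            `roi_mask` (the seed, amplitude `magnitude`) and,
                            scaled by `per_group_slope[group] * magnitude`,
                            the `coupling_partner_roi`; the across-subject
                            regression slope of partner GMV on seed GMV is
                            then the per-group slope
      ``hama_signal``       add `magnitude` * z-scored HAMA-14 inside `roi_mask`
    """

    roi_mask: np.ndarray
    kind: str
    magnitude: float = 0.0
    target_group: str = "all"
    covariate: str = "age"
    coupling_partner_roi: np.ndarray | None = None
    per_group_slope: dict | None = None

    def validate(self, mask: np.ndarray) -> None:
        if self.kind not in {"group_mean_shift", "covariate_slope", "seed_coupling", "hama_signal"}:
            raise ValueError(f"unknown effect kind {self.kind!r}")
        if np.any(self.roi_mask & ~mask):
            raise ValueError("effect ROI extends outside the brain mask")
        if not np.isfinite(self.magnitude):
            raise ValueError("magnitude must be finite")
        if self.kind == "seed_coupling":
            if self.coupling_partner_roi is None or self.per_group_slope is None:
                raise ValueError("seed_coupling needs coupling_partner_roi and per_group_slope")
            if np.any(self.coupling_partner_roi & ~mask):
                raise ValueError("partner ROI extends outside the brain mask")


def classify_primary(hamd17: int, hama14: int) -> str:
    """Primary-cohort diagnostic rule on the two Hamilton scales.

    AD requires HAMD-17 >= 17 and HAMA-14 >= 14; NAD requires HAMD-17 >= 17
    with HAMA-14 < 14; anything below the depression cutoff is unclassified.
    """
    if hamd17 < 0 or hama14 < 0:
        raise ValueError("scale scores must be nonnegative")
    if hamd17 >= HAMD_CUTOFF:
        return "AD" if hama14 >= HAMA_CUTOFF else "NAD"
    return "unclassified"


def classify_external(hama14: int) -> str:
    """External-cohort rule (no HAMD available): AD iff HAMA-14 >= 14."""
    if hama14 < 0:
        raise ValueError("scale scores must be nonnegative")
    return "AD" if hama14 >= HAMA_CUTOFF else "NAD"


def _truncnorm_int(rng, mean, sd, lo, hi, constraint, max_tries=10000):
    """Rounded truncated-normal integer draw rejection-sampled on `constraint`."""
    for _ in range(max_tries):
        v = int(round(rng.normal(mean, sd)))
        v = min(max(v, lo), hi)
        if constraint(v):
            return v
    raise RuntimeError(
        "rejection sampling failed; score parameters are incompatible with the "
        "group's diagnostic constraint"
    )


def _score_constraints(group: str):
    if group == "AD":
        return (lambda v: v >= HAMD_CUTOFF), (lambda v: v >= HAMA_CUTOFF)
    if group == "NAD":
        return (lambda v: v >= HAMD_CUTOFF), (lambda v: v < HAMA_CUTOFF)
    # controls: below both patient cutoffs
    return (lambda v: v < HAMD_CUTOFF), (lambda v: v < HAMA_CUTOFF)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a cohort table with rule-consistent group labels.

    Returns a DataFrame with columns
    ``id, group, age, sex, education, site, hamd17, hama14``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    rows = []
    for group in spec.group_names:
        hamd_c, hama_c = _score_constraints(group)
        for i in range(spec.n_per_group):
            age = float(np.clip(rng.normal(*spec.age_params[group]), 15.0, 90.0))
            edu = float(np.clip(rng.normal(*spec.edu_params[group]), 0.0, 25.0))
            sex = "M" if rng.random() < spec.sex_probs[group] else "F"
            site = f"site{rng.integers(spec.n_sites)}"
            hamd = _truncnorm_int(rng, *spec.hamd_params[group], 0, HAMD17_MAX, hamd_c)
            hama = _truncnorm_int(rng, *spec.hama_params[group], 0, HAMA14_MAX, hama_c)
            rows.append(
                dict(
                    id=f"{group}{i:03d}",
                    group=group,
                    age=round(age, 1),
                    sex=sex,
                    education=round(edu, 1),
                    site=site,
                    hamd17=hamd,
                    hama14=hama,
                )
            )
    return pd.DataFrame(rows)


def smooth_within_mask(
    fields: np.ndarray, fwhm_mm: float, voxel_size_mm: float, mask: np.ndarray
) -> np.ndarray:
    """Gaussian-smooth 3D field(s) inside a mask, mass-preserving boundary rule.

    Each voxel's value is redistributed with Gaussian weights renormalised
    over the in-mask voxels it can reach, so the sum (hence the mean) of the
    field over the mask is preserved exactly.  Accepts a single volume or a
    stack with the volume axes last three.
    """
    if fwhm_mm == 0.0:
        return np.where(mask, fields, 0.0)
    sigma = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size_mm
    m = mask.astype(float)
    reach = gaussian_filter(m, sigma)  # total in-mask weight reachable from each source

    def _one(vol):
        src = np.where(mask, vol / np.maximum(reach, 1e-12), 0.0)
        return np.where(mask, gaussian_filter(src, sigma), 0.0)

    if fields.ndim == 3:
        return _one(fields)
    out = np.empty_like(fields, dtype=float)
    for idx in np.ndindex(fields.shape[:-3]):
        out[idx] = _one(fields[idx])
    return out


def generate_images(
    cohort: pd.DataFrame,
    ispec: ImageSpec,
    effects: list[PlantedEffect],
    rng_seed: int = 0,
    site_offset_sd: float = 0.0,
) -> np.ndarray:
    """Generate the per-subject GMV stack (n_subjects x grid).

    Each image is ``baseline + planted effects + smoothed noise``, clipped
    at zero.  When ``site_offset_sd > 0``, small additive global GMV offsets
    (one per site label) emulate scanner/site differences, giving covariate
    adjustment something real to remove.  With no effects, no noise and no
    site offsets each image equals the baseline template exactly.
    """
    ispec.validate()
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    for eff in effects:
        eff.validate(ispec.mask)
    rng = np.random.default_rng(rng_seed)
    n = len(cohort)
    stack = np.broadcast_to(ispec.baseline_template, (n,) + ispec.grid_shape).copy()

    groups = cohort["group"].to_numpy()
    for eff in effects:
        roi = eff.roi_mask
        if eff.kind == "group_mean_shift":
            sel = np.ones(n, bool) if eff.target_group == "all" else groups == eff.target_group
            stack[sel] += eff.magnitude * roi
        elif eff.kind == "covariate_slope":
            cov = cohort[eff.covariate].to_numpy(float)
            z = (cov - cov.mean()) / cov.std()
            stack += eff.magnitude * z[:, None, None, None] * roi
        elif eff.kind == "hama_signal":
            hama = cohort["hama14"].to_numpy(float)
            z = (hama - hama.mean()) / hama.std()
            sel = np.ones(n, bool) if eff.target_group == "all" else groups == eff.target_group
            stack[sel] += eff.magnitude * z[sel, None, None, None] * roi
        elif eff.kind == "seed_coupling":
            latent = rng.standard_normal(n)
            stack += eff.magnitude * latent[:, None, None, None] * roi
            slope = np.array([eff.per_group_slope.get(g, 0.0) for g in groups])
            stack += (
                eff.magnitude
                * (slope * latent)[:, None, None, None]
                * eff.coupling_partner_roi
            )

    if site_offset_sd > 0:
        # per-site additive global offsets, fixed across subjects of a site
        sites = sorted(cohort["site"].unique())
        offsets = {s: rng.normal(0.0, site_offset_sd) for s in sites}
        site_off = np.array([offsets[s] for s in cohort["site"]])
        stack += site_off[:, None, None, None] * ispec.mask

    if ispec.noise_sd > 0:
        noise = rng.normal(0.0, ispec.noise_sd, size=(n,) + ispec.grid_shape)
        stack += smooth_within_mask(
            noise, ispec.smoothing_fwhm_mm, ispec.voxel_size_mm, ispec.mask
        )
    stack = np.clip(stack, 0.0, None)
    return np.where(ispec.mask, stack, 0.0)


def realized_noise_sd(ispec: ImageSpec, rng_seed: int = 0, n: int = 20) -> float:
    """Empirical in-mask voxel SD of the smoothed noise field.

    Smoothing shrinks the white-noise SD by the kernel norm, so effect sizes
    relative to the observed voxel noise are computed against this value.
    """
    rng = np.random.default_rng(rng_seed)
    noise = rng.normal(0.0, ispec.noise_sd, size=(n,) + ispec.grid_shape)
    sm = smooth_within_mask(noise, ispec.smoothing_fwhm_mm, ispec.voxel_size_mm, ispec.mask)
    return float(sm[:, ispec.mask].std())


def ellipsoid_mask(grid_shape: tuple[int, int, int], scale: float = 0.9) -> np.ndarray:
    """Ellipsoidal brain-like mask inscribed in the grid."""
    idx = np.indices(grid_shape).astype(float)
    c = [(d - 1) / 2.0 for d in grid_shape]
    r = [scale * d / 2.0 for d in grid_shape]
    d2 = sum(((idx[i] - c[i]) / r[i]) ** 2 for i in range(3))
    return d2 <= 1.0


def box_roi(grid_shape, corner, size) -> np.ndarray:
    """Rectangular ROI mask: convenience for planting effects."""
    roi = np.zeros(grid_shape, dtype=bool)
    sl = tuple(slice(c, c + s) for c, s in zip(corner, size))
    roi[sl] = True
    return roi


def default_image_spec(
    grid_shape=(20, 24, 20),
    voxel_size_mm=6.0,
    smoothing_fwhm_mm=8.0,
    noise_sd=0.05,
    baseline_level=0.5,
) -> ImageSpec:
    """Desk-scale image geometry: ~5-6k in-mask voxels on an MNI-like grid.

    The affine is RAS+ with the grid centred on the origin, mimicking MNI
    millimetre space at the chosen voxel size.
    """
    mask = ellipsoid_mask(grid_shape)
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    affine[:3, 3] = -(np.array(grid_shape) - 1) / 2.0 * voxel_size_mm
    baseline = np.where(mask, baseline_level, 0.0)
    return ImageSpec(
        grid_shape=tuple(grid_shape),
        voxel_size_mm=float(voxel_size_mm),
        affine=affine,
        smoothing_fwhm_mm=float(smoothing_fwhm_mm),
        noise_sd=float(noise_sd),
        baseline_template=baseline,
        mask=mask,
    )
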