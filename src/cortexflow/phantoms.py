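"""Synthetic phantoms with analytically known ground truth.

Three generators feed the downstream pipeline stages:

* a folded-cortex label volume whose pial surface is the parametric
  radial perturbation r(theta, phi) = R + a sin(k theta) sin(2k phi),
  with closed-form (quadrature) surface area and volume;
* a pulsatile phase-contrast velocity series with parabolic (Poiseuille)
  vessel profiles and closed-form time-averaged flow;
* a two-group cohort table in which gyrification index and grey-matter
  volume depend linearly on cerebral oxygen delivery plus Gaussian noise.

All generators are deterministic given their spec (and seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .volumes import LabelVolume, RegionScheme

__all__ = [
    "FoldedBrainSpec",
    "FlowPhantomSpec",
    "CohortSpec",
    "EnvelopeValidityError",
    "make_folded_brain",
    "folded_brain_scheme",
    "analytic_phantom_areas",
    "analytic_phantom_volume",
    "make_phase_contrast_phantom",
    "make_cohort",
]

# label layout of the folded-brain phantom: one cGM and one WM label per
# azimuthal "lobe" sector
_LOBES = ("frontal", "parietal", "temporal", "occipital")
_CGM_LABELS = {1: "frontal", 2: "parietal", 3: "temporal", 4: "occipital"}
_WM_LABELS = {11: "frontal", 12: "parietal", 13: "temporal", 14: "occipital"}


class EnvelopeValidityError(ValueError):
    """Fold wavelength too large for the morphological hull to match the
    analytic envelope sphere."""


@dataclass(frozen=True)
class FoldedBrainSpec:
    """Parameters of the folded-cortex phantom.

    The pial surface is r(theta, phi) = R + a sin(k theta) sin(2k phi) in
    spherical coordinates about the grid centre; cortical grey matter is the
    ribbon of the stated thickness under it and white matter fills the
    interior.  Defaults describe a neonatal-brain-scale solid (R = 45 mm
    gives ~382 ml, close to a term newborn's whole-brain volume) at the
    study resolution of 0.8 mm, with folds coarse enough (wavelength
    ~26 mm) to pass unharmed through the pipeline's median/Laplacian
    cleaning; the matching hull closing radius is then 12 voxels (pass
    ``closing_radius_mm=12 * voxel_size_mm`` to the area oracle and
    ``n_dilations=12, n_erosions=11`` to the GI pipeline).
    """

    base_radius_mm: float = 45.0
    fold_amplitude_mm: float = 4.5
    fold_frequency: int = 6
    cortical_thickness_mm: float = 3.0
    voxel_size_mm: float = 0.8
    grid_shape: tuple[int, int, int] = (144, 144, 144)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_radius_mm <= 0:
            raise ValueError("base_radius_mm must be positive")
        if self.fold_amplitude_mm < 0:
            raise ValueError("fold_amplitude_mm must be non-negative")
        if not (self.fold_amplitude_mm < self.base_radius_mm / 2):
            raise ValueError(
                "fold_amplitude_mm must be < base_radius_mm / 2 "
                f"({self.fold_amplitude_mm} vs {self.base_radius_mm / 2})"
            )
        if self.fold_frequency < 1:
            raise ValueError("fold_frequency must be a positive integer")
        if self.cortical_thickness_mm <= 0:
            raise ValueError("cortical_thickness_mm must be positive")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        required = self.required_grid_shape()
        if any(g < r for g, r in zip(self.grid_shape, required)):
            raise ValueError(
                "grid too small to contain the phantom plus a 4-voxel margin: "
                f"need at least {required}, got {tuple(self.grid_shape)}"
            )

    def required_grid_shape(self) -> tuple[int, int, int]:
        """Smallest grid holding the sphere R + a plus a 4-voxel margin."""
        r_max = self.base_radius_mm + self.fold_amplitude_mm
        n = int(np.ceil(2 * r_max / self.voxel_size_mm)) + 8
        return (n, n, n)


def _pial_radius(spec: FoldedBrainSpec, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    k = spec.fold_frequency
    return spec.base_radius_mm + spec.fold_amplitude_mm * np.sin(k * theta) * np.sin(
        2 * k * phi
    )


def folded_brain_scheme() -> RegionScheme:
    """Region scheme matching the labels emitted by :func:`make_folded_brain`."""
    mapping = {0: ("background", "none")}
    for lab, lobe in _CGM_LABELS.items():
        mapping[lab] = ("cGM", lobe)
    for lab, lobe in _WM_LABELS.items():
        mapping[lab] = ("WM", lobe)
    return RegionScheme(mapping)


def make_folded_brain(spec: FoldedBrainSpec) -> LabelVolume:
    """Voxelise the folded-cortex phantom into an integer label volume.

    Labels 1-4 are cortical grey matter, 11-14 white matter, partitioned
    into four azimuthal lobe sectors; 0 is background.  A voxel belongs to
    the solid when its centre lies inside the pial surface.
    """
    nx, ny, nz = spec.grid_shape
    h = spec.voxel_size_mm
    centre = (np.array(spec.grid_shape) - 1) / 2.0
    xs = (np.arange(nx) - centre[0]) * h
    ys = (np.arange(ny) - centre[1]) * h
    zs = (np.arange(nz) - centre[2]) * h
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    r = np.sqrt(X * X + Y * Y + Z * Z)
    ratio = np.divide(Z, r, out=np.zeros_like(Z), where=r > 0)
    theta = np.arccos(np.clip(ratio, -1.0, 1.0))
    theta[r == 0] = 0.0
    phi = np.mod(np.arctan2(Y, X), 2 * np.pi)

    pial = _pial_radius(spec, theta, phi)
    inside = r <= pial
    cgm = inside & (r > pial - spec.cortical_thickness_mm)
    wm = inside & ~cgm

    # four azimuthal sectors -> frontal, parietal, temporal, occipital
    sector = np.minimum((phi / (np.pi / 2)).astype(np.int64), 3)
    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    labels[cgm] = (sector[cgm] + 1).astype(np.int16)
    labels[wm] = (sector[wm] + 11).astype(np.int16)

    affine = np.diag([h, h, h, 1.0])
    return LabelVolume(voxels=labels, spacing_mm=(h, h, h), affine=affine)


def _quadrature_grid(n: int) -> tuple[np.ndarray, np.ndarray, float]:
    """Midpoint-rule grid over (theta, phi) in [0, pi] x [0, 2 pi]."""
    dt = np.pi / n
    dp = 2 * np.pi / n
    theta = (np.arange(n) + 0.5) * dt
    phi = (np.arange(n) + 0.5) * dp
    T, P = np.meshgrid(theta, phi, indexing="ij")
    return T, P, dt * dp


def analytic_phantom_volume(spec: FoldedBrainSpec, n: int = 2000) -> float:
    """Volume (mm^3) of the parametric solid by midpoint quadrature of
    r(theta, phi)^3 / 3 over the sphere."""
    T, P, w = _quadrature_grid(n)
    f = _pial_radius(spec, T, P)
    return float(np.sum(f**3 / 3.0 * np.sin(T)) * w)


def analytic_phantom_areas(
    spec: FoldedBrainSpec,
    n: int = 2000,
    closing_radius_mm: float | None = None,
) -> tuple[float, float]:
    """Ground-truth (pial_area_mm2, hull_area_mm2) for the folded phantom.

    The pial area is the dense midpoint quadrature of the first fundamental
    form of r(theta, phi); the hull area is the envelope sphere of radius
    R + a.  The envelope is only the correct hull when the fold wavelength
    is small relative to the morphological closing radius, so specs with
    pi (R + a) / k exceeding 3x the closing radius are rejected rather than
    silently returning an invalid oracle.

    Parameters
    ----------
    closing_radius_mm:
        Radius of the morphological closing the pipeline will apply;
        defaults to 3 dilation steps of one voxel.
    """
    R, a, k = spec.base_radius_mm, spec.fold_amplitude_mm, spec.fold_frequency
    if closing_radius_mm is None:
        closing_radius_mm = 3.0 * spec.voxel_size_mm
    if a > 0:
        wavelength = np.pi * (R + a) / k
        if wavelength > 3.0 * closing_radius_mm:
            raise EnvelopeValidityError(
                f"fold wavelength pi(R+a)/k = {wavelength:.2f} mm exceeds 3x the "
                f"closing radius ({3 * closing_radius_mm:.2f} mm); the sphere of "
                "radius R+a is not a valid hull for this spec"
            )
    pial = _parametric_area(spec, n)
    hull = 4 * np.pi * (R + a) ** 2
    return float(pial), float(hull)


def _parametric_area(spec: FoldedBrainSpec, n: int = 2000) -> float:
    """Area of r = f(theta, phi): dA = f sqrt(f^2 sin^2 t + f_t^2 sin^2 t + f_p^2)."""
    R, a, k = spec.base_radius_mm, spec.fold_amplitude_mm, spec.fold_frequency
    T, P, w = _quadrature_grid(n)
    st = np.sin(T)
    f = R + a * np.sin(k * T) * np.sin(2 * k * P)
    ft = a * k * np.cos(k * T) * np.sin(2 * k * P)
    fp = 2 * a * k * np.sin(k * T) * np.cos(2 * k * P)
    integrand = f * np.sqrt(f * f * st * st + ft * ft * st * st + fp * fp)
    return float(np.sum(integrand) * w)


# ---------------------------------------------------------------------------
# phase-contrast flow phantom
# ---------------------------------------------------------------------------

_VESSELS = ("left_ica", "right_ica", "basilar")
VENC_CM_S = 140.0  # encoding ceiling of the emulated acquisition


def _default_waveform(n: int = 20) -> tuple[float, ...]:
    """Pulsatile modulation with mean exactly 1 over the cardiac cycle."""
    p = np.arange(n)
    return tuple(1.0 + 0.6 * np.cos(2 * np.pi * p / n))


@dataclass(frozen=True)
class FlowPhantomSpec:
    """Three-vessel pulsatile Poiseuille phantom (left/right internal
    carotid and basilar arteries).

    Velocities are in cm/s (through-plane, signed), radii and pixels in mm.
    Peak velocities must stay below the 140 cm/s encoding ceiling.
    """

    vessel_radii_mm: tuple[float, float, float] = (1.5, 1.5, 1.2)
    peak_velocities_cm_s: tuple[float, float, float] = (60.0, 60.0, 50.0)
    n_phases: int = 20
    waveform_modulation: tuple[float, ...] = field(default_factory=_default_waveform)
    pixel_size_mm: float = 0.3
    grid_shape: tuple[int, int] = (96, 96)
    centres_mm: tuple[tuple[float, float], ...] = ((-6.0, -4.0), (6.0, -4.0), (0.0, 6.0))

    def __post_init__(self) -> None:
        if len(self.vessel_radii_mm) != 3 or any(r <= 0 for r in self.vessel_radii_mm):
            raise ValueError("vessel_radii_mm must be 3 positive reals")
        if len(self.peak_velocities_cm_s) != 3:
            raise ValueError("peak_velocities_cm_s must have 3 entries")
        if any(v < 0 for v in self.peak_velocities_cm_s):
            raise ValueError("peak velocities must be non-negative")
        if max(self.peak_velocities_cm_s) * max(self.waveform_modulation, default=1.0) > VENC_CM_S:
            raise ValueError(
                f"peak modulated velocity exceeds the encoding ceiling (vENC {VENC_CM_S} cm/s)"
            )
        if self.n_phases < 1:
            raise ValueError("n_phases must be positive")
        if len(self.waveform_modulation) != self.n_phases:
            raise ValueError("waveform_modulation must have n_phases entries")
        if any(m < 0 for m in self.waveform_modulation):
            raise ValueError("waveform_modulation must be non-negative")
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel_size_mm must be positive")
        # pairwise non-overlap of vessel disks
        for i in range(3):
            for j in range(i + 1, 3):
                ci, cj = np.array(self.centres_mm[i]), np.array(self.centres_mm[j])
                if np.linalg.norm(ci - cj) <= self.vessel_radii_mm[i] + self.vessel_radii_mm[j]:
                    raise ValueError(
                        f"vessels {_VESSELS[i]} and {_VESSELS[j]} overlap on the grid"
                    )


def make_phase_contrast_phantom(
    spec: FlowPhantomSpec,
) -> tuple["PhaseContrastSeries", dict[str, np.ndarray], dict[str, float]]:
    """Build the velocity series, exact vessel ROI masks and analytic flows.

    Each vessel carries the parabolic profile
    v(r, p) = v_peak * m_p * (1 - (r / R_v)^2); its analytic time-averaged
    flow is (v_peak / 2) * pi R_v^2 * mean(m) * 60, reported in ml/min.
    """
    from .flow import PhaseContrastSeries  # local import to avoid a cycle

    ny, nx = spec.grid_shape
    h = spec.pixel_size_mm
    cy = (np.arange(ny) - (ny - 1) / 2.0) * h
    cx = (np.arange(nx) - (nx - 1) / 2.0) * h
    Y, X = np.meshgrid(cy, cx, indexing="ij")

    m = np.asarray(spec.waveform_modulation, dtype=float)
    maps = np.zeros((spec.n_phases, ny, nx), dtype=float)
    rois: dict[str, np.ndarray] = {}
    analytic: dict[str, float] = {}
    for name, radius, v_peak, (x0, y0) in zip(
        _VESSELS, spec.vessel_radii_mm, spec.peak_velocities_cm_s, spec.centres_mm
    ):
        rr2 = (X - x0) ** 2 + (Y - y0) ** 2
        mask = rr2 <= radius**2
        profile = v_peak * (1.0 - rr2 / radius**2)
        profile[~mask] = 0.0
        maps += m[:, None, None] * profile[None, :, :]
        rois[name] = mask
        # (v_peak/2) * pi R^2 [cm^2] * mean(m) * 60 -> ml/min
        area_cm2 = np.pi * (radius / 10.0) ** 2
        analytic[name] = 0.5 * v_peak * area_cm2 * float(m.mean()) * 60.0
    analytic["total_cbf"] = sum(analytic[v] for v in _VESSELS)

    series = PhaseContrastSeries(velocity_maps=maps, pixel_spacing_mm=(h, h))
    return series, rois, analytic


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """Two-group cohort with a linear CDO2 -> (GI, grey-matter volume) effect.

    Defaults emulate a term-born surgical CHD cohort against healthy
    controls: matched gestational/postmenstrual ages, CDO2 centred near
    1700 ml O2/min, GI near 2.4 and grey-matter-scale volumes, with slopes
    and noise set so the population R^2 of GI on CDO2 is ~0.28 and of
    volume on CDO2 is ~0.48.  The group offsets depress GI and volume in
    the CHD group.  CDO2 is reported only for CHD subjects (as acquired in
    the emulated study) but acts as a latent driver in both groups.
    """

    n_per_group: int = 30
    ga_mean_wk: float = 38.7
    ga_sd_wk: float = 0.8
    pma_mean_wk: float = 39.2
    pma_sd_wk: float = 0.7
    cdo2_mean: float = 1700.0
    cdo2_sd: float = 450.0
    gi_intercept: float = 2.033
    gi_slope_per_cdo2: float = 2.0e-4
    gi_noise_sd: float = 0.145
    gmv_intercept_ml: float = 88.0
    gmv_slope_per_cdo2: float = 0.02
    gmv_noise_sd_ml: float = 9.4
    group_gi_offset: float = -0.091
    group_gmv_offset_ml: float = -27.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ga_sd_wk", "pma_sd_wk", "cdo2_sd", "gi_noise_sd", "gmv_noise_sd_ml"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.n_per_group < 3:
            raise ValueError("n_per_group must be >= 3")


def make_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw the synthetic cohort table.

    Columns: subject_id, group, ga_wk, pma_wk, cdo2, gi, gmv_ml.  The CDO2
    column is NaN for controls (unmeasured), though the latent value still
    drives their outcomes; group offsets apply to the CHD group only.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_per_group
    rows = []
    for group, offset_gi, offset_gmv in (
        ("control", 0.0, 0.0),
        ("CHD", spec.group_gi_offset, spec.group_gmv_offset_ml),
    ):
        ga = rng.normal(spec.ga_mean_wk, spec.ga_sd_wk, n)
        pma = rng.normal(spec.pma_mean_wk, spec.pma_sd_wk, n)
        cdo2 = rng.normal(spec.cdo2_mean, spec.cdo2_sd, n)
        gi = (
            spec.gi_intercept
            + spec.gi_slope_per_cdo2 * cdo2
            + offset_gi
            + rng.normal(0.0, spec.gi_noise_sd, n)
        )
        gmv = (
            spec.gmv_intercept_ml
            + spec.gmv_slope_per_cdo2 * cdo2
            + offset_gmv
            + rng.normal(0.0, spec.gmv_noise_sd_ml, n)
        )
        for i in range(n):
            rows.append(
                {
                    "subject_id": f"{group}-{i + 1:03d}",
                    "group": group,
                    "ga_wk": ga[i],
                    "pma_wk": pma[i],
                    "cdo2": cdo2[i] if group == "CHD" else np.nan,
                    "gi": gi[i],
                    "gmv_ml": gmv[i],
                }
            )
    return pd.DataFrame(rows)


def cohort_spec_with(base: CohortSpec | None = None, **overrides) -> CohortSpec:
    """Convenience: a CohortSpec derived from ``base`` with fields replaced."""
    return dataclasses.replace(base or CohortSpec(), **overrides)
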