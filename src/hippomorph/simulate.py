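"""Synthetic two-group cohorts of hippocampus-like contour stacks.

Real hippocampal tracings are not redistributable, so the pipeline is
exercised on simulated cohorts with *known* ground truth: tube-like shapes
built around a gently curved medial arc (a "banana" roughly 40 mm long),
with an enlarged anterior head, per-subject global scale variation, TIV
correlated with scale cubed, white Gaussian radial noise on every traced
boundary point, and — in patients only — a localized inward deformation
patch whose position is known exactly in grid coordinates.

Coronal slicing is emulated by cutting the tube with planes perpendicular
to the z axis (the arc's curvature is kept mild so every cross-section is a
simple, star-shaped polygon).  Cross-sections are circular by default so
that the analysis grid's arc-length parameterization coincides exactly with
the generative angle parameterization; an elliptical eccentricity option is
available for robustness studies where that correspondence is deliberately
broken.

All randomness derives from a single seed through ``numpy``
``SeedSequence`` spawning: child 0 drives the covariate draws, children
1..n the per-subject surface noise streams, so cohorts are bit-reproducible
and individual subjects can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .contours import Contour, ContourStack, CohortTable
from .errors import ConfigError

__all__ = [
    "ShapeTemplate",
    "DeformationPatch",
    "CohortConfig",
    "GroundTruth",
    "generate_subject_stack",
    "generate_cohort",
    "true_effect_summary",
]


# ---------------------------------------------------------------------------
# template geometry
# ---------------------------------------------------------------------------

@dataclass
class ShapeTemplate:
    """Idealized hippocampus: a curved tube with an anterior head bulge.

    The medial arc runs anterior (t=0) to posterior (t=1) with a mild
    lateral bend; the radius profile ``rho(t, theta)`` combines a body
    radius, a sinusoidal taper towards both ends, and a Gaussian head bulge
    centered at ``head_center``.  Default dimensions give an arc of ~40 mm,
    radii within 2-6 mm, and a volume near 2,600 mm^3 — plausible for an
    adult hippocampus traced on ~40 coronal planes at 1 mm spacing.

    Parameters
    ----------
    n_slices, slice_thickness
        Number of coronal tracing planes and their spacing (mm).
    bend
        Lateral amplitude of the medial arc (mm).
    r_base, taper, head_amp, head_center, head_width
        Radius profile parameters (mm, mm, mm, unitless position, unitless
        width).
    eccentricity
        Relative 2-theta modulation of the radius (0 = circular sections).
    n_boundary
        Traced points per contour.
    """

    n_slices: int = 40
    slice_thickness: float = 1.0
    bend: float = 6.0
    r_base: float = 2.6
    taper: float = 1.2
    head_amp: float = 2.4
    head_center: float = 0.17
    head_width: float = 0.13
    eccentricity: float = 0.0
    n_boundary: int = 120

    def medial_xy(self, t: np.ndarray) -> np.ndarray:
        """In-plane medial arc position at normalized position t."""
        t = np.asarray(t, float)
        x = self.bend * np.sin(np.pi * t)
        y = np.zeros_like(x)
        return np.stack([x, y], axis=-1)

    def rho(self, t: np.ndarray, theta: np.ndarray) -> np.ndarray:
        """Base radial distance (mm) at longitudinal position t, angle theta."""
        t = np.asarray(t, float)
        theta = np.asarray(theta, float)
        radial = (
            self.r_base
            + self.taper * np.sin(np.pi * t)
            + self.head_amp * np.exp(-(((t - self.head_center) / self.head_width) ** 2))
        )
        return radial * (1.0 + self.eccentricity * np.cos(2.0 * theta))

    @property
    def z_positions(self) -> np.ndarray:
        return np.arange(self.n_slices) * self.slice_thickness

    @property
    def t_positions(self) -> np.ndarray:
        return np.arange(self.n_slices) / (self.n_slices - 1)

    def validate(self) -> "ShapeTemplate":
        if self.n_slices < 3:
            raise ConfigError("template.n_slices must be >= 3")
        tt, th = np.meshgrid(np.linspace(0, 1, 201), np.linspace(0, 2 * np.pi, 181))
        r = self.rho(tt, th)
        if r.min() < 1.0:
            raise ConfigError(f"template radius drops below 1 mm (min {r.min():.3f})")
        return self


@dataclass
class DeformationPatch:
    """Localized inward deformation, defined in normalized grid coordinates.

    ``level_range`` is a (lo, hi) fraction of the longitudinal axis,
    ``circ_range`` a (lo, hi) fraction of the circumference (may wrap if
    lo > hi).  Defining the patch in grid coordinates keeps the ground-truth
    mask exactly aligned with the analysis grid.
    """

    level_range: tuple[float, float] = (0.04, 0.30)
    circ_range: tuple[float, float] = (0.15, 0.55)

    def contains(self, t: np.ndarray, frac_theta: np.ndarray) -> np.ndarray:
        t = np.asarray(t, float)
        f = np.mod(np.asarray(frac_theta, float), 1.0)
        lo, hi = self.level_range
        # a full-extent patch (hi = 1) includes the posterior end slice
        in_level = (t >= lo) & ((t < hi) if hi < 1.0 else (t <= 1.0))
        clo, chi = self.circ_range
        if clo <= chi:
            in_circ = (f >= clo) & (f < chi)
        else:
            in_circ = (f >= clo) | (f < chi)
        return in_level & in_circ

    def mask(self, L: int, C: int) -> np.ndarray:
        t = np.arange(L) / (L - 1)
        f = np.arange(C) / C
        return self.contains(t[:, None], f[None, :])


@dataclass
class CohortConfig:
    """Study conditions for one simulated cohort.

    Defaults emulate the target two-group design: ~30 subjects per group,
    patient/control ages of 62.8 +/- 13.0 vs 61.8 +/- 5.9 years, a 15%
    inward deformation confined to an anterior head patch in patients,
    0.3 mm white radial tracing noise, log-normal subject scale (sd 0.05 on
    the log scale) and TIV proportional to scale cubed with 3% relative
    noise around 1.5e6 mm^3.
    """

    n_patients: int = 30
    n_controls: int = 30
    template: ShapeTemplate = field(default_factory=ShapeTemplate)
    patch: DeformationPatch = field(default_factory=DeformationPatch)
    depth: float = 0.15  # fractional radius reduction in patients
    noise_sigma: float = 0.3  # mm, white per boundary point
    noise_smooth: float = 0.0  # optional correlated-noise kernel sd, in points
    scale_sigma: float = 0.05  # sd of log subject scale
    tiv_kappa: float = 1.5e6  # mm^3 at scale 1
    tiv_sigma: float = 0.03  # relative TIV noise
    age_patients: tuple[float, float] = (62.8, 13.0)
    age_controls: tuple[float, float] = (61.8, 5.9)
    alsfrs_r: tuple[float, float] = (37.8, 5.4)  # patient clinical score
    duration_lognorm: tuple[float, float] = (2.73, 0.83)  # months, log-scale mu/sd
    seed: int = 0

    def validate(self) -> "CohortConfig":
        if not (0.0 <= self.depth < 0.5):
            raise ConfigError(
                f"deformation.depth must be in [0, 0.5), got {self.depth}"
            )
        if self.noise_sigma < 0:
            raise ConfigError("noise_sigma must be >= 0")
        if min(self.n_patients, self.n_controls) < 3:
            raise ConfigError("need >= 3 subjects per group")
        for lo, hi in (self.patch.level_range,):
            if not (0.0 <= lo < hi <= 1.0):
                raise ConfigError(f"patch level_range out of bounds: {(lo, hi)}")
        self.template.validate()
        return self


@dataclass
class GroundTruth:
    """Everything the analysis is supposed to recover."""

    patch_mask_fn: Callable[[int, int], np.ndarray]
    depth: float
    noiseless_volumes: pd.Series
    config: CohortConfig

    def patch_mask(self, L: int, C: int) -> np.ndarray:
        return self.patch_mask_fn(L, C)


# ---------------------------------------------------------------------------
# subject- and cohort-level generation
# ---------------------------------------------------------------------------

def _smooth_noise(noise: np.ndarray, kernel_sd: float) -> np.ndarray:
    """Circular Gaussian smoothing of per-point noise along the boundary."""
    from scipy import ndimage

    return ndimage.gaussian_filter1d(noise, kernel_sd, mode="wrap")


def generate_subject_stack(
    template: ShapeTemplate,
    subject_id: str,
    scale: float = 1.0,
    deformation: tuple[DeformationPatch, float] | None = None,
    noise_sigma: float = 0.0,
    noise_smooth: float = 0.0,
    seed: int | np.random.Generator = 0,
    side: str = "left",
) -> ContourStack:
    """Sample one subject's contour stack from the template.

    Every slice is a polygon of ``template.n_boundary`` points at uniform
    angles around the medial arc position, with radius
    ``rho(t, theta) * scale * (1 - depth inside the patch) + N(0, sigma)``.
    ``scale`` acts as a similarity transform (radii, medial arc and slice
    spacing all scale together), so the noiseless volume is exactly
    ``scale**3`` times the template volume.  Radial perturbation of a
    star-shaped section cannot self-intersect, so the output is always a
    valid stack.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if deformation is not None and not (0.0 <= deformation[1] < 0.5):
        raise ConfigError(
            f"deformation.depth must be in [0, 0.5), got {deformation[1]}"
        )
    M = template.n_boundary
    theta = 2.0 * np.pi * np.arange(M) / M
    t_pos = template.t_positions
    centers = template.medial_xy(t_pos) * scale
    r = template.rho(t_pos[:, None], theta[None, :]) * scale  # (K, M)
    if deformation is not None:
        patch, depth = deformation
        inside = patch.contains(t_pos[:, None], theta[None, :] / (2.0 * np.pi))
        r = r * np.where(inside, 1.0 - depth, 1.0)
    if noise_sigma > 0:
        eps = rng.normal(0.0, noise_sigma, r.shape)
        if noise_smooth > 0:
            eps = _smooth_noise(eps, noise_smooth)
        r = r + eps
    if np.any(r <= 0):
        bad = int(np.argwhere(r.min(axis=1) <= 0)[0, 0])
        raise ConfigError(
            f"{subject_id}: non-positive radius on slice {bad} "
            "(deformation.depth or noise too large)"
        )
    unit = np.column_stack([np.cos(theta), np.sin(theta)])
    pts_all = centers[:, None, :] + r[:, :, None] * unit[None, :, :]
    contours = [
        Contour(points=pts_all[k], slice_index=k, z=float(z) * scale)
        for k, z in enumerate(template.z_positions)
    ]
    return ContourStack(subject_id, contours, template.slice_thickness * scale, side)


def _analytic_volume(
    template: ShapeTemplate,
    scale: float,
    deformation: tuple[DeformationPatch, float] | None,
) -> float:
    """Noiseless planimetric volume from the polygonal cross-sections."""
    M = template.n_boundary
    theta = 2.0 * np.pi * np.arange(M) / M
    total = 0.0
    for t in template.t_positions:
        r = template.rho(t, theta) * scale
        if deformation is not None:
            patch, depth = deformation
            inside = patch.contains(np.full(M, t), theta / (2.0 * np.pi))
            r = r * np.where(inside, 1.0 - depth, 1.0)
        # area of the inscribed polygon with vertices at radius r(theta_i)
        r_next = np.roll(r, -1)
        total += 0.5 * np.abs(np.sum(r * r_next * np.sin(2.0 * np.pi / M)))
    return float(total * template.slice_thickness * scale)


def generate_cohort(
    config: CohortConfig,
) -> tuple[dict[str, ContourStack], CohortTable, GroundTruth]:
    """Generate a full two-group cohort: stacks, covariates and ground truth.

    Controls are undeformed; patients carry the configured inward patch.
    Covariates (scale, TIV, age, clinical scores) come from stream 0 of the
    spawned seed sequence, subject ``i``'s surface noise from stream
    ``i + 1``.
    """
    config.validate()
    n = config.n_patients + config.n_controls
    streams = np.random.SeedSequence(config.seed).spawn(n + 1)
    cov_rng = np.random.default_rng(streams[0])

    ids = [f"pat{i:03d}" for i in range(config.n_patients)] + [
        f"con{i:03d}" for i in range(config.n_controls)
    ]
    groups = ["ALS"] * config.n_patients + ["HC"] * config.n_controls
    scales = np.exp(cov_rng.normal(0.0, config.scale_sigma, n))
    tiv = config.tiv_kappa * scales**3 * (1.0 + cov_rng.normal(0.0, config.tiv_sigma, n))
    age = np.concatenate(
        [
            cov_rng.normal(*config.age_patients, config.n_patients),
            cov_rng.normal(*config.age_controls, config.n_controls),
        ]
    )
    alsfrs = np.clip(cov_rng.normal(*config.alsfrs_r, config.n_patients), 0, 48)
    mu, sd = config.duration_lognorm
    duration = cov_rng.lognormal(mu, sd, config.n_patients)

    deformation = (config.patch, config.depth) if config.depth > 0 else None
    stacks: dict[str, ContourStack] = {}
    noiseless = {}
    for i, (sid, grp) in enumerate(zip(ids, groups)):
        deform = deformation if grp == "ALS" else None
        stacks[sid] = generate_subject_stack(
            config.template,
            sid,
            scale=float(scales[i]),
            deformation=deform,
            noise_sigma=config.noise_sigma,
            noise_smooth=config.noise_smooth,
            seed=np.random.default_rng(streams[i + 1]),
        )
        noiseless[sid] = _analytic_volume(config.template, float(scales[i]), deform)

    table = pd.DataFrame(
        {
            "group": groups,
            "age": age,
            "tiv": tiv,
            "alsfrs_r": np.concatenate([alsfrs, np.full(config.n_controls, np.nan)]),
            "duration_months": np.concatenate(
                [duration, np.full(config.n_controls, np.nan)]
            ),
        },
        index=pd.Index(ids, name="id"),
    )
    truth = GroundTruth(
        patch_mask_fn=config.patch.mask,
        depth=config.depth,
        noiseless_volumes=pd.Series(noiseless, name="noiseless_volume"),
        config=config,
    )
    return stacks, CohortTable(table, control_label="HC"), truth


def true_effect_summary(truth: GroundTruth, n_quad: int = 2000) -> dict:
    """Analytic expected patient/control volume ratio for the configured patch.

    Integrates ``rho^2`` (scaled by ``(1 - depth)^2`` inside the patch) over
    a fine (t, theta) quadrature grid; the ratio is scale-free, so it is the
    expected group mean volume ratio at any subject scale distribution.
    """
    cfg = truth.config
    t = np.linspace(0.0, 1.0, n_quad)
    theta = 2.0 * np.pi * (np.arange(n_quad) + 0.5) / n_quad
    tt, th = np.meshgrid(t, theta, indexing="ij")
    rho2 = cfg.template.rho(tt, th) ** 2
    inside = cfg.patch.contains(tt, th / (2.0 * np.pi))
    deformed = rho2 * np.where(inside, (1.0 - truth.depth) ** 2, 1.0)
    ratio = float(deformed.sum() / rho2.sum())
    mask = truth.patch_mask(150, 100)
    return {
        "volume_ratio": ratio,
        "depth": truth.depth,
        "patch_vertices_default_grid": int(mask.sum()),
    }
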