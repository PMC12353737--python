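"""Synthetic segmentation phantoms and cohorts with known ground truth.

The phantom is three concentric spheres: a white-matter core, a
gray-matter shell, and a CSF shell, in air.  Partial volumes across each
boundary follow a logistic profile of the signed distance to the boundary
sphere, so every downstream quantity (junction shell volume, tissue
totals) has a closed form.  ``transition_width_mm`` is the distance over
which the GM<->WM blend moves from 5% to 95% — the physical width of the
gray-white junction that the imaging pipeline is built to measure.

Cohorts add two layers of variation on top of a shared geometry:

* between-subject biology — each subject's junction width in a target
  subregion (one octant of the sphere) is drawn around the population
  mean, and the "plaque" group's mean width is reduced by a fractional
  ``junction_effect``;
* metabolic covariates — drawn from a joint normal built from per-variable
  correlations with age and with the subject's regional junction width, via
  a fixed two-factor assembly (age factor + width factor + independent
  residual).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .junction import SegmentationSet, Volume3D

#: Logistic scale such that the 5%->95% rise spans one transition width:
#: width = 2 * ln(19) * s  =>  s = width / (2 ln 19).
_LOGISTIC_5_95 = 2.0 * np.log(19.0)


class GeometrySpecError(ValueError):
    """Phantom geometry does not fit the grid or is mis-ordered."""


class CovarianceError(ValueError):
    """Requested covariate correlations do not form a valid covariance."""


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, contrast and noise of a single synthetic subject.

    Radii are nested ``wm < gm < csf`` and must fit inside the grid.
    ``mu_*`` are mean T1 signal intensities in arbitrary units with the
    usual T1-weighted ordering CSF < GM < WM; ``noise_sd`` is the SD of
    additive white Gaussian noise on the T1 volume.
    """

    grid_shape: tuple = (64, 64, 64)
    voxel_size_mm: tuple = (1.0, 1.0, 1.0)
    csf_radius_mm: float = 28.0
    gm_radius_mm: float = 24.0
    wm_radius_mm: float = 16.0
    transition_width_mm: float = 2.0
    outer_transition_mm: float = 1.0
    mu_csf: float = 40.0
    mu_gm: float = 100.0
    mu_wm: float = 160.0
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.wm_radius_mm < self.gm_radius_mm < self.csf_radius_mm):
            raise GeometrySpecError("radii must satisfy 0 < wm < gm < csf")
        if self.transition_width_mm <= 0 or self.outer_transition_mm <= 0:
            raise GeometrySpecError("transition widths must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        half_extent = min(
            n * v / 2.0 for n, v in zip(self.grid_shape, self.voxel_size_mm)
        )
        if self.csf_radius_mm + self.outer_transition_mm > half_extent:
            raise GeometrySpecError(
                f"outer radius {self.csf_radius_mm} mm does not fit a grid of "
                f"half-extent {half_extent:.1f} mm"
            )

    @property
    def affine(self) -> np.ndarray:
        """Voxel-to-mm affine placing the mm origin at the grid center."""
        aff = np.diag([*self.voxel_size_mm, 1.0])
        aff[:3, 3] = [
            -(n - 1) * v / 2.0 for n, v in zip(self.grid_shape, self.voxel_size_mm)
        ]
        return aff


def _logistic(x: np.ndarray, width: float) -> np.ndarray:
    """Logistic blend rising 5%->95% over ``width`` around x=0."""
    s = width / _LOGISTIC_5_95
    return 1.0 / (1.0 + np.exp(-x / s))


def _radius_grid(spec: PhantomSpec) -> np.ndarray:
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * v
        for n, v in zip(spec.grid_shape, spec.voxel_size_mm)
    ]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    return np.sqrt(xx**2 + yy**2 + zz**2)


def partial_volumes(
    spec: PhantomSpec, r: np.ndarray | None = None, width_map=None
) -> tuple:
    """Closed-form (gm, wm, csf) partial-volume fields at radius ``r``.

    ``width_map`` optionally overrides the GM<->WM transition width per
    voxel (scalar or array), which is how cohort subjects get their
    individual junction widths.
    """
    if r is None:
        r = _radius_grid(spec)
    width = spec.transition_width_mm if width_map is None else width_map
    s_inner = np.asarray(width, dtype=np.float64) / _LOGISTIC_5_95
    wm = 1.0 / (1.0 + np.exp(np.clip((r - spec.wm_radius_mm) / s_inner, -60, 60)))
    brain = _logistic(spec.gm_radius_mm - r, spec.outer_transition_mm)
    head = _logistic(spec.csf_radius_mm - r, spec.outer_transition_mm)
    brain = np.minimum(brain, head)
    wm = np.minimum(wm, brain)
    gm = brain - wm
    csf = head - brain
    return gm, wm, csf


def make_phantom(spec: PhantomSpec, width_map=None) -> SegmentationSet:
    """Generate one synthetic subject: T1 plus GM/WM/CSF partial volumes.

    The T1 intensity is the partial-volume-weighted mix of the tissue mean
    intensities plus additive Gaussian noise; outside the head it decays
    to zero.  Deterministic given ``spec.seed``.
    """
    gm, wm, csf = partial_volumes(spec, width_map=width_map)
    t1 = spec.mu_gm * gm + spec.mu_wm * wm + spec.mu_csf * csf
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        t1 = t1 + rng.normal(0.0, spec.noise_sd, size=t1.shape)
    aff = spec.affine
    return SegmentationSet(
        t1=Volume3D(t1, aff),
        gm_pv=Volume3D(gm, aff),
        wm_pv=Volume3D(wm, aff),
        csf_pv=Volume3D(csf, aff),
    )


def target_region_mask(spec: PhantomSpec) -> Volume3D:
    """The cohort target subregion: the (+,+,+) octant in mm coordinates."""
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * v
        for n, v in zip(spec.grid_shape, spec.voxel_size_mm)
    ]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    mask = (xx > 0) & (yy > 0) & (zz > 0)
    return Volume3D(mask.astype(np.float64), spec.affine)


def junction_roi_mask(spec: PhantomSpec, band_mm: float = 3.0) -> Volume3D:
    """ROI covering the junction shell inside the target octant.

    The band extends ``band_mm`` on either side of the GM/WM boundary
    sphere, wide enough to capture the blurred junction for any plausible
    subject width.
    """
    r = _radius_grid(spec)
    shell = np.abs(r - spec.wm_radius_mm) <= band_mm
    octant = target_region_mask(spec).values > 0
    return Volume3D((shell & octant).astype(np.float64), spec.affine)


def shell_volume_mm3(spec: PhantomSpec, width_mm, octant_only: bool = True) -> float:
    """Analytic volume of the junction shell of a given width.

    The shell is the region where the GM partial volume lies in
    (0.05, 0.95), i.e. radius within half a transition width of the GM/WM
    boundary sphere; restricted to the target octant when requested.
    """
    lo = spec.wm_radius_mm - width_mm / 2.0
    hi = spec.wm_radius_mm + width_mm / 2.0
    vol = 4.0 / 3.0 * np.pi * (hi**3 - max(lo, 0.0) ** 3)
    return float(vol / 8.0) if octant_only else float(vol)


@dataclass(frozen=True)
class CovariateModel:
    """One metabolic covariate of the synthetic cohort.

    ``r_age`` and ``r_gwjtv`` are the target correlations with age and
    with the subject's regional junction width (hence with regional gwJTV,
    which is monotone in that width).  The two-factor construction needs
    ``r_age**2 + r_gwjtv**2 < 1``.
    """

    name: str
    mean: float
    sd: float
    r_age: float = 0.0
    r_gwjtv: float = 0.0

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError(f"{self.name}: sd must be positive")
        for r in (self.r_age, self.r_gwjtv):
            if not -1 < r < 1:
                raise CovarianceError(f"{self.name}: correlations must lie in (-1, 1)")
        if self.r_age**2 + self.r_gwjtv**2 >= 1:
            raise CovarianceError(
                f"{self.name}: r_age^2 + r_gwjtv^2 >= 1 makes the implied "
                "covariance non-positive-definite"
            )


@dataclass(frozen=True)
class CohortSpec:
    """Study-level design of a synthetic cohort.

    Defaults mirror a two-group carotid-plaque study: 33 subjects without
    and 36 with plaque, ages uniform on 30-70 years.  ``junction_effect``
    is the fractional reduction of the mean junction width in the plaque
    group within the target octant; ``width_between_subject_sd_mm`` is the
    biological between-subject SD of that width, the denominator of any
    group effect size.
    """

    n_no_plaque: int = 33
    n_plaque: int = 36
    junction_effect: float = 0.15
    age_range: tuple = (30.0, 70.0)
    width_between_subject_sd_mm: float = 0.25
    covariate_model: tuple = ()
    seed: int = 0

    def __post_init__(self):
        if self.n_no_plaque < 2 or self.n_plaque < 2:
            raise ValueError("need at least 2 subjects per group")
        if not 0 <= self.junction_effect < 1:
            raise ValueError("junction_effect must lie in [0, 1)")
        if self.width_between_subject_sd_mm < 0:
            raise ValueError("width SD must be non-negative")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be increasing")
        object.__setattr__(
            self,
            "covariate_model",
            tuple(
                c if isinstance(c, CovariateModel) else CovariateModel(*c)
                for c in self.covariate_model
            ),
        )

    @property
    def n_total(self) -> int:
        return self.n_no_plaque + self.n_plaque


def make_cohort_table(cspec: CohortSpec, pspec: PhantomSpec) -> pd.DataFrame:
    """Draw the per-subject table: group, age, covariates, ground truth.

    Ground-truth columns ``gt_width_mm`` (subject's junction width in the
    target octant) and ``gt_region_gwjtv_mm3`` (analytic shell volume at
    that width) let statistical stages be validated without running the
    imaging chain.  Deterministic given ``cspec.seed``.
    """
    rng = np.random.default_rng(cspec.seed)
    n = cspec.n_total
    group = np.array(["no_plaque"] * cspec.n_no_plaque + ["plaque"] * cspec.n_plaque)

    age = rng.uniform(*cspec.age_range, size=n)
    # standardized age factor (uniform has sd = range/sqrt(12))
    age_sd = (cspec.age_range[1] - cspec.age_range[0]) / np.sqrt(12.0)
    z_age = (age - np.mean(cspec.age_range)) / age_sd

    z_width = rng.standard_normal(n)
    base = pspec.transition_width_mm
    mean_width = np.where(
        group == "plaque", base * (1.0 - cspec.junction_effect), base
    )
    width = mean_width + cspec.width_between_subject_sd_mm * z_width
    width = np.clip(width, 0.05 * base, None)

    data = {
        "id": [f"sub-{i:03d}" for i in range(n)],
        "group": group,
        "age": age,
        "gt_width_mm": width,
        "gt_region_gwjtv_mm3": [shell_volume_mm3(pspec, w) for w in width],
    }
    for cov in cspec.covariate_model:
        resid = np.sqrt(1.0 - cov.r_age**2 - cov.r_gwjtv**2)
        z = cov.r_age * z_age + cov.r_gwjtv * z_width + resid * rng.standard_normal(n)
        data[cov.name] = cov.mean + cov.sd * z
    return pd.DataFrame(data)


def make_cohort(
    cspec: CohortSpec, pspec: PhantomSpec, make_volumes: bool = True
) -> tuple:
    """Generate a cohort: per-subject segmentations plus the cohort table.

    Each subject's phantom uses their own junction width inside the target
    octant and the population base width elsewhere, with an independent
    per-subject noise seed derived from ``cspec.seed``.  With
    ``make_volumes=False`` only the table is drawn (same table either
    way), for statistical work that needs no images.
    """
    table = make_cohort_table(cspec, pspec)
    if not make_volumes:
        return [], table
    octant = target_region_mask(pspec).values > 0
    seeds = np.random.SeedSequence(cspec.seed).spawn(len(table))
    subjects = []
    for (_, row), ss in zip(table.iterrows(), seeds):
        width_map = np.where(octant, row["gt_width_mm"], pspec.transition_width_mm)
        sub_seed = int(ss.generate_state(1)[0] % (2**31))
        subjects.append(
            make_phantom(replace(pspec, seed=sub_seed), width_map=width_map)
        )
    return subjects, table
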