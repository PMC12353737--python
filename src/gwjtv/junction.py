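"""Gray-white matter junction tissue volume (gwJTV) mapping.

The junction map is derived from a spatially normalized T1-weighted volume
together with gray-matter (GM), white-matter (WM) and CSF partial-volume
maps.  The processing chain is:

1. intensity thresholds from the >50%-GM and >50%-WM voxel populations,
2. a binary junction map (in-band signal intensity restricted to brain
   tissue),
3. a normalized 5x5x5 box blur of the binary map,
4. conversion to tissue volume (mL) and division by total intracranial
   volume (TIV),
5. Gaussian smoothing at a given FWHM for voxel-based statistics.

GM and WM volume maps receive the same TIV normalization and smoothing so
that all three tissue measures enter group statistics on the same footing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from scipy import ndimage

logger = logging.getLogger("gwjtv")

#: FWHM of a Gaussian equals sigma * 2*sqrt(2*ln 2).
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: Partial-volume fraction a voxel must exceed to count as ">50% tissue".
TISSUE_MAJORITY = 0.5

#: Minimum combined GM+WM partial volume for a voxel to be eligible for the
#: binary junction map (keeps in-band CSF/background voxels out).
BRAIN_MASK_MIN = 0.5

#: Tolerance on the GM+WM+CSF partial-volume closure per voxel.
PV_CLOSURE_TOL = 1e-6


class GeometryError(ValueError):
    """Raised when volumes disagree on grid shape or voxel geometry."""


class DegenerateSegmentationError(ValueError):
    """Raised when a tissue class has fewer than two majority voxels."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Volume3D:
    """A 3D scalar grid with voxel size and a voxel-to-mm affine.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Finite scalar field (intensity, partial volume, or statistic).
    affine : ndarray, shape (4, 4)
        Maps 0-based voxel indices to mm coordinates (NIfTI convention).
    """

    values: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.float64)
        affine = np.asarray(self.affine, dtype=np.float64)
        if values.ndim != 3:
            raise ValueError(f"expected a 3D grid, got shape {values.shape}")
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not np.all(np.isfinite(values)):
            raise ValueError("volume contains non-finite values")
        if np.any(self.voxel_size_from(affine) <= 0):
            raise ValueError("voxel sizes must be positive")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "affine", affine)

    @staticmethod
    def voxel_size_from(affine: np.ndarray) -> np.ndarray:
        return np.sqrt((np.asarray(affine)[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Edge lengths of one voxel in mm, per axis."""
        return self.voxel_size_from(self.affine)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def voxel_to_mm(self, ijk) -> np.ndarray:
        """Map voxel indices (0-based) to mm coordinates via the affine."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=np.float64))
        xyz = ijk @ self.affine[:3, :3].T + self.affine[:3, 3]
        return xyz[0] if xyz.shape[0] == 1 else xyz

    def same_grid(self, other: "Volume3D", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )

    def with_values(self, values: np.ndarray) -> "Volume3D":
        return replace(self, values=np.asarray(values, dtype=np.float64))

    # NIfTI round trip -----------------------------------------------------
    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.values.astype(np.float32), self.affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path) -> "Volume3D":
        img = nib.load(str(path))
        return cls(np.asarray(img.get_fdata(), dtype=np.float64), img.affine)


@dataclass(frozen=True)
class SegmentationSet:
    """Co-registered T1 intensity plus GM/WM/CSF partial-volume maps."""

    t1: Volume3D
    gm_pv: Volume3D
    wm_pv: Volume3D
    csf_pv: Volume3D

    def __post_init__(self):
        vols = (self.t1, self.gm_pv, self.wm_pv, self.csf_pv)
        for v in vols[1:]:
            if not self.t1.same_grid(v):
                raise GeometryError("all volumes must share one grid and affine")
        for name in ("gm_pv", "wm_pv", "csf_pv"):
            pv = getattr(self, name).values
            if pv.min() < -PV_CLOSURE_TOL or pv.max() > 1 + PV_CLOSURE_TOL:
                raise ValueError(f"{name} outside [0, 1]")
        total = self.gm_pv.values + self.wm_pv.values + self.csf_pv.values
        if total.max() > 1 + PV_CLOSURE_TOL:
            raise ValueError("GM+WM+CSF partial volumes exceed 1 somewhere")

    @property
    def shape(self) -> tuple:
        return self.t1.shape


@dataclass(frozen=True)
class JunctionThresholds:
    """Signal-intensity statistics defining the junction band.

    ``bt_lower``/``bt_upper`` are the binary thresholds: the junction band
    is ``[mean_GM + SD_GM, mean_WM - SD_WM]`` since the stored 2SD fields
    enter with a factor of one half.
    """

    si_gm50_mean: float
    si_wm50_mean: float
    si_gm50_2sd: float
    si_wm50_2sd: float
    bt_lower: float
    bt_upper: float
    n_gm50: int
    n_wm50: int

    def __post_init__(self):
        if self.n_gm50 < 2 or self.n_wm50 < 2:
            raise DegenerateSegmentationError(
                "need at least 2 majority voxels per tissue"
            )
        for got, want in (
            (self.bt_lower, self.si_gm50_mean + 0.5 * self.si_gm50_2sd),
            (self.bt_upper, self.si_wm50_mean - 0.5 * self.si_wm50_2sd),
        ):
            if not np.isclose(got, want, rtol=1e-12, atol=1e-12):
                raise ValueError("bt fields inconsistent with mean/2SD fields")


@dataclass(frozen=True)
class SubjectTissueVolumes:
    """Per-subject totals (mL) and the normalized, smoothed maps."""

    gmv_total: float
    wmv_total: float
    csf_total: float
    tiv: float
    gwjtv_total: float
    gmv_map: Volume3D
    wmv_map: Volume3D
    gwjtv_map: Volume3D
    thresholds: JunctionThresholds
    tiv_mode: str = "scaled"

    def __post_init__(self):
        if not np.isclose(self.tiv, self.gmv_total + self.wmv_total + self.csf_total,
                          rtol=1e-9):
            raise ValueError("TIV must equal GMV + WMV + CSF")


# ---------------------------------------------------------------------------
# Operations, in pipeline order
# ---------------------------------------------------------------------------

def compute_thresholds(seg: SegmentationSet) -> JunctionThresholds:
    """Junction-band thresholds from the >50% GM and >50% WM voxel sets.

    The mean and twice the sample standard deviation (n-1 divisor) of the
    T1 signal intensity are taken over voxels whose GM (resp. WM) partial
    volume strictly exceeds 0.5.  The lower threshold is the GM mean plus
    half its 2SD; the upper is the WM mean minus half its 2SD.
    """
    si = seg.t1.values
    gm_sel = seg.gm_pv.values > TISSUE_MAJORITY
    wm_sel = seg.wm_pv.values > TISSUE_MAJORITY
    n_gm, n_wm = int(gm_sel.sum()), int(wm_sel.sum())
    if n_gm < 2 or n_wm < 2:
        raise DegenerateSegmentationError(
            f"majority voxels: GM={n_gm}, WM={n_wm}; need >=2 each"
        )
    gm_si, wm_si = si[gm_sel], si[wm_sel]
    gm_mean, wm_mean = float(gm_si.mean()), float(wm_si.mean())
    gm_2sd = 2.0 * float(gm_si.std(ddof=1))
    wm_2sd = 2.0 * float(wm_si.std(ddof=1))
    return JunctionThresholds(
        si_gm50_mean=gm_mean,
        si_wm50_mean=wm_mean,
        si_gm50_2sd=gm_2sd,
        si_wm50_2sd=wm_2sd,
        bt_lower=gm_mean + 0.5 * gm_2sd,
        bt_upper=wm_mean - 0.5 * wm_2sd,
        n_gm50=n_gm,
        n_wm50=n_wm,
    )


def binarize_junction(
    seg: SegmentationSet,
    thr: JunctionThresholds,
    brain_mask_min: float = BRAIN_MASK_MIN,
) -> Volume3D:
    """Binary junction map: 1 where the T1 intensity lies inside the
    threshold band *and* the voxel is predominantly brain tissue.

    The tissue condition ``gm_pv + wm_pv >= brain_mask_min`` applies the
    location information of the segmented GM and WM maps, so CSF or
    background voxels whose intensity happens to fall in-band stay out of
    the junction.  An inverted band (``bt_lower > bt_upper``) produces an
    all-zero map with a logged warning.
    """
    si = seg.t1.values
    if thr.bt_lower > thr.bt_upper:
        logger.warning(
            "junction band is empty (bt_lower=%.4g > bt_upper=%.4g); "
            "binary map is all-zero", thr.bt_lower, thr.bt_upper,
        )
        return seg.t1.with_values(np.zeros_like(si))
    in_band = (si >= thr.bt_lower) & (si <= thr.bt_upper)
    brain = (seg.gm_pv.values + seg.wm_pv.values) >= brain_mask_min
    return seg.t1.with_values((in_band & brain).astype(np.float64))


def box_blur_125(binary: Volume3D) -> Volume3D:
    """Normalized 5x5x5 box convolution (kernel weight 1/125, zero padding).

    Spreads the one-voxel-thin binary junction line into a local junction
    density in [0, 1]; interior sums are conserved.
    """
    vals = binary.values
    if any(s < 5 for s in vals.shape):
        raise ValueError(f"every axis must span >=5 voxels, got {vals.shape}")
    uniq = np.unique(vals)
    if not np.all(np.isin(uniq, (0.0, 1.0))):
        raise ValueError("box_blur_125 expects a binary {0,1} map")
    out = ndimage.uniform_filter(vals, size=5, mode="constant", cval=0.0)
    return binary.with_values(np.clip(out, 0.0, 1.0))


def tissue_totals(seg: SegmentationSet) -> tuple:
    """Total GMV, WMV, CSF volume and TIV in mL.

    Each total is the sum of the partial-volume map times the voxel volume;
    TIV is their sum (1 mL = 1000 mm^3).
    """
    vv = seg.gm_pv.voxel_volume_mm3 / 1000.0  # mm^3 -> mL
    gmv = float(seg.gm_pv.values.sum()) * vv
    wmv = float(seg.wm_pv.values.sum()) * vv
    csf = float(seg.csf_pv.values.sum()) * vv
    return gmv, wmv, csf, gmv + wmv + csf


def junction_volume(
    blurred: Volume3D,
    tiv: float,
    tiv_mode: str = "scaled",
    tiv_ref: float | None = None,
) -> tuple:
    """Convert the blurred junction map to tissue volume and normalize by TIV.

    Returns ``(gwjtv_total, gwjtv_map)``.  The total is the sum of the
    blurred map times the voxel volume, in mL.  The map is divided by TIV
    to remove head-size differences; with ``tiv_mode="scaled"`` (default)
    it is then multiplied by a reference TIV (the cohort mean; the
    subject's own TIV when none is given) so that map values keep the
    magnitude of the local junction density, while ``tiv_mode="fraction"``
    leaves the raw per-TIV fraction.
    """
    if tiv <= 0:
        raise ValueError("TIV must be positive")
    if tiv_mode not in ("scaled", "fraction"):
        raise ValueError(f"unknown tiv_mode {tiv_mode!r}")
    vv = blurred.voxel_volume_mm3 / 1000.0
    total = float(blurred.values.sum()) * vv
    norm = blurred.values / tiv
    if tiv_mode == "scaled":
        norm = norm * (tiv if tiv_ref is None else tiv_ref)
    return total, blurred.with_values(norm)


def gaussian_smooth_fwhm(vol: Volume3D, fwhm_mm=8.0) -> Volume3D:
    """Separable Gaussian smoothing specified by FWHM in mm.

    sigma = FWHM / (2 sqrt(2 ln 2)) per axis, converted to voxel units via
    the voxel size; the kernel is truncated at 4 sigma with zero padding.
    """
    fwhm = np.broadcast_to(np.asarray(fwhm_mm, dtype=np.float64), (3,))
    if np.any(fwhm <= 0):
        raise ValueError("FWHM components must be positive")
    sigma_vox = fwhm * FWHM_TO_SIGMA / vol.voxel_size_mm
    out = ndimage.gaussian_filter(
        vol.values, sigma=sigma_vox, mode="constant", cval=0.0, truncate=4.0
    )
    return vol.with_values(out)


def process_subject(
    seg: SegmentationSet,
    fwhm_mm=8.0,
    tiv_mode: str = "scaled",
    tiv_ref: float | None = None,
    brain_mask_min: float = BRAIN_MASK_MIN,
) -> SubjectTissueVolumes:
    """Full single-subject chain: thresholds -> binary map -> box blur ->
    TIV normalization -> Gaussian smoothing, for gwJTV, GMV and WMV maps.

    GM and WM maps are the partial-volume maps themselves, TIV-normalized
    and smoothed identically to the junction map.
    """
    thr = compute_thresholds(seg)
    binary = binarize_junction(seg, thr, brain_mask_min=brain_mask_min)
    blurred = box_blur_125(binary)
    gmv, wmv, csf, tiv = tissue_totals(seg)
    gwjtv_total, gwjtv_norm = junction_volume(blurred, tiv, tiv_mode, tiv_ref)
    scale = (tiv if tiv_ref is None else tiv_ref) if tiv_mode == "scaled" else 1.0
    gm_norm = seg.gm_pv.with_values(seg.gm_pv.values / tiv * scale)
    wm_norm = seg.wm_pv.with_values(seg.wm_pv.values / tiv * scale)
    return SubjectTissueVolumes(
        gmv_total=gmv,
        wmv_total=wmv,
        csf_total=csf,
        tiv=tiv,
        gwjtv_total=gwjtv_total,
        gmv_map=gaussian_smooth_fwhm(gm_norm, fwhm_mm),
        wmv_map=gaussian_smooth_fwhm(wm_norm, fwhm_mm),
        gwjtv_map=gaussian_smooth_fwhm(gwjtv_norm, fwhm_mm),
        thresholds=thr,
        tiv_mode=tiv_mode,
    )
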