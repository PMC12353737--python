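"""Voxel-based analysis: mass-univariate GLMs and cluster-extent thresholding.

At every voxel an ordinary least-squares model is fitted across subjects:

* group comparison — ``map ~ 1 + group + age`` with the t statistic of the
  group indicator (two-sample t-test with age as a covariate);
* parameter regression — ``map ~ 1 + param + age`` with the t statistic of
  the metabolic parameter.

Inference uses an uncorrected voxelwise alpha applied one-sided per
direction (positive and negative contrasts reported separately, as in the
SPM convention) combined with a minimum cluster extent under 18-neighbour
connectivity.  No further multiple-comparison correction is applied;
outputs are labelled "uncorrected" accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .junction import Volume3D

#: Clamp for z-equivalents of extreme t statistics (|z| of p ~ 1e-16).
Z_CLAMP = 8.2


class DesignRankError(ValueError):
    """The design matrix is rank deficient (confounded or constant columns)."""


@dataclass(frozen=True)
class StatMap:
    """Voxelwise t statistics for one contrast of one fitted GLM."""

    t_values: Volume3D
    df: int
    contrast: str  # group_diff | param_positive | param_negative
    n_subjects: int
    zero_variance: np.ndarray | None = None  # flagged voxels with t forced to 0

    def __post_init__(self):
        if self.df < 1:
            raise ValueError("degrees of freedom must be >= 1")


@dataclass(frozen=True)
class ClusterRecord:
    """One suprathreshold cluster surviving the extent threshold."""

    size: int
    peak_coord_mm: tuple
    peak_t: float
    peak_z: float
    direction: str  # positive | negative

    def __post_init__(self):
        if self.direction not in ("positive", "negative"):
            raise ValueError(f"bad direction {self.direction!r}")
        if self.peak_t != 0 and (self.peak_t > 0) != (self.direction == "positive"):
            raise ValueError("sign of peak_t inconsistent with direction")


def _stack(maps) -> tuple:
    """Stack subject volumes into (n_subjects, n_voxels) and keep the grid."""
    first = maps[0]
    for m in maps[1:]:
        if not first.same_grid(m):
            raise ValueError("all subject maps must share one grid")
    data = np.stack([m.values.reshape(-1) for m in maps], axis=0)
    return data, first


def _ols_t(data: np.ndarray, X: np.ndarray, col: int) -> tuple:
    """Vectorized per-voxel OLS t statistic for one design column.

    Returns (t, df, zero_variance_mask).  Voxels with no between-subject
    variance are undefined under OLS and get t = 0, flagged.
    """
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise DesignRankError("design matrix is rank deficient")
    df = n - p
    if df < 1:
        raise ValueError(f"need more subjects than design columns ({n} vs {p})")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ data  # (p, V)
    resid = data - X @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    sigma2 = rss / df
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[col, col], 0.0))
    zero_var = (data == data[0]).all(axis=0)  # no between-subject variation
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[col] / np.where(se > 0, se, 1.0), 0.0)
    t[zero_var] = 0.0
    return t, df, zero_var


def analysis_mask(data: np.ndarray) -> np.ndarray:
    """Voxels eligible for inference: any between-subject variation."""
    return ~(data == data[0]).all(axis=0)


def fit_group_glm(maps, group, age) -> StatMap:
    """Voxelwise two-sample comparison with age as a covariate.

    ``group`` may be string labels or a binary indicator; the t statistic
    is for the group-difference coefficient (first label minus second in
    sorted order for string labels, i.e. no_plaque minus plaque).
    """
    data, grid = _stack(maps)
    group = np.asarray(group)
    labels = np.unique(group)
    if labels.size != 2:
        raise ValueError(f"need exactly two group labels, got {labels}")
    indicator = (group == labels[0]).astype(np.float64)
    if indicator.sum() < 2 or (1 - indicator).sum() < 2:
        raise ValueError("need at least 2 subjects per group")
    age = np.asarray(age, dtype=np.float64)
    X = np.column_stack([np.ones(len(group)), indicator, age])
    t, df, zero_var = _ols_t(data, X, col=1)
    return StatMap(
        t_values=grid.with_values(t.reshape(grid.shape)),
        df=df,
        contrast="group_diff",
        n_subjects=len(group),
        zero_variance=zero_var.reshape(grid.shape),
    )


def fit_param_glm(maps, param, age) -> StatMap:
    """Voxelwise regression of the tissue map on one metabolic parameter,
    adjusted for age.  Positive and negative associations are read off the
    same t map via one-sided thresholding per direction.
    """
    data, grid = _stack(maps)
    param = np.asarray(param, dtype=np.float64)
    age = np.asarray(age, dtype=np.float64)
    if len(param) < 4:
        raise ValueError("need at least 4 subjects")
    if np.ptp(param) == 0:
        raise ValueError("parameter is constant across subjects")
    X = np.column_stack([np.ones(len(param)), param, age])
    t, df, zero_var = _ols_t(data, X, col=1)
    return StatMap(
        t_values=grid.with_values(t.reshape(grid.shape)),
        df=df,
        contrast="param",
        n_subjects=len(param),
        zero_variance=zero_var.reshape(grid.shape),
    )


def _connectivity_structure(connectivity: int) -> np.ndarray:
    order = {6: 1, 18: 2, 26: 3}
    if connectivity not in order:
        raise ValueError("connectivity must be 6, 18 or 26")
    return ndimage.generate_binary_structure(3, order[connectivity])


def t_to_z(t: float, df: int) -> float:
    """Standard-normal equivalent of a t statistic (clamped for extremes)."""
    z = stats.norm.ppf(stats.t.cdf(t, df))
    return float(np.clip(z, -Z_CLAMP, Z_CLAMP))


def threshold_clusters(
    stat: StatMap,
    alpha: float = 0.0005,
    k_min: int = 100,
    connectivity: int = 18,
) -> list:
    """Uncorrected voxelwise threshold plus minimum cluster extent.

    For each direction the one-sided critical t at ``alpha`` is applied,
    suprathreshold voxels are grouped by the given connectivity, and
    clusters below ``k_min`` voxels are discarded.  Records are sorted by
    size descending; peak z is the standard-normal equivalent of peak t.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if k_min < 1:
        raise ValueError("k_min must be >= 1")
    t_crit = stats.t.isf(alpha, stat.df)
    structure = _connectivity_structure(connectivity)
    grid = stat.t_values
    records = []
    for direction, sign in (("positive", 1.0), ("negative", -1.0)):
        supra = sign * grid.values > t_crit
        labels, n_lab = ndimage.label(supra, structure=structure)
        for lab in range(1, n_lab + 1):
            idx = np.argwhere(labels == lab)
            if len(idx) < k_min:
                continue
            tvals = grid.values[tuple(idx.T)]
            peak_pos = idx[np.argmax(sign * tvals)]
            peak_t = float(grid.values[tuple(peak_pos)])
            records.append(
                ClusterRecord(
                    size=len(idx),
                    peak_coord_mm=tuple(np.round(grid.voxel_to_mm(peak_pos), 6)),
                    peak_t=peak_t,
                    peak_z=t_to_z(peak_t, stat.df),
                    direction=direction,
                )
            )
    records.sort(key=lambda r: r.size, reverse=True)
    return records


def clusters_to_frame(records, contrast: str = "", parameter: str = "") -> pd.DataFrame:
    """Tidy cluster table (one row per cluster) for CSV export."""
    rows = [
        {
            "size": r.size,
            "peak_x_mm": r.peak_coord_mm[0],
            "peak_y_mm": r.peak_coord_mm[1],
            "peak_z_mm": r.peak_coord_mm[2],
            "peak_t": r.peak_t,
            "peak_z": r.peak_z,
            "direction": r.direction,
            "contrast": contrast,
            "parameter": parameter,
            "inference": "uncorrected",
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "size", "peak_x_mm", "peak_y_mm", "peak_z_mm", "peak_t", "peak_z",
            "direction", "contrast", "parameter", "inference",
        ],
    )
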