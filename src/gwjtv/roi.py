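"""Region-of-interest statistics: group tests, partial correlations,
statistical power under the noncentral t distribution, stepwise regression
with forced covariates, and the Pearson correlation heatmap.

Power conventions
-----------------
All tests are two-sided.  Power is the probability that the test statistic
exceeds the two-sided critical value under a noncentral t alternative:

* two-sample t-test — noncentrality d / sqrt(1/n_a + 1/n_b) with
  d = (mean_a - mean_b) / pooled SD and df = n_a + n_b - 2;
* partial correlation (k controlled covariates) — noncentrality
  |r| sqrt(n - 2 - k) / sqrt(1 - r^2) with df = n - 2 - k.

The default significance level is 0.016, a Bonferroni adjustment of 0.05
across the three tissue measures (GMV, WMV, gwJTV) analysed in parallel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .junction import Volume3D

logger = logging.getLogger("gwjtv")

#: Default ROI-level significance level: 0.05 Bonferroni-divided by the
#: three tissue measures tested in parallel.
DEFAULT_ALPHA_ROI = 0.016


class UndefinedCorrelationError(ValueError):
    """Correlation undefined because one residual vector is constant."""


# ---------------------------------------------------------------------------
# ROI extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RoiMask:
    """A binary region-of-interest on the analysis grid."""

    mask: Volume3D
    label: str = ""

    def __post_init__(self):
        vals = self.mask.values
        if not np.all(np.isin(np.unique(vals), (0.0, 1.0))):
            raise ValueError("ROI mask must be binary {0,1}")
        if vals.sum() < 1:
            raise ValueError("ROI mask has no voxels")


def extract_roi_value(vol: Volume3D, roi: RoiMask) -> float:
    """Mean of the map over the nonzero mask voxels."""
    if not vol.same_grid(roi.mask):
        raise ValueError("map and ROI are on different grids")
    sel = roi.mask.values > 0
    return float(vol.values[sel].mean())


# ---------------------------------------------------------------------------
# Group comparison with power
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupTestResult:
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t: float
    df: int
    p: float
    power: float
    alpha: float


def _noncentral_t_two_sided_power(delta: float, df: int, alpha: float) -> float:
    """P(|T'| > t_crit) for a noncentral t with noncentrality delta.

    scipy's nct can return NaN deep in the opposite tail at large
    noncentrality; that term is a vanishing probability, so it is dropped.
    """
    t_crit = stats.t.isf(alpha / 2.0, df)
    upper = stats.nct.sf(t_crit, df, delta)
    lower = stats.nct.cdf(-t_crit, df, delta)
    upper = 0.0 if np.isnan(upper) else upper
    lower = 0.0 if np.isnan(lower) else lower
    return float(np.clip(upper + lower, 0.0, 1.0))


def group_ttest_from_summary(
    mean_a, sd_a, n_a, mean_b, sd_b, n_b, alpha: float = DEFAULT_ALPHA_ROI
) -> GroupTestResult:
    """Pooled-variance two-sample t-test with observed power, from group
    summaries (mean, SD, n), so published tables can be re-analysed.

    Power is evaluated at the observed effect: noncentrality
    (mean_a - mean_b) / (sd_pooled sqrt(1/n_a + 1/n_b)) under the
    noncentral t with df = n_a + n_b - 2.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("need at least 2 subjects per group")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    df = n_a + n_b - 2
    sp2 = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / df
    diff = mean_a - mean_b
    if sp2 <= 0:
        if diff == 0:
            return GroupTestResult(mean_a, sd_a, n_a, mean_b, sd_b, n_b,
                                   t=0.0, df=df, p=1.0, power=alpha, alpha=alpha)
        raise ValueError("zero pooled variance with unequal means")
    se = np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
    t = diff / se
    p = 2.0 * stats.t.sf(abs(t), df)
    power = _noncentral_t_two_sided_power(abs(t), df, alpha)
    return GroupTestResult(
        mean_a=float(mean_a), sd_a=float(sd_a), n_a=int(n_a),
        mean_b=float(mean_b), sd_b=float(sd_b), n_b=int(n_b),
        t=float(t), df=df, p=float(min(p, 1.0)), power=power, alpha=alpha,
    )


def group_ttest_with_power(a, b, alpha: float = DEFAULT_ALPHA_ROI) -> GroupTestResult:
    """Pooled-variance two-sample t-test with observed power, from raw values."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    return group_ttest_from_summary(
        a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b), alpha
    )


# ---------------------------------------------------------------------------
# Partial correlation with power
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PartialCorrResult:
    r: float
    n: int
    k: int
    df: int
    p: float
    power: float
    alpha: float


def _residualize(y: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones(len(y)), covariates])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def partial_correlation(
    x, y, covariates=None, alpha: float = DEFAULT_ALPHA_ROI
) -> PartialCorrResult:
    """Pearson partial correlation by the residual method.

    Both variables are residualized on the covariates (plus intercept) by
    least squares, and the plain Pearson correlation of the residuals is
    tested with df = n - 2 - k.  With no covariates this reduces exactly
    to the ordinary Pearson correlation.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if covariates is None:
        cov = np.empty((len(x), 0))
    else:
        cov = np.atleast_2d(np.asarray(covariates, dtype=np.float64))
        if cov.shape[0] != len(x):
            cov = cov.T
    k = cov.shape[1]
    n = len(x)
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 (n={n}, k={k})")
    rx = _residualize(x, cov)
    ry = _residualize(y, cov)
    df = n - 2 - k
    # Residuals that vanish relative to the input mean the covariates explain
    # the variable completely: the remaining association is zero by residual
    # orthogonality.  A variable that was constant to begin with is an error.
    degen = []
    for orig, res in ((x, rx), (y, ry)):
        if orig.std() == 0:
            raise UndefinedCorrelationError(
                "constant input; correlation undefined"
            )
        degen.append(res.std() <= 1e-10 * orig.std())
    if any(degen):
        return PartialCorrResult(r=0.0, n=n, k=k, df=df, p=1.0, power=alpha,
                                 alpha=alpha)
    r = float(np.corrcoef(rx, ry)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        p, power = 0.0, 1.0
    else:
        t = r * np.sqrt(df) / np.sqrt(1.0 - r**2)
        p = float(min(2.0 * stats.t.sf(abs(t), df), 1.0))
        power = partial_corr_power(r, n, k, alpha)
    return PartialCorrResult(r=r, n=n, k=k, df=df, p=p, power=power, alpha=alpha)


def partial_corr_power(
    r: float, n: int, k: int = 1, alpha: float = DEFAULT_ALPHA_ROI
) -> float:
    """Two-sided power of a partial-correlation test at the observed r.

    Uses the noncentral t distribution with df = n - 2 - k and
    noncentrality |r| sqrt(df) / sqrt(1 - r^2); at r = 0 the power equals
    alpha by construction.
    """
    if not abs(r) < 1:
        raise ValueError("|r| must be < 1")
    df = n - 2 - k
    if df < 1:
        raise ValueError("need n > k + 2")
    delta = abs(r) * np.sqrt(df) / np.sqrt(1.0 - r**2)
    return _noncentral_t_two_sided_power(delta, df, alpha)


# ---------------------------------------------------------------------------
# Stepwise regression with forced covariates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StepwiseResult:
    forced_terms: tuple
    included_terms: tuple  # (name, beta, p) for every term in the final model
    excluded_terms: tuple
    step_log: tuple  # ("enter"|"remove", name, p) in order

    @property
    def selected(self) -> tuple:
        """Names of non-forced terms retained in the final model."""
        return tuple(
            name for name, _, _ in self.included_terms
            if name not in self.forced_terms and name != "intercept"
        )


def _ols_term_stats(y: np.ndarray, X: np.ndarray, names) -> dict:
    """Coefficients and two-sided p-values of one OLS fit, keyed by name."""
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = n - p
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))
    out = {}
    for j, name in enumerate(names):
        if se[j] > 0:
            t = beta[j] / se[j]
            pval = float(min(2.0 * stats.t.sf(abs(t), df), 1.0))
        else:
            pval = 1.0
        out[name] = (float(beta[j]), pval)
    return out


def stepwise_regression(
    y,
    candidates: pd.DataFrame,
    forced=("age", "HbA1c"),
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    max_iter: int = 100,
) -> StepwiseResult:
    """Stepwise OLS variable selection around a forced covariate core.

    Starting from the forced-only model, the candidate with the smallest
    partial p-value enters if it is below ``p_enter``; after each entry,
    any non-forced included term whose p-value rose above ``p_remove`` is
    removed.  Entry/removal p-values follow the partial-F = squared-t
    convention (identical for single-term steps).  Forced terms are never
    removed regardless of their p-values.  Candidates whose inclusion
    would make the design rank deficient are skipped with a warning.
    """
    if not p_enter < p_remove:
        raise ValueError("p_enter must be smaller than p_remove")
    y = np.asarray(y, dtype=np.float64)
    forced = tuple(forced)
    missing = [f for f in forced if f not in candidates.columns]
    if missing:
        raise ValueError(f"forced terms missing from candidates: {missing}")
    pool = [c for c in candidates.columns if c not in forced]
    if len(candidates) <= len(candidates.columns) + 1:
        raise ValueError("need more observations than model terms")

    included: list = []
    log: list = []

    def design(terms):
        cols = [np.ones(len(y))] + [
            candidates[t].to_numpy(dtype=np.float64) for t in terms
        ]
        return np.column_stack(cols), ["intercept", *terms]

    for _ in range(max_iter):
        changed = False
        # entry step: best candidate by partial p
        best_name, best_p = None, np.inf
        for cand in pool:
            if cand in included:
                continue
            X, names = design(list(forced) + included + [cand])
            if np.linalg.matrix_rank(X) < X.shape[1]:
                logger.warning("skipping collinear candidate %r", cand)
                continue
            pval = _ols_term_stats(y, X, names)[cand][1]
            if pval < best_p:
                best_name, best_p = cand, pval
        if best_name is not None and best_p < p_enter:
            included.append(best_name)
            log.append(("enter", best_name, best_p))
            changed = True
        # removal step: any included non-forced term above p_remove
        while included:
            X, names = design(list(forced) + included)
            term_stats = _ols_term_stats(y, X, names)
            worst = max(included, key=lambda t: term_stats[t][1])
            if term_stats[worst][1] > p_remove:
                included.remove(worst)
                log.append(("remove", worst, term_stats[worst][1]))
                changed = True
            else:
                break
        if not changed:
            break

    X, names = design(list(forced) + included)
    final = _ols_term_stats(y, X, names)
    included_terms = tuple(
        (name, final[name][0], final[name][1]) for name in names
    )
    excluded = tuple(c for c in pool if c not in included)
    return StepwiseResult(
        forced_terms=forced,
        included_terms=included_terms,
        excluded_terms=excluded,
        step_log=tuple(log),
    )


# ---------------------------------------------------------------------------
# Heatmap and helpers
# ---------------------------------------------------------------------------

def pearson_heatmap(table: pd.DataFrame, columns=None, min_pairs: int = 3) -> pd.DataFrame:
    """Symmetric matrix of pairwise Pearson correlations.

    Pairwise-complete handling: each entry uses the rows where both
    columns are present, requiring at least ``min_pairs`` of them.
    Constant columns yield NaN (undefined) off-diagonal entries; the
    diagonal is 1 wherever the column varies.
    """
    cols = list(columns) if columns is not None else [
        c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])
    ]
    data = table[cols].apply(pd.to_numeric, errors="coerce")
    corr = data.corr(method="pearson", min_periods=min_pairs)
    for c in cols:
        if data[c].std(skipna=True) == 0 or data[c].count() < 2:
            corr.loc[c, :] = np.nan
            corr.loc[:, c] = np.nan
        else:
            corr.loc[c, c] = 1.0
    return corr


def render_heatmap(corr: pd.DataFrame, path) -> None:
    """Render a correlation matrix to an image file (Agg backend)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(0.4 * len(corr) + 2,) * 2)
    im = ax.imshow(corr.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(corr)), corr.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(corr)), corr.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def bonferroni_alpha(base: float = 0.05, m: int = 3) -> float:
    """Bonferroni-adjusted significance level: base / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return base / m
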