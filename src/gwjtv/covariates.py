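"""Clinical covariate derivations and cohort-table validation.

Implements the handful of derived metabolic quantities whose formulas are
standard in the diabetes/atherosclerosis literature — HOMA-IR, BMI, the
apolipoprotein B/A1 ratio, the ankle-brachial index — and the validation
rules for the per-subject cohort table consumed by the statistical stages.

Note on the apolipoprotein ratio: clinical tables frequently label this
quantity "ApoA1/B ratio" while printing values that are only consistent
with ApoB/ApoA1 (ApoB runs ~60-75 against ApoA1 ~125-135, and the printed
ratios sit near 0.5).  The implementation follows the numbers: the ratio
returned is ApoB divided by ApoA1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Denominator constant of the homeostasis model assessment (mg/dL based).
HOMA_IR_DENOMINATOR = 405.0

GROUP_LABELS = ("no_plaque", "plaque")

#: Metabolic column names recognised in cohort tables (clinical shorthand).
METABOLIC_COLUMNS = (
    "DMdur", "BMI", "ALT", "AST", "ApoA1", "ApoB", "BA1ratio", "BUN", "Cr",
    "ACR", "GFR1", "HbA1c", "FBS", "HOMAIR", "insulinA", "Cpep", "HScrp",
    "logcrp", "Lpa", "logLpa", "LtABI", "RtABI", "SBP", "DBP", "HDL", "LDL",
    "TC", "TG",
)


class CohortValidationError(ValueError):
    """A cohort table violates the schema required downstream."""


def homa_ir(glucose, insulin):
    """Homeostasis model assessment of insulin resistance.

    HOMA-IR = fasting glucose (mg/dL) x fasting insulin (uU/mL) / 405.
    Bilinear in both inputs; zero insulin gives zero.
    """
    glucose = np.asarray(glucose, dtype=np.float64)
    insulin = np.asarray(insulin, dtype=np.float64)
    if np.any(glucose < 0) or np.any(insulin < 0):
        raise ValueError("glucose and insulin must be non-negative")
    out = glucose * insulin / HOMA_IR_DENOMINATOR
    return float(out) if out.ndim == 0 else out


def bmi(weight_kg, height_m):
    """Body mass index: weight divided by the square of height (kg/m^2)."""
    weight_kg = np.asarray(weight_kg, dtype=np.float64)
    height_m = np.asarray(height_m, dtype=np.float64)
    if np.any(height_m <= 0):
        raise ValueError("height must be positive")
    out = weight_kg / height_m**2
    return float(out) if out.ndim == 0 else out


def apo_ratio(apob, apoa1):
    """Apolipoprotein ratio, computed as ApoB / ApoA1 (see module note)."""
    apob = np.asarray(apob, dtype=np.float64)
    apoa1 = np.asarray(apoa1, dtype=np.float64)
    if np.any(apoa1 <= 0):
        raise ValueError("ApoA1 must be positive")
    out = apob / apoa1
    return float(out) if out.ndim == 0 else out


def abi(ankle_systolics, brachial_systolics):
    """Ankle-brachial index.

    The highest systolic pressure measured at the ankle divided by the
    highest systolic pressure in either arm.  Scale-invariant.
    """
    ankle = np.asarray(ankle_systolics, dtype=np.float64)
    arm = np.asarray(brachial_systolics, dtype=np.float64)
    if ankle.size == 0 or arm.size == 0:
        raise ValueError("pressure lists must be non-empty")
    if np.any(ankle <= 0) or np.any(arm <= 0):
        raise ValueError("pressures must be positive")
    return float(ankle.max() / arm.max())


def log10_marker(values):
    """Base-10 log transform used for the skewed markers hsCRP and Lp(a)."""
    values = np.asarray(values, dtype=np.float64)
    if np.any(values <= 0):
        raise ValueError("log-transformed markers must be positive")
    out = np.log10(values)
    return float(out) if out.ndim == 0 else out


def validate_cohort_table(
    table: pd.DataFrame,
    age_range=(18.0, 100.0),
    strict: bool = False,
) -> pd.DataFrame:
    """Validate a cohort table against the downstream schema.

    Requirements: ``group`` and ``age`` columns present; group takes
    exactly the two labels ``no_plaque``/``plaque``; ages inside the
    plausible range; ``mmse`` (when present) in [0, 30]; no duplicated
    ``id``.  In strict mode any unrecognised metabolic column is also an
    error.  Returns the table unchanged for call chaining.
    """
    for col in ("group", "age"):
        if col not in table.columns:
            raise CohortValidationError(f"cohort table missing column {col!r}")
    bad = set(table["group"].unique()) - set(GROUP_LABELS)
    if bad:
        raise CohortValidationError(f"unknown group labels: {sorted(bad)}")
    age = pd.to_numeric(table["age"], errors="coerce")
    if age.isna().any():
        raise CohortValidationError("non-numeric ages")
    if ((age < age_range[0]) | (age > age_range[1])).any():
        raise CohortValidationError(f"ages outside plausible range {age_range}")
    if "mmse" in table.columns:
        mmse = pd.to_numeric(table["mmse"], errors="coerce")
        if ((mmse < 0) | (mmse > 30)).any():
            raise CohortValidationError("MMSE scores must lie in [0, 30]")
    if "id" in table.columns and table["id"].duplicated().any():
        raise CohortValidationError("duplicated subject ids")
    if strict:
        known = {"id", "group", "age", "sex", "mmse", *METABOLIC_COLUMNS}
        extra = [
            c for c in table.columns
            if c not in known and not c.startswith("gt_")
        ]
        if extra:
            raise CohortValidationError(f"unrecognised columns: {extra}")
    return table


def read_cohort_csv(path, strict: bool = False, **validate_kwargs) -> pd.DataFrame:
    """Read and validate a cohort CSV (UTF-8, header row, '.' decimal)."""
    table = pd.read_csv(path)
    return validate_cohort_table(table, strict=strict, **validate_kwargs)


def write_cohort_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)
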