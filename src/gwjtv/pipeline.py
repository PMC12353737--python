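"""End-to-end orchestration: phantom cohort -> junction maps -> voxel-based
analysis -> ROI statistics, with JSON configuration, derived per-stage
seeds, and a hashed artifact manifest for reproducibility checks.

Also implements study-enrollment filtering: sequential application of
consent/MRI exclusions and eligibility criteria (age 30-70, BMI < 40,
HbA1c <= 10.0, eGFR >= 30), counting removals per criterion in order, plus
the MMSE >= 26 sensitivity filter.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import covariates, junction, phantom, roi, vba

logger = logging.getLogger("gwjtv")

#: Eligibility rules applied by the enrollment filter, in order.
ELIGIBILITY = (
    ("age_low", lambda t: t["age"] >= 30),
    ("age_high", lambda t: t["age"] <= 70),
    ("bmi", lambda t: t["BMI"] < 40),
    ("hba1c", lambda t: t["HbA1c"] <= 10.0),
    ("egfr", lambda t: t["GFR1"] >= 30),
)

FLAG_COLUMNS = ("consent_withdrawn", "mri_refused", "mri_incomplete")


class StageDependencyError(RuntimeError):
    """A stage was asked to run without its upstream artifact."""


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    Statistical defaults are the study settings: voxelwise alpha 0.0005
    uncorrected with a 100-voxel extent threshold, ROI alpha 0.016
    (0.05/3), 8 mm FWHM smoothing.
    """

    out_dir: str = "gwjtv_run"
    seed: int = 0
    stages: tuple = ("phantom", "junction", "vba", "roi")
    phantom_spec: phantom.PhantomSpec = field(default_factory=phantom.PhantomSpec)
    cohort_spec: phantom.CohortSpec = field(default_factory=phantom.CohortSpec)
    alpha_voxel: float = 0.0005
    k_min: int = 100
    alpha_roi: float = roi.DEFAULT_ALPHA_ROI
    fwhm_mm: float = 8.0
    tiv_mode: str = "scaled"
    connectivity: int = 18
    save_volumes: bool = False
    log_level: str = "INFO"

    def __post_init__(self):
        for name in ("alpha_voxel", "alpha_roi"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.k_min < 1:
            raise ValueError("k_min must be >= 1")
        if self.fwhm_mm <= 0:
            raise ValueError("fwhm_mm must be positive")
        if self.tiv_mode not in ("scaled", "fraction"):
            raise ValueError("tiv_mode must be 'scaled' or 'fraction'")
        unknown = set(self.stages) - {"phantom", "junction", "vba", "roi"}
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if "phantom_spec" in raw:
            raw["phantom_spec"] = phantom.PhantomSpec(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in raw["phantom_spec"].items()
            })
        if "cohort_spec" in raw:
            cs = dict(raw["cohort_spec"])
            if "covariate_model" in cs:
                cs["covariate_model"] = tuple(
                    phantom.CovariateModel(**c) if isinstance(c, dict)
                    else phantom.CovariateModel(*c)
                    for c in cs["covariate_model"]
                )
            if "age_range" in cs:
                cs["age_range"] = tuple(cs["age_range"])
            raw["cohort_spec"] = phantom.CohortSpec(**cs)
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def derive_seed(root_seed: int, stage: str) -> int:
    """Per-stage random stream derived from one root seed (below 2^31)."""
    digest = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _hash_array(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order and write a hashed manifest.

    Returns the manifest dict.  Deterministic stages re-run with the same
    config and seed reproduce identical hashes.
    """
    logging.basicConfig(
        level=config.log_level,
        format="%(levelname)s [%(name)s] %(message)s",
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": _config_to_jsonable(config),
        "artifacts": {},
        "volume_hashes": {},
    }

    cspec = dataclasses.replace(
        config.cohort_spec, seed=derive_seed(config.seed, "cohort")
    )
    pspec = dataclasses.replace(
        config.phantom_spec, seed=derive_seed(config.seed, "phantom")
    )

    subjects = table = None
    if "phantom" in config.stages:
        logger.info("stage phantom: %d subjects", cspec.n_total)
        subjects, table = phantom.make_cohort(cspec, pspec)
        covariates.write_cohort_csv(table, out / "cohort.csv")
        manifest["artifacts"]["cohort.csv"] = _sha256(out / "cohort.csv")
        for i, seg in enumerate(subjects):
            manifest["volume_hashes"][f"sub-{i:03d}_t1"] = _hash_array(seg.t1.values)
        if config.save_volumes:
            vol_dir = out / "volumes"
            vol_dir.mkdir(exist_ok=True)
            for i, seg in enumerate(subjects):
                for name, vol in (("t1", seg.t1), ("gm", seg.gm_pv),
                                  ("wm", seg.wm_pv), ("csf", seg.csf_pv)):
                    vol.save(vol_dir / f"sub-{i:03d}_{name}.nii.gz")

    results = None
    if "junction" in config.stages:
        if subjects is None:
            raise StageDependencyError(
                "junction stage needs phantom output (segmentations)"
            )
        logger.info("stage junction: tiv_mode=%s fwhm=%s", config.tiv_mode,
                    config.fwhm_mm)
        tivs = [junction.tissue_totals(s)[3] for s in subjects]
        tiv_ref = float(np.mean(tivs))
        results = [
            junction.process_subject(
                s, fwhm_mm=config.fwhm_mm, tiv_mode=config.tiv_mode,
                tiv_ref=tiv_ref,
            )
            for s in subjects
        ]
        sidecar = [
            {
                "subject": f"sub-{i:03d}",
                "gmv_mL": r.gmv_total,
                "wmv_mL": r.wmv_total,
                "csf_mL": r.csf_total,
                "tiv_mL": r.tiv,
                "gwjtv_mL": r.gwjtv_total,
                "tiv_mode": r.tiv_mode,
                "bt_lower": r.thresholds.bt_lower,
                "bt_upper": r.thresholds.bt_upper,
            }
            for i, r in enumerate(results)
        ]
        with open(out / "tissue_volumes.json", "w") as fh:
            json.dump(sidecar, fh, indent=1)
        manifest["artifacts"]["tissue_volumes.json"] = _sha256(
            out / "tissue_volumes.json"
        )
        for i, r in enumerate(results):
            manifest["volume_hashes"][f"sub-{i:03d}_gwjtv"] = _hash_array(
                r.gwjtv_map.values
            )

    if "vba" in config.stages:
        if results is None or table is None:
            raise StageDependencyError("vba stage needs junction output")
        logger.info("stage vba: alpha=%g k_min=%d (uncorrected)",
                    config.alpha_voxel, config.k_min)
        frames = []
        for measure in ("gwjtv", "gmv", "wmv"):
            maps = [getattr(r, f"{measure}_map") for r in results]
            stat = vba.fit_group_glm(maps, table["group"], table["age"])
            recs = vba.threshold_clusters(
                stat, alpha=config.alpha_voxel, k_min=config.k_min,
                connectivity=config.connectivity,
            )
            frames.append(vba.clusters_to_frame(recs, contrast="group_diff",
                                                parameter=measure))
        pd.concat(frames, ignore_index=True).to_csv(
            out / "clusters.csv", index=False
        )
        manifest["artifacts"]["clusters.csv"] = _sha256(out / "clusters.csv")

    if "roi" in config.stages:
        if results is None or table is None:
            raise StageDependencyError("roi stage needs junction output")
        logger.info("stage roi: alpha=%g", config.alpha_roi)
        roi_mask = roi.RoiMask(phantom.junction_roi_mask(pspec), "target_octant")
        rows = []
        for measure in ("gwjtv", "gmv", "wmv"):
            vals = np.array([
                roi.extract_roi_value(getattr(r, f"{measure}_map"), roi_mask)
                for r in results
            ])
            a = vals[(table["group"] == "no_plaque").to_numpy()]
            b = vals[(table["group"] == "plaque").to_numpy()]
            res = roi.group_ttest_with_power(a, b, alpha=config.alpha_roi)
            rows.append({
                "roi": roi_mask.label, "measure": measure, "t": res.t,
                "df": res.df, "p": res.p, "power": res.power,
                "mean_no_plaque": res.mean_a, "mean_plaque": res.mean_b,
            })
            table[f"roi_{measure}"] = vals
        pd.DataFrame(rows).to_csv(out / "roi_group_tests.csv", index=False)
        manifest["artifacts"]["roi_group_tests.csv"] = _sha256(
            out / "roi_group_tests.csv"
        )

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def _config_to_jsonable(config: RunConfig) -> dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (tuple, list)):
            return [convert(v) for v in obj]
        if isinstance(obj, np.generic):
            return obj.item()
        return obj

    return convert(config)


# ---------------------------------------------------------------------------
# Enrollment
# ---------------------------------------------------------------------------

def filter_enrollment(recruits: pd.DataFrame) -> tuple:
    """Apply study exclusions sequentially and return (enrolled, counts).

    Exclusion order: withdrew consent, refused MRI, incomplete MRI, then
    the eligibility criteria (age 30-70 years, BMI < 40 kg/m^2,
    HbA1c <= 10.0 %, eGFR >= 30 mL/min/1.73m^2).  A subject failing
    several criteria is counted under the first that applies, so the
    per-criterion counts always sum to the number removed.
    """
    missing = [c for c in FLAG_COLUMNS if c not in recruits.columns]
    if missing:
        raise covariates.CohortValidationError(
            f"recruitment table missing flag columns: {missing}"
        )
    for col in ("age", "BMI", "HbA1c", "GFR1"):
        if col not in recruits.columns:
            raise covariates.CohortValidationError(
                f"recruitment table missing eligibility column: {col!r}"
            )
    remaining = recruits.copy()
    counts: dict = {}
    for flag in FLAG_COLUMNS:
        drop = remaining[flag].astype(bool)
        counts[flag] = int(drop.sum())
        remaining = remaining[~drop]
    for name, rule in ELIGIBILITY:
        keep = rule(remaining)
        counts[name] = int((~keep).sum())
        remaining = remaining[keep]
    for crit, n in counts.items():
        if n:
            logger.info("enrollment: removed %d by %s", n, crit)
    return remaining.reset_index(drop=True), counts


def filter_mmse(table: pd.DataFrame, min_mmse: float = 26.0) -> pd.DataFrame:
    """Cognitive sensitivity filter: keep subjects with MMSE >= min_mmse."""
    if "mmse" not in table.columns:
        raise covariates.CohortValidationError("table has no 'mmse' column")
    kept = table[table["mmse"] >= min_mmse].reset_index(drop=True)
    logger.info("MMSE filter: kept %d of %d", len(kept), len(table))
    return kept


def make_recruitment_table(
    seed: int = 0,
    n_recruited: int = 101,
    n_withdrawn: int = 10,
    n_refused: int = 16,
    n_incomplete: int = 6,
    n_low_mmse=(7, 8),
    group_sizes=(33, 36),
) -> pd.DataFrame:
    """Synthetic recruitment table with a realistic exclusion structure.

    Defaults reproduce a 101-recruit screening flow: 10 withdraw consent,
    16 refuse MRI, 6 do not complete the scan, leaving 69 enrolled
    (33 without and 36 with carotid plaque), of whom 7 and 8 per group
    score MMSE < 26.  All eligible subjects fall inside the eligibility
    windows; covariate values are drawn at plausible clinical levels.
    """
    n_excluded = n_withdrawn + n_refused + n_incomplete
    n_enrolled = n_recruited - n_excluded
    if sum(group_sizes) != n_enrolled:
        raise ValueError("group sizes must sum to the enrolled count")
    rng = np.random.default_rng(seed)
    table = pd.DataFrame({
        "id": [f"rec-{i:03d}" for i in range(n_recruited)],
        "age": rng.uniform(32, 68, n_recruited),
        "BMI": rng.uniform(20, 35, n_recruited),
        "HbA1c": rng.uniform(5.8, 9.5, n_recruited),
        "GFR1": rng.uniform(45, 130, n_recruited),
        "consent_withdrawn": False,
        "mri_refused": False,
        "mri_incomplete": False,
        "group": "",
        "mmse": 0.0,
    })
    order = rng.permutation(n_recruited)
    w, r, c = order[:n_withdrawn], order[n_withdrawn:n_withdrawn + n_refused], \
        order[n_withdrawn + n_refused:n_excluded]
    table.loc[w, "consent_withdrawn"] = True
    table.loc[r, "mri_refused"] = True
    table.loc[c, "mri_incomplete"] = True
    enrolled_idx = order[n_excluded:]
    groups = np.array(
        ["no_plaque"] * group_sizes[0] + ["plaque"] * group_sizes[1]
    )
    table.loc[enrolled_idx, "group"] = groups
    # MMSE: low scorers per group below 26, the rest at/above
    for g, n_low in zip(("no_plaque", "plaque"), n_low_mmse):
        g_idx = np.asarray(enrolled_idx)[groups == g]
        low = rng.choice(g_idx, size=n_low, replace=False)
        high = np.setdiff1d(g_idx, low)
        table.loc[low, "mmse"] = rng.integers(20, 26, size=n_low).astype(float)
        table.loc[high, "mmse"] = rng.integers(26, 31, size=len(high)).astype(float)
    return table
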