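"""Biomarker harmonization and outcome/covariate derivation.

Fixed processing order: medication adjustment -> 4-SD outlier removal ->
log transform of skewed biomarkers -> z-scoring of all continuous measures.
Medication adjustments approximate pre-treatment values (LDL / 0.7,
triglycerides / 0.8, +15 / +10 mmHg on systolic / diastolic pressure) and
glucose and HbA1c are set missing under diabetic medication, since no
accepted back-correction exists for them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "HarmonizationRules", "adjust_for_medication", "remove_outliers",
    "transform_and_standardize", "derive_obesity", "map_education",
    "map_education_series", "derive_any_disease", "prepare_phenotypes",
    "EDUCATION_YEARS", "METABOLIC_COMPONENTS", "CARDIOVASCULAR_COMPONENTS",
]

# years of schooling implied by each self-reported attainment category
EDUCATION_YEARS = {
    "no education (did not finish primary school)": 1,
    "primary education": 7,
    "lower or preparatory secondary vocational education": 10,
    "junior general secondary education": 10,
    "secondary vocational education": 13,
    "senior general secondary education": 13,
    "higher vocational education": 20,
    "university education": 20,
}
_HIGH_EDUCATION_YEARS = 20  # higher vocational / university

METABOLIC_COMPONENTS = ["type2_diabetes", "obesity", "hypertension"]
CARDIOVASCULAR_COMPONENTS = [
    "thrombosis", "myocardial_infarction", "atherosclerosis", "stroke",
    "narrowing_carotid_arteries", "heart_failure", "atrial_fibrillation",
    "heart_valve_disorders", "aneurysm", "cabg_history",
]

_DEFAULT_LOG = (
    "leucocytes", "hba1c", "glucose", "hdl", "triglycerides", "alt", "ast",
    "alkaline_phosphatase", "gamma_gt", "creatinine", "creatinine_clearance",
    "urine_albumin", "uric_acid", "tsh", "free_t3", "free_t4", "acr", "uae",
)

_DEFAULT_CONTINUOUS = _DEFAULT_LOG + (
    "total_cholesterol", "ldl", "hs_crp", "systolic_bp", "diastolic_bp",
    "haematocrit", "haemoglobin", "egfr", "bmi",
)


@dataclass
class HarmonizationRules:
    """Medication adjustments, exclusions, trimming and transform lists."""

    ldl_divisor: float = 0.7
    tg_divisor: float = 0.8
    sbp_offset: float = 15.0
    dbp_offset: float = 10.0
    diabetic_exclusions: tuple[str, ...] = ("glucose", "hba1c")
    outlier_sd: float = 4.0
    log_transformed: tuple[str, ...] = _DEFAULT_LOG
    continuous: tuple[str, ...] = _DEFAULT_CONTINUOUS
    ldl_col: str = "ldl"
    tg_col: str = "triglycerides"
    sbp_col: str = "systolic_bp"
    dbp_col: str = "diastolic_bp"
    lipid_flag: str = "lipid_lowering_med"
    bp_flag: str = "bp_lowering_med"
    diabetes_flag: str = "diabetes_med"

    def __post_init__(self) -> None:
        for name in ("ldl_divisor", "tg_divisor"):
            if not (0.0 < getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1]")
        for name in ("sbp_offset", "dbp_offset"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _flagged(pheno: pd.DataFrame, col: str) -> np.ndarray:
    return pheno[col].fillna(0).astype(float).to_numpy() == 1


def adjust_for_medication(pheno: pd.DataFrame,
                          rules: HarmonizationRules | None = None) -> pd.DataFrame:
    """Approximate pre-medication biomarker values for flagged samples.

    Idempotency is guarded by a provenance marker: calling this twice on the
    same table raises, since re-dividing would corrupt the values.
    """
    rules = rules or HarmonizationRules()
    if pheno.attrs.get("medication_adjusted"):
        raise ValueError("phenotypes already medication-adjusted "
                         "(provenance marker present)")
    out = pheno.copy()
    out.attrs = dict(pheno.attrs)

    for col, flag, op in [
        (rules.ldl_col, rules.lipid_flag, lambda v: v / rules.ldl_divisor),
        (rules.tg_col, rules.lipid_flag, lambda v: v / rules.tg_divisor),
        (rules.sbp_col, rules.bp_flag, lambda v: v + rules.sbp_offset),
        (rules.dbp_col, rules.bp_flag, lambda v: v + rules.dbp_offset),
    ]:
        if col not in out.columns or flag not in out.columns:
            continue
        values = out[col].to_numpy(dtype=float)
        if np.nanmin(values) < 0:
            raise ValueError(f"negative value in {col!r}: check units")
        mask = _flagged(out, flag)
        values = values.copy()
        values[mask] = op(values[mask])
        out[col] = values

    if rules.diabetes_flag in out.columns:
        mask = _flagged(out, rules.diabetes_flag)
        for col in rules.diabetic_exclusions:
            if col in out.columns:
                vals = out[col].to_numpy(dtype=float).copy()
                vals[mask] = np.nan
                out[col] = vals
    out.attrs["medication_adjusted"] = True
    return out


def remove_outliers(values: pd.Series, sd_limit: float = 4.0
                    ) -> tuple[pd.Series, int]:
    """Set values more than ``sd_limit`` SDs from the mean to missing.

    Mean and SD are computed once over the non-missing values (single pass,
    not iterated).  A zero-SD series is returned unchanged.
    """
    v = values.astype(float)
    ok = v.notna()
    if ok.sum() < 2:
        raise ValueError("need at least 2 non-missing values")
    mean = v[ok].mean()
    sd = v[ok].std(ddof=1)
    if sd == 0 or np.isnan(sd):
        return v, 0
    out_mask = ok & ((v - mean).abs() > sd_limit * sd)
    out = v.mask(out_mask)
    return out, int(out_mask.sum())


def transform_and_standardize(pheno: pd.DataFrame,
                              rules: HarmonizationRules | None = None,
                              columns: list[str] | None = None
                              ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Natural-log-transform the listed skewed biomarkers, then z-score all
    continuous measures over their non-missing values.  Non-positive values
    hitting the log are set missing and counted."""
    rules = rules or HarmonizationRules()
    out = pheno.copy()
    out.attrs = dict(pheno.attrs)
    cols = columns if columns is not None else \
        [c for c in rules.continuous if c in out.columns]
    log_failures: dict[str, int] = {}
    for col in cols:
        v = out[col].astype(float)
        if col in rules.log_transformed:
            bad = v.notna() & (v <= 0)
            if bad.any():
                log_failures[col] = int(bad.sum())
                v = v.mask(bad)
            v = np.log(v)
        mean = v.mean()
        sd = v.std(ddof=0)
        out[col] = (v - mean) / sd if sd and not np.isnan(sd) else v - mean
    out.attrs["standardized"] = True
    return out, log_failures


def derive_obesity(bmi: pd.Series) -> pd.Series:
    """Obesity indicator: 1 iff BMI >= 30 kg/m^2; missing propagates."""
    v = bmi.astype(float)
    if (v.dropna() <= 0).any():
        raise ValueError("BMI must be positive")
    return pd.Series(np.where(v.isna(), np.nan, (v >= 30).astype(float)),
                     index=bmi.index, name="obesity")


def map_education(category: str) -> tuple[int, str]:
    """Map a self-reported attainment category to years of schooling and a
    low/high level (high = higher vocational or university)."""
    if category not in EDUCATION_YEARS:
        raise ValueError(f"unknown education category {category!r}; valid: "
                         f"{sorted(EDUCATION_YEARS)}")
    years = EDUCATION_YEARS[category]
    return years, ("high" if years >= _HIGH_EDUCATION_YEARS else "low")


def map_education_series(categories: pd.Series) -> pd.DataFrame:
    mapped = [map_education(c) if pd.notna(c) else (np.nan, np.nan)
              for c in categories]
    return pd.DataFrame(mapped, columns=["education_years", "education_level"],
                        index=categories.index)


def derive_any_disease(pheno: pd.DataFrame, group: str | list[str]) -> pd.Series:
    """Logical OR over component disease indicators.

    Missing components count as 0 unless every component is missing, in
    which case the result is missing.
    """
    if isinstance(group, str):
        components = {"metabolic": METABOLIC_COMPONENTS,
                      "cardiovascular": CARDIOVASCULAR_COMPONENTS}.get(group)
        if components is None:
            raise ValueError(f"unknown disease group {group!r}")
        components = [c for c in components if c in pheno.columns]
        name = f"{group}_disease"
    else:
        components = list(group)
        name = "any_disease"
    if not components:
        raise ValueError("empty disease component group")
    block = pheno[components].astype(float)
    any_pos = (block == 1).any(axis=1)
    all_missing = block.isna().all(axis=1)
    out = any_pos.astype(float).mask(all_missing)
    out.name = name
    return out


def prepare_phenotypes(pheno: pd.DataFrame,
                       rules: HarmonizationRules | None = None
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full harmonization in the fixed order, returning the cleaned table
    and a per-biomarker report (outliers removed, log failures)."""
    rules = rules or HarmonizationRules()
    out = adjust_for_medication(pheno, rules)
    cols = [c for c in rules.continuous if c in out.columns]
    outlier_counts = {}
    for col in cols:
        if out[col].notna().sum() >= 2:
            out[col], outlier_counts[col] = remove_outliers(out[col],
                                                            rules.outlier_sd)
        else:
            outlier_counts[col] = 0
    if "bmi" in out.columns:
        out["obesity"] = derive_obesity(out["bmi"])
    if "education_category" in out.columns:
        out[["education_years", "education_level"]] = \
            map_education_series(out["education_category"])
    out, log_failures = transform_and_standardize(out, rules, columns=cols)
    for grp in ("metabolic", "cardiovascular"):
        comps = METABOLIC_COMPONENTS if grp == "metabolic" else CARDIOVASCULAR_COMPONENTS
        if any(c in out.columns for c in comps):
            out[f"{grp}_disease"] = derive_any_disease(out, grp)
    report = pd.DataFrame({
        "biomarker": cols,
        "outliers_removed": [outlier_counts[c] for c in cols],
        "log_transformed": [c in rules.log_transformed for c in cols],
        "log_failures": [log_failures.get(c, 0) for c in cols],
    })
    report.attrs["order"] = ("medication_adjustment -> outlier_removal -> "
                             "log_transform -> z_score")
    return out, report
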