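"""Cohort descriptive statistics (Table-1-style summaries)."""

from __future__ import annotations

import pandas as pd

__all__ = ["percent_female", "cohort_descriptives"]


def percent_female(n_female: int, n_male: int) -> float:
    """Female percentage from female/male counts."""
    total = n_female + n_male
    if total <= 0:
        raise ValueError("need at least one counted individual")
    return 100.0 * n_female / total


def cohort_descriptives(pheno: pd.DataFrame,
                        sibling_ids=None) -> dict[str, float]:
    """Summary statistics of a phenotype table (and optionally its sibling
    subsample): N, female %, mean/SD age, completion of higher education."""
    def _summ(df: pd.DataFrame, prefix: str) -> dict[str, float]:
        out = {f"{prefix}n": int(len(df))}
        if "sex" in df.columns:
            n_f = int((df["sex"] == 1).sum())
            out[f"{prefix}pct_female"] = percent_female(n_f, len(df) - n_f)
        if "age" in df.columns:
            out[f"{prefix}mean_age"] = float(df["age"].mean())
            out[f"{prefix}sd_age"] = float(df["age"].std())
        if "education_category" in df.columns:
            high = df["education_category"].isin(
                ["higher vocational education", "university education"])
            out[f"{prefix}pct_higher_education"] = float(100.0 * high.mean())
        return out

    stats = _summ(pheno, "")
    if sibling_ids is not None:
        sib = pheno[pheno["individual_id"].isin(set(sibling_ids))]
        stats.update(_summ(sib, "sib_"))
    return stats
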