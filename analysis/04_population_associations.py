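#!/usr/bin/env python
"""Population-level associations of the PGS with diseases and biomarkers.

Fits working-independence GLMs (logit for diseases, identity for
biomarkers) with family-clustered sandwich SEs and the full covariate set
(age, sex, chip, 8 genotype PCs, chip x PC interactions), reports OR/beta
with 95% CI, Delta-R^2 and pooled BH-FDR, plus the sensitivity rerun
excluding self-reported ADHD and the age/sex/education stratifications.
Writes results under results/assoc/.
"""

from pathlib import Path

import pandas as pd

from sibscore.assoc import (ModelSpec, results_to_frame, run_association,
                            run_interaction)
from sibscore.io_formats import read_phenotypes, write_results

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "assoc"
COVARIATES = ["age", "sex", "chip"] + [f"PC{i}" for i in range(1, 9)]

OUTCOMES = [
    ("metabolic_disease", "logit"), ("type2_diabetes", "logit"),
    ("obesity", "logit"), ("hypertension", "logit"),
    ("hdl", "identity"), ("triglycerides", "identity"),
    ("glucose", "identity"), ("systolic_bp", "identity"),
    ("leucocytes", "identity"), ("total_cholesterol", "identity"),
]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    data = read_phenotypes(ROOT / "phenotypes" / "phenotypes_clean.tsv")
    pgs = pd.read_csv(ROOT / "pgs" / "pgs.tsv", sep="\t")
    data = data.merge(pgs.rename(columns={"IID": "individual_id"}),
                      on="individual_id")

    results = []
    for outcome, link in OUTCOMES:
        spec = ModelSpec(outcome=outcome, link=link, covariates=COVARIATES)
        results.append(run_association(data, spec, model_label="main"))
        results.append(run_association(
            data, ModelSpec(outcome=outcome, link=link,
                            covariates=COVARIATES,
                            sample_filter="adhd_self_report == 0"),
            model_label="excl_adhd"))
        if outcome != "obesity":
            results.append(run_association(
                data, ModelSpec(outcome=outcome, link=link,
                                covariates=COVARIATES + ["bmi"]),
                model_label="bmi_adjusted"))
    frame = results_to_frame(results)
    write_results(frame, OUT / "assoc_results.tsv")

    inter = [run_interaction(data, ModelSpec(outcome=o, link=lk,
                                             covariates=COVARIATES), mod)
             for o, lk in OUTCOMES[:4] for mod in ("age", "sex")]
    pd.DataFrame(inter).to_csv(OUT / "moderation.tsv", sep="\t", index=False)

    main_rows = frame[frame["model"] == "main"]
    print("population associations (main model):")
    for _, r in main_rows.iterrows():
        eff = (f"OR {r['odds_ratio']:.3f}" if pd.notna(r["odds_ratio"])
               else f"beta {r['estimate']:+.3f}")
        print(f"  {r['outcome']:<18} {eff}  dR2 {100 * r['r2_delta']:.2f}%  "
              f"p_fdr {r['p_fdr']:.2g}")
    print(f"tables written to {OUT}")


if __name__ == "__main__":
    main()
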