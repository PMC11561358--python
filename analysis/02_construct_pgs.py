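#!/usr/bin/env python
"""Construct the polygenic score.

Reruns the cohort simulation (same seed as 01) to recover the genotype
matrices, then applies the scoring pipeline: QC (strand-ambiguous, MAF,
INFO), allele harmonization, LD clumping (r^2 < 0.1, 250 kb) against the
founder reference panel, scoring at 11 p-value thresholds, and PGS-PCA
aggregation.  Writes per-sample scores and the QC report under
results/pgs/.
"""

from pathlib import Path

import numpy as np

from sibscore.pgs import run_pgs_pipeline
from sibscore.synthdata import SimConfig, simulate_study

OUT = Path(__file__).resolve().parents[1] / "results" / "pgs"
SEED = 20240901


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(n_families=2000, sibs_per_family=2, n_variants=1000,
                    block_size=10, seed=SEED)
    study = simulate_study(cfg)
    result, scores, report = run_pgs_pipeline(
        study.sumstats, study.offspring, reference=study.founders)
    result.to_frame().to_csv(OUT / "pgs.tsv", sep="\t", index=False)
    report.to_csv(OUT / "qc_report.tsv", sep="\t", index=False)

    r = np.corrcoef(result.score, study.truth.true_pgs)[0, 1]
    print("QC / scoring report:")
    print(report.to_string(index=False))
    print(f"first PC explains {100 * result.variance_explained:.1f}% of the "
          f"threshold-score variance")
    print(f"correlation of final PGS with the true generative score: {r:.3f}")
    print(f"tables written to {OUT}")


if __name__ == "__main__":
    main()
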