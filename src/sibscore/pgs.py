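"""Polygenic score construction: QC, allele harmonization, LD clumping,
multi-threshold scoring and PGS-PCA aggregation.

The score for one individual at a p-value threshold t is the sum over
retained variants with p <= t of (risk-allele dosage x log-odds weight).
Scores at the 11 canonical thresholds are z-scored and aggregated by taking
the first principal component ("PGS-PCA"), which sidesteps choosing a single
best threshold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GenotypeSet

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_THRESHOLDS", "ThresholdScores", "PgsResult",
    "qc_filter", "harmonize", "ld_clump", "score", "pgs_pca",
    "compute_genotype_pcs", "run_pgs_pipeline",
]

DEFAULT_THRESHOLDS = (5e-8, 1e-7, 1e-6, 1e-5, 1e-4, 1e-3, 0.01, 0.05, 0.1, 0.5, 1.0)

_AMBIGUOUS_SETS = ({"A", "T"}, {"C", "G"})


@dataclass
class ThresholdScores:
    """Raw and z-scored per-sample scores at each p-value threshold."""

    sample_ids: list[str]
    thresholds: tuple[float, ...]
    raw: np.ndarray          # (n_samples, n_thresholds)
    z: np.ndarray            # z-scored columns (all-zero where undefined)
    n_variants: np.ndarray   # variants entering each threshold


@dataclass
class PgsResult:
    """Final PGS: first principal component of the z-scored threshold scores."""

    sample_ids: list[str]
    score: np.ndarray
    loadings: np.ndarray
    variance_explained: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"IID": self.sample_ids, "PGS": self.score})


def qc_filter(sumstats: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Remove strand-ambiguous variants (A/T, C/G) and those failing
    MAF > 0.01 or INFO > 0.8 (strict inequalities, applied in that order)."""
    ss = sumstats
    ambiguous = np.array([{e, o} in _AMBIGUOUS_SETS
                          for e, o in zip(ss["effect_allele"], ss["other_allele"])])
    low_maf = ~ambiguous & ~(ss["maf"].to_numpy() > 0.01)
    low_info = ~ambiguous & ~low_maf & ~(ss["info"].to_numpy() > 0.8)
    counts = {"ambiguous": int(ambiguous.sum()),
              "maf": int(low_maf.sum()),
              "info": int(low_info.sum())}
    kept = ss[~(ambiguous | low_maf | low_info)].reset_index(drop=True)
    if kept.empty:
        warnings.warn("qc_filter removed every variant", stacklevel=2)
    return kept, counts


def harmonize(sumstats: pd.DataFrame, genotypes: GenotypeSet) -> pd.DataFrame:
    """Align summary-statistic weights to the genotype counted allele.

    Variants are intersected on id; the weight is kept when the counted
    allele equals the effect allele, negated when it equals the other
    allele, and the variant is dropped when the allele sets disagree.
    Returns a frame with columns id, weight, p and the genotype column index.
    """
    geno = genotypes.variants[["id", "counted_allele", "other_allele"]].copy()
    geno["col"] = np.arange(len(geno))
    merged = sumstats.merge(geno, on="id", suffixes=("", "_geno"))
    if merged.empty:
        raise ValueError("no overlapping variants between summary statistics "
                         "and genotypes")
    same = ((merged["effect_allele"] == merged["counted_allele"])
            & (merged["other_allele"] == merged["other_allele_geno"]))
    flipped = ((merged["effect_allele"] == merged["other_allele_geno"])
               & (merged["other_allele"] == merged["counted_allele"]))
    mismatched = ~(same | flipped)
    if mismatched.any():
        logger.info("harmonize: dropped %d variant(s) with mismatching alleles",
                    int(mismatched.sum()))
    out = merged[~mismatched].copy()
    out["weight"] = np.where(same[~mismatched], out["weight"], -out["weight"])
    out = out[["id", "weight", "p", "col"]].reset_index(drop=True)
    out.attrs["n_allele_mismatch"] = int(mismatched.sum())
    return out


def ld_clump(sumstats: pd.DataFrame, reference: GenotypeSet,
             r2_max: float = 0.1, window_bp: int = 250_000,
             on_missing: str = "warn") -> list[str]:
    """Greedy LD clumping.

    Repeatedly take the remaining variant with the smallest p-value as the
    index (ties broken by chromosome, position, id), retain it, and remove
    every remaining variant on the same chromosome within ``window_bp``
    (|pos_i - pos_j| <= window) whose squared dosage correlation with the
    index exceeds ``r2_max``.  Returns the retained ids, ordered by p.
    """
    ref = reference.variants
    ref_pos = {vid: i for i, vid in enumerate(ref["id"])}
    present = sumstats["id"].isin(ref_pos).to_numpy()
    if (~present).any():
        msg = (f"{int((~present).sum())} variant(s) absent from the LD "
               f"reference were dropped")
        if on_missing == "error":
            raise ValueError(msg)
        logger.warning("ld_clump: %s", msg)
    cand = sumstats[present].reset_index(drop=True)
    if cand.empty:
        return []

    cols = np.array([ref_pos[v] for v in cand["id"]])
    D = reference.dosage[:, cols].astype(float)
    # mean-impute missing dosages for the correlation computation
    if np.isnan(D).any():
        mu = np.nanmean(D, axis=0)
        idx = np.where(np.isnan(D))
        D[idx] = np.take(mu, idx[1])
    Dc = D - D.mean(axis=0)
    norms = np.sqrt((Dc ** 2).sum(axis=0))
    norms[norms == 0] = 1.0
    Dn = Dc / norms

    p = cand["p"].to_numpy()
    chrom = cand["chrom"].astype(str).to_numpy()
    pos = cand["pos"].to_numpy()
    ids = cand["id"].to_numpy()
    order = np.lexsort((ids, pos, chrom, p))

    active = np.ones(len(cand), dtype=bool)
    kept: list[str] = []
    for i in order:
        if not active[i]:
            continue
        active[i] = False
        kept.append(ids[i])
        near = active & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window_bp)
        if near.any():
            r = Dn[:, near].T @ Dn[:, i]
            drop = np.flatnonzero(near)[r ** 2 > r2_max]
            active[drop] = False
    return kept


def score(genotypes: GenotypeSet, weights: pd.DataFrame,
          thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS) -> ThresholdScores:
    """Per-sample weighted dosage sums at each p-value threshold (p <= t,
    inclusive), then z-scored per threshold.  Missing dosages are
    mean-imputed per variant."""
    thresholds = tuple(sorted(thresholds))
    cols = weights["col"].to_numpy()
    w = weights["weight"].to_numpy()
    p = weights["p"].to_numpy()
    D = genotypes.dosage[:, cols].astype(float)
    if np.isnan(D).any():
        mu = np.nanmean(D, axis=0)
        mu = np.where(np.isnan(mu), 0.0, mu)
        idx = np.where(np.isnan(D))
        D[idx] = np.take(mu, idx[1])

    n = genotypes.n_samples
    raw = np.zeros((n, len(thresholds)))
    z = np.zeros_like(raw)
    counts = np.zeros(len(thresholds), dtype=int)
    for k, t in enumerate(thresholds):
        mask = p <= t
        counts[k] = int(mask.sum())
        if counts[k] == 0:
            warnings.warn(f"threshold {t} selects no variants", stacklevel=2)
            continue
        raw[:, k] = D[:, mask] @ w[mask]
        sd = raw[:, k].std()
        if sd == 0:
            warnings.warn(f"threshold {t} yields a constant score", stacklevel=2)
            continue
        z[:, k] = (raw[:, k] - raw[:, k].mean()) / sd
    return ThresholdScores(sample_ids=list(genotypes.sample_ids),
                           thresholds=thresholds, raw=raw, z=z,
                           n_variants=counts)


def pgs_pca(scores: ThresholdScores) -> PgsResult:
    """First principal component of the z-scored threshold scores,
    sign-aligned to correlate non-negatively with their column mean."""
    Z = scores.z
    n = Z.shape[0]
    if n < 2:
        raise ValueError("pgs_pca requires at least 2 samples")
    keep = Z.std(axis=0) > 0
    if not keep.any():
        raise ValueError("all threshold scores are constant; no PGS defined")
    Zk = Z[:, keep]
    corr = (Zk.T @ Zk) / n
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    v = eigvec[:, order[0]]
    pc = Zk @ v
    ref = Zk.mean(axis=1)
    if np.dot(pc - pc.mean(), ref - ref.mean()) < 0:
        v = -v
        pc = -pc
    loadings = np.zeros(Z.shape[1])
    loadings[keep] = v
    return PgsResult(sample_ids=list(scores.sample_ids), score=pc,
                     loadings=loadings,
                     variance_explained=float(eigval[0] / eigval.sum()))


def compute_genotype_pcs(genotypes: GenotypeSet | np.ndarray, k: int = 8) -> pd.DataFrame:
    """Top-k principal components of the mean-centered dosage matrix, each
    z-scored.  If k exceeds the matrix rank, fewer components are returned
    with a warning."""
    if isinstance(genotypes, GenotypeSet):
        X = genotypes.dosage.astype(float)
        index = list(genotypes.sample_ids)
    else:
        X = np.asarray(genotypes, dtype=float)
        index = list(range(X.shape[0]))
    if k == 0:
        return pd.DataFrame(index=index)
    if X.shape[0] < k + 1:
        raise ValueError(f"need at least {k + 1} samples for {k} PCs")
    if np.isnan(X).any():
        mu = np.nanmean(X, axis=0)
        idx = np.where(np.isnan(X))
        X = X.copy()
        X[idx] = np.take(mu, idx[1])
    Xc = X - X.mean(axis=0)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    tol = max(Xc.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int((s > tol).sum())
    if k > rank:
        warnings.warn(f"requested {k} PCs but rank is {rank}; returning {rank}",
                      stacklevel=2)
        k = rank
    # canonical sign from the loadings, so sample order cannot flip a PC
    for j in range(k):
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            u[:, j] = -u[:, j]
            vt[j] = -vt[j]
    pcs = u[:, :k] * s[:k]
    sd = pcs.std(axis=0)
    sd[sd == 0] = 1.0
    pcs = (pcs - pcs.mean(axis=0)) / sd
    return pd.DataFrame(pcs, columns=[f"PC{j + 1}" for j in range(k)], index=index)


def run_pgs_pipeline(sumstats: pd.DataFrame, genotypes: GenotypeSet,
                     reference: GenotypeSet | None = None,
                     r2_max: float = 0.1, window_bp: int = 250_000,
                     thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
                     ) -> tuple[PgsResult, ThresholdScores, pd.DataFrame]:
    """QC -> harmonize -> clump -> multi-threshold score -> PGS-PCA.

    ``reference`` is the LD panel for clumping (the target genotypes by
    default).  Returns the final PGS, the threshold scores and a QC report
    (rule, variants removed/retained).
    """
    reference = reference if reference is not None else genotypes
    qc, counts = qc_filter(sumstats)
    aligned = harmonize(qc, genotypes)
    kept = ld_clump(aligned.rename(columns={})  # aligned carries id/p
                    .merge(sumstats[["id", "chrom", "pos"]], on="id"),
                    reference, r2_max=r2_max, window_bp=window_bp)
    clumped = aligned[aligned["id"].isin(kept)].reset_index(drop=True)
    ts = score(genotypes, clumped, thresholds=thresholds)
    result = pgs_pca(ts)
    report = pd.DataFrame({
        "rule": ["input", "ambiguous_strand", "low_maf", "low_info",
                 "allele_mismatch", "clump_removed", "scored"],
        "variants": [len(sumstats), counts["ambiguous"], counts["maf"],
                     counts["info"], aligned.attrs.get("n_allele_mismatch", 0),
                     len(aligned) - len(clumped), len(clumped)],
    })
    return result, ts, report
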