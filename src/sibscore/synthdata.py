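"""Synthetic family cohort generator with known causal structure.

Generates nuclear families (two founders plus full siblings), block-LD
genotypes, noisy GWAS summary statistics, and phenotypes built from a
direct genetic effect of the child's own polygenic score, an indirect
("genetic nurture") effect of the midparent score, a shared family
environment, and residual noise.  Optional switches add two-subpopulation
structure (population stratification) and assortative mating.  A
:class:`TruthLedger` records every latent quantity so downstream stages
can be tested for parameter recovery.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "SimConfig",
    "TruthLedger",
    "SimStudy",
    "simulate_founders",
    "build_pedigree",
    "transmit",
    "simulate_sumstats",
    "simulate_phenotypes",
    "simulate_study",
]

VARIANT_SPACING_BP = 10_000

# Non-complementary allele pairs (strand-resolvable); complementary pairs
# are assigned only to the deliberately "ambiguous" QC-exercise fraction.
_UNAMBIGUOUS = [("A", "G"), ("G", "A"), ("A", "C"), ("C", "A"),
                ("T", "G"), ("G", "T"), ("T", "C"), ("C", "T")]
_AMBIGUOUS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]

# Biomarker panel: name, population mean, SD, log-normal scale?, sign of the
# genetic effect.  Means/SDs chosen to resemble adult cohort laboratory values.
BIOMARKER_PANEL = [
    ("glucose", 4.96, 0.73, True, +1),
    ("hba1c", 5.49, 0.32, True, +1),
    ("total_cholesterol", 5.09, 1.02, False, +1),
    ("ldl", 3.25, 0.93, False, +1),
    ("hdl", 1.47, 0.37, True, -1),
    ("triglycerides", 1.11, 0.57, True, +1),
    ("gamma_gt", 24.44, 14.77, True, +1),
    ("creatinine", 73.29, 12.14, True, +1),
    ("leucocytes", 5.98, 1.50, True, +1),
    ("hs_crp", 2.90, 2.90, True, +1),
    ("systolic_bp", 126.59, 16.56, False, +1),
    ("diastolic_bp", 74.27, 10.08, False, +1),
    ("bmi", 26.0, 3.6, False, +1),
]

EDUCATION_CATEGORIES = {
    "no education (did not finish primary school)": 0.010,
    "primary education": 0.040,
    "lower or preparatory secondary vocational education": 0.150,
    "junior general secondary education": 0.100,
    "secondary vocational education": 0.280,
    "senior general secondary education": 0.155,
    "higher vocational education": 0.190,
    "university education": 0.075,
}

_DEFAULT_PREVALENCE = {
    "type2_diabetes": 0.027,
    "hypertension": 0.205,
    "thrombosis": 0.013,
    "myocardial_infarction": 0.010,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Named substream of the master seed (one stream per stochastic op)."""
    return np.random.default_rng([int(seed), zlib.crc32(stream.encode())])


@dataclass
class SimConfig:
    """Conditions of the simulated study.

    Effect sizes are on the scale of the standardized true polygenic score:
    ``beta_direct`` is the per-SD direct effect of the child's own score on
    the (unit-variance) phenotype liability, ``beta_nurture`` the per-SD
    effect of the standardized midparent score.  With the default values the
    liability has variance ~1, so coefficients are directly comparable to
    standardized regression slopes.
    """

    n_families: int = 2000
    sibs_per_family: int = 2
    n_variants: int = 5000
    block_size: int = 10
    within_block_rho: float = 0.6
    allele_freq_range: tuple[float, float] = (0.1, 0.5)
    beta_direct: float = 0.2
    beta_nurture: float = 0.3
    var_shared_env: float = 0.15
    var_noise: float = 0.705
    n_subpops: int = 1
    freq_divergence: float = 0.0
    subpop_env_effect: float = 0.0
    mate_corr: float = 0.0
    disease_prevalence: Mapping[str, float] | float = field(
        default_factory=lambda: dict(_DEFAULT_PREVALENCE))
    med_flag_quantile: float = 0.9
    gwas_se: float = 0.01
    weight_sd: float = 0.05
    frac_ambiguous: float = 0.05
    frac_low_maf: float = 0.05
    frac_low_info: float = 0.05
    adhd_prevalence: float = 0.01
    female_fraction: float = 0.59
    n_pcs: int = 8
    seed: int = 2026

    def __post_init__(self) -> None:
        if self.n_families < 1 or self.sibs_per_family < 1:
            raise ValueError("n_families and sibs_per_family must be >= 1")
        if self.n_subpops not in (1, 2):
            raise ValueError("n_subpops > 2 is unsupported (must be 1 or 2)")
        if not (0.0 <= self.mate_corr < 1.0):
            raise ValueError("mate_corr must lie in [0, 1)")
        if not (0.0 <= self.within_block_rho < 1.0):
            raise ValueError("within_block_rho must lie in [0, 1)")
        lo, hi = self.allele_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("allele_freq_range must lie inside (0, 1)")
        for name in ("var_shared_env", "var_noise", "gwas_se", "weight_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if isinstance(self.disease_prevalence, (int, float)):
            self.disease_prevalence = {"disease": float(self.disease_prevalence)}
        for dis, prev in self.disease_prevalence.items():
            if not (0.0 < prev < 1.0):
                raise ValueError(f"prevalence of {dis!r} must lie in (0, 1)")

    @property
    def blocks(self) -> list[slice]:
        """LD blocks; the last block is truncated if block_size does not divide."""
        return [slice(b, min(b + self.block_size, self.n_variants))
                for b in range(0, self.n_variants, self.block_size)]

    def noise_for_unit_variance(self) -> float:
        """Residual variance making the phenotype liability have variance 1.

        Var(liability) = b_d^2 + b_n^2/2 + b_d*b_n + var_shared_env + var_noise
        under random mating with standardized scores.
        """
        explained = (self.beta_direct ** 2 + 0.5 * self.beta_nurture ** 2
                     + self.beta_direct * self.beta_nurture + self.var_shared_env)
        if explained >= 1.0:
            raise ValueError("structural variance already exceeds 1")
        return 1.0 - explained


@dataclass
class TruthLedger:
    """Ground truth of a simulated study, for parameter-recovery tests."""

    variants: pd.DataFrame          # id, chrom, pos, counted_allele, other_allele, base_freq, causal
    weights: np.ndarray             # true per-variant log-OR weights
    founder_ids: list[str]
    founder_pgs_raw: np.ndarray
    founder_subpop: np.ndarray
    founder_proxy: np.ndarray       # liability proxy used for assortative mating
    family_ids: list[str]
    family_subpop: np.ndarray
    sample_ids: list[str] | None = None       # offspring, set by simulate_phenotypes
    true_pgs: np.ndarray | None = None        # standardized over the offspring cohort
    midparent_pgs: np.ndarray | None = None
    family_env: np.ndarray | None = None      # per offspring (family draw broadcast)
    subpop: np.ndarray | None = None          # per offspring
    structural: np.ndarray | None = None      # b_d*S + b_n*Smid + F
    latents: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class SimStudy:
    """Everything one simulated study produces."""

    config: SimConfig
    founders: "GenotypeSet"
    offspring: "GenotypeSet"
    pedigree: pd.DataFrame
    sumstats: pd.DataFrame
    pheno: pd.DataFrame
    truth: TruthLedger


def _family_ids(config: SimConfig) -> list[str]:
    return [f"FAM{i:05d}" for i in range(config.n_families)]


def _draw_haplotypes(rng: np.random.Generator, config: SimConfig,
                     thresholds: np.ndarray, person_subpop: np.ndarray) -> np.ndarray:
    """Binary haplotypes via a thresholded AR(1) Gaussian latent within blocks.

    thresholds: (n_subpops, n_variants) normal quantiles of the allele freqs.
    Returns (n_persons, 2, n_variants) int8.
    """
    n = person_subpop.size
    rho = config.within_block_rho
    hap = np.empty((n, 2, config.n_variants), dtype=np.int8)
    t = thresholds[person_subpop]  # (n, n_variants)
    for blk in config.blocks:
        width = blk.stop - blk.start
        z = np.empty((n, 2, width))
        z[:, :, 0] = rng.standard_normal((n, 2))
        innov = rng.standard_normal((n, 2, width - 1)) if width > 1 else None
        for j in range(1, width):
            z[:, :, j] = rho * z[:, :, j - 1] + np.sqrt(1 - rho ** 2) * innov[:, :, j - 1]
        hap[:, :, blk] = (z < t[:, None, blk]).astype(np.int8)
    return hap


def _variant_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    m = config.n_variants
    ids = [f"rs{i + 1:06d}" for i in range(m)]
    pos = 1 + np.arange(m) * VARIANT_SPACING_BP
    n_amb = int(round(config.frac_ambiguous * m))
    amb_idx = rng.choice(m, size=n_amb, replace=False) if n_amb else np.array([], dtype=int)
    is_amb = np.zeros(m, dtype=bool)
    is_amb[amb_idx] = True
    pair_choice = rng.integers(0, 8, size=m)
    counted, other = [], []
    for i in range(m):
        a, b = (_AMBIGUOUS[pair_choice[i] % 4] if is_amb[i]
                else _UNAMBIGUOUS[pair_choice[i]])
        counted.append(a)
        other.append(b)
    return pd.DataFrame({
        "id": ids, "chrom": "1", "pos": pos,
        "counted_allele": counted, "other_allele": other,
    })


def simulate_founders(config: SimConfig):
    """Simulate two founder parents per family.

    Returns ``(founders, parent_pedigree, truth)`` where *founders* is a
    :class:`~sibscore.io_formats.GenotypeSet` carrying haplotypes, the
    pedigree holds the parents-only rows, and *truth* is a started
    :class:`TruthLedger` (weights, founder scores, subpopulation labels).

    Allele frequencies are drawn per variant from ``allele_freq_range``;
    with two subpopulations they are offset by ``freq_divergence/2`` in
    opposite directions (risk-allele-aligned for causal variants, random
    direction for null variants).  Under assortative mating, parent pairs
    are formed by rank-matching a phenotypic liability proxy, giving a
    spouse correlation of approximately ``mate_corr``.
    """
    from .io_formats import GenotypeSet  # local import to avoid a cycle

    cfg = config
    m = cfg.n_variants
    n_fam = cfg.n_families

    rng_freq = _rng(cfg.seed, "allele-freqs")
    rng_w = _rng(cfg.seed, "true-weights")
    rng_var = _rng(cfg.seed, "variant-table")
    rng_hap = _rng(cfg.seed, "founder-haplotypes")
    rng_mate = _rng(cfg.seed, "assortative-mating")

    variants = _variant_table(cfg, rng_var)
    base_freq = rng_freq.uniform(*cfg.allele_freq_range, size=m)

    causal = np.zeros(m, dtype=bool)
    causal[np.arange(0, m, cfg.block_size)] = True  # one causal variant per block
    weights = np.zeros(m)
    weights[causal] = rng_w.normal(0.0, cfg.weight_sd, size=int(causal.sum()))

    if cfg.n_subpops == 2:
        sign = np.where(rng_freq.random(m) < 0.5, -1.0, 1.0)
        nz = causal & (weights != 0)
        sign[nz] = np.sign(weights[nz])  # subpop 1 = higher mean genetic liability
        half = cfg.freq_divergence / 2.0
        freqs = np.clip(np.stack([base_freq - sign * half, base_freq + sign * half]),
                        0.01, 0.99)
    else:
        freqs = base_freq[None, :]

    family_ids = _family_ids(cfg)
    fam_subpop = np.arange(n_fam) % cfg.n_subpops
    person_subpop = np.concatenate([fam_subpop, fam_subpop])  # fathers then mothers

    thresholds = norm.ppf(freqs)
    hap = _draw_haplotypes(rng_hap, cfg, thresholds, person_subpop)
    dosage = hap.sum(axis=1).astype(float)

    pgs_raw = dosage @ weights
    sd = pgs_raw.std()
    pgs_std = (pgs_raw - pgs_raw.mean()) / sd if sd > 0 else np.zeros_like(pgs_raw)
    env_sd = np.sqrt(cfg.var_shared_env + cfg.var_noise)
    proxy = cfg.beta_direct * pgs_std + rng_mate.normal(0.0, env_sd, size=2 * n_fam)
    psd = proxy.std()
    if psd > 0:
        proxy = (proxy - proxy.mean()) / psd

    # Pair fathers (slots 0..n-1) with mothers (slots n..2n-1).  Rank-matching
    # on a noisy copy of the mother's proxy yields spouse corr ~ mate_corr.
    if cfg.mate_corr > 0:
        mother_perm = np.arange(n_fam)
        f_proxy = proxy[:n_fam]
        m_proxy = proxy[n_fam:]
        key = (cfg.mate_corr * m_proxy
               + np.sqrt(1 - cfg.mate_corr ** 2) * rng_mate.standard_normal(n_fam))
        for sp in range(cfg.n_subpops):
            members = np.flatnonzero(fam_subpop == sp)
            f_order = members[np.argsort(f_proxy[members], kind="stable")]
            m_order = members[np.argsort(key[members], kind="stable")]
            mother_perm[f_order] = m_order
        hap[n_fam:] = hap[n_fam + mother_perm]
        dosage[n_fam:] = dosage[n_fam + mother_perm]
        pgs_raw[n_fam:] = pgs_raw[n_fam + mother_perm]
        proxy[n_fam:] = proxy[n_fam + mother_perm]

    father_ids = [f + "_F" for f in family_ids]
    mother_ids = [f + "_M" for f in family_ids]
    founder_ids = father_ids + mother_ids

    founders = GenotypeSet(sample_ids=founder_ids, variants=variants,
                           dosage=dosage, haplotypes=hap)
    parent_ped = pd.DataFrame({
        "family_id": family_ids * 2,
        "individual_id": founder_ids,
        "father_id": "0", "mother_id": "0",
        "sex": [1] * n_fam + [2] * n_fam,
    })
    truth_variants = variants.copy()
    truth_variants["base_freq"] = base_freq
    truth_variants["causal"] = causal
    truth = TruthLedger(
        variants=truth_variants, weights=weights,
        founder_ids=founder_ids, founder_pgs_raw=pgs_raw,
        founder_subpop=person_subpop, founder_proxy=proxy,
        family_ids=family_ids, family_subpop=fam_subpop,
    )
    return founders, parent_ped, truth


def build_pedigree(config: SimConfig) -> pd.DataFrame:
    """Full pedigree: parent rows followed by ``sibs_per_family`` offspring rows."""
    family_ids = _family_ids(config)
    rng_sex = _rng(config.seed, "offspring-sex")
    rows = []
    for fam in family_ids:
        rows.append((fam, fam + "_F", "0", "0", 1))
        rows.append((fam, fam + "_M", "0", "0", 2))
    sexes = rng_sex.random((len(family_ids), config.sibs_per_family))
    for i, fam in enumerate(family_ids):
        for j in range(config.sibs_per_family):
            sex = 2 if sexes[i, j] < config.female_fraction else 1
            rows.append((fam, f"{fam}_S{j + 1}", fam + "_F", fam + "_M", sex))
    return pd.DataFrame(rows, columns=["family_id", "individual_id",
                                       "father_id", "mother_id", "sex"])


def transmit(parents, pedigree: pd.DataFrame, config: SimConfig):
    """Mendelian transmission: each offspring receives one uniformly chosen
    parental haplotype per LD block from each parent (no recombination within
    blocks); dosage is the allele sum in {0, 1, 2}."""
    from .io_formats import GenotypeSet

    if parents.haplotypes is None:
        raise ValueError("parent GenotypeSet must carry haplotypes")
    offspring = pedigree[(pedigree["father_id"] != "0") & (pedigree["mother_id"] != "0")]
    pos = {iid: i for i, iid in enumerate(parents.sample_ids)}
    fa_idx, mo_idx = [], []
    for _, row in offspring.iterrows():
        if row["father_id"] not in pos or row["mother_id"] not in pos:
            raise ValueError(
                f"missing parent genotypes for family {row['family_id']!r}")
        fa_idx.append(pos[row["father_id"]])
        mo_idx.append(pos[row["mother_id"]])
    fa_idx = np.asarray(fa_idx)
    mo_idx = np.asarray(mo_idx)

    n_off = len(offspring)
    blocks = config.blocks
    lens = np.array([b.stop - b.start for b in blocks])
    rng = _rng(config.seed, "transmission")
    pat_choice = np.repeat(rng.integers(0, 2, (n_off, len(blocks))), lens, axis=1)
    mat_choice = np.repeat(rng.integers(0, 2, (n_off, len(blocks))), lens, axis=1)

    pat = np.take_along_axis(parents.haplotypes[fa_idx],
                             pat_choice[:, None, :], axis=1)[:, 0, :]
    mat = np.take_along_axis(parents.haplotypes[mo_idx],
                             mat_choice[:, None, :], axis=1)[:, 0, :]
    hap = np.stack([pat, mat], axis=1)
    return GenotypeSet(sample_ids=list(offspring["individual_id"]),
                       variants=parents.variants.copy(),
                       dosage=hap.sum(axis=1).astype(float), haplotypes=hap)


def simulate_sumstats(truth: TruthLedger, config: SimConfig,
                      founders=None) -> pd.DataFrame:
    """GWAS summary statistics: true weight plus Normal(0, gwas_se^2) noise,
    Wald p-values, and QC-exercise fractions with low reported MAF or INFO.

    With ``gwas_se == 0`` the estimates equal the true weights and the
    p-value is 1 for null variants (and numerically zero otherwise).
    """
    if config.gwas_se < 0:
        raise ValueError("gwas_se must be >= 0")
    rng = _rng(config.seed, "sumstats")
    m = len(truth.weights)
    w = truth.weights
    if config.gwas_se > 0:
        beta = w + rng.normal(0.0, config.gwas_se, size=m)
        z = beta / config.gwas_se
        p = 2.0 * norm.sf(np.abs(z))
        p = np.clip(p, 1e-300, 1.0)
    else:
        beta = w.copy()
        p = np.where(w == 0.0, 1.0, 1e-300)

    if founders is not None:
        freq = founders.dosage.mean(axis=0) / 2.0
    else:
        freq = truth.variants["base_freq"].to_numpy()
    maf = np.minimum(freq, 1.0 - freq)
    maf = np.clip(maf, 1e-4, 0.5)
    info = np.ones(m)

    def _flag(frac: float) -> np.ndarray:
        k = int(round(frac * m))
        idx = rng.choice(m, size=k, replace=False) if k else np.array([], dtype=int)
        return idx

    maf_idx = _flag(config.frac_low_maf)
    maf[maf_idx] = rng.uniform(0.001, 0.009, size=len(maf_idx))
    info_idx = _flag(config.frac_low_info)
    info[info_idx] = rng.uniform(0.3, 0.79, size=len(info_idx))

    v = truth.variants
    return pd.DataFrame({
        "id": v["id"], "chrom": v["chrom"], "pos": v["pos"],
        "effect_allele": v["counted_allele"], "other_allele": v["other_allele"],
        "weight": beta, "se": np.full(m, config.gwas_se), "p": p,
        "maf": maf, "info": info,
    })


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def _founder_pcs(founders, offspring, k: int) -> np.ndarray:
    """PCA fitted on mean-centered founder dosages, projected onto offspring,
    each component z-scored over the offspring."""
    if k == 0:
        return np.empty((len(offspring.sample_ids), 0))
    X = founders.dosage - founders.dosage.mean(axis=0)
    k = min(k, min(X.shape) - 1)
    # right singular vectors of the founder matrix
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    proj = (offspring.dosage - founders.dosage.mean(axis=0)) @ vt[:k].T
    sd = proj.std(axis=0)
    sd[sd == 0] = 1.0
    return (proj - proj.mean(axis=0)) / sd


def simulate_phenotypes(genotypes, pedigree: pd.DataFrame, truth: TruthLedger,
                        config: SimConfig) -> pd.DataFrame:
    """Phenotypes for the offspring generation.

    Each biomarker's liability is ``sign * (b_d*S + b_n*Smid) + F + e`` with a
    family-level environment F ~ N(0, var_shared_env) (plus a subpopulation
    offset when configured) and an independent residual per biomarker.
    Binary diseases are thresholded at the empirical (1 - prevalence)
    quantile of their liability.  Medication flags mark the upper
    ``med_flag_quantile`` tail of LDL, systolic BP and glucose.
    """
    cfg = config
    ids = genotypes.sample_ids
    n = len(ids)
    rng_env = _rng(cfg.seed, "family-env")
    rng_bio = _rng(cfg.seed, "biomarkers")
    rng_dis = _rng(cfg.seed, "diseases")
    rng_cov = _rng(cfg.seed, "covariates")

    raw = genotypes.dosage @ truth.weights
    mu, sd = raw.mean(), raw.std()
    S = (raw - mu) / sd if sd > 0 else np.zeros(n)

    ped = pedigree.set_index("individual_id")
    fam = ped.loc[ids, "family_id"].to_numpy()
    father = ped.loc[ids, "father_id"].to_numpy()
    mother = ped.loc[ids, "mother_id"].to_numpy()
    founder_raw = dict(zip(truth.founder_ids, truth.founder_pgs_raw))
    if sd > 0:
        s_f = (np.array([founder_raw[f] for f in father]) - mu) / sd
        s_m = (np.array([founder_raw[m] for m in mother]) - mu) / sd
        midparent = (s_f + s_m) / 2.0
    else:
        midparent = np.zeros(n)

    fam_index = {f: i for i, f in enumerate(truth.family_ids)}
    fam_pos = np.array([fam_index[f] for f in fam])
    env_draw = rng_env.normal(0.0, np.sqrt(cfg.var_shared_env), size=len(truth.family_ids))
    if cfg.n_subpops == 2 and cfg.subpop_env_effect != 0.0:
        env_draw = env_draw + cfg.subpop_env_effect * (truth.family_subpop == 1)
    F = env_draw[fam_pos]

    genetic = cfg.beta_direct * S + cfg.beta_nurture * midparent
    structural = genetic + F

    pheno = pd.DataFrame({"individual_id": ids, "family_id": fam})
    latents: dict[str, np.ndarray] = {}
    noise_sd = np.sqrt(cfg.var_noise)
    for name, mean, sdev, log_scale, sign in BIOMARKER_PANEL:
        lat = sign * genetic + F + rng_bio.normal(0.0, noise_sd, size=n)
        latents[name] = lat
        lsd = lat.std()
        z = (lat - lat.mean()) / lsd if lsd > 0 else np.zeros(n)
        if log_scale:
            lmu, lsig = _lognormal_params(mean, sdev)
            pheno[name] = np.exp(lmu + lsig * z)
        else:
            # floor at 1% of the mean: lab values cannot be negative
            pheno[name] = np.maximum(mean + sdev * z, 0.01 * mean)

    for dis, prev in cfg.disease_prevalence.items():
        if prev * n < 20:
            warnings.warn(
                f"expected case count for {dis!r} is below 20 "
                f"(prevalence {prev}, n {n})", stacklevel=2)
        lat = structural + rng_dis.normal(0.0, noise_sd, size=n)
        latents[dis] = lat
        cut = np.quantile(lat, 1.0 - prev)
        pheno[dis] = (lat > cut).astype(int)

    q = cfg.med_flag_quantile
    pheno["lipid_lowering_med"] = (pheno["ldl"] >= pheno["ldl"].quantile(q)).astype(int)
    pheno["bp_lowering_med"] = (
        pheno["systolic_bp"] >= pheno["systolic_bp"].quantile(q)).astype(int)
    pheno["diabetes_med"] = (pheno["glucose"] >= pheno["glucose"].quantile(q)).astype(int)

    adhd_lat = S + rng_cov.normal(0.0, 2.0, size=n)
    pheno["adhd_self_report"] = (
        adhd_lat > np.quantile(adhd_lat, 1.0 - cfg.adhd_prevalence)).astype(int)

    pheno["age"] = np.clip(rng_cov.normal(44.36, 13.60, size=n), 18.0, 90.0)
    pheno["sex"] = (ped.loc[ids, "sex"].to_numpy() == 2).astype(int)  # 1 = female
    cats = list(EDUCATION_CATEGORIES)
    probs = np.array(list(EDUCATION_CATEGORIES.values()))
    pheno["education_category"] = rng_cov.choice(cats, size=n, p=probs / probs.sum())
    pheno["chip"] = rng_cov.choice(["GSA", "CytoSNP"], size=n, p=[0.715, 0.285])

    # genotype PCs: fitted on founders, projected onto the analysis samples
    founders_gs = getattr(truth, "_founders", None)
    if founders_gs is not None:
        pcs = _founder_pcs(founders_gs, genotypes, cfg.n_pcs)
    else:
        X = genotypes.dosage - genotypes.dosage.mean(axis=0)
        k = min(cfg.n_pcs, min(X.shape) - 1) if cfg.n_pcs else 0
        if k:
            u, s, _ = np.linalg.svd(X, full_matrices=False)
            pcs = u[:, :k] * s[:k]
            psd = pcs.std(axis=0)
            psd[psd == 0] = 1.0
            pcs = (pcs - pcs.mean(axis=0)) / psd
        else:
            pcs = np.empty((n, 0))
    for j in range(pcs.shape[1]):
        pheno[f"PC{j + 1}"] = pcs[:, j]

    truth.sample_ids = list(ids)
    truth.true_pgs = S
    truth.midparent_pgs = midparent
    truth.family_env = F
    truth.subpop = truth.family_subpop[fam_pos]
    truth.structural = structural
    truth.latents = latents
    return pheno


def simulate_study(config: SimConfig) -> SimStudy:
    """Run the whole generator: founders -> pedigree -> transmission ->
    summary statistics -> phenotypes."""
    founders, _, truth = simulate_founders(config)
    pedigree = build_pedigree(config)
    offspring = transmit(founders, pedigree, config)
    sumstats = simulate_sumstats(truth, config, founders=founders)
    truth._founders = founders  # used for founder-based PC projection
    pheno = simulate_phenotypes(offspring, pedigree, truth, config)
    return SimStudy(config=config, founders=founders, offspring=offspring,
                    pedigree=pedigree, sumstats=sumstats, pheno=pheno, truth=truth)
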