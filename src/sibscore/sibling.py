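"""Within-sibling fixed-effects analysis of direct genetic effects.

Full siblings share both parents, so differences in their polygenic scores
arise only from Mendelian segregation and are independent of everything
constant within the family: parental genotype effects (genetic nurture),
shared environment, population stratification and assortative mating.
Comparing the within-sibship slope with the population (between-sibling)
slope therefore separates the direct genetic effect from familial
confounding.

Continuous outcomes use within-sibship demeaning (family fixed effects);
binary outcomes use conditional logistic regression, conditioning on the
number of cases per sibship via the recursive denominator algorithm.  The
formal between-versus-within comparison is a Wald test of coefficient
equality in a joint model carrying the sibship-mean and deviation
components of the score.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .assoc import ModelSpec, build_design, fit_glm, sandwich_se

logger = logging.getLogger(__name__)

__all__ = [
    "Sibship", "WithinFit", "SibComparison",
    "build_sibships", "decompose_pgs", "fit_within_linear",
    "fit_within_logistic", "compare_between_within", "attenuation_pct",
]


@dataclass
class Sibship:
    """Full siblings (same non-missing father and mother) with data."""

    family_id: str
    member_ids: list[str]

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass
class WithinFit:
    """A within-sibship (fixed-effects or conditional-logistic) estimate."""

    estimate: float
    se: float
    params: pd.Series
    cov: np.ndarray
    n: int
    n_sibships: int
    n_discordant: int | None = None
    nonestimable: bool = False
    dropped: list[str] | None = None


@dataclass
class SibComparison:
    """Between- vs within-sibling coefficients for one outcome."""

    outcome: str
    link: str
    n: int
    n_sibships: int
    n_discordant: int | None
    b_between: float
    se_between: float
    b_within: float
    se_within: float
    pct_change: float
    p_compare: float          # Wald test in the joint decomposition model
    z_compare: float
    p_compare_naive: float    # z from the two separate fits, for reference
    delta_r2_between: float | None = None


def build_sibships(pedigree: pd.DataFrame, sample_ids,
                   min_size: int = 2) -> tuple[list[Sibship], dict[str, int]]:
    """Group genotyped/phenotyped individuals into full sibships.

    Individuals sharing the same non-missing father AND mother form a
    sibship; groups smaller than ``min_size`` (only children) are counted
    but not returned.
    """
    available = set(sample_ids)
    ped = pedigree[pedigree["individual_id"].isin(available)]
    both = ped[(ped["father_id"].astype(str) != "0")
               & (ped["mother_id"].astype(str) != "0")
               & ped["father_id"].notna() & ped["mother_id"].notna()]
    sibships: list[Sibship] = []
    n_only = 0
    for (fa, mo), grp in both.groupby(["father_id", "mother_id"], sort=True):
        if len(grp) >= min_size:
            fam = str(grp["family_id"].iloc[0])
            sibships.append(Sibship(family_id=fam,
                                    member_ids=list(grp["individual_id"])))
        else:
            n_only += len(grp)
    counts = {
        "n_individuals": int(sum(s.size for s in sibships)),
        "n_sibships": len(sibships),
        "n_singletons": n_only,
    }
    if not sibships:
        warnings.warn("no full sibships of size >= 2 found", stacklevel=2)
    return sibships, counts


def decompose_pgs(values: pd.Series, sibships: list[Sibship]) -> pd.DataFrame:
    """Split each member's score into the sibship mean and the deviation
    from it.  Deviations sum to zero within every sibship by construction."""
    rows = []
    for sib in sibships:
        v = values.loc[sib.member_ids].to_numpy(dtype=float)
        mean = v.mean()
        for iid, val in zip(sib.member_ids, v):
            rows.append((iid, sib.family_id, mean, val - mean))
    return pd.DataFrame(rows, columns=["individual_id", "family_id",
                                       "sib_mean", "deviation"]
                        ).set_index("individual_id")


def _sibship_frame(data: pd.DataFrame, sibships: list[Sibship],
                   columns: list[str]) -> pd.DataFrame:
    """Rows for sibship members with complete data, tagged by sibship.

    Sibships reduced below two complete members are dropped."""
    df = data.set_index("individual_id") if "individual_id" in data.columns else data
    sib_of = {m: i for i, sib in enumerate(sibships) for m in sib.member_ids}
    fam_of = {i: sib.family_id for i, sib in enumerate(sibships)}
    sub = df[df.index.isin(sib_of)]
    cols = [c for c in dict.fromkeys(columns) if c in sub.columns]
    sub = sub[cols].dropna().copy()
    sub["sibship_id"] = sub.index.map(sib_of)
    sub["family_id"] = sub["sibship_id"].map(fam_of)
    sizes = sub.groupby("sibship_id")["sibship_id"].transform("size")
    sub = sub[sizes >= 2]
    if sub.empty:
        raise ValueError("no sibship has >= 2 members with complete data")
    return sub.sort_values("sibship_id")


def fit_within_linear(data: pd.DataFrame, sibships: list[Sibship],
                      outcome: str, exposure: str = "PGS",
                      covariates: list[str] | None = None) -> WithinFit:
    """Family fixed effects for a continuous outcome.

    Outcome and regressors are demeaned within each sibship and fit by
    least squares; the SE is a sibship-clustered sandwich whose small-sample
    correction counts the absorbed family means as estimated parameters.
    Covariates constant within every sibship are absorbed and dropped.
    """
    covariates = covariates or []
    cols = [outcome, exposure] + list(covariates)
    df = _sibship_frame(data, sibships, cols)
    grp = df.groupby("sibship_id")
    numeric = [c for c in cols if np.issubdtype(df[c].dtype, np.number)]
    non_numeric = [c for c in cols if c not in numeric]
    if non_numeric:
        logger.info("fit_within_linear: dropping non-numeric covariate(s) %s "
                    "(family-constant factors are absorbed)", non_numeric)
    demeaned = df[numeric] - grp[numeric].transform("mean")
    dropped = [c for c in numeric if c not in (outcome,)
               and demeaned[c].abs().max() < 1e-12]
    if dropped:
        logger.info("fit_within_linear: absorbed family-constant column(s) %s",
                    dropped)
    keep = [c for c in numeric if c != outcome and c not in dropped]
    X = demeaned[keep]
    y = demeaned[outcome].to_numpy()
    fit = fit_glm(y, X, "identity")
    n_sib = df["sibship_id"].nunique()
    cov, se = sandwich_se(fit, df["sibship_id"].to_numpy(), extra_dof=n_sib)
    return WithinFit(estimate=float(fit.params[exposure]),
                     se=float(se[exposure]), params=fit.params, cov=cov,
                     n=len(df), n_sibships=n_sib,
                     dropped=dropped + non_numeric)


# ---------------------------------------------------------------------------
# conditional logistic regression

def _clogit_stratum_parts(eta: np.ndarray, X: np.ndarray, d: int
                          ) -> tuple[float, np.ndarray]:
    """log denominator and its gradient for one stratum.

    The denominator sums exp(score) over all subsets of size d; B[r] and
    G[r] accumulate the subset sums and their gradients by the standard
    recursion over members.
    """
    m, k = X.shape
    shift = eta.max()
    e = np.exp(eta - shift)
    B = np.zeros(d + 1)
    Gd = np.zeros((d + 1, k))
    B[0] = 1.0
    for j in range(m):
        top = min(d, j + 1)
        for r in range(top, 0, -1):
            Gd[r] = Gd[r] + e[j] * (Gd[r - 1] + B[r - 1] * X[j])
            B[r] = B[r] + e[j] * B[r - 1]
    return float(np.log(B[d]) + d * shift), Gd[d] / B[d]


def _clogit_negloglik_grad(beta: np.ndarray, strata) -> tuple[float, np.ndarray]:
    nll = 0.0
    grad = np.zeros_like(beta)
    for X, y in strata:
        eta = X @ beta
        d = int(y.sum())
        log_denom, mean_x = _clogit_stratum_parts(eta, X, d)
        nll -= float(eta[y == 1].sum()) - log_denom
        grad -= X[y == 1].sum(axis=0) - mean_x
    return nll, grad


def _clogit_hessian(beta: np.ndarray, strata) -> np.ndarray:
    """Observed information by central differences of the analytic gradient."""
    k = beta.size
    H = np.zeros((k, k))
    h = 1e-5
    for j in range(k):
        bp, bm = beta.copy(), beta.copy()
        bp[j] += h
        bm[j] -= h
        _, gp = _clogit_negloglik_grad(bp, strata)
        _, gm = _clogit_negloglik_grad(bm, strata)
        H[:, j] = (gp - gm) / (2 * h)
    return (H + H.T) / 2


def fit_within_logistic(data: pd.DataFrame, sibships: list[Sibship],
                        outcome: str, exposure: str = "PGS",
                        covariates: list[str] | None = None) -> WithinFit:
    """Conditional logistic regression with sibships as strata.

    Conditioning on the number of cases per sibship eliminates the family
    intercepts; outcome-concordant sibships contribute nothing to the
    likelihood and are only counted.  Covariates constant within every
    stratum are dropped (they are absorbed by the conditioning).
    """
    covariates = covariates or []
    cols = [outcome, exposure] + list(covariates)
    df = _sibship_frame(data, sibships, cols)
    numeric = [c for c in cols if c != outcome
               and np.issubdtype(df[c].dtype, np.number)]
    grp = df.groupby("sibship_id")
    centered = df[numeric] - grp[numeric].transform("mean")
    varying = [c for c in numeric if centered[c].abs().max() > 1e-12]
    dropped = [c for c in cols if c != outcome and c not in varying]
    if dropped:
        logger.info("fit_within_logistic: absorbed stratum-constant "
                    "column(s) %s", dropped)

    strata = []
    n_concordant = 0
    n_used = 0
    for _, sub in grp:
        y = sub[outcome].to_numpy(dtype=float)
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise ValueError(f"outcome {outcome!r} is not binary")
        if y.min() == y.max():
            n_concordant += 1
            continue
        # centering within the stratum is likelihood-invariant but stabler
        X = (sub[varying] - sub[varying].mean()).to_numpy(dtype=float)
        strata.append((X, y))
        n_used += len(sub)
    if not strata:
        warnings.warn("no outcome-discordant sibships: within-sibling "
                      "logistic effect is non-estimable", stacklevel=2)
        k = len(varying)
        return WithinFit(estimate=np.nan, se=np.nan,
                         params=pd.Series(np.full(k, np.nan), index=varying),
                         cov=np.full((k, k), np.nan), n=0,
                         n_sibships=df["sibship_id"].nunique(),
                         n_discordant=0, nonestimable=True, dropped=dropped)

    k = len(varying)
    res = optimize.minimize(
        _clogit_negloglik_grad, np.zeros(k), args=(strata,), jac=True,
        method="BFGS", options={"gtol": 1e-10, "maxiter": 500})
    beta = res.x
    _, grad = _clogit_negloglik_grad(beta, strata)
    if np.linalg.norm(grad) > 1e-8:
        # polish with Newton steps on the analytic gradient
        for _ in range(25):
            H = _clogit_hessian(beta, strata)
            try:
                beta = beta - np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                break
            _, grad = _clogit_negloglik_grad(beta, strata)
            if np.linalg.norm(grad) < 1e-10:
                break
    nonestimable = bool(np.abs(beta).max() > 15)
    H = _clogit_hessian(beta, strata)
    cov = np.linalg.pinv(H)
    params = pd.Series(beta, index=varying)
    se = np.sqrt(np.diag(cov))
    return WithinFit(estimate=float(params[exposure]),
                     se=float(se[varying.index(exposure)]),
                     params=params, cov=cov, n=n_used,
                     n_sibships=df["sibship_id"].nunique(),
                     n_discordant=len(strata), nonestimable=nonestimable,
                     dropped=dropped)


def attenuation_pct(b_between: float, b_within: float) -> float:
    """Percent change 100 (b_within - b_between) / b_between, on the
    log-OR/beta scale.  Undefined (NaN) when b_between is zero."""
    if b_between == 0 or np.isnan(b_between):
        return np.nan
    return 100.0 * (b_within - b_between) / b_between


def compare_between_within(data: pd.DataFrame, sibships: list[Sibship],
                           outcome: str, link: str, exposure: str = "PGS",
                           covariates: list[str] | None = None,
                           cluster: str = "family_id") -> SibComparison:
    """Between-sibling reference fit, within-sibling fit, and the formal
    coefficient-equality test.

    The between estimate refits the population model on the sibling
    subsample.  The comparison p-value is a Wald test of equality of the
    sibship-mean and deviation coefficients in a joint model with
    family-clustered sandwich SEs; the z-statistic from the two separate
    fits is reported alongside for reference.
    """
    covariates = covariates or []
    cols = [outcome, exposure] + list(covariates)
    sib_df = _sibship_frame(data, sibships, cols + ([cluster] if cluster in
                                                    data.columns else []))
    sib_df = sib_df.reset_index().rename(columns={"index": "individual_id"})
    # z-score the exposure once over the sibling analysis sample so the
    # between, within and joint fits share a scale
    e = sib_df[exposure].to_numpy(dtype=float)
    sd = e.std()
    sib_df[exposure] = (e - e.mean()) / sd if sd > 0 else e - e.mean()
    if link == "identity":
        yv = sib_df[outcome].to_numpy(dtype=float)
        ysd = yv.std()
        sib_df[outcome] = (yv - yv.mean()) / ysd if ysd > 0 else yv - yv.mean()

    spec = ModelSpec(outcome=outcome, link=link, covariates=list(covariates),
                     exposure=exposure, cluster="family_id",
                     chip_pc_interactions=True)
    y, X, clusters, used = build_design(sib_df, spec)
    # build_design re-z-scores the exposure; harmless (already z-scored)
    fit_b = fit_glm(y, X, link)
    _, se_b = sandwich_se(fit_b, clusters)
    b_between = float(fit_b.params[exposure])
    se_between = float(se_b[exposure])

    n_discordant = None
    if link == "identity":
        fit_w = fit_within_linear(sib_df, sibships, outcome, exposure,
                                  covariates)
    else:
        fit_w = fit_within_logistic(sib_df, sibships, outcome, exposure,
                                    covariates)
        n_discordant = fit_w.n_discordant

    # joint decomposition model on the same rows as the between fit
    joint = sib_df.loc[used.index].copy()
    joint["sib_mean"] = joint.groupby("sibship_id")[exposure].transform("mean")
    joint["deviation"] = joint[exposure] - joint["sib_mean"]
    jspec = ModelSpec(outcome=outcome, link=link,
                      covariates=list(covariates) + ["sib_mean"],
                      exposure="deviation", cluster="family_id",
                      chip_pc_interactions=True)
    yj, Xj, cj, _ = build_design(joint.reset_index(), jspec)
    # keep the deviation on its natural scale: replace the z-scored column
    Xj = Xj.copy()
    Xj["deviation"] = joint["deviation"].to_numpy(dtype=float)
    fit_j = fit_glm(yj, Xj, link)
    cov_j, _ = sandwich_se(fit_j, cj)
    names = list(fit_j.params.index)
    im, id_ = names.index("sib_mean"), names.index("deviation")
    diff = float(fit_j.params.iloc[im] - fit_j.params.iloc[id_])
    var = float(cov_j[im, im] + cov_j[id_, id_] - 2 * cov_j[im, id_])
    z = diff / np.sqrt(var) if var > 0 else np.nan
    p_compare = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else np.nan

    denom = np.sqrt(se_between ** 2 + fit_w.se ** 2)
    z_naive = (b_between - fit_w.estimate) / denom if denom > 0 else np.nan
    p_naive = float(2 * stats.norm.sf(abs(z_naive))) if np.isfinite(z_naive) else np.nan

    return SibComparison(
        outcome=outcome, link=link, n=len(used), n_sibships=fit_w.n_sibships,
        n_discordant=n_discordant,
        b_between=b_between, se_between=se_between,
        b_within=fit_w.estimate, se_within=fit_w.se,
        pct_change=attenuation_pct(b_between, fit_w.estimate),
        p_compare=p_compare, z_compare=float(z) if np.isfinite(z) else np.nan,
        p_compare_naive=p_naive)
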