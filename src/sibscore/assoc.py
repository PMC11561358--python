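"""Population-level association models.

Working-independence GLMs (identity or logit link) with family-clustered
sandwich standard errors reproduce the GEE-style estimand: point estimates
from an ordinary GLM, variance from B^-1 M B^-1 where B is the information
(bread) and M sums outer products of within-cluster score sums, with a
G/(G-1) finite-cluster correction.  Variance explained by the exposure is
the Nagelkerke pseudo-R^2 difference (logit) or plain R^2 difference
(identity) between the full and the covariates-only model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec", "FitResult", "AssocResult",
    "fit_glm", "sandwich_se", "nagelkerke_delta_r2",
    "run_association", "run_interaction", "run_stratified", "bh_fdr",
    "build_design", "results_to_frame",
]

_SEPARATION_BOUND = 15.0
_MIN_SAMPLE = 50


@dataclass
class ModelSpec:
    """One association model: outcome, link, covariates, clustering."""

    outcome: str
    link: str  # "logit" or "identity"
    covariates: list[str] = field(default_factory=lambda: [
        "age", "sex", "chip"] + [f"PC{i}" for i in range(1, 9)])
    exposure: str = "PGS"
    cluster: str = "family_id"
    interaction: str | None = None
    sample_filter: str | None = None  # pandas query string
    chip_pc_interactions: bool = True

    def __post_init__(self) -> None:
        if self.link not in ("logit", "identity"):
            raise ValueError(f"unknown link {self.link!r}")
        if self.exposure in self.covariates:
            raise ValueError("exposure must not also appear among covariates")


@dataclass
class FitResult:
    """A fitted GLM with everything the sandwich and R^2 steps need."""

    params: pd.Series
    cov_naive: np.ndarray
    llf: float
    fitted: np.ndarray
    link: str
    X: pd.DataFrame
    y: np.ndarray
    converged: bool
    nonestimable: bool
    dropped: list[str]

    @property
    def n(self) -> int:
        return len(self.y)


@dataclass
class AssocResult:
    """Estimate for the exposure term with clustered inference."""

    outcome: str
    model: str
    link: str
    n: int
    n_clusters: int
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    delta_r2: float
    odds_ratio: float | None = None
    or_ci_low: float | None = None
    or_ci_high: float | None = None
    nonestimable: bool = False
    p_fdr: float | None = None


def _drop_collinear(X: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """QR with column pivoting; columns beyond the numerical rank are dropped."""
    A = X.to_numpy(dtype=float)
    if A.shape[1] == 0:
        return X, []
    _, R, piv = linalg.qr(A, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(A.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    rank = int((diag > tol).sum())
    keep = sorted(piv[:rank])
    dropped = [X.columns[j] for j in piv[rank:]]
    if dropped:
        warnings.warn(f"dropping collinear column(s): {dropped}", stacklevel=3)
    return X.iloc[:, keep], dropped


def fit_glm(y: np.ndarray, X: pd.DataFrame, link: str) -> FitResult:
    """Least squares (identity) or IRLS to score-norm < 1e-8 (logit).

    A logit coefficient diverging beyond 15 flags the fit as non-estimable
    (perfect separation).
    """
    y = np.asarray(y, dtype=float)
    X, dropped = _drop_collinear(X)
    A = X.to_numpy(dtype=float)
    n, k = A.shape
    if link == "identity":
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        fitted = A @ beta
        rss = float(((y - fitted) ** 2).sum())
        sigma2 = rss / n
        llf = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0) if sigma2 > 0 else np.inf
        cov = sigma2 * np.linalg.pinv(A.T @ A) * n / max(n - k, 1)
        return FitResult(pd.Series(beta, index=X.columns), cov, llf, fitted,
                         link, X, y, True, False, dropped)
    if link != "logit":
        raise ValueError(f"unknown link {link!r}")

    beta = np.zeros(k)
    converged = False
    nonestimable = False
    XtX_w = None
    for _ in range(100):
        eta = A @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        p = np.clip(p, 1e-12, 1 - 1e-12)
        grad = A.T @ (y - p)
        w = p * (1 - p)
        XtX_w = (A * w[:, None]).T @ A
        if np.linalg.norm(grad) < 1e-8:
            converged = True
            break
        try:
            step = np.linalg.solve(XtX_w, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(XtX_w, grad, rcond=None)[0]
        # dampen huge steps for stability
        nrm = np.abs(step).max()
        if nrm > 10:
            step *= 10 / nrm
        beta = beta + step
        if np.abs(beta).max() > _SEPARATION_BOUND:
            nonestimable = True
            break
    eta = A @ beta
    p = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
    llf = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
    w = p * (1 - p)
    XtX_w = (A * w[:, None]).T @ A
    cov = np.linalg.pinv(XtX_w)
    if nonestimable:
        warnings.warn("possible perfect separation: coefficient exceeded "
                      f"{_SEPARATION_BOUND} on the logit scale", stacklevel=2)
    return FitResult(pd.Series(beta, index=X.columns), cov, llf, p, link,
                     X, y, converged, nonestimable, dropped)


def sandwich_se(fit: FitResult, groups: np.ndarray,
                extra_dof: int = 0) -> tuple[np.ndarray, pd.Series]:
    """Cluster-robust covariance B^-1 M B^-1 with a G/(G-1) correction.

    The scores are x_i (y_i - mu_i), summed within clusters; the bread is
    X'WX (W = mu(1-mu) for logit, identity weights otherwise).  ``extra_dof``
    adds absorbed parameters (e.g. family means in fixed-effects fits) to
    the small-sample correction.
    """
    groups = np.asarray(groups)
    uniq, inverse = np.unique(groups, return_inverse=True)
    G = len(uniq)
    if G < 2:
        raise ValueError("sandwich_se requires at least 2 clusters")
    A = fit.X.to_numpy(dtype=float)
    resid = fit.y - fit.fitted
    U = A * resid[:, None]
    # within-cluster score sums
    k = A.shape[1]
    sums = np.zeros((G, k))
    np.add.at(sums, inverse, U)
    meat = sums.T @ sums
    if fit.link == "logit":
        w = fit.fitted * (1 - fit.fitted)
    else:
        w = np.ones(fit.n)
    bread_inv = np.linalg.pinv((A * w[:, None]).T @ A)
    c = G / (G - 1)
    if extra_dof:
        n = fit.n
        denom = max(n - k - extra_dof, 1)
        c *= (n - 1) / denom
    cov = c * bread_inv @ meat @ bread_inv
    se = pd.Series(np.sqrt(np.diag(cov)), index=fit.params.index)
    return cov, se


def nagelkerke_delta_r2(fit_full: FitResult, fit_null: FitResult,
                        fit_intercept: FitResult | None = None) -> float:
    """Variance explained by the exposure.

    Logit: Nagelkerke R^2 = [1 - exp(2(ll0 - ll)/n)] / [1 - exp(2 ll0/n)]
    with ll0 the intercept-only log-likelihood, differenced between the full
    and the covariates-only model.  Identity: plain R^2 difference.
    """
    if not set(fit_null.params.index) <= set(fit_full.params.index):
        raise ValueError("null model is not nested in the full model")
    n = fit_full.n
    if fit_null.n != n:
        raise ValueError("full and null fits use different samples")
    if fit_full.link == "identity":
        y = fit_full.y
        tss = float(((y - y.mean()) ** 2).sum())
        r2f = 1.0 - float(((y - fit_full.fitted) ** 2).sum()) / tss
        r2n = 1.0 - float(((y - fit_null.fitted) ** 2).sum()) / tss
        return r2f - r2n
    if fit_intercept is None:
        raise ValueError("logit Nagelkerke R^2 needs the intercept-only fit")
    ll0 = fit_intercept.llf

    def _nagelkerke(ll: float) -> float:
        cox_snell = 1.0 - np.exp(2.0 * (ll0 - ll) / n)
        ceiling = 1.0 - np.exp(2.0 * ll0 / n)
        return cox_snell / ceiling

    return _nagelkerke(fit_full.llf) - _nagelkerke(fit_null.llf)


def build_design(data: pd.DataFrame, spec: ModelSpec,
                 include_exposure: bool = True) -> tuple[np.ndarray, pd.DataFrame,
                                                          np.ndarray, pd.DataFrame]:
    """Assemble (y, X, clusters, used-rows frame) for one model.

    Categorical covariates (chip, education level, ...) become dummy
    columns; chip x PC interaction columns are added when requested and a
    chip column is among the covariates.  Complete-case on all used columns;
    the exposure is z-scored within the analysis sample, as is a continuous
    outcome.
    """
    df = data
    if spec.sample_filter:
        df = df.query(spec.sample_filter)
    used = [spec.outcome, spec.exposure, spec.cluster] + list(spec.covariates)
    if spec.interaction:
        used.append(spec.interaction)
    used = list(dict.fromkeys(u for u in used if u in df.columns))
    missing = [u for u in [spec.outcome, spec.exposure, spec.cluster]
               if u not in df.columns]
    if missing:
        raise ValueError(f"data is missing required column(s) {missing}")
    df = df[used].dropna()
    n = len(df)
    if n < _MIN_SAMPLE:
        raise ValueError(
            f"only {n} complete cases for outcome {spec.outcome!r}; "
            f"refusing to fit with n < {_MIN_SAMPLE}")

    y = df[spec.outcome].to_numpy(dtype=float)
    if spec.link == "logit":
        vals = set(np.unique(y))
        if not vals <= {0.0, 1.0}:
            raise ValueError(f"logit outcome {spec.outcome!r} is not binary")
    else:
        sd = y.std()
        y = (y - y.mean()) / sd if sd > 0 else y - y.mean()

    X = pd.DataFrame({"const": np.ones(n)}, index=df.index)
    if include_exposure:
        e = df[spec.exposure].to_numpy(dtype=float)
        sd = e.std()
        X[spec.exposure] = (e - e.mean()) / sd if sd > 0 else e - e.mean()
    dummy_sources = {}
    for cov in spec.covariates:
        if cov not in df.columns:
            continue
        col = df[cov]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True, dtype=float)
            dummy_sources[cov] = list(dummies.columns)
            X = pd.concat([X, dummies], axis=1)
        else:
            X[cov] = col.to_numpy(dtype=float)
    if spec.chip_pc_interactions and "chip" in dummy_sources:
        pcs = [c for c in spec.covariates if c.startswith("PC") and c in X.columns]
        for chip_col in dummy_sources["chip"]:
            for pc in pcs:
                X[f"{chip_col}:{pc}"] = X[chip_col] * X[pc]
    if spec.interaction:
        mod = df[spec.interaction]
        if mod.dtype == object:
            raise ValueError("interaction moderator must be numeric or binary")
        m = mod.to_numpy(dtype=float)
        if np.ptp(m) == 0:
            raise ValueError(f"moderator {spec.interaction!r} is constant")
        if spec.interaction not in X.columns:
            X[spec.interaction] = m
        X[f"{spec.exposure}:{spec.interaction}"] = X[spec.exposure].to_numpy() * m
    clusters = df[spec.cluster].to_numpy()
    return y, X, clusters, df


def run_association(data: pd.DataFrame, spec: ModelSpec,
                    model_label: str = "main") -> AssocResult:
    """Full pipeline for one outcome: GLM + clustered sandwich + Delta-R^2.

    Logit estimates are reported as log-OR with the OR and its Wald 95% CI
    alongside; identity estimates are standardized betas (outcome and
    exposure z-scored).
    """
    y, X, clusters, _ = build_design(data, spec)
    fit_full = fit_glm(y, X, spec.link)
    X_null = X.drop(columns=[c for c in X.columns
                             if c == spec.exposure or c.startswith(f"{spec.exposure}:")])
    fit_null = fit_glm(y, X_null, spec.link)
    if spec.link == "logit":
        fit_icept = fit_glm(y, X[["const"]], spec.link)
        delta_r2 = nagelkerke_delta_r2(fit_full, fit_null, fit_icept)
    else:
        delta_r2 = nagelkerke_delta_r2(fit_full, fit_null)
    _, se = sandwich_se(fit_full, clusters)
    est = float(fit_full.params[spec.exposure])
    s = float(se[spec.exposure])
    ci = (est - 1.96 * s, est + 1.96 * s)
    p = float(2 * stats.norm.sf(abs(est / s))) if s > 0 else np.nan
    result = AssocResult(
        outcome=spec.outcome, model=model_label, link=spec.link,
        n=fit_full.n, n_clusters=len(np.unique(clusters)),
        estimate=est, se=s, ci_low=ci[0], ci_high=ci[1], p=p,
        delta_r2=float(delta_r2), nonestimable=fit_full.nonestimable)
    if spec.link == "logit":
        result.odds_ratio = float(np.exp(est))
        result.or_ci_low = float(np.exp(ci[0]))
        result.or_ci_high = float(np.exp(ci[1]))
    return result


def run_interaction(data: pd.DataFrame, spec: ModelSpec,
                    moderator: str) -> dict:
    """Moderation test: add moderator main effect and exposure x moderator
    term; report the interaction coefficient with its sandwich SE."""
    ispec = replace(spec, interaction=moderator)
    y, X, clusters, _ = build_design(data, ispec)
    fit = fit_glm(y, X, ispec.link)
    _, se = sandwich_se(fit, clusters)
    term = f"{ispec.exposure}:{moderator}"
    est = float(fit.params[term])
    s = float(se[term])
    return {"outcome": spec.outcome, "moderator": moderator, "term": term,
            "estimate": est, "se": s,
            "p": float(2 * stats.norm.sf(abs(est / s))) if s > 0 else np.nan,
            "n": fit.n}


def run_stratified(data: pd.DataFrame, spec: ModelSpec,
                   strata: dict[str, str] | str) -> dict[str, AssocResult]:
    """Independent refits per stratum.

    Built-in splits: ``"age"`` (younger < 60 vs older >= 60), ``"sex"``
    (male/female), ``"education"`` (low/high attainment level).  A mapping
    of name -> pandas query defines custom strata.
    """
    if isinstance(strata, str):
        builtin = {
            "age": {"younger": "age < 60", "older": "age >= 60"},
            "sex": {"male": "sex == 0", "female": "sex == 1"},
            "education": {"low": "education_level == 'low'",
                          "high": "education_level == 'high'"},
        }
        if strata not in builtin:
            raise ValueError(f"unknown stratification {strata!r}")
        strata = builtin[strata]
    results: dict[str, AssocResult] = {}
    for name, query in strata.items():
        sub = data.query(query)
        if sub.empty:
            warnings.warn(f"stratum {name!r} is empty; skipped", stacklevel=2)
            continue
        sspec = replace(spec, sample_filter=None)
        try:
            results[name] = run_association(sub, sspec,
                                            model_label=f"stratum:{name}")
        except ValueError as exc:
            warnings.warn(f"stratum {name!r} skipped: {exc}", stacklevel=2)
    return results


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def results_to_frame(results: list[AssocResult]) -> pd.DataFrame:
    """Results table in the canonical output layout, with pooled BH-FDR."""
    df = pd.DataFrame([{
        "outcome": r.outcome, "model": r.model, "n": r.n,
        "estimate": r.estimate, "se": r.se,
        "ci_low": r.ci_low, "ci_high": r.ci_high, "p": r.p,
        "r2_delta": r.delta_r2, "odds_ratio": r.odds_ratio,
        "link": r.link, "n_clusters": r.n_clusters,
    } for r in results])
    ok = df["p"].notna()
    df["p_fdr"] = np.nan
    if ok.any():
        df.loc[ok, "p_fdr"] = bh_fdr(df.loc[ok, "p"].to_numpy())
    return df
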