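"""GLM estimation, clustered sandwich inference, pseudo-R^2, moderation,
stratification and FDR — each against an independent oracle."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from sibscore.assoc import (ModelSpec, bh_fdr, fit_glm, nagelkerke_delta_r2,
                            run_association, run_interaction, run_stratified,
                            sandwich_se)

COVARIATES = ["age", "sex", "chip"] + [f"PC{i}" for i in range(1, 9)]


def _design(df, cols):
    X = pd.DataFrame({"const": np.ones(len(df))}, index=df.index)
    for c in cols:
        X[c] = df[c].to_numpy(dtype=float)
    return X


class TestFitGlm:
    def test_two_by_two_logistic_slope_closed_form(self):
        # exposed: 30 cases / 20 controls; unexposed: 10 cases / 40 controls
        x = np.array([1] * 50 + [0] * 50, float)
        y = np.array([1] * 30 + [0] * 20 + [1] * 10 + [0] * 40, float)
        X = pd.DataFrame({"const": np.ones(100), "x": x})
        fit = fit_glm(y, X, "logit")
        assert fit.params["x"] == pytest.approx(np.log(6.0), abs=1e-8)

    def test_identity_exact_fit_has_zero_residuals(self, rng):
        x = rng.normal(size=40)
        y = 2.0 + 0.5 * x
        fit = fit_glm(y, pd.DataFrame({"const": np.ones(40), "x": x}),
                      "identity")
        assert np.abs(y - fit.fitted).max() < 1e-10

    @pytest.mark.parametrize("link", ["identity", "logit"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_statsmodels_reference(self, link, seed):
        rng = np.random.default_rng(seed)
        n = 300
        X = pd.DataFrame({"const": np.ones(n), "x": rng.normal(size=n),
                          "z": rng.normal(size=n)})
        eta = 0.4 * X["x"] - 0.7 * X["z"] + 0.1
        if link == "identity":
            y = eta + rng.normal(size=n)
            ref = sm.GLM(y, X, family=sm.families.Gaussian()).fit()
        else:
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
            ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        fit = fit_glm(np.asarray(y), X, link)
        np.testing.assert_allclose(fit.params.to_numpy(), ref.params.to_numpy(),
                                   rtol=1e-6)
        assert fit.llf == pytest.approx(ref.llf, abs=1e-6)

    def test_perfect_separation_flagged(self):
        x = np.linspace(-2, 2, 40)
        y = (x > 0).astype(float)
        fit = fit_glm(y, pd.DataFrame({"const": np.ones(40), "x": x}), "logit")
        assert fit.nonestimable

    def test_collinear_column_dropped_with_warning(self, rng):
        x = rng.normal(size=60)
        X = pd.DataFrame({"const": np.ones(60), "x": x, "x2": 2 * x})
        with pytest.warns(UserWarning, match="collinear"):
            fit = fit_glm(x + rng.normal(size=60), X, "identity")
        assert len(fit.dropped) == 1


class TestSandwich:
    def _clustered_data(self, rng, G=60, m=5):
        g = np.repeat(np.arange(G), m)
        x = rng.normal(size=G)[g] + rng.normal(size=G * m) * 0.3
        u = rng.normal(size=G)[g] * 0.7 + rng.normal(size=G * m) * 0.7
        y = 0.5 * x + u
        X = pd.DataFrame({"const": np.ones(G * m), "x": x})
        return y, X, g

    def test_matches_statsmodels_cluster_up_to_known_factor(self, rng):
        y, X, g = self._clustered_data(rng)
        fit = fit_glm(y, X, "identity")
        _, se = sandwich_se(fit, g)
        ref = sm.GLM(y, X, family=sm.families.Gaussian()).fit(
            cov_type="cluster", cov_kwds={"groups": g})
        n, k = X.shape
        # statsmodels additionally applies (n-1)/(n-k); we follow G/(G-1) only
        factor = np.sqrt((n - 1) / (n - k))
        np.testing.assert_allclose(se.to_numpy() * factor, ref.bse.to_numpy(),
                                   rtol=1e-8)

    def test_singleton_clusters_reduce_to_hc(self, rng):
        n = 120
        x = rng.normal(size=n)
        y = 0.3 * x + rng.normal(size=n) * (1 + np.abs(x))
        X = pd.DataFrame({"const": np.ones(n), "x": x})
        fit = fit_glm(y, X, "identity")
        cov, _ = sandwich_se(fit, np.arange(n))
        A = X.to_numpy()
        e = y - fit.fitted
        bread = np.linalg.inv(A.T @ A)
        hc0 = bread @ (A * (e ** 2)[:, None]).T @ A @ bread
        np.testing.assert_allclose(cov, hc0 * n / (n - 1), rtol=1e-10)

    def test_duplicating_clusters_preserves_coefficients(self, rng):
        y, X, g = self._clustered_data(rng)
        fit1 = fit_glm(y, X, "identity")
        y2 = np.concatenate([y, y])
        X2 = pd.concat([X, X], ignore_index=True)
        fit2 = fit_glm(y2, X2, "identity")
        np.testing.assert_allclose(fit1.params, fit2.params, atol=1e-12)

    def test_single_cluster_rejected(self, rng):
        y, X, _ = self._clustered_data(rng)
        fit = fit_glm(y, X, "identity")
        with pytest.raises(ValueError, match="2 clusters"):
            sandwich_se(fit, np.zeros(len(y)))


class TestNagelkerke:
    def test_six_observation_instance_matches_likelihood_oracle(self):
        y = np.array([1, 0, 1, 1, 0, 0], float)
        x = np.array([2.0, 1.0, 0.5, -0.5, -1.0, 0.3])
        X = pd.DataFrame({"const": np.ones(6), "x": x})
        full = fit_glm(y, X, "logit")
        null = fit_glm(y, X[["const"]], "logit")

        def loglik(eta):
            p = 1 / (1 + np.exp(-eta))
            return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))

        # independent likelihood evaluation at the fitted parameters
        ll1 = loglik(X.to_numpy() @ full.params.to_numpy())
        ll0 = loglik(np.full(6, null.params.iloc[0]))
        n = 6
        r2 = ((1 - np.exp(2 * (ll0 - ll1) / n)) / (1 - np.exp(2 * ll0 / n)))
        delta = nagelkerke_delta_r2(full, null, null)
        assert delta == pytest.approx(r2 - 0.0, abs=1e-10)

    def test_null_exposure_gives_near_zero_delta(self, rng):
        n = 10_000
        x = rng.normal(size=n)
        y = (rng.random(n) < 0.3).astype(float)
        X = pd.DataFrame({"const": np.ones(n), "x": x})
        full = fit_glm(y, X, "logit")
        null = fit_glm(y, X[["const"]], "logit")
        assert nagelkerke_delta_r2(full, null, null) < 0.001

    def test_identity_orthogonal_regressor_delta_is_b_squared(self, rng):
        n = 20_000
        x = rng.normal(size=n)
        y = 0.3 * x + rng.normal(scale=np.sqrt(1 - 0.09), size=n)
        y = (y - y.mean()) / y.std()
        X = pd.DataFrame({"const": np.ones(n), "x": x})
        full = fit_glm(y, X, "identity")
        null = fit_glm(y, X[["const"]], "identity")
        assert nagelkerke_delta_r2(full, null) == pytest.approx(0.09, abs=0.01)

    def test_non_nested_models_rejected(self, rng):
        n = 100
        a, b = rng.normal(size=n), rng.normal(size=n)
        y = a + rng.normal(size=n)
        fa = fit_glm(y, pd.DataFrame({"const": np.ones(n), "a": a}), "identity")
        fb = fit_glm(y, pd.DataFrame({"const": np.ones(n), "b": b}), "identity")
        with pytest.raises(ValueError, match="nested"):
            nagelkerke_delta_r2(fa, fb)


class TestRunAssociation:
    def test_recovers_population_slope_with_nurture_inflation(self, recovery_data):
        # direct 0.2 + nurture 0.3 / 2 = 0.35 expected at the population level
        res = run_association(recovery_data,
                              ModelSpec(outcome="total_cholesterol",
                                        link="identity", covariates=COVARIATES))
        assert abs(res.estimate - 0.35) < 3 * res.se
        assert res.delta_r2 > 0.05

    def test_logit_outcome_reports_odds_ratio(self, recovery_data):
        res = run_association(recovery_data,
                              ModelSpec(outcome="hypertension", link="logit",
                                        covariates=COVARIATES))
        assert res.odds_ratio == pytest.approx(np.exp(res.estimate))
        assert res.or_ci_low < res.odds_ratio < res.or_ci_high
        assert res.estimate > 0

    def test_permutation_null_calibration(self, rng):
        n, reps, hits = 400, 200, 0
        for _ in range(reps):
            fam = np.repeat(np.arange(n // 2), 2)
            df = pd.DataFrame({
                "y": rng.normal(size=n), "PGS": rng.normal(size=n),
                "family_id": fam})
            res = run_association(df, ModelSpec(outcome="y", link="identity",
                                                covariates=[]))
            hits += abs(res.estimate) < 3 * res.se
        assert hits / reps >= 0.94

    def test_small_sample_refused(self, rng):
        df = pd.DataFrame({"y": rng.normal(size=30),
                           "PGS": rng.normal(size=30),
                           "family_id": np.arange(30)})
        with pytest.raises(ValueError, match="n < 50"):
            run_association(df, ModelSpec(outcome="y", link="identity",
                                          covariates=[]))

    def test_constant_chip_interactions_do_not_move_estimate(self, recovery_data):
        df = recovery_data.copy()
        df["chip"] = "GSA"  # degenerate covariate
        with_chip = run_association(df, ModelSpec(
            outcome="total_cholesterol", link="identity",
            covariates=COVARIATES))
        without = run_association(df, ModelSpec(
            outcome="total_cholesterol", link="identity",
            covariates=[c for c in COVARIATES if c != "chip"]))
        assert with_chip.estimate == pytest.approx(without.estimate, abs=1e-12)

    def test_excluding_random_flags_shifts_less_than_one_se(self, recovery_data):
        rng = np.random.default_rng(9)
        df = recovery_data.copy()
        df["random_flag"] = rng.random(len(df)) < 0.01
        base = run_association(df, ModelSpec(
            outcome="total_cholesterol", link="identity", covariates=COVARIATES))
        excl = run_association(df, ModelSpec(
            outcome="total_cholesterol", link="identity", covariates=COVARIATES,
            sample_filter="~random_flag"))
        joint_se = np.hypot(base.se, excl.se)
        assert abs(base.estimate - excl.estimate) < joint_se

    def test_bmi_adjustment_removes_fully_mediated_effect(self, rng):
        # PGS -> BMI -> outcome with no direct path: adding BMI should
        # shrink the PGS estimate by far more than 80%
        n = 4000
        pgs = rng.normal(size=n)
        bmi = 0.6 * pgs + rng.normal(scale=0.8, size=n)
        y = 0.8 * bmi + rng.normal(scale=0.6, size=n)
        df = pd.DataFrame({"y": y, "PGS": pgs, "bmi": bmi,
                           "family_id": np.arange(n)})
        base = run_association(df, ModelSpec(outcome="y", link="identity",
                                             covariates=[]))
        adj = run_association(df, ModelSpec(outcome="y", link="identity",
                                            covariates=["bmi"]))
        assert abs(adj.estimate) < 0.2 * abs(base.estimate)


class TestModeration:
    def _two_strata(self, rng, b0, b1, n=6000):
        mod = rng.integers(0, 2, size=n).astype(float)
        pgs = rng.normal(size=n)
        y = np.where(mod == 0, b0 * pgs, b1 * pgs) + rng.normal(size=n)
        return pd.DataFrame({"y": y, "PGS": pgs, "moderator": mod,
                             "age": rng.uniform(20, 80, n),
                             "family_id": np.arange(n)})

    def test_equal_slopes_give_null_interaction(self, rng):
        df = self._two_strata(rng, 0.2, 0.2)
        out = run_interaction(df, ModelSpec(outcome="y", link="identity",
                                            covariates=[]), "moderator")
        assert abs(out["estimate"]) < 3 * out["se"]

    def test_slope_difference_recovered(self, rng):
        df = self._two_strata(rng, 0.1, 0.3)
        out = run_interaction(df, ModelSpec(outcome="y", link="identity",
                                            covariates=[]), "moderator")
        assert abs(out["estimate"] - 0.2) < 3 * out["se"]

    def test_constant_moderator_rejected(self, rng):
        df = self._two_strata(rng, 0.2, 0.2)
        df["moderator"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            run_interaction(df, ModelSpec(outcome="y", link="identity",
                                          covariates=[]), "moderator")

    def test_age_sixty_belongs_to_older_stratum(self, rng):
        df = self._two_strata(rng, 0.2, 0.2)
        df["age"] = np.where(np.arange(len(df)) % 2 == 0, 60.0, 40.0)
        res = run_stratified(df, ModelSpec(outcome="y", link="identity",
                                           covariates=[]), "age")
        assert res["older"].n == (df["age"] == 60.0).sum()

    def test_strata_consistent_with_interaction(self, rng):
        df = self._two_strata(rng, 0.1, 0.3)
        strat = run_stratified(
            df, ModelSpec(outcome="y", link="identity", covariates=[]),
            {"m0": "moderator == 0", "m1": "moderator == 1"})
        inter = run_interaction(df, ModelSpec(outcome="y", link="identity",
                                              covariates=[]), "moderator")
        # identity fits are unscaled equally (y z-scored on each sample);
        # compare the stratum difference with the interaction on z scale
        diff = strat["m1"].estimate - strat["m0"].estimate
        joint = np.sqrt(strat["m1"].se ** 2 + strat["m0"].se ** 2
                        + inter["se"] ** 2)
        assert abs(diff - inter["estimate"]) < 3 * joint


class TestBhFdr:
    def brute_force(self, p):
        m = len(p)
        order = np.argsort(p, kind="stable")
        adj = np.empty(m)
        prev = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            val = min(prev, p[i] * m / rank)
            adj[i] = val
            prev = val
        return adj

    def test_worked_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_and_singleton(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])
        np.testing.assert_allclose(bh_fdr([0.2]), [0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_bruteforce_stepup(self, pvals):
        p = np.array(pvals)
        np.testing.assert_allclose(bh_fdr(p), self.brute_force(p), atol=1e-12)
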