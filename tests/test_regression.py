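"""Logistic fit, cluster-robust sandwich, and fit diagnostics."""

import numpy as np
import pytest
from scipy import optimize
from scipy.special import expit

from egonet.regression import (
    SeparationWarning,
    cluster_robust_covariance,
    fit_logistic,
    hosmer_lemeshow,
    odds_ratio_table,
    predicted_probabilities,
    pseudo_r2,
    vif,
)


def simulate(seed, n=200, beta=(-0.3, 0.5, -0.4, 0.2)):
    rng = np.random.default_rng(seed)
    beta = np.asarray(beta)
    X = np.column_stack(
        [np.ones(n)] + [rng.normal(size=n) for _ in range(len(beta) - 2)]
        + [rng.binomial(1, 0.4, n)]
    )
    y = rng.binomial(1, expit(X @ beta))
    return X, y, beta


class TestFitLogistic:
    def test_intercept_only_balanced(self):
        y = np.array([0, 1] * 25)
        fit = fit_logistic(np.ones((50, 1)), y)
        assert fit.beta[0] == pytest.approx(0.0, abs=1e-10)
        assert fit.converged

    def test_two_by_two_closed_form(self):
        # x=1: 30 events of 50; x=0: 20 of 50 -> OR = (30*30)/(20*20) = 2.25
        x = np.repeat([1, 0], 50)
        y = np.concatenate([np.ones(30), np.zeros(20), np.ones(20), np.zeros(30)])
        fit = fit_logistic(np.column_stack([np.ones(100), x]), y)
        assert fit.beta[1] == pytest.approx(np.log(2.25), abs=1e-8)
        assert fit.beta[0] == pytest.approx(np.log(2 / 3), abs=1e-8)

    def test_matches_generic_optimizer_oracle(self):
        X, y, _ = simulate(0, n=200)

        def negll(b):
            p = expit(X @ b)
            p = np.clip(p, 1e-12, 1 - 1e-12)
            return -(y @ np.log(p) + (1 - y) @ np.log(1 - p))

        res = optimize.minimize(negll, np.zeros(X.shape[1]), method="BFGS",
                                options={"gtol": 1e-10})
        fit = fit_logistic(X, y)
        assert np.allclose(fit.beta, res.x, atol=1e-6)

    def test_score_equations_satisfied(self):
        X, y, _ = simulate(1, n=500)
        fit = fit_logistic(X, y)
        score = X.T @ (y - fit.predict(X))
        assert np.linalg.norm(score, ord=np.inf) < 1e-8

    def test_null_loglik_nested(self):
        X, y, _ = simulate(2, n=300)
        fit = fit_logistic(X, y)
        assert fit.loglik >= fit.loglik_null

    def test_rank_deficiency_rejected(self):
        X = np.ones((40, 2))
        y = np.random.default_rng(0).integers(0, 2, 40)
        with pytest.raises(np.linalg.LinAlgError):
            fit_logistic(X, y)

    def test_separation_flagged(self):
        x = np.linspace(-2, 2, 40)
        y = (x > 0).astype(int)
        with pytest.warns(SeparationWarning):
            fit = fit_logistic(np.column_stack([np.ones(40), x]), y)
        assert not fit.converged

    def test_matches_independent_ml_implementation(self):
        sm = pytest.importorskip("statsmodels.api")
        X, y, _ = simulate(3, n=400)
        fit = fit_logistic(X, y)
        ref = sm.Logit(y, X).fit(disp=0)
        assert np.allclose(fit.beta, ref.params, atol=1e-8)
        assert np.allclose(np.sqrt(np.diag(fit.vcov_classical)), ref.bse, atol=1e-8)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-8)


class TestClusterRobust:
    def test_singleton_clusters_collapse_to_hc0(self):
        X, y, _ = simulate(4, n=300)
        fit = fit_logistic(X, y)
        rob = cluster_robust_covariance(fit, X, y, np.arange(300))
        resid = y - fit.predict(X)
        meat = (X * resid[:, None]).T @ (X * resid[:, None])
        hc0 = fit.vcov_classical @ meat @ fit.vcov_classical
        assert np.allclose(rob.vcov_cluster, hc0 * 300 / 299, rtol=1e-10)

    def test_duplicating_rows_within_cluster_invariant(self):
        X, y, _ = simulate(5, n=120)
        clusters = np.arange(120)
        k = 3
        Xk, yk, ck = np.repeat(X, k, 0), np.repeat(y, k), np.repeat(clusters, k)
        fit1 = fit_logistic(X, y)
        fitk = fit_logistic(Xk, yk)
        assert np.allclose(fit1.beta, fitk.beta, atol=1e-8)
        r1 = cluster_robust_covariance(fit1, X, y, clusters, small_sample=False)
        rk = cluster_robust_covariance(fitk, Xk, yk, ck, small_sample=False)
        assert np.allclose(r1.vcov_cluster, rk.vcov_cluster, rtol=1e-8)

    def test_ego_constant_rows_match_collapsed_classical(self):
        # dyad design: everything constant within ego -> cluster-robust SEs
        # approximate the classical SEs of the one-row-per-ego fit
        rng = np.random.default_rng(6)
        M = 10_000
        Xe = np.column_stack([np.ones(M), 0.5 * rng.normal(size=M), rng.binomial(1, 0.5, M)])
        ye = rng.binomial(1, expit(Xe @ np.array([0.05, 0.2, -0.15])))
        X, y, cl = np.repeat(Xe, 4, 0), np.repeat(ye, 4), np.repeat(np.arange(M), 4)
        fit_dyad = fit_logistic(X, y)
        fit_ego = fit_logistic(Xe, ye)
        assert np.allclose(fit_dyad.beta, fit_ego.beta, atol=1e-10)
        rob = cluster_robust_covariance(fit_dyad, X, y, cl, small_sample=False)
        se_r = np.sqrt(np.diag(rob.vcov_cluster))
        se_c = np.sqrt(np.diag(fit_ego.vcov_classical))
        assert np.allclose(se_r, se_c, rtol=0.01)

    def test_invariant_to_relabelling_and_row_order(self):
        X, y, _ = simulate(7, n=200)
        clusters = np.repeat(np.arange(50), 4)
        fit = fit_logistic(X, y)
        v1 = cluster_robust_covariance(fit, X, y, clusters).vcov_cluster
        # relabel clusters
        relabel = np.array([f"c{99 - c}" for c in clusters])
        v2 = cluster_robust_covariance(fit, X, y, relabel).vcov_cluster
        # permute rows
        perm = np.random.default_rng(8).permutation(200)
        fitp = fit_logistic(X[perm], y[perm])
        v3 = cluster_robust_covariance(fitp, X[perm], y[perm], clusters[perm]).vcov_cluster
        assert np.allclose(v1, v2, rtol=1e-12)
        assert np.allclose(v1, v3, rtol=1e-6)

    def test_single_cluster_rejected(self):
        X, y, _ = simulate(9, n=50)
        fit = fit_logistic(X, y)
        with pytest.raises(ValueError):
            cluster_robust_covariance(fit, X, y, np.zeros(50))

    def test_matches_independent_cluster_implementation(self):
        sm = pytest.importorskip("statsmodels.api")
        X, y, _ = simulate(10, n=400)
        clusters = np.repeat(np.arange(100), 4)
        fit = fit_logistic(X, y)
        rob = cluster_robust_covariance(fit, X, y, clusters)
        ref = sm.Logit(y, X).fit(disp=0, cov_type="cluster", cov_kwds={"groups": clusters})
        # statsmodels multiplies by an extra (n-1)/(n-k) beyond M/(M-1)
        n, k = X.shape
        adj = (n - 1) / (n - k)
        assert np.allclose(np.diag(rob.vcov_cluster) * adj,
                           np.diag(np.asarray(ref.cov_params())), rtol=1e-6)


class TestORTable:
    def test_null_coefficient(self):
        y = np.array([0, 1] * 30)
        fit = fit_logistic(np.ones((60, 1)), y)
        tab = odds_ratio_table(fit)
        assert tab["or"][0] == pytest.approx(1.0, abs=1e-8)
        assert np.log(tab["ci_low"][0]) == pytest.approx(-np.log(tab["ci_high"][0]), abs=1e-8)

    def test_two_by_two_wald_interval(self):
        x = np.repeat([1, 0], 50)
        y = np.concatenate([np.ones(30), np.zeros(20), np.ones(20), np.zeros(30)])
        fit = fit_logistic(np.column_stack([np.ones(100), x]), y)
        tab = odds_ratio_table(fit)
        se = np.sqrt(1 / 30 + 1 / 20 + 1 / 20 + 1 / 30)  # contingency-table formula
        z = 1.959963984540054
        assert tab["or"][1] == pytest.approx(2.25, rel=1e-6)
        assert tab["ci_low"][1] == pytest.approx(np.exp(np.log(2.25) - z * se), rel=1e-6)
        assert tab["ci_high"][1] == pytest.approx(np.exp(np.log(2.25) + z * se), rel=1e-6)

    def test_ci_excludes_one_iff_p_below_alpha(self):
        X, y, _ = simulate(11, n=500)
        fit = fit_logistic(X, y)
        tab = odds_ratio_table(fit)
        for _, row in tab.iterrows():
            excludes = row["ci_low"] > 1 or row["ci_high"] < 1
            assert excludes == (row["p"] < 0.05)


class TestPredictedProbabilities:
    def test_intercept_only_recovers_mean(self):
        y = np.array([1] * 30 + [0] * 70)
        X = np.ones((100, 1))
        fit = fit_logistic(X, y)
        out = predicted_probabilities(fit, fit.vcov_classical, X, {"all": {}})
        assert out["p_hat"][0] == pytest.approx(0.3, abs=1e-8)

    def test_zero_covariance_degenerate_ci(self):
        X, y, _ = simulate(12, n=200)
        fit = fit_logistic(X, y)
        out = predicted_probabilities(fit, np.zeros((X.shape[1],) * 2), X, {"base": {}})
        assert out["ci_low"][0] == pytest.approx(out["p_hat"][0])
        assert out["ci_high"][0] == pytest.approx(out["p_hat"][0])

    def test_monotone_in_focal_coefficient_and_bounded(self):
        X, y, _ = simulate(13, n=400)
        fit = fit_logistic(X, y)
        focal = {"off": {"x2": 0}, "on": {"x2": 1}}
        out = predicted_probabilities(fit, fit.vcov_classical, X,
                                      {k: dict(v, **{}) for k, v in focal.items()})
        p_by = dict(zip(out["category"], out["p_hat"]))
        assert 0 < p_by["off"] < 1 and 0 < p_by["on"] < 1
        assert (p_by["on"] > p_by["off"]) == (fit.beta[fit.names.index("x2")] > 0)

    def test_unknown_category_rejected(self):
        X, y, _ = simulate(14, n=100)
        fit = fit_logistic(X, y)
        with pytest.raises(KeyError):
            predicted_probabilities(fit, fit.vcov_classical, X, {"bad": {"nope": 1}})


class TestHosmerLemeshow:
    def test_perfect_calibration_zero_chi2(self):
        # observed equals expected in every decile
        qs = np.arange(1, 11) / 20  # 20*q events out of 20 is an integer
        p = np.repeat(qs, 20)
        y = np.concatenate([[1] * int(20 * q) + [0] * int(20 * (1 - q)) for q in qs])
        chi2, df, pval = hosmer_lemeshow(y, p, g=10)
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert df == 8

    def test_type_one_error_calibrated(self):
        rej = 0
        nsim = 1000
        for s in range(nsim):
            rng = np.random.default_rng(1_000 + s)
            n = 1000
            X = np.column_stack([np.ones(n), rng.normal(size=n), rng.binomial(1, 0.5, n)])
            y = rng.binomial(1, expit(X @ np.array([-0.4, 0.6, 0.3])))
            fit = fit_logistic(X, y)
            chi2, df, p = hosmer_lemeshow(y, fit.predict(X))
            rej += p < 0.05
        assert 0.03 <= rej / nsim <= 0.07

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            hosmer_lemeshow(np.array([0, 1]), np.array([0.2, 0.8]), g=2)


class TestPseudoR2AndVIF:
    def test_null_model_zero(self):
        y = np.random.default_rng(15).integers(0, 2, 200)
        fit = fit_logistic(np.ones((200, 1)), y)
        mcf, nag = pseudo_r2(fit)
        assert mcf == pytest.approx(0.0, abs=1e-8)
        assert nag == pytest.approx(0.0, abs=1e-8)

    def test_two_by_two_closed_form_logliks(self):
        x = np.repeat([1, 0], 50)
        y = np.concatenate([np.ones(30), np.zeros(20), np.ones(20), np.zeros(30)])
        fit = fit_logistic(np.column_stack([np.ones(100), x]), y)
        L1 = 30 * np.log(0.6) + 20 * np.log(0.4) + 20 * np.log(0.4) + 30 * np.log(0.6)
        L0 = 100 * (0.5 * np.log(0.5) + 0.5 * np.log(0.5))
        mcf, nag = pseudo_r2(fit)
        assert mcf == pytest.approx(1 - L1 / L0, abs=1e-8)
        assert nag == pytest.approx((1 - np.exp(2 * (L0 - L1) / 100)) / (1 - np.exp(2 * L0 / 100)),
                                    abs=1e-8)

    def test_bounds_on_converged_fits(self):
        for seed in range(3):
            X, y, _ = simulate(seed, n=300)
            mcf, nag = pseudo_r2(fit_logistic(X, y))
            assert 0 <= mcf <= 1 and 0 <= nag <= 1

    def test_orthogonal_columns_unit_vif(self):
        rng = np.random.default_rng(16)
        G = np.column_stack([np.ones(100), rng.normal(size=(100, 4))])
        Q, _ = np.linalg.qr(G)  # columns 1.. are orthonormal and mean-zero
        out = vif(Q[:, 1:])
        assert np.allclose(out["vif"], 1.0, atol=1e-8)

    def test_two_correlated_columns_closed_form(self):
        rng = np.random.default_rng(17)
        x1 = rng.normal(size=5000)
        r = 0.6
        x2 = r * x1 + np.sqrt(1 - r**2) * rng.normal(size=5000)
        out = vif(np.column_stack([x1, x2]))
        emp_r = np.corrcoef(x1, x2)[0, 1]
        assert np.allclose(out["vif"], 1 / (1 - emp_r**2), rtol=1e-8)

    def test_matches_independent_vif_implementation(self):
        smo = pytest.importorskip("statsmodels.stats.outliers_influence")
        X, _, _ = simulate(18, n=300)
        out = vif(X[:, 1:])
        ref = [smo.variance_inflation_factor(X, j) for j in range(1, X.shape[1])]
        assert np.allclose(out["vif"], ref, rtol=1e-8)

    def test_collinear_column_rejected(self):
        x = np.random.default_rng(19).normal(size=100)
        with pytest.raises(ValueError):
            vif(np.column_stack([x, 2 * x]))
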