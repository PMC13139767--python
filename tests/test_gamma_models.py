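"""Design building, gamma GLM/GLMM likelihoods, AICc and fit statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import special

from telodyn.gamma_models import (
    FitError,
    ModelSpec,
    ModelSpecError,
    aicc,
    build_design,
    deviance_explained,
    fit_gamma_glm,
    fit_gamma_glmm,
    fit_model,
    gamma_deviance,
    gamma_loglik,
    glmm_marginal_loglik,
    nagelkerke_r2,
)


def _samples(n=60, seed=0, sigma_year=0.0):
    rng = np.random.default_rng(seed)
    sex = rng.choice(["female", "male", "unknown"], size=n, p=[0.45, 0.5, 0.05])
    tissue = rng.choice(["blood", "tail"], size=n)
    year = rng.choice(range(2015, 2020), size=n)
    svl = rng.normal(110, 12, size=n)
    u = {y: rng.normal(0, sigma_year) for y in range(2015, 2020)}
    eta = 0.1 - 0.2 * (sex == "male") + 0.15 * (tissue == "tail") + np.array([u[y] for y in year])
    y_resp = rng.gamma(8.0, np.exp(eta) / 8.0)
    return pd.DataFrame(
        {
            "sex": sex, "tissue": tissue, "year": year, "svl": svl,
            "rtl_shifted": y_resp,
        }
    )


class TestModelSpec:
    def test_interaction_requires_parents(self):
        with pytest.raises(ModelSpecError):
            ModelSpec(fixed_terms=("sex", "sex:svl"))

    def test_valid_interaction(self):
        spec = ModelSpec(fixed_terms=("sex", "svl", "sex:svl"))
        assert "sex:svl" in spec.fixed_terms


class TestBuildDesign:
    def test_missing_rows_dropped(self):
        df = _samples(10)
        df.loc[[2, 5], "svl"] = np.nan
        d = build_design(df, ModelSpec(fixed_terms=("svl",)))
        assert d.X.shape[0] == 8 and d.n_dropped == 2

    def test_interaction_columns_present(self):
        d = build_design(_samples(80), ModelSpec(fixed_terms=("sex", "svl", "sex:svl")))
        assert "sex_male:svl" in d.names and "sex_unknown:svl" in d.names

    def test_all_female_subset_errors(self):
        df = _samples(40)
        df["sex"] = "female"
        with pytest.raises(ModelSpecError, match="male"):
            build_design(df, ModelSpec(fixed_terms=("sex",)))

    def test_continuous_standardised(self):
        d = build_design(_samples(50), ModelSpec(fixed_terms=("svl",)))
        col = d.X[:, d.names.index("svl")]
        assert abs(col.mean()) < 1e-12 and np.std(col, ddof=1) == pytest.approx(1.0)


class TestGammaGlm:
    def test_intercept_only_is_log_mean(self, rng):
        y = rng.gamma(5, 0.5, size=80)
        f = fit_gamma_glm(np.ones((80, 1)), y)
        assert f.beta[0] == pytest.approx(np.log(y.mean()), abs=1e-9)

    def test_duplicate_column_rank_error(self, rng):
        x = rng.normal(size=40)
        X = np.column_stack([np.ones(40), x, x])
        y = rng.gamma(5, 0.5, size=40)
        with pytest.raises(FitError, match="rank"):
            fit_gamma_glm(X, y, names=["intercept", "a", "a_copy"])

    def test_simulation_recovery_within_three_se(self, rng):
        n = 5000
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.normal(size=n)])
        beta = np.array([0.3, -0.15, 0.08])
        y = rng.gamma(10.0, np.exp(X @ beta) / 10.0)
        f = fit_gamma_glm(X, y)
        assert np.all(np.abs(f.beta - beta) < 3 * f.se())
        assert f.shape == pytest.approx(10.0, rel=0.15)

    def test_loglik_is_exact_gamma_loglik(self, rng):
        y = rng.gamma(4, 0.5, size=30)
        f = fit_gamma_glm(np.ones((30, 1)), y)
        assert f.loglik == pytest.approx(gamma_loglik(y, f.mu, f.shape), abs=1e-10)

    def test_adding_a_term_never_decreases_loglik(self):
        df = _samples(100, seed=3)
        f0 = fit_model(df, ModelSpec(fixed_terms=("sex",)))
        f1 = fit_model(df, ModelSpec(fixed_terms=("sex", "svl")))
        assert f1.loglik >= f0.loglik - 1e-8


class TestGammaGlmm:
    def test_sigma_zero_boundary_matches_glm(self):
        # per-group n large enough that group-mean sampling noise (~1/sqrt(
        # shape * n_g)) sits well below the 0.02 bound on the boundary fit
        rng = np.random.default_rng(4)
        years = np.repeat(np.arange(2013, 2023), 200)
        y = rng.gamma(8.0, np.exp(0.1) / 8.0, size=2000)
        df = pd.DataFrame({"rtl_shifted": y, "year": years})
        glm = fit_model(df, ModelSpec(fixed_terms=()))
        glmm = fit_model(df, ModelSpec(fixed_terms=(), random_intercept="year"))
        assert glmm.sigma_group < 0.02
        assert glmm.loglik == pytest.approx(glm.loglik, abs=0.01)

    def test_agq_matches_trapezoid_oracle_on_toy(self, rng):
        n = 30
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        beta = np.array([0.2, 0.3])
        sigma, shape = 0.4, 5.0
        gidx = np.repeat([0, 1, 2], 10)
        u = rng.normal(0, sigma, 3)
        y = rng.gamma(shape, np.exp(X @ beta + u[gidx]) / shape)
        ll = glmm_marginal_loglik(X, y, gidx, 3, beta, shape, sigma, n_quad=15)
        grid = np.linspace(-6 * sigma, 6 * sigma, 10001)
        oracle = 0.0
        for g in range(3):
            yi, eta = y[gidx == g], (X @ beta)[gidx == g]
            lp = np.array(
                [
                    np.sum(
                        shape * np.log(shape)
                        - special.gammaln(shape)
                        + (shape - 1) * np.log(yi)
                        - shape * (eta + ug)
                        - shape * yi * np.exp(-(eta + ug))
                    )
                    - 0.5 * ug**2 / sigma**2
                    - 0.5 * np.log(2 * np.pi * sigma**2)
                    for ug in grid
                ]
            )
            m = lp.max()
            oracle += m + np.log(np.trapezoid(np.exp(lp - m), grid))
        assert ll == pytest.approx(oracle, abs=1e-4)

    def test_quadrature_refinement_approaches_oracle(self, rng):
        n = 24
        X = np.ones((n, 1))
        gidx = np.repeat([0, 1, 2], 8)
        u = rng.normal(0, 0.5, 3)
        y = rng.gamma(4.0, np.exp(0.2 + u[gidx]) / 4.0)
        lls = [
            glmm_marginal_loglik(X, y, gidx, 3, np.array([0.2]), 4.0, 0.5, n_quad=q)
            for q in (1, 5, 15, 31)
        ]
        errs = np.abs(np.diff(lls))
        assert errs[-1] < errs[0] + 1e-12
        assert abs(lls[-1] - lls[-2]) < 1e-6

    def test_sigma_recovery_over_seeds(self):
        hits = 0
        n_seeds = 50
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            years = np.repeat(np.arange(10), 50)
            u = rng.normal(0, 0.3, 10)
            y = rng.gamma(8.0, np.exp(0.1 + u[years]) / 8.0)
            df = pd.DataFrame({"rtl_shifted": y, "year": years})
            f = fit_model(
                df, ModelSpec(fixed_terms=(), random_intercept="year"), compute_vcov=False
            )
            if 0.15 <= f.sigma_group <= 0.45:
                hits += 1
        assert hits >= 0.9 * n_seeds

    def test_score_vanishes_at_optimum(self):
        df = _samples(150, seed=6, sigma_year=0.2)
        f = fit_model(df, ModelSpec(fixed_terms=("sex",), random_intercept="year"))
        codes, uniq = pd.factorize(df.dropna()["year"])
        d = build_design(df, ModelSpec(fixed_terms=("sex",), random_intercept="year"))
        codes, uniq = pd.factorize(d.groups)

        def ll(theta):
            return glmm_marginal_loglik(
                d.X, d.y, codes, len(uniq), theta[:-2], np.exp(theta[-2]), np.exp(theta[-1])
            )

        theta = np.concatenate([f.beta, [np.log(f.shape), np.log(f.sigma_group)]])
        eps = 1e-6
        for i in range(len(theta)):
            e = np.zeros_like(theta)
            e[i] = eps
            g = (ll(theta + e) - ll(theta - e)) / (2 * eps)
            assert abs(g) < 1e-2  # flat to numerical-optimiser resolution


class TestFitStatistics:
    def test_aicc_worked_example(self):
        f = _FakeFit(loglik=-100, k=4, n=50)
        assert aicc(f) == pytest.approx(208 + 40 / 45)

    def test_aicc_k_zero_limit(self):
        assert aicc(_FakeFit(loglik=-100, k=0, n=50)) == pytest.approx(200.0)

    def test_aicc_approaches_aic_for_large_n(self):
        small = aicc(_FakeFit(loglik=-100, k=4, n=50))
        big = aicc(_FakeFit(loglik=-100, k=4, n=10**7))
        assert big == pytest.approx(208.0, abs=1e-4)
        assert small > big

    def test_aicc_undefined_when_n_too_small(self):
        with pytest.raises(ValueError):
            aicc(_FakeFit(loglik=-10, k=4, n=5))

    def test_nagelkerke_zero_when_equal(self):
        a = _FakeFit(loglik=-120, k=1, n=200)
        assert nagelkerke_r2(a, a) == pytest.approx(0.0)

    def test_nagelkerke_formula_arithmetic(self):
        full = _FakeFit(loglik=-100, k=3, n=200)
        null = _FakeFit(loglik=-120, k=1, n=200)
        expected = (1 - np.exp(2 * (-120 + 100) / 200)) / (1 - np.exp(2 * -120 / 200))
        assert nagelkerke_r2(full, null) == pytest.approx(expected, abs=1e-12)
        assert 0 < nagelkerke_r2(full, null) < 1

    def test_nagelkerke_approaches_one_near_saturation(self):
        null = _FakeFit(loglik=-120, k=1, n=200)
        r2s = [nagelkerke_r2(_FakeFit(loglik=l1, k=3, n=200), null) for l1 in (-50, -10, -1e-6)]
        assert all(np.diff(r2s) > 0) and r2s[-1] < 1.0 and r2s[-1] > 0.999

    def test_deviance_explained_bounds(self):
        y = np.array([1.0, 2.0, 4.0])
        perfect = _FakeFit(loglik=0, k=1, n=3, y=y, mu=y.copy())
        null_mu = np.full(3, y.mean())
        null = _FakeFit(loglik=0, k=1, n=3, y=y, mu=null_mu)
        assert deviance_explained(perfect, null) == pytest.approx(1.0)
        assert deviance_explained(null, null) == pytest.approx(0.0)

    def test_gamma_deviance_hand_computed(self):
        y = np.array([1.0, 2.0, 4.0])
        mu = np.full(3, 2.0)
        # 2 * [(-ln .5 - .5) + 0 + (-ln 2 + 1)] = 1.0
        assert gamma_deviance(y, mu) == pytest.approx(1.0, abs=1e-12)


class _FakeFit:
    def __init__(self, loglik, k, n, y=None, mu=None):
        self.loglik = loglik
        self.k = k
        self.n = n
        self.y = y
        self.mu = mu
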