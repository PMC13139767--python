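"""Model enumeration, Akaike weights, averaging, marginal means and trends."""

import numpy as np
import pandas as pd
import pytest

from telodyn.gamma_models import FitResult, ModelSpec, ModelSpecError, fit_model
from telodyn.selection import (
    AveragedCoefficients,
    average_coefficients,
    emmeans,
    enumerate_models,
    marginal_trend,
    rank_models,
    standardised_effects,
    subset_model_set,
    tukey_adjusted_p,
)


def _fake_fit(terms, beta, vcov, loglik, n=100, names=None):
    names = names or (["intercept"] + list(terms))
    beta = np.asarray(beta, float)
    return FitResult(
        spec=ModelSpec(fixed_terms=tuple(terms)),
        names=names,
        beta=beta,
        vcov=np.asarray(vcov, float),
        shape=5.0,
        sigma_group=0.0,
        loglik=loglik,
        n=n,
        k=len(beta) + 1,
        converged=True,
        y=np.ones(n),
        mu=np.ones(n),
    )


class TestEnumeration:
    def test_study_term_set_gives_eighty_models(self):
        spec = ModelSpec(
            fixed_terms=("env_pc1", "env_pc2", "sex", "svl", "tissue", "morphotype", "sex:svl"),
            random_intercept="year",
        )
        models = enumerate_models(spec)
        assert len(models) == 80  # 2^6 main subsets + 2^4 containing sex:svl
        assert all(m.random_intercept == "year" for m in models)

    def test_single_term_gives_two_models(self):
        assert len(enumerate_models(ModelSpec(fixed_terms=("svl",)))) == 2

    def test_marginality_enforced_at_spec_level(self):
        with pytest.raises(ModelSpecError):
            ModelSpec(fixed_terms=("svl", "sex:svl"))


class TestRanking:
    def test_weights_for_delta_zero_two(self):
        fits = [
            _fake_fit(["a"], [0.0, 1.0], np.eye(2) * 0.01, loglik=-50.0),
            _fake_fit(["b"], [0.0, 1.0], np.eye(2) * 0.01, loglik=-51.0),
        ]
        ms = rank_models(fits)  # equal k => delta = (0, 2)
        assert ms.delta == pytest.approx([0.0, 2.0])
        assert ms.weight == pytest.approx([0.7311, 0.2689], abs=5e-5)

    def test_equal_aicc_splits_weight(self):
        fits = [
            _fake_fit(["a"], [0.0, 1.0], np.eye(2) * 0.01, loglik=-50.0),
            _fake_fit(["b"], [0.0, 1.0], np.eye(2) * 0.01, loglik=-50.0),
        ]
        assert rank_models(fits).weight == pytest.approx([0.5, 0.5])

    def test_single_model_weight_one(self):
        ms = rank_models([_fake_fit(["a"], [0.0, 1.0], np.eye(2) * 0.01, loglik=-50.0)])
        assert ms.weight == pytest.approx([1.0])

    def test_weights_invariant_to_aicc_offset(self):
        lls = [-50.0, -51.3, -52.9]
        fits1 = [_fake_fit(["a"], [0, 1], np.eye(2) * 0.01, ll) for ll in lls]
        fits2 = [_fake_fit(["a"], [0, 1], np.eye(2) * 0.01, ll - 7.5) for ll in lls]
        assert rank_models(fits1).weight == pytest.approx(rank_models(fits2).weight)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            rank_models([])


class TestAveraging:
    def test_single_model_averaging_is_identity(self):
        f = _fake_fit(["a"], [0.5, 1.2], [[0.04, 0.0], [0.0, 0.09]], loglik=-40.0)
        avg = average_coefficients(rank_models([f]))
        i = avg.terms.index("a")
        assert avg.full_estimate[i] == pytest.approx(1.2)
        assert avg.conditional_estimate[i] == pytest.approx(1.2)
        assert avg.adjusted_se[i] == pytest.approx(0.3)
        assert avg.importance[i] == pytest.approx(1.0)

    def test_term_in_one_of_two_models(self):
        from telodyn.gamma_models import aicc

        # construct the second fit's loglik so delta = 2*ln(0.6/0.4), i.e.
        # Akaike weights are exactly (0.6, 0.4)
        d = 2 * np.log(0.6 / 0.4)
        f1 = _fake_fit(["a"], [0.0, 1.0], np.zeros((2, 2)), loglik=-40.0)
        f2 = _fake_fit([], [0.0], np.zeros((1, 1)), loglik=-40.0)
        target_aicc = aicc(f1) + d
        f2.loglik = -(target_aicc - 2 * f2.k - 2 * f2.k * (f2.k + 1) / (f2.n - f2.k - 1)) / 2
        ms = rank_models([f1, f2])
        assert ms.weight == pytest.approx([0.6, 0.4], abs=1e-12)
        avg = average_coefficients(ms)
        i = avg.terms.index("a")
        assert avg.full_estimate[i] == pytest.approx(0.6)
        assert avg.conditional_estimate[i] == pytest.approx(1.0)

    def test_matches_brute_force_weighted_sums(self):
        rng = np.random.default_rng(8)
        fits = []
        for ll in (-40.0, -41.2, -43.5):
            beta = rng.normal(size=3)
            v = rng.normal(size=(3, 3))
            fits.append(_fake_fit(["a", "b"], beta, v @ v.T / 50, loglik=ll))
        ms = rank_models(fits)
        avg = average_coefficients(ms)
        for t in ("a", "b"):
            idx = [f.names.index(t) for f in ms.fits]
            betas = np.array([f.beta[j] for f, j in zip(ms.fits, idx)])
            vars_ = np.array([f.vcov[j, j] for f, j in zip(ms.fits, idx)])
            bbar = np.sum(ms.weight * betas)
            se = np.sum(ms.weight * np.sqrt(vars_ + (betas - bbar) ** 2))
            i = avg.terms.index(t)
            assert avg.full_estimate[i] == pytest.approx(bbar, abs=1e-12)
            assert avg.adjusted_se[i] == pytest.approx(se, abs=1e-12)

    def test_full_shrinks_towards_zero_relative_to_conditional(self):
        d = 2 * np.log(0.7 / 0.3)
        f1 = _fake_fit(["a"], [0.0, 0.8], np.eye(2) * 0.01, loglik=-40.0)
        f2 = _fake_fit([], [0.0], np.eye(1) * 0.01, loglik=-40.0 - (d - 2) / 2)
        avg = average_coefficients(rank_models([f1, f2]))
        i = avg.terms.index("a")
        assert abs(avg.full_estimate[i]) <= abs(avg.conditional_estimate[i])

    def test_delta_subset_rule(self):
        fits = [
            _fake_fit(["a"], [0, 1.0], np.eye(2) * 0.01, loglik=-50.0),
            _fake_fit(["b"], [0, 1.0], np.eye(2) * 0.01, loglik=-50.5),
            _fake_fit(["c"], [0, 1.0], np.eye(2) * 0.01, loglik=-54.0),
        ]
        ms = rank_models(fits)
        sub = subset_model_set(ms, "delta", 2.0)
        assert len(sub.fits) == 2
        assert sub.weight.sum() == pytest.approx(1.0)


@pytest.fixture(scope="module")
def one_factor_fit():
    rng = np.random.default_rng(21)
    tissue = np.repeat(["blood", "tail"], 60)
    y = rng.gamma(6.0, np.exp(0.1 + 0.3 * (tissue == "tail")) / 6.0)
    df = pd.DataFrame({"tissue": tissue, "rtl_shifted": y})
    return df, fit_model(df, ModelSpec(fixed_terms=("tissue",)))


class TestEmmeans:
    def test_balanced_one_factor_emms_equal_group_means(self, one_factor_fit):
        df, fit = one_factor_fit
        e = emmeans(fit, "tissue")
        for lv, mean in df.groupby("tissue")["rtl_shifted"].mean().items():
            i = e.levels.index(lv)
            # gamma log-link score equation matches fitted level means to
            # arithmetic group means exactly
            assert e.response_mean[i] == pytest.approx(mean, rel=1e-8)

    def test_contrast_equals_link_mean_difference(self, one_factor_fit):
        _, fit = one_factor_fit
        e = emmeans(fit, "tissue")
        est = e.contrasts["estimate"].iloc[0]
        assert est == pytest.approx(e.link_mean[0] - e.link_mean[1], abs=1e-12)

    def test_identical_groups_contrast_zero_p_one(self):
        rng = np.random.default_rng(22)
        y_half = rng.gamma(6.0, 1 / 6.0, size=50)
        df = pd.DataFrame(
            {"tissue": np.repeat(["blood", "tail"], 50), "rtl_shifted": np.tile(y_half, 2)}
        )
        e = emmeans(fit_model(df, ModelSpec(fixed_terms=("tissue",))), "tissue")
        assert e.contrasts["estimate"].iloc[0] == pytest.approx(0.0, abs=1e-10)
        assert e.contrasts["tukey_p"].iloc[0] == pytest.approx(1.0, abs=1e-8)

    def test_factor_absent_errors(self, one_factor_fit):
        _, fit = one_factor_fit
        with pytest.raises(ValueError):
            emmeans(fit, "sex")


class TestTukey:
    def test_two_levels_reduces_to_normal_p(self):
        from scipy import stats

        for z in (0.5, 1.96, 2.8):
            assert tukey_adjusted_p(z, 2) == pytest.approx(2 * stats.norm.sf(z), rel=1e-5)

    def test_zero_statistic_p_one(self):
        assert tukey_adjusted_p(0.0, 3) == pytest.approx(1.0)

    def test_three_level_five_percent_boundary(self):
        # studentized-range 95% point for k=3, df=inf is 3.3145 => |z| = q/sqrt(2)
        assert tukey_adjusted_p(3.3145 / np.sqrt(2), 3) == pytest.approx(0.05, abs=1e-3)

    def test_monotone_in_z(self):
        ps = [tukey_adjusted_p(z, 4) for z in (0.5, 1.0, 2.0, 3.0)]
        assert all(np.diff(ps) < 0)


class TestMarginalTrend:
    def test_no_interaction_identical_slopes(self):
        df = _trend_data(n=400, b_f=-0.1, b_m=-0.1, seed=31)
        fit = fit_model(df, ModelSpec(fixed_terms=("sex", "svl")))
        t = marginal_trend(fit, "svl", by="sex")
        assert t["slope"].nunique() == 1

    def test_recovers_sex_specific_slopes(self):
        df = _trend_data(n=5000, b_f=-0.08, b_m=-0.01, seed=32)
        fit = fit_model(df, ModelSpec(fixed_terms=("sex", "svl", "sex:svl")), )
        t = marginal_trend(fit, "svl", by="sex").set_index("level")
        # svl standardised with sd ~1 in the generator, so slopes are per-SD
        assert abs(t.loc["female", "slope"] - (-0.08)) < 3 * t.loc["female", "se"]
        assert abs(t.loc["male", "slope"] - (-0.01)) < 3 * t.loc["male", "se"]

    def test_var_absent_errors(self):
        df = _trend_data(n=100, b_f=0, b_m=0, seed=33)
        fit = fit_model(df, ModelSpec(fixed_terms=("sex",)))
        with pytest.raises(ValueError):
            marginal_trend(fit, "svl")


class TestStandardisedEffects:
    def test_sorted_by_magnitude(self):
        avg = AveragedCoefficients(
            terms=["intercept", "sex_male", "svl", "tissue_tail"],
            full_estimate=np.array([0.1, -0.131, -0.046, 0.140]),
            conditional_estimate=np.array([0.1, -0.131, -0.046, 0.140]),
            adjusted_se=np.array([0.1, 0.046, 0.017, 0.055]),
            conditional_se=np.array([0.1, 0.046, 0.017, 0.055]),
            z=np.zeros(4),
            p=np.ones(4),
            importance=np.ones(4),
        )
        tab = standardised_effects(avg)
        assert list(tab["term"]) == ["tissue_tail", "sex_male", "svl"]
        assert "intercept" not in set(tab["term"])

    def test_matches_independent_sort_oracle(self, rng):
        est = rng.normal(size=6)
        terms = [f"t{i}" for i in range(6)]
        avg = AveragedCoefficients(
            terms=terms,
            full_estimate=est,
            conditional_estimate=est,
            adjusted_se=np.abs(rng.normal(size=6)),
            conditional_se=np.abs(rng.normal(size=6)),
            z=np.zeros(6),
            p=np.ones(6),
            importance=np.ones(6),
        )
        tab = standardised_effects(avg)
        oracle = [terms[i] for i in np.argsort(-np.abs(est), kind="stable")]
        assert list(tab["term"]) == oracle


def _trend_data(n, b_f, b_m, seed):
    rng = np.random.default_rng(seed)
    sex = rng.choice(["female", "male"], size=n)
    svl = rng.normal(0, 1, size=n)
    eta = 0.1 + b_f * svl * (sex == "female") + b_m * svl * (sex == "male") - 0.1 * (sex == "male")
    y = rng.gamma(10.0, np.exp(eta) / 10.0)
    return pd.DataFrame({"sex": sex, "svl": svl, "rtl_shifted": y})
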