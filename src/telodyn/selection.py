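"""All-subsets model selection, AICc averaging, marginal means and trends.

Implements the "dredge" workflow: every subset of the global fixed-effect
terms that respects marginality (an interaction only appears with both
parents) is fitted, models are ranked by AICc and given Akaike weights
w_i = exp(-delta_i/2) / sum_j exp(-delta_j/2), and coefficients are averaged
across the set. Two averages are reported per term: the *full* average
(absent terms count as zero) and the *conditional* average (only models
containing the term contribute), with the revised unconditional standard
error se = sum_i w_i sqrt(var_i + (beta_i - beta_bar)^2).

Estimated marginal means for a factor are link-scale predictions averaged
with equal weights over the levels of the other factors, continuous
covariates held at their means; pairwise contrasts use a normal-theory
Tukey (studentized-range) adjustment.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .gamma_models import (
    FACTOR_LEVELS,
    FitResult,
    ModelSpec,
    aicc,
    fit_model,
)

logger = logging.getLogger(__name__)


@dataclass
class ModelSet:
    fits: list[FitResult]
    aicc: np.ndarray
    delta: np.ndarray
    weight: np.ndarray
    term_presence: pd.DataFrame  # fits x terms indicator

    def table(self) -> pd.DataFrame:
        rows = []
        for i, f in enumerate(self.fits):
            rows.append(
                {
                    "model": f.spec.label if f.spec else str(i),
                    "k": f.k,
                    "loglik": f.loglik,
                    "aicc": self.aicc[i],
                    "delta": self.delta[i],
                    "weight": self.weight[i],
                }
            )
        return pd.DataFrame(rows)


@dataclass
class AveragedCoefficients:
    """Model-averaged coefficient table (full and conditional averages)."""

    terms: list[str]
    full_estimate: np.ndarray
    conditional_estimate: np.ndarray
    adjusted_se: np.ndarray
    conditional_se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    importance: np.ndarray

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": self.full_estimate,
                "conditional_estimate": self.conditional_estimate,
                "adjusted_se": self.adjusted_se,
                "conditional_se": self.conditional_se,
                "z": self.z,
                "p": self.p,
                "importance": self.importance,
            }
        )


@dataclass
class EmmResult:
    factor: str
    levels: list[str]
    link_mean: np.ndarray
    link_se: np.ndarray
    response_mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    contrasts: pd.DataFrame = field(default_factory=pd.DataFrame)


def enumerate_models(global_spec: ModelSpec) -> list[ModelSpec]:
    """All term subsets respecting marginality; intercept always included."""
    main = [t for t in global_spec.fixed_terms if ":" not in t]
    inters = [t for t in global_spec.fixed_terms if ":" in t]
    specs = []
    for r in range(len(main) + 1):
        for subset in itertools.combinations(main, r):
            base = tuple(subset)
            ok_inters = [i for i in inters if all(p in base for p in i.split(":"))]
            for ir in range(len(ok_inters) + 1):
                for isub in itertools.combinations(ok_inters, ir):
                    specs.append(
                        ModelSpec(
                            response=global_spec.response,
                            fixed_terms=base + isub,
                            random_intercept=global_spec.random_intercept,
                        )
                    )
    return specs


def rank_models(fits: list[FitResult]) -> ModelSet:
    """AICc ranking with Akaike weights; non-converged fits are excluded."""
    kept = [f for f in fits if f.converged]
    skipped = len(fits) - len(kept)
    if skipped:
        logger.warning("rank_models: excluded %d non-converged fit(s)", skipped)
    if not kept:
        raise ValueError("no converged fits to rank")
    a = np.array([aicc(f) for f in kept])
    order = np.argsort(a, kind="stable")
    kept = [kept[i] for i in order]
    a = a[order]
    delta = a - a[0]
    w = np.exp(-delta / 2.0)
    w /= w.sum()
    all_terms = sorted({name for f in kept for name in f.names if name != "intercept"})
    presence = pd.DataFrame(
        [[t in f.names for t in all_terms] for f in kept], columns=all_terms
    )
    return ModelSet(fits=kept, aicc=a, delta=delta, weight=w, term_presence=presence)


def subset_model_set(ms: ModelSet, rule: str = "all", value: float = 2.0) -> ModelSet:
    """Restrict a ranked set: 'all', 'delta' (delta <= value) or 'cumweight'
    (smallest prefix reaching cumulative weight >= value); weights are
    renormalised within the subset."""
    if rule == "all":
        idx = np.arange(len(ms.fits))
    elif rule == "delta":
        idx = np.flatnonzero(ms.delta <= value)
    elif rule == "cumweight":
        cum = np.cumsum(ms.weight)
        idx = np.arange(int(np.searchsorted(cum, value - 1e-12)) + 1)
    else:
        raise ValueError(f"unknown subset rule {rule!r}")
    fits = [ms.fits[i] for i in idx]
    a = ms.aicc[idx]
    delta = a - a[0]
    w = np.exp(-delta / 2.0)
    w /= w.sum()
    return ModelSet(
        fits=fits, aicc=a, delta=delta, weight=w,
        term_presence=ms.term_presence.iloc[idx].reset_index(drop=True),
    )


def average_coefficients(ms: ModelSet) -> AveragedCoefficients:
    """Multimodel-averaged coefficients over a (possibly subset) model set.

    z and p are Wald statistics of the full-average estimate against the
    revised unconditional SE, using the normal reference distribution.
    """
    terms = ["intercept"] + list(ms.term_presence.columns)
    n_terms = len(terms)
    full = np.zeros(n_terms)
    cond = np.zeros(n_terms)
    se_full = np.zeros(n_terms)
    se_cond = np.zeros(n_terms)
    importance = np.zeros(n_terms)
    for ti, term in enumerate(terms):
        betas, variances, weights = [], [], []
        for f, w in zip(ms.fits, ms.weight):
            if term in f.names:
                j = f.names.index(term)
                betas.append(f.beta[j])
                variances.append(f.vcov[j, j])
                weights.append(w)
        if not betas:
            logger.warning("term %r appears in no model of the subset", term)
            full[ti] = cond[ti] = se_full[ti] = se_cond[ti] = np.nan
            continue
        betas = np.array(betas)
        variances = np.array(variances)
        weights = np.array(weights)
        wsum = weights.sum()
        importance[ti] = wsum
        full[ti] = float(np.sum(weights * betas))  # absent models contribute 0
        cond[ti] = float(np.sum(weights * betas) / wsum)
        # revised unconditional SE (absent models: beta = 0, var = 0)
        se_full[ti] = float(
            np.sum(weights * np.sqrt(variances + (betas - full[ti]) ** 2))
            + (1.0 - wsum) * np.abs(0.0 - full[ti])
        )
        se_cond[ti] = float(
            np.sum((weights / wsum) * np.sqrt(variances + (betas - cond[ti]) ** 2))
        )
    z = np.divide(full, se_full, out=np.zeros_like(full), where=se_full > 0)
    p = 2 * stats.norm.sf(np.abs(z))
    return AveragedCoefficients(
        terms=terms,
        full_estimate=full,
        conditional_estimate=cond,
        adjusted_se=se_full,
        conditional_se=se_cond,
        z=z,
        p=p,
        importance=importance,
    )


# ---------------------------------------------------------------------------
# estimated marginal means, contrasts, trends


def _fit_factors(fit: FitResult) -> dict[str, list[str]]:
    """Factors present in a fitted model, with their modelled levels."""
    present = {}
    for factor, levels in FACTOR_LEVELS.items():
        modelled = [lv for lv in levels[1:] if f"{factor}_{lv}" in fit.names]
        if modelled:
            observed = fit.design_info.get("factor_levels", {}).get(
                factor, [levels[0]] + modelled
            )
            present[factor] = observed
    return present


def _grid_row(fit: FitResult, assignment: dict[str, str]) -> np.ndarray:
    """Design row for one factor-level combination; continuous terms at their
    (standardised) means, i.e. zero."""
    row = np.zeros(len(fit.names))
    for j, name in enumerate(fit.names):
        if name == "intercept":
            row[j] = 1.0
        elif ":" in name:
            parts = name.split(":")
            val = 1.0
            for part in parts:
                val *= _term_value(part, assignment)
            row[j] = val
        else:
            row[j] = _term_value(name, assignment)
    return row


def _term_value(name: str, assignment: dict[str, str]) -> float:
    for factor in FACTOR_LEVELS:
        if name.startswith(f"{factor}_"):
            level = name[len(factor) + 1 :]
            return 1.0 if assignment.get(factor) == level else 0.0
    return 0.0  # standardised continuous covariate held at its mean


def emmeans(fit: FitResult, factor: str) -> EmmResult:
    """Estimated marginal means for a categorical factor.

    Link-scale predictions at each level, averaged with equal weights over
    the levels of the other modelled factors; back-transformed by exp with
    delta-method asymptotic CIs. Pairwise contrasts carry Tukey-adjusted p.
    """
    factors = _fit_factors(fit)
    if factor not in factors:
        raise ValueError(f"factor {factor!r} not in the fitted model")
    others = {k: v for k, v in factors.items() if k != factor}
    other_combos = [
        dict(zip(others, combo))
        for combo in itertools.product(*others.values())
    ] or [{}]
    levels = factors[factor]
    L = np.zeros((len(levels), len(fit.names)))
    for i, lv in enumerate(levels):
        rows = [
            _grid_row(fit, {factor: lv, **combo}) for combo in other_combos
        ]
        L[i] = np.mean(rows, axis=0)
    link_mean = L @ fit.beta
    link_var = np.einsum("ij,jk,ik->i", L, fit.vcov, L)
    link_se = np.sqrt(link_var)
    resp = np.exp(link_mean)
    ci_low = np.exp(link_mean - 1.96 * link_se)
    ci_high = np.exp(link_mean + 1.96 * link_se)
    result = EmmResult(
        factor=factor, levels=list(levels), link_mean=link_mean, link_se=link_se,
        response_mean=resp, ci_low=ci_low, ci_high=ci_high,
    )
    result.contrasts = tukey_contrasts(result, fit, L)
    return result


def tukey_adjusted_p(z_stat: float, n_levels: int) -> float:
    """Two-sided p for a pairwise contrast, Tukey-adjusted via the
    studentized-range distribution with infinite error df (normal theory).

    For k = 2 this reduces exactly to the unadjusted two-sided normal p.
    """
    q = abs(z_stat) * np.sqrt(2.0)
    return float(np.clip(stats.studentized_range.sf(q, n_levels, np.inf), 0.0, 1.0))


def tukey_contrasts(e: EmmResult, fit: FitResult, L: np.ndarray) -> pd.DataFrame:
    """All pairwise link-scale contrasts between factor levels."""
    rows = []
    k = len(e.levels)
    for i, j in itertools.combinations(range(k), 2):
        c = L[i] - L[j]
        est = float(c @ fit.beta)
        se = float(np.sqrt(c @ fit.vcov @ c))
        z = est / se if se > 0 else 0.0
        rows.append(
            {
                "contrast": f"{e.levels[i]} - {e.levels[j]}",
                "estimate": est,
                "se": se,
                "z": z,
                "tukey_p": tukey_adjusted_p(z, k) if se > 0 else 1.0,
            }
        )
    return pd.DataFrame(rows)


def marginal_trend(
    fit: FitResult, var: str, by: str | None = None
) -> pd.DataFrame:
    """Link-scale slope of a continuous predictor, optionally per factor level.

    Without an interaction the slope is identical across levels; with a
    var-by-factor interaction the level slope adds the interaction
    coefficient. SEs by the delta method; p from the normal reference.
    """
    if var not in fit.names:
        raise ValueError(f"continuous term {var!r} not in the fitted model")
    j_var = fit.names.index(var)
    levels = ["overall"]
    if by is not None:
        factors = _fit_factors(fit)
        if by not in factors:
            raise ValueError(f"factor {by!r} not in the fitted model")
        levels = factors[by]
    rows = []
    for lv in levels:
        c = np.zeros(len(fit.names))
        c[j_var] = 1.0
        if by is not None:
            for name in (f"{by}_{lv}:{var}", f"{var}:{by}_{lv}"):
                if name in fit.names:
                    c[fit.names.index(name)] = 1.0
        est = float(c @ fit.beta)
        se = float(np.sqrt(c @ fit.vcov @ c))
        z = est / se if se > 0 else 0.0
        p = 2 * stats.norm.sf(abs(z)) if se > 0 else 1.0
        rows.append({"level": lv, "slope": est, "se": se, "z": z, "p": p})
    return pd.DataFrame(rows)


def standardised_effects(avg: AveragedCoefficients) -> pd.DataFrame:
    """Effect-size table: link-scale estimate +/- SE ordered by |estimate|.

    Meaningful as standardised effects when continuous inputs were scaled at
    the design stage (the default).
    """
    tab = avg.table()
    tab = tab[tab["term"] != "intercept"].copy()
    tab["abs_estimate"] = tab["estimate"].abs()
    tab = tab.sort_values(
        ["abs_estimate", "term"], ascending=[False, True], kind="stable"
    ).drop(columns="abs_estimate")
    return tab.reset_index(drop=True)


def dredge(
    samples: pd.DataFrame,
    global_spec: ModelSpec,
    n_quad: int = 15,
    compute_vcov: bool = True,
) -> ModelSet:
    """Fit every marginality-respecting subset of the global model and rank."""
    specs = enumerate_models(global_spec)
    fits = []
    for spec in specs:
        try:
            fits.append(
                fit_model(samples, spec, n_quad=n_quad, compute_vcov=compute_vcov)
                if spec.random_intercept
                else fit_model(samples, spec)
            )
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("fit failed for %s: %s", spec.label, exc)
    return rank_models(fits)
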