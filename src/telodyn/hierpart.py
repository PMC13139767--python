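"""Hierarchical partitioning of model goodness-of-fit (Chevan-Sutherland).

The goodness-of-fit gain of the full model over the null is decomposed into
an independent contribution I per predictor by averaging, over hierarchy
levels h, the mean improvement gof(S + {i}) - gof(S) across all subsets S
of size h not containing i (this is the Shapley value of the gof game).
The joint contribution is J_i = gof({i}) - gof(null) - I_i. A randomisation
test permutes each predictor block independently and flags predictors whose
observed I exceeds the randomised distribution by Z >= 1.65 (upper
one-sided 95%).

Predictor blocks keep a factor's contrast columns together so a categorical
predictor is added or removed as a unit.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gamma_models import fit_gamma_glm, gamma_deviance

logger = logging.getLogger(__name__)


@dataclass
class PartitionResult:
    predictors: list[str]
    independent: np.ndarray  # I, in gof units
    joint: np.ndarray  # J, in gof units
    percent_independent: np.ndarray  # share of sum(I), in %
    gof_measure: str
    total_gof: float  # gof(full) - gof(null)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "predictor": self.predictors,
                "independent": self.independent,
                "joint": self.joint,
                "percent_independent": self.percent_independent,
            }
        )


@dataclass
class RandomisationResult:
    predictors: list[str]
    observed: np.ndarray
    rand_mean: np.ndarray
    rand_sd: np.ndarray
    z: np.ndarray
    significant: np.ndarray  # Z >= 1.65

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "predictor": self.predictors,
                "independent": self.observed,
                "z": self.z,
                "significant": self.significant,
            }
        )


def _gof_function(gof_measure: str):
    """gof(X_subset, y) evaluators. 'loglik' and 'deviance_explained' are
    gamma-GLM based; 'r2' uses an ordinary least-squares R^2 (useful for
    linear toy problems and cross-checks)."""
    if gof_measure == "loglik":
        def gof(X, y):
            return fit_gamma_glm(X, y).loglik
    elif gof_measure == "deviance_explained":
        def gof(X, y):
            null_mu = np.full_like(y, y.mean())
            fit = fit_gamma_glm(X, y)
            return 1.0 - gamma_deviance(y, fit.mu) / gamma_deviance(y, null_mu)
    elif gof_measure == "r2":
        def gof(X, y):
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            ss_tot = np.sum((y - y.mean()) ** 2)
            return float(1.0 - np.sum(resid**2) / ss_tot)
    else:
        raise ValueError(f"unknown gof measure {gof_measure!r}")
    return gof


def all_subsets_gof(
    X_blocks: dict[str, np.ndarray], y: np.ndarray, gof_measure: str = "loglik"
) -> dict[frozenset, float]:
    """Goodness of fit for every subset of predictor blocks (incl. empty).

    Each block holds one predictor's design columns (factor contrasts stay
    together); an intercept is always included. Limited to <= 12 blocks.
    """
    names = list(X_blocks)
    if len(names) > 12:
        raise ValueError("subset lattice limited to 12 predictor blocks")
    y = np.asarray(y, float)
    blocks = {k: np.atleast_2d(np.asarray(v, float).T).T for k, v in X_blocks.items()}
    gof = _gof_function(gof_measure)
    out: dict[frozenset, float] = {}
    ones = np.ones((len(y), 1))
    for r in range(len(names) + 1):
        for subset in itertools.combinations(names, r):
            X = np.hstack([ones] + [blocks[k] for k in subset]) if subset else ones
            out[frozenset(subset)] = gof(X, y)
    return out


def partition(
    gof_map: dict[frozenset, float], gof_measure: str = "loglik"
) -> PartitionResult:
    """Chevan-Sutherland decomposition of a complete gof lattice."""
    full = max(gof_map, key=len)
    names = sorted(full)
    k = len(names)
    expected = 2**k
    if len(gof_map) != expected:
        missing = [
            set(c)
            for r in range(k + 1)
            for c in itertools.combinations(names, r)
            if frozenset(c) not in gof_map
        ]
        raise ValueError(f"incomplete lattice; missing subsets: {missing}")
    I = np.zeros(k)
    for i, name in enumerate(names):
        rest = [n for n in names if n != name]
        level_means = []
        for h in range(k):  # subsets of size h not containing i
            improvements = [
                gof_map[frozenset(S) | {name}] - gof_map[frozenset(S)]
                for S in itertools.combinations(rest, h)
            ]
            level_means.append(np.mean(improvements))
        I[i] = float(np.mean(level_means))
    null = gof_map[frozenset()]
    J = np.array([gof_map[frozenset({n})] - null for n in names]) - I
    total = gof_map[full] - null
    s = I.sum()
    pct = 100.0 * I / s if s != 0 else np.full(k, np.nan)
    return PartitionResult(
        predictors=names,
        independent=I,
        joint=J,
        percent_independent=pct,
        gof_measure=gof_measure,
        total_gof=float(total),
    )


def hierarchical_partition(
    X_blocks: dict[str, np.ndarray], y: np.ndarray, gof_measure: str = "loglik"
) -> PartitionResult:
    """Convenience: lattice + partition in one call."""
    return partition(all_subsets_gof(X_blocks, y, gof_measure), gof_measure)


def randomisation_test(
    X_blocks: dict[str, np.ndarray],
    y: np.ndarray,
    gof_measure: str = "loglik",
    n_rand: int = 999,
    seed: int | None = None,
    z_crit: float = 1.65,
) -> RandomisationResult:
    """Significance of independent contributions by block permutation.

    Each randomisation independently permutes the rows of every predictor
    block (breaking predictor-response and predictor-predictor association),
    recomputes the full partition, and the observed I is compared with the
    randomised distribution: Z = (I_obs - mean I*) / sd I*, significant at
    Z >= 1.65 (upper one-sided 0.95).
    """
    if n_rand < 30:
        logger.warning("n_rand=%d is small; randomisation SD will be unstable", n_rand)
    rng = np.random.default_rng(seed)
    obs = hierarchical_partition(X_blocks, y, gof_measure)
    names = obs.predictors
    rand_I = np.empty((n_rand, len(names)))
    y = np.asarray(y, float)
    for r in range(n_rand):
        perm_blocks = {
            k: np.atleast_2d(np.asarray(v, float).T).T[rng.permutation(len(y))]
            for k, v in X_blocks.items()
        }
        res = hierarchical_partition(perm_blocks, y, gof_measure)
        # res.predictors is sorted; align to obs order
        idx = [res.predictors.index(n) for n in names]
        rand_I[r] = res.independent[idx]
    mean = rand_I.mean(axis=0)
    sd = rand_I.std(axis=0, ddof=1)
    z = np.divide(obs.independent - mean, sd, out=np.zeros(len(names)), where=sd > 0)
    return RandomisationResult(
        predictors=names,
        observed=obs.independent,
        rand_mean=mean,
        rand_sd=sd,
        z=z,
        significant=z >= z_crit,
    )
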