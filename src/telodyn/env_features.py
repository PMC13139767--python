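"""Annual aggregation and PCA reduction of microclimate variables.

Locality-level microclimate series (radiant sky temperature, wind speed,
relative humidity, solar radiation) are aggregated to annual mean/max/min
per locality and, together with elevation, reduced by principal component
analysis on the correlation matrix. On an elevation gradient the leading
component typically captures a joint elevation-humidity-temperature axis
and is used as a single environmental predictor downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MICROCLIMATE_VARIABLES = (
    "elevation",
    "radiant_sky_temperature",
    "wind_speed",
    "relative_humidity",
    "solar_radiation",
)


@dataclass
class PcaResult:
    """Correlation-matrix PCA with a fixed sign convention.

    loadings: (n_variables, n_components), orthonormal columns, each flipped
    so its largest-magnitude entry is positive.
    """

    loadings: np.ndarray
    prop_variance: np.ndarray
    scores: np.ndarray
    centers: np.ndarray
    scales: np.ndarray
    variables: list[str]


def aggregate_annual(monthly: pd.DataFrame) -> pd.DataFrame:
    """Aggregate monthly values to annual mean/max/min per locality/variable.

    ``monthly`` needs columns locality, year, month, variable, value. Output
    is long-form with columns locality, year, variable, stat, value plus an
    n_months QC column; groups with no data simply yield no rows.
    """
    required = {"locality", "year", "month", "variable", "value"}
    missing = required - set(monthly.columns)
    if missing:
        raise ValueError(f"monthly table missing columns {sorted(missing)}")
    g = monthly.groupby(["locality", "year", "variable"])["value"]
    agg = g.agg(mean="mean", max="max", min="min", n_months="count").reset_index()
    out = agg.melt(
        id_vars=["locality", "year", "variable", "n_months"],
        value_vars=["mean", "max", "min"],
        var_name="stat",
        value_name="value",
    )
    return out[["locality", "year", "variable", "stat", "value", "n_months"]].sort_values(
        ["locality", "year", "variable", "stat"], ignore_index=True
    )


def run_pca(data: pd.DataFrame | np.ndarray, variables: list[str] | None = None) -> PcaResult:
    """PCA of centred and scaled columns (correlation-matrix PCA).

    Components are ordered by decreasing explained variance; each loading
    column is sign-flipped so its largest-magnitude entry is positive, making
    orientations reproducible (component orientation is arbitrary and has no
    effect on downstream model fits).
    """
    if isinstance(data, pd.DataFrame):
        variables = list(data.columns)
        X = data.to_numpy(dtype=float)
    else:
        X = np.asarray(data, dtype=float)
        variables = variables or [f"v{i + 1}" for i in range(X.shape[1])]
    n, p = X.shape
    if n < 2 or p < 2:
        raise ValueError("PCA needs >= 2 observations and >= 2 variables")
    if not np.all(np.isfinite(X)):
        raise ValueError("PCA input contains missing or non-finite cells")
    centers = X.mean(axis=0)
    scales = X.std(axis=0, ddof=1)
    const = np.flatnonzero(scales == 0)
    if const.size:
        raise ValueError(f"constant variable(s): {[variables[i] for i in const]}")
    Z = (X - centers) / scales
    # SVD of the standardised matrix == eigen-decomposition of the correlation matrix
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    var = s**2 / (n - 1)
    prop = var / var.sum()
    loadings = Vt.T
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = Z @ loadings
    return PcaResult(
        loadings=loadings,
        prop_variance=prop,
        scores=scores,
        centers=centers,
        scales=scales,
        variables=variables,
    )


def loading_contributions(p: PcaResult, component: int) -> np.ndarray:
    """Percentage contribution of each variable to one component.

    contribution_i = 100 * loading_i**2 / sum_j loading_j**2; sums to 100.
    Components are 1-based.
    """
    if not 1 <= component <= p.loadings.shape[1]:
        raise ValueError(f"component {component} out of range")
    col = p.loadings[:, component - 1]
    return 100.0 * col**2 / np.sum(col**2)


def select_components(p: PcaResult, min_cum_variance: float = 0.85) -> list[int]:
    """Smallest prefix of components reaching the cumulative-variance target.

    Returns 1-based component indices.
    """
    cum = np.cumsum(p.prop_variance)
    k = int(np.searchsorted(cum, min_cum_variance - 1e-12) + 1)
    k = min(k, len(cum))
    return list(range(1, k + 1))


def annual_table_to_wide(
    annual: pd.DataFrame,
    stats: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Pivot the long annual table to one row per (locality, year).

    By default the annual *mean* of each climatic variable is used alongside
    elevation (constant within locality). ``stats`` maps variable -> stat to
    override.
    """
    stats = stats or {v: "mean" for v in MICROCLIMATE_VARIABLES}
    frames = []
    for var, stat in stats.items():
        sub = annual[(annual["variable"] == var) & (annual["stat"] == stat)]
        if sub.empty:
            continue
        frames.append(sub.set_index(["locality", "year"])["value"].rename(var))
    wide = pd.concat(frames, axis=1).reset_index()
    return wide


def environmental_scores(
    annual: pd.DataFrame,
    min_cum_variance: float = 0.85,
    stats: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, PcaResult]:
    """PCA of the locality-year microclimate table.

    Returns (scores table with columns locality, year, env_pc1, env_pc2, ...,
    for the selected leading components; the full PcaResult).
    """
    wide = annual_table_to_wide(annual, stats=stats)
    vars_ = [c for c in wide.columns if c not in ("locality", "year")]
    pca = run_pca(wide[vars_])
    keep = select_components(pca, min_cum_variance)
    out = wide[["locality", "year"]].copy()
    for comp in keep:
        out[f"env_pc{comp}"] = pca.scores[:, comp - 1]
    return out, pca
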