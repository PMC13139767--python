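"""End-to-end pipeline orchestration.

Seven stages: (1) input loading or synthetic generation, (2) qPCR
quantification to rTL, (3) environmental PCA, (4) model dredging and
ranking, (5) multimodel averaging with marginal means/trends/effect sizes,
(6) intrinsic-vs-extrinsic partial models and hierarchical partitioning,
(7) extreme-weather cross-correlation. Every stage writes its tables to the
output directory and a manifest records configuration hash, seed and stage
status, so a run is reproducible byte-for-byte from (inputs, config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .climate import climate_rtl_analysis
from .env_features import environmental_scores
from .gamma_models import (
    ModelSpec,
    aicc,
    deviance_explained,
    fit_model,
    nagelkerke_r2,
)
from .hierpart import hierarchical_partition, randomisation_test
from .io import PipelineConfig, read_microclimate, read_qpcr, read_samples, read_weather
from .qpcr import quantify_plates
from .selection import (
    average_coefficients,
    dredge,
    emmeans,
    marginal_trend,
    standardised_effects,
    subset_model_set,
)
from .synthetic import generate_study

logger = logging.getLogger(__name__)

STAGES = (
    "inputs", "qpcr", "env_pca", "dredge", "averaging", "partitioning", "climate",
)


def _config_hash(config: PipelineConfig) -> str:
    def default(o):
        if hasattr(o, "__dict__"):
            return o.__dict__
        return str(o)

    d = asdict(config)
    d.pop("outdir", None)  # analysis identity must not depend on output location
    blob = json.dumps(d, sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _apply_sensitivity_filters(samples: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    out = samples
    if config.drop_unknown_sex:
        out = out[out["sex"] != "unknown"]
    if config.tissue_subset:
        out = out[out["tissue"] == config.tissue_subset]
    if config.morphotype_subset:
        out = out[out["morphotype"].isin(config.morphotype_subset)]
    return out.reset_index(drop=True)


def _prune_terms(terms: tuple[str, ...], samples: pd.DataFrame) -> tuple[str, ...]:
    """Drop factor terms that no longer vary in a filtered subset."""
    kept = []
    for t in terms:
        if ":" in t:
            if all(p in kept for p in t.split(":")):
                kept.append(t)
            continue
        if t in ("sex", "tissue", "morphotype") and samples[t].nunique() < 2:
            logger.warning("dropping term %r: single level after filtering", t)
            continue
        kept.append(t)
    return tuple(kept)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns a result bundle keyed by stage."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
    }
    results: dict = {"manifest": manifest}

    def done(stage: str) -> None:
        manifest["stages"][stage] = "complete"

    try:
        # 1. inputs -------------------------------------------------------
        if config.synthetic is not None:
            study = generate_study(config.synthetic.with_(seed=config.seed))
            samples = study.samples
            plates = study.plates
            microclimate = study.microclimate
            weather = study.weather
            qpcr_eff = config.qpcr_efficiencies or {
                "telomere": study.truth.e_tel, "scg": study.truth.e_scg,
            }
        else:
            samples = read_samples(config.samples_csv, config.column_rename)
            plates = read_qpcr(config.qpcr_csv, config.column_rename)
            microclimate = read_microclimate(config.microclimate_csv, config.column_rename)
            weather = read_weather(config.weather_csv, config.column_rename)
            qpcr_eff = config.qpcr_efficiencies
        results["samples_in"] = samples
        done("inputs")

        # 2. qPCR quantification ------------------------------------------
        rtl = quantify_plates(plates, thresholds=config.qpcr_thresholds, efficiencies=qpcr_eff)
        rtl.to_csv(outdir / "rtl.csv", index=False)
        # synthetic inputs carry latent truth columns under the same names;
        # the pipeline always models the quantified values
        samples = samples.drop(
            columns=[c for c in ("rtl_raw", "rtl_z", "rtl_shifted") if c in samples.columns]
        )
        samples = samples.merge(
            rtl[["sample_id", "rtl_raw", "rtl_z", "rtl_shifted"]], on="sample_id", how="inner"
        )
        results["rtl"] = rtl
        done("qpcr")

        # 3. environmental PCA --------------------------------------------
        scores, pca = environmental_scores(
            microclimate, min_cum_variance=config.pca_min_cum_variance
        )
        pd.DataFrame(
            {
                "component": np.arange(1, len(pca.prop_variance) + 1),
                "prop_variance": pca.prop_variance,
                "cumulative": np.cumsum(pca.prop_variance),
            }
        ).to_csv(outdir / "pca_variance.csv", index=False)
        pd.DataFrame(pca.loadings, index=pca.variables).to_csv(outdir / "pca_loadings.csv")
        for col in ("env_pc1", "env_pc2"):
            if col in samples.columns:
                samples = samples.drop(columns=col)
        samples = samples.merge(scores, on=["locality", "year"], how="left")
        if "env_pc2" not in samples.columns:
            samples["env_pc2"] = 0.0
        samples["svl"] = samples["svl_mm"] if "svl_mm" in samples.columns else samples["svl"]
        results["pca"] = pca
        results["samples"] = samples
        done("env_pca")

        # 4. dredge the global model --------------------------------------
        samples_m = _apply_sensitivity_filters(samples, config)
        terms = _prune_terms(config.model_terms, samples_m)
        group = "locality" if config.locality_as_group else config.random_intercept
        global_spec = ModelSpec(
            response="rtl_shifted", fixed_terms=terms, random_intercept=group
        )
        ms = dredge(samples_m, global_spec, n_quad=config.n_quad)
        ms.table().to_csv(outdir / "model_set.csv", index=False)
        results["model_set"] = ms
        done("dredge")

        # 5. averaging, marginal means, trends, effect sizes --------------
        subset = subset_model_set(ms, config.averaging_rule, config.averaging_value)
        avg = average_coefficients(subset)
        avg.table().to_csv(outdir / "averaged_coefficients.csv", index=False)
        best = ms.fits[0]
        emm_tables, trend_tables = {}, {}
        for factor in ("sex", "tissue", "morphotype"):
            if any(n.startswith(f"{factor}_") for n in best.names):
                e = emmeans(best, factor)
                emm_tables[factor] = e
                e.contrasts.to_csv(outdir / f"emm_contrasts_{factor}.csv", index=False)
        if "svl" in best.names:
            by = "sex" if any(n.startswith("sex_") for n in best.names) else None
            trend_tables["svl"] = marginal_trend(best, "svl", by=by)
            trend_tables["svl"].to_csv(outdir / "trend_svl.csv", index=False)
        if "env_pc1" in best.names:
            trend_tables["env_pc1"] = marginal_trend(best, "env_pc1")
        effects = standardised_effects(avg)
        effects.to_csv(outdir / "standardised_effects.csv", index=False)
        results.update(avg=avg, emmeans=emm_tables, trends=trend_tables, effects=effects)
        done("averaging")

        # 6. partial models and hierarchical partitioning -----------------
        partial_specs = {
            "full": ("sex", "svl", "env_pc1", "env_pc2"),
            "intrinsic": ("sex", "svl"),
            "extrinsic": ("env_pc1", "env_pc2"),
        }
        null_fit = fit_model(samples_m, ModelSpec(fixed_terms=(), random_intercept=None))
        partial_rows = []
        for name, pterms in partial_specs.items():
            pterms = _prune_terms(pterms, samples_m)
            f = fit_model(samples_m, ModelSpec(fixed_terms=pterms, random_intercept=None))
            partial_rows.append(
                {
                    "model": name,
                    "nagelkerke_r2": nagelkerke_r2(f, null_fit),
                    "deviance_explained": deviance_explained(f, null_fit),
                    "aicc": aicc(f),
                }
            )
        partial = pd.DataFrame(partial_rows)
        partial.to_csv(outdir / "partial_models.csv", index=False)

        from .gamma_models import build_design

        part_terms = tuple(
            t for t in ("tissue", "svl", "sex", "env_pc1", "env_pc2") if t in terms
        )
        blocks = {}
        for t in part_terms:
            d = build_design(samples_m, ModelSpec(fixed_terms=(t,)))
            blocks[t] = d.X[:, 1:]  # strip intercept; keep factor contrasts whole
        y_part = build_design(samples_m, ModelSpec(fixed_terms=part_terms)).y
        hp = hierarchical_partition(blocks, y_part, gof_measure=config.partition_gof)
        rt = randomisation_test(
            blocks, y_part, gof_measure=config.partition_gof,
            n_rand=config.partition_n_rand, seed=config.seed,
        )
        part_table = hp.table().merge(rt.table()[["predictor", "z", "significant"]], on="predictor")
        part_table.to_csv(outdir / "hierarchical_partitioning.csv", index=False)
        results.update(partial_models=partial, partition=hp, partition_test=rt)
        done("partitioning")

        # 7. extreme-weather cross-correlation ----------------------------
        climate = climate_rtl_analysis(
            weather, samples, q=config.climate_q, max_lag=config.climate_max_lag,
            n_perm=config.climate_n_perm, seed=config.seed,
        )
        climate["merged"].to_csv(outdir / "annual_series.csv", index=False)
        report = {}
        for kind in ("drought", "heatwave"):
            ccf = climate[f"{kind}_ccf"]
            ccf.table().to_csv(outdir / f"ccf_{kind}.csv", index=False)
            report[kind] = {
                "r0": float(ccf.r[len(ccf.r) // 2]),
                "perm_p": ccf.perm_p,
                "n_perm": ccf.n_perm,
                "threshold": ccf.threshold,
            }
        with open(outdir / "climate_report.json", "w") as fh:
            json.dump({"seed": config.seed, **report}, fh, indent=2)
        results["climate"] = climate
        done("climate")
    finally:
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return results
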