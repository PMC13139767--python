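"""Input table schemas, validation and pipeline configuration.

Four flat CSV schemas cover the study inputs:

* samples: sample_id, locality, year, sex, svl_mm, tissue, morphotype
* qpcr wells: plate_id, target, sample_id, replicate, is_calibrator and
  either a ``cq`` column or cycle-wise fluorescence columns f1..fN
* microclimate (annual): locality, year, variable, stat, value
* weather (monthly): station, year, month, tmax, tmean, precip

Categorical levels are normalised to lower case on read; out-of-range rows
are flagged, logged and excluded. A column-rename block in the config maps
externally named columns onto these schemas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .qpcr import QpcrPlate, QpcrWell
from .synthetic import StudyConfig

logger = logging.getLogger(__name__)

SAMPLE_COLUMNS = ("sample_id", "locality", "year", "sex", "svl_mm", "tissue", "morphotype")
QPCR_COLUMNS = ("plate_id", "target", "sample_id", "replicate", "is_calibrator")
MICROCLIMATE_COLUMNS = ("locality", "year", "variable", "stat", "value")
WEATHER_COLUMNS = ("station", "year", "month", "tmax", "tmean", "precip")

VALID_LEVELS = {
    "sex": {"female", "male", "unknown"},
    "tissue": {"blood", "tail"},
    "morphotype": {"galloti", "eisentrauti", "insulanagae"},
}


class SchemaError(ValueError):
    """A CSV does not match its expected schema."""


@dataclass
class PipelineConfig:
    """Everything needed for one fully reproducible pipeline run."""

    # exactly one of (input paths) / (synthetic) must be provided
    samples_csv: str | None = None
    qpcr_csv: str | None = None
    microclimate_csv: str | None = None
    weather_csv: str | None = None
    synthetic: StudyConfig | None = None

    qpcr_thresholds: dict = field(default_factory=dict)
    qpcr_efficiencies: dict | None = None
    pca_min_cum_variance: float = 0.85
    model_terms: tuple[str, ...] = (
        "env_pc1", "env_pc2", "sex", "svl", "tissue", "morphotype", "sex:svl",
    )
    random_intercept: str | None = "year"
    n_quad: int = 15
    averaging_rule: str = "all"  # 'all' | 'delta' | 'cumweight'
    averaging_value: float = 2.0
    partition_gof: str = "loglik"
    partition_n_rand: int = 999
    climate_q: float = 0.10
    climate_max_lag: int = 6
    climate_n_perm: int = 5000
    # sensitivity re-runs of the modelling stages on data subsets
    drop_unknown_sex: bool = False
    tissue_subset: str | None = None
    morphotype_subset: tuple[str, ...] | None = None
    locality_as_group: bool = False
    column_rename: dict = field(default_factory=dict)
    outdir: str = "telodyn_out"
    seed: int = 0

    def __post_init__(self) -> None:
        has_paths = any(
            p is not None
            for p in (self.samples_csv, self.qpcr_csv, self.microclimate_csv, self.weather_csv)
        )
        if has_paths and self.synthetic is not None:
            raise ValueError("provide either input CSV paths or a synthetic block, not both")
        if not has_paths and self.synthetic is None:
            raise ValueError("provide input CSV paths or a synthetic block")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            syn = raw["synthetic"]
            for key in ("years", "drought_years", "heat_years"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            if "localities" in syn:
                syn["localities"] = tuple((str(n), float(e)) for n, e in syn["localities"])
            raw["synthetic"] = StudyConfig(**syn)
        for key in ("model_terms", "morphotype_subset"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _require(df: pd.DataFrame, columns: tuple[str, ...], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table missing column(s): {missing}")
    if df.empty:
        raise SchemaError(f"{what} table is empty")


def read_samples(path: str | Path, column_rename: dict | None = None) -> pd.DataFrame:
    df = pd.read_csv(path).rename(columns=column_rename or {})
    _require(df, SAMPLE_COLUMNS, "samples")
    for col in ("sex", "tissue", "morphotype"):
        df[col] = df[col].astype(str).str.lower().str.strip()
        bad = ~df[col].isin(VALID_LEVELS[col]) & df[col].notna()
        if bad.any():
            logger.warning("samples: %d row(s) with invalid %s excluded", bad.sum(), col)
            df = df[~bad]
    bad_svl = df["svl_mm"].notna() & (df["svl_mm"] <= 0)
    if bad_svl.any():
        logger.warning("samples: %d row(s) with non-positive SVL excluded", bad_svl.sum())
        df = df[~bad_svl]
    df = df.copy()
    df["svl"] = df["svl_mm"]
    return df.reset_index(drop=True)


def read_qpcr(path: str | Path, column_rename: dict | None = None) -> list[QpcrPlate]:
    df = pd.read_csv(path).rename(columns=column_rename or {})
    _require(df, QPCR_COLUMNS, "qpcr")
    fluor_cols = sorted(
        (c for c in df.columns if c.startswith("f") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    if "cq" not in df.columns and not fluor_cols:
        raise SchemaError("qpcr table needs a 'cq' column or fluorescence columns f1..fN")
    df["target"] = df["target"].astype(str).str.lower().str.strip()
    plates = []
    for (plate_id, target), sub in df.groupby(["plate_id", "target"], sort=True):
        wells = []
        for _, row in sub.iterrows():
            fluor = None
            if fluor_cols and not row[fluor_cols].isna().any():
                fluor = row[fluor_cols].to_numpy(float)
            cq = float(row["cq"]) if "cq" in df.columns and pd.notna(row.get("cq")) else None
            wells.append(
                QpcrWell(
                    sample_id=str(row["sample_id"]),
                    target=target,
                    plate_id=str(plate_id),
                    replicate=int(row["replicate"]),
                    fluorescence=fluor,
                    cq=cq,
                    is_calibrator=bool(row["is_calibrator"]),
                )
            )
        plates.append(QpcrPlate(plate_id=str(plate_id), target=target, wells=wells))
    return plates


def read_microclimate(path: str | Path, column_rename: dict | None = None) -> pd.DataFrame:
    df = pd.read_csv(path).rename(columns=column_rename or {})
    _require(df, MICROCLIMATE_COLUMNS, "microclimate")
    df["variable"] = df["variable"].astype(str).str.lower().str.strip()
    df["stat"] = df["stat"].astype(str).str.lower().str.strip()
    return df


def read_weather(path: str | Path, column_rename: dict | None = None) -> pd.DataFrame:
    df = pd.read_csv(path).rename(columns=column_rename or {})
    _require(df, WEATHER_COLUMNS, "weather")
    bad = (df["precip"] < 0) | (df["tmax"] < df["tmean"])
    if bad.any():
        logger.warning("weather: %d inconsistent row(s) excluded", int(bad.sum()))
        df = df[~bad]
    return df.reset_index(drop=True)


def plates_to_frame(plates: list[QpcrPlate]) -> pd.DataFrame:
    """Serialise plates to the flat qPCR CSV schema."""
    rows = []
    n_cycles = 0
    for plate in plates:
        for w in plate.wells:
            row = {
                "plate_id": plate.plate_id,
                "target": plate.target,
                "sample_id": w.sample_id,
                "replicate": w.replicate,
                "is_calibrator": w.is_calibrator,
                "cq": w.cq,
            }
            if w.fluorescence is not None:
                n_cycles = max(n_cycles, len(w.fluorescence))
                for i, v in enumerate(w.fluorescence, start=1):
                    row[f"f{i}"] = v
            rows.append(row)
    return pd.DataFrame(rows)


def write_study_inputs(study, outdir: str | Path) -> dict[str, Path]:
    """Write a synthetic study out as the four input CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    samples = study.samples[list(SAMPLE_COLUMNS)]
    paths["samples"] = outdir / "samples.csv"
    samples.to_csv(paths["samples"], index=False)
    paths["qpcr"] = outdir / "qpcr.csv"
    plates_to_frame(study.plates).to_csv(paths["qpcr"], index=False)
    paths["microclimate"] = outdir / "microclimate.csv"
    study.microclimate.to_csv(paths["microclimate"], index=False)
    paths["weather"] = outdir / "weather.csv"
    study.weather.to_csv(paths["weather"], index=False)
    return paths
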