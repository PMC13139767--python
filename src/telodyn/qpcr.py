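"""qPCR relative telomere length (rTL) quantification.

Turns raw amplification data into per-sample relative telomere length via
the efficiency-corrected ratio method (Pfaffl): each sample's telomere
amplicon is normalised to a single-copy gene (SCG) amplicon and referenced
to a pooled calibrator ("gold standard") run on every plate,

    rTL = E_tel ** dCq_tel / E_scg ** dCq_scg,

with dCq = Cq(calibrator) - Cq(sample), so earlier amplification of the
telomere target (more telomeric repeats) yields a larger ratio.

Quantification cycles (Cq) are called from baseline-corrected fluorescence
curves at a constant per-target threshold (defaults 0.171 for telomere
plates and 0.144 for SCG plates). Amplification efficiencies are estimated
per well by a window-of-linearity fit over the exponential phase and
averaged per plate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Constant fluorescence thresholds used to call Cq, per target.
DEFAULT_THRESHOLDS = {"telomere": 0.171, "scg": 0.144}

TARGETS = ("telomere", "scg")


class QpcrError(ValueError):
    """Raised for invalid qPCR inputs (non-amplifying wells, bad plates)."""


class NonAmplifyingWell(QpcrError):
    """The baseline-corrected curve never crosses the threshold."""


@dataclass
class QpcrWell:
    """A single well: one sample x target x replicate.

    Either a per-cycle ``fluorescence`` trace or a pre-called ``cq`` must be
    present. Cycles are implicitly 1..len(fluorescence).
    """

    sample_id: str
    target: str
    plate_id: str
    replicate: int = 1
    fluorescence: np.ndarray | None = None
    cq: float | None = None
    is_calibrator: bool = False

    def __post_init__(self) -> None:
        if self.target not in TARGETS:
            raise QpcrError(f"unknown target {self.target!r}; expected one of {TARGETS}")
        if self.fluorescence is None and self.cq is None:
            raise QpcrError(f"well {self.sample_id}/{self.target}: need fluorescence or cq")
        if self.fluorescence is not None:
            self.fluorescence = np.asarray(self.fluorescence, dtype=float)
            if not np.all(np.isfinite(self.fluorescence)):
                raise QpcrError(f"well {self.sample_id}/{self.target}: non-finite fluorescence")


@dataclass
class QpcrPlate:
    """One plate: a single target, a constant threshold, >=1 calibrator well."""

    plate_id: str
    target: str
    wells: list[QpcrWell] = field(default_factory=list)
    threshold: float | None = None
    no_template_controls: list[QpcrWell] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.threshold is None:
            self.threshold = DEFAULT_THRESHOLDS[self.target]
        for w in self.wells:
            if w.target != self.target:
                raise QpcrError(
                    f"plate {self.plate_id}: well target {w.target!r} != plate target {self.target!r}"
                )

    @property
    def calibrator_wells(self) -> list[QpcrWell]:
        return [w for w in self.wells if w.is_calibrator]


def baseline_correct(fluorescence: np.ndarray, n_baseline: int = 5) -> np.ndarray:
    """Subtract the median of the first ``n_baseline`` cycles."""
    f = np.asarray(fluorescence, dtype=float)
    return f - np.median(f[:n_baseline])


def call_cq(well: QpcrWell, threshold: float) -> float:
    """Fractional cycle of the first upward threshold crossing.

    The curve is baseline-corrected (median of the first five cycles) and the
    crossing located by linear interpolation between the bracketing cycles.
    """
    if well.fluorescence is None:
        raise QpcrError(f"well {well.sample_id}/{well.target}: no fluorescence trace")
    f = baseline_correct(well.fluorescence)
    cycles = np.arange(1, len(f) + 1, dtype=float)
    above = f >= threshold
    # first index where the curve moves from below to at/above the threshold
    idx = np.flatnonzero(above[1:] & ~above[:-1])
    if above[0]:
        raise NonAmplifyingWell(
            f"well {well.sample_id}/{well.target}: already above threshold at cycle 1"
        )
    if idx.size == 0:
        raise NonAmplifyingWell(
            f"well {well.sample_id}/{well.target}: never crosses threshold {threshold}"
        )
    i = int(idx[0])  # crossing between cycles i+1 and i+2 (0-based index i)
    f0, f1 = f[i], f[i + 1]
    return float(cycles[i] + (threshold - f0) / (f1 - f0))


def estimate_efficiency_winol(
    well: QpcrWell,
    window_sizes: Iterable[int] = (4, 5, 6),
    lower_frac: float = 0.05,
    upper_frac: float = 0.80,
) -> float:
    """Amplification efficiency from a window-of-linearity fit.

    log10(fluorescence) is regressed on cycle number over every contiguous
    window of 4-6 readings lying in the exponential phase (between 5% and 80%
    of the plateau signal); the window with the highest coefficient of
    determination wins and efficiency = 10**slope, clipped to (1, 2.2].
    """
    if well.fluorescence is None:
        raise QpcrError(f"well {well.sample_id}/{well.target}: no fluorescence trace")
    f = baseline_correct(well.fluorescence)
    plateau = float(np.max(f))
    if plateau <= 0:
        raise QpcrError(f"well {well.sample_id}/{well.target}: no signal above baseline")
    in_phase = (f >= lower_frac * plateau) & (f <= upper_frac * plateau) & (f > 0)
    cycles = np.arange(1, len(f) + 1, dtype=float)
    best_r2, best_slope = -np.inf, None
    candidates = np.flatnonzero(in_phase)
    for w in window_sizes:
        for start in candidates:
            stop = start + w
            if stop > len(f):
                continue
            if not np.all(in_phase[start:stop]):
                continue
            seg = f[start:stop]
            if np.any(np.diff(seg) <= 0):
                continue  # exponential phase must be strictly increasing
            x, ylog = cycles[start:stop], np.log10(seg)
            slope, intercept = np.polyfit(x, ylog, 1)
            resid = ylog - (slope * x + intercept)
            ss_tot = float(np.sum((ylog - ylog.mean()) ** 2))
            r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else -np.inf
            if r2 > best_r2:
                best_r2, best_slope = r2, slope
    if best_slope is None or best_slope <= 0:
        raise QpcrError(
            f"well {well.sample_id}/{well.target}: no valid window of linearity"
        )
    eff = 10.0**best_slope
    if eff <= 1.0:
        raise QpcrError(f"well {well.sample_id}/{well.target}: efficiency {eff:.3f} <= 1")
    return float(min(eff, 2.2))


def plate_efficiency(plate: QpcrPlate) -> float:
    """Mean window-of-linearity efficiency over wells with a valid window."""
    effs = []
    for w in plate.wells:
        if w.fluorescence is None:
            continue
        try:
            effs.append(estimate_efficiency_winol(w))
        except QpcrError as exc:
            logger.warning("plate %s: %s (excluded from efficiency mean)", plate.plate_id, exc)
    if not effs:
        raise QpcrError(f"plate {plate.plate_id}: no well yielded a valid efficiency")
    return float(np.mean(effs))


def aggregate_triplicates(
    wells: Sequence[QpcrWell], threshold: float, outlier_cycles: float = 1.0
) -> tuple[float, int]:
    """Mean Cq over 1-3 replicate wells after a median-deviation QC rule.

    Wells whose Cq deviates from the replicate median by more than
    ``outlier_cycles`` are excluded (logged). Returns (mean Cq, n retained).
    """
    if not 1 <= len(wells) <= 3:
        raise QpcrError(f"expected 1-3 replicate wells, got {len(wells)}")
    cqs = []
    for w in wells:
        if w.cq is not None:
            cqs.append(float(w.cq))
        else:
            try:
                cqs.append(call_cq(w, threshold))
            except NonAmplifyingWell as exc:
                logger.warning("%s", exc)
    if not cqs:
        raise NonAmplifyingWell(
            f"sample {wells[0].sample_id}/{wells[0].target}: no amplifying replicate"
        )
    cqs = np.asarray(cqs)
    med = np.median(cqs)
    keep = np.abs(cqs - med) <= outlier_cycles
    if not np.all(keep):
        logger.warning(
            "sample %s/%s: excluded %d replicate(s) > %.1f cycles from median",
            wells[0].sample_id, wells[0].target, int((~keep).sum()), outlier_cycles,
        )
    if not np.any(keep):
        raise NonAmplifyingWell(
            f"sample {wells[0].sample_id}/{wells[0].target}: all replicates excluded"
        )
    return float(cqs[keep].mean()), int(keep.sum())


def pfaffl_rtl(e_tel: float, e_scg: float, dcq_tel: float, dcq_scg: float) -> float:
    """Efficiency-corrected relative telomere length.

    ``dcq`` is oriented calibrator minus sample, so a sample amplifying one
    cycle earlier than the calibrator (dcq = +1) at efficiency 2 doubles rTL.
    """
    vals = (e_tel, e_scg, dcq_tel, dcq_scg)
    if not all(math.isfinite(v) for v in vals):
        raise QpcrError(f"non-finite Pfaffl inputs {vals}")
    if not (1.0 < e_tel <= 2.2 and 1.0 < e_scg <= 2.2):
        raise QpcrError(f"efficiencies must lie in (1, 2.2], got {e_tel}, {e_scg}")
    return float(e_tel**dcq_tel / e_scg**dcq_scg)


def standardise(rtl_values: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Z-score raw rTL and shift to a strictly positive modelling response.

    z uses the sample SD (n-1). The conventional shift is +1; when that would
    leave non-positive values (z <= -1) a larger shift of |min(z)| + 0.001 is
    applied instead and a warning logged, since a gamma response must be
    positive.
    """
    x = np.asarray(rtl_values, dtype=float)
    if x.size < 2:
        raise QpcrError("need >= 2 rTL values to standardise")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise QpcrError("zero spread in rTL values; cannot standardise")
    z = (x - x.mean()) / sd
    shift = 1.0
    if np.min(z) + shift <= 0:
        shift = abs(float(np.min(z))) + 0.001
        logger.warning(
            "z-scores below -1 present; using shift %.4f instead of +1 to keep the "
            "response positive", shift,
        )
    return z, z + shift


def quantify_plates(
    plates: Sequence[QpcrPlate],
    thresholds: dict[str, float] | None = None,
    efficiencies: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Full plate-to-rTL pipeline.

    For each target, per plate: call/collect Cq per well, estimate plate
    efficiency (window of linearity, unless ``efficiencies`` overrides),
    average calibrator wells (same replicate QC rule), aggregate sample
    triplicates, and form dCq = Cq(calibrator) - Cq(sample). Samples present
    for both targets get the Pfaffl ratio; the raw ratios are then z-scored
    and positively shifted across the whole dataset.

    Returns a DataFrame with columns sample_id, e_tel, e_scg, dcq_tel,
    dcq_scg, rtl_raw, rtl_z, rtl_shifted, n_used_tel, n_used_scg.
    """
    thresholds = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    per_target: dict[str, dict[str, tuple[float, int]]] = {t: {} for t in TARGETS}
    eff: dict[str, list[float]] = {t: [] for t in TARGETS}

    for plate in plates:
        thr = thresholds[plate.target]
        if efficiencies and plate.target in efficiencies:
            plate_e = efficiencies[plate.target]
        else:
            has_curves = any(w.fluorescence is not None for w in plate.wells)
            plate_e = plate_efficiency(plate) if has_curves else 2.0
        eff[plate.target].append(plate_e)

        cal_wells = plate.calibrator_wells
        if not cal_wells:
            raise QpcrError(f"plate {plate.plate_id}: no calibrator well")
        cal_cq, _ = aggregate_triplicates(cal_wells[:3], thr)

        by_sample: dict[str, list[QpcrWell]] = {}
        for w in plate.wells:
            if not w.is_calibrator:
                by_sample.setdefault(w.sample_id, []).append(w)
        for sid, ws in by_sample.items():
            try:
                mean_cq, n_used = aggregate_triplicates(ws, thr)
            except NonAmplifyingWell as exc:
                logger.warning("dropping %s on %s: %s", sid, plate.plate_id, exc)
                continue
            per_target[plate.target][sid] = (cal_cq - mean_cq, n_used)

    mean_eff = {t: float(np.mean(v)) if v else 2.0 for t, v in eff.items()}
    common = sorted(set(per_target["telomere"]) & set(per_target["scg"]))
    dropped = set(per_target["telomere"]) ^ set(per_target["scg"])
    if dropped:
        logger.warning("samples missing one target, dropped: %s", sorted(dropped))
    rows = []
    for sid in common:
        dcq_tel, n_tel = per_target["telomere"][sid]
        dcq_scg, n_scg = per_target["scg"][sid]
        rows.append(
            {
                "sample_id": sid,
                "e_tel": mean_eff["telomere"],
                "e_scg": mean_eff["scg"],
                "dcq_tel": dcq_tel,
                "dcq_scg": dcq_scg,
                "rtl_raw": pfaffl_rtl(mean_eff["telomere"], mean_eff["scg"], dcq_tel, dcq_scg),
                "n_used_tel": n_tel,
                "n_used_scg": n_scg,
            }
        )
    out = pd.DataFrame(rows)
    if len(out) >= 2:
        z, shifted = standardise(out["rtl_raw"].to_numpy())
        out["rtl_z"], out["rtl_shifted"] = z, shifted
    return out
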