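"""Whole-plate analysis: trim, fit, QC, calibrate, quantify.

This ties the per-well kinetics to the plate-level context: lag phases are
trimmed, both exponential models are fitted and compared per well, the
plate's background-rate statistics and lowest-calibration amplitude are
collected, the six checkpoints are applied, a calibration line is built
from the surviving calibration wells, detection limits are estimated from
the replicates at the lowest included amount, and sample wells are
quantified and normalized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import (
    CalibrationModel,
    QuantResult,
    build_calibration,
    estimate_lod_loq,
    quantify_well,
)
from .curves_io import PlateLayout, ProgressCurve, WellInfo, WellRole
from .kinetics import ExpFitResult, FitConfig, select_model, trim_lag
from .plate_qc import PlateContext, QcFlags, apply_checkpoints

__all__ = ["AnalysisConfig", "WellResult", "PlateResult", "analyze_plate"]


@dataclass
class AnalysisConfig:
    fit: FitConfig = field(default_factory=FitConfig)
    k2_sd_multiplier: float = 1.0
    calibration_range: tuple[float, float] | None = None
    exclude_wells: tuple[str, ...] = ()


@dataclass
class WellResult:
    well_id: str
    info: WellInfo | None
    fit: ExpFitResult | None = None
    qc: QcFlags | None = None
    quant: QuantResult | None = None
    error: str | None = None

    @property
    def usable(self) -> bool:
        return self.fit is not None and self.qc is not None and self.qc.ok


@dataclass
class PlateResult:
    wells: list[WellResult]
    calibration: CalibrationModel | None
    context: PlateContext
    layout: PlateLayout

    def well(self, well_id: str) -> WellResult:
        for w in self.wells:
            if w.well_id == well_id:
                return w
        raise KeyError(well_id)

    def to_frame(self) -> pd.DataFrame:
        """One report row per well (the xlsx/csv 'wells' table)."""
        rows = []
        for w in self.wells:
            f = w.fit
            q = w.quant
            info = w.info
            rows.append({
                "well": w.well_id,
                "role": info.role.value if info else "",
                "nominal_pmol": info.amount_pmol if info else None,
                "sample_id": info.sample_id if info else None,
                "model": f.model if f else None,
                "A1": f.A1 if f else None,
                "se_A1": f.se_A1 if f else None,
                "k1obs": f.k1obs if f else None,
                "se_k1obs": f.se_k1obs if f else None,
                "A2": f.A2 if f else None,
                "se_A2": f.se_A2 if f else None,
                "k2obs": f.k2obs if f else None,
                "se_k2obs": f.se_k2obs if f else None,
                "F0": f.F0 if f else None,
                "se_F0": f.se_F0 if f else None,
                "rss": f.rss if f else None,
                "aicc_single": f.aicc_single if f else None,
                "aicc_double": f.aicc_double if f else None,
                "trim_offset_s": f.trim_offset_s if f else None,
                "converged": f.converged if f else False,
                "qc_pass": w.qc.ok if w.qc else False,
                "qc_flags": ",".join(sorted(c.value for c in w.qc.codes)) if w.qc else "",
                "failure_explanation": (
                    w.error if w.error else (w.qc.explanation() if w.qc else "")
                ),
                "pmol_in_reaction": q.pmol_in_reaction if q else None,
                "quant_flag": q.flag if q else "",
                "normalized_amount": q.normalized_amount if q else None,
                "in_calibration_range": (q.flag != "ABOVE_RANGE") if q and
                    q.pmol_in_reaction is not None else None,
            })
        return pd.DataFrame(rows)


def analyze_plate(
    curves: list[ProgressCurve],
    layout: PlateLayout,
    config: AnalysisConfig | None = None,
) -> PlateResult:
    """Run the full kinetic-analysis pipeline on one plate."""
    config = config or AnalysisConfig()
    rng = np.random.default_rng(config.fit.seed)

    results: list[WellResult] = []
    fits: dict[str, ExpFitResult] = {}
    for curve in curves:
        info = layout.wells.get(curve.well_id)
        wr = WellResult(well_id=curve.well_id, info=info)
        if info is None or info.role is WellRole.EXCLUDED:
            wr.error = "well excluded or absent from layout"
            results.append(wr)
            continue
        try:
            trimmed, offset = trim_lag(curve, config.fit)
            fit = select_model(trimmed, config.fit, rng)
            fit.trim_offset_s = offset
        except ValueError as exc:
            wr.error = str(exc)
            results.append(wr)
            continue
        wr.fit = fit
        fits[curve.well_id] = fit
        results.append(wr)

    ctx = PlateContext.from_plate(fits, layout, k2_sd_multiplier=config.k2_sd_multiplier)
    qc: dict[str, QcFlags] = {}
    for wr in results:
        if wr.fit is None or wr.info is None:
            continue
        wr.qc = apply_checkpoints(wr.fit, ctx, role=wr.info.role)
        qc[wr.well_id] = wr.qc

    calibration = None
    try:
        calibration = build_calibration(
            fits, layout, qc,
            range_selection=config.calibration_range,
            exclude_wells=config.exclude_wells,
        )
        low = min(p.amount_pmol for p in calibration.points if p.included)
        reps = [p.A1 for p in calibration.points if p.included and p.amount_pmol == low]
        estimate_lod_loq(calibration, reps if len(reps) >= 2 else None)
    except ValueError:
        pass

    if calibration is not None and calibration.usable:
        for wr in results:
            if wr.info is None or wr.fit is None or wr.qc is None:
                continue
            if wr.info.role is not WellRole.SAMPLE:
                continue
            wr.quant = quantify_well(wr.fit, calibration, wr.info, wr.qc)
            wr.quant.well_id = wr.well_id

    return PlateResult(wells=results, calibration=calibration, context=ctx, layout=layout)
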