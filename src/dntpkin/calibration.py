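"""A1-based calibration, LOD/LOQ, quantification and assay statistics.

The fast-phase amplitude A1 is directly proportional to the amount of the
limiting dNTP in the reaction, and — unlike the observed rates — is not
perturbed by matrix effects of biological extracts.  Quantification is
therefore a straight line A1 = slope * amount + intercept fitted over the
QC-passing calibration wells, inverted for unknown wells, followed by
normalization to a fixed cell count (1e6 cells for human, 1e8 CFU for
bacterial samples).

Detection limits follow two routes: the lowest calibration amount whose
wells still support a reliable double-exponential fit (method A), and the
3*SD (LOD) / 5*SD (LOQ) of replicate A1 values at the lowest calibration
point, expressed on the amount axis through the slope (method B).  When
method B falls below the lowest resolvable calibration point, the latter is
reported instead.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .curves_io import PlateLayout, WellInfo, WellRole, _BASES
from .kinetics import ExpFitResult
from .plate_qc import QcFlags

__all__ = [
    "CalibrationPoint",
    "CalibrationModel",
    "QuantResult",
    "build_calibration",
    "estimate_lod_loq",
    "quantify_well",
    "normalize_amount",
    "cv_percent",
    "accuracy_percent",
    "recovery_percent",
    "assay_statistics",
]


@dataclass
class CalibrationPoint:
    well_id: str
    amount_pmol: float
    A1: float | None
    included: bool
    reason: str = ""


@dataclass
class CalibrationModel:
    """Linear A1-vs-amount model with detection limits."""

    dntp_species: str
    slope: float
    intercept: float
    r_squared: float
    fitted_range: tuple[float, float]
    points: list[CalibrationPoint] = field(default_factory=list)
    se_slope: float = math.nan
    se_intercept: float = math.nan
    lod_pmol: float | None = None
    loq_pmol: float | None = None

    def __post_init__(self) -> None:
        if self.lod_pmol is not None and self.loq_pmol is not None:
            if self.lod_pmol > self.loq_pmol:
                raise ValueError("LOD must not exceed LOQ")

    @property
    def usable(self) -> bool:
        return self.slope > 0

    def amount_from_A1(self, A1: float) -> float:
        return (A1 - self.intercept) / self.slope

    def A1_from_amount(self, amount_pmol: float) -> float:
        return self.slope * amount_pmol + self.intercept

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "dntp_species": self.dntp_species,
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "se_slope": self.se_slope,
            "se_intercept": self.se_intercept,
            "fitted_range": list(self.fitted_range),
            "lod_pmol": self.lod_pmol,
            "loq_pmol": self.loq_pmol,
            "points": [
                {"well_id": p.well_id, "amount_pmol": p.amount_pmol, "A1": p.A1,
                 "included": p.included, "reason": p.reason}
                for p in self.points
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "CalibrationModel":
        points = [CalibrationPoint(**p) for p in data.get("points", [])]
        return cls(
            dntp_species=data["dntp_species"], slope=data["slope"],
            intercept=data["intercept"], r_squared=data["r_squared"],
            fitted_range=tuple(data["fitted_range"]), points=points,
            se_slope=data.get("se_slope", math.nan),
            se_intercept=data.get("se_intercept", math.nan),
            lod_pmol=data.get("lod_pmol"), loq_pmol=data.get("loq_pmol"),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CalibrationModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def build_calibration(
    fits: dict[str, ExpFitResult],
    layout: PlateLayout,
    qc: dict[str, QcFlags] | None = None,
    range_selection: tuple[float, float] | None = None,
    exclude_wells: tuple[str, ...] = (),
) -> CalibrationModel:
    """Ordinary least-squares line through the usable (amount, A1) points.

    Blanks never enter; QC-flagged wells and wells whose double fit failed
    (recorded as "under the detection limit") are excluded but kept in
    ``points`` with their reason, so a user can audit — and, via
    ``exclude_wells``, iteratively refine — the calibration.
    """
    qc = qc or {}
    points: list[CalibrationPoint] = []
    for well, info in sorted(layout.wells_with_role(WellRole.CALIBRATION).items()):
        fit = fits.get(well)
        if fit is None or not fit.converged:
            points.append(CalibrationPoint(well, info.amount_pmol, None, False,
                                           "under the detection limit (no fit)"))
            continue
        if fit.model != "double":
            points.append(CalibrationPoint(well, info.amount_pmol, None, False,
                                           "under the detection limit (double fit failed)"))
            continue
        flags = qc.get(well)
        if flags is not None and not flags.ok:
            points.append(CalibrationPoint(well, info.amount_pmol, fit.A1, False,
                                           f"QC failed: {flags.explanation()}"))
            continue
        if well in exclude_wells:
            points.append(CalibrationPoint(well, info.amount_pmol, fit.A1, False,
                                           "excluded by user"))
            continue
        if range_selection is not None and not (
            range_selection[0] <= info.amount_pmol <= range_selection[1]
        ):
            points.append(CalibrationPoint(well, info.amount_pmol, fit.A1, False,
                                           "outside selected range"))
            continue
        points.append(CalibrationPoint(well, info.amount_pmol, fit.A1, True))

    used = [p for p in points if p.included]
    amounts = np.array([p.amount_pmol for p in used])
    a1s = np.array([p.A1 for p in used])
    if len(used) < 2:
        raise ValueError("need >= 2 usable calibration points")
    if np.unique(amounts).size < 2:
        raise ValueError("calibration points all at one amount")

    res = stats.linregress(amounts, a1s)
    return CalibrationModel(
        dntp_species=layout.dntp_species,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue ** 2),
        se_slope=float(res.stderr),
        se_intercept=float(res.intercept_stderr),
        fitted_range=(float(amounts.min()), float(amounts.max())),
        points=points,
    )


def estimate_lod_loq(
    calib: CalibrationModel,
    low_point_A1_replicates=None,
) -> tuple[float, float]:
    """Detection/quantification limits in pmol; sets them on ``calib``.

    Method A is the lowest calibration amount that still produced usable
    fits; method B is 3*SD (LOD) or 5*SD (LOQ) of the replicate A1 values
    at that amount, divided by the slope.  The larger of the two is
    reported, so a mathematically tiny method-B value never undercuts the
    lowest resolvable point.
    """
    included = [p for p in calib.points if p.included]
    if not included:
        raise ValueError("calibration has no included points")
    method_a = min(p.amount_pmol for p in included)

    if low_point_A1_replicates is None:
        reps = [p.A1 for p in included if p.amount_pmol == method_a]
    else:
        reps = list(low_point_A1_replicates)
    if len(reps) < 2:
        warnings.warn(
            "no replicates at the lowest calibration amount; "
            "LOD/LOQ from the lowest fittable point only",
            stacklevel=2,
        )
        lod = loq = method_a
    else:
        sd = float(np.std(reps, ddof=1))
        lod = max(3.0 * sd / calib.slope, method_a)
        loq = max(5.0 * sd / calib.slope, method_a)
    calib.lod_pmol, calib.loq_pmol = float(lod), float(loq)
    return calib.lod_pmol, calib.loq_pmol


@dataclass
class QuantResult:
    """Quantified dNTP amount for one well."""

    well_id: str
    pmol_in_reaction: float | None
    flag: str  # OK | BELOW_LOD | BELOW_LOQ | ABOVE_RANGE | QC_FAILED
    normalized_amount: float | None = None
    sample_id: str | None = None
    explanation: str = ""


def quantify_well(
    fit: ExpFitResult,
    calib: CalibrationModel,
    info: WellInfo | None = None,
    qc: QcFlags | None = None,
) -> QuantResult:
    """Invert the calibration line for one well's A1."""
    well_id = getattr(fit, "well_id", None) or ""
    sample_id = info.sample_id if info is not None else None
    if qc is not None and not qc.ok:
        return QuantResult(well_id, None, "QC_FAILED",
                           sample_id=sample_id, explanation=qc.explanation())
    if not calib.usable:
        raise ValueError("calibration not usable (non-positive slope)")
    pmol = calib.amount_from_A1(fit.A1)
    if pmol > calib.fitted_range[1]:
        flag = "ABOVE_RANGE"
    elif calib.lod_pmol is not None and pmol < calib.lod_pmol:
        flag = "BELOW_LOD"
    elif calib.loq_pmol is not None and pmol < calib.loq_pmol:
        flag = "BELOW_LOQ"
    else:
        flag = "OK"
    normalized = None
    if info is not None and info.has_normalization_meta:
        normalized = normalize_amount(
            pmol,
            dilution_factor=info.dilution_factor,
            extract_volume_ul=info.extract_volume_ul,
            assayed_volume_ul=info.assayed_volume_ul,
            cells_extracted=info.cells_extracted,
            basis=info.basis,
        )
    return QuantResult(well_id, float(pmol), flag,
                       normalized_amount=normalized, sample_id=sample_id)


def normalize_amount(
    pmol_in_reaction: float,
    *,
    dilution_factor: float = 1.0,
    extract_volume_ul: float,
    assayed_volume_ul: float,
    cells_extracted: float,
    basis: str,
) -> float:
    """Scale a per-reaction amount up to the whole extract and a fixed
    cell count (pmol per 1e6 cells or per 1e8 CFU)."""
    if basis not in _BASES:
        raise ValueError(f"basis must be one of {sorted(_BASES)}")
    if extract_volume_ul <= 0 or assayed_volume_ul <= 0:
        raise ValueError("volumes must be positive")
    if cells_extracted <= 0:
        raise ValueError("cells_extracted must be positive")
    total = pmol_in_reaction * dilution_factor * (extract_volume_ul / assayed_volume_ul)
    return total * _BASES[basis] / cells_extracted


# ---------------------------------------------------------------------------
# assay performance statistics


def cv_percent(values) -> float:
    """Coefficient of variation, 100 * sample SD / mean."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("CV needs >= 2 replicates")
    return float(100.0 * np.std(values, ddof=1) / np.mean(values))


def accuracy_percent(measured, nominal) -> float:
    """100 * mean(measured / nominal)."""
    measured = np.asarray(measured, dtype=float)
    return float(100.0 * np.mean(measured / np.asarray(nominal, dtype=float)))


def recovery_percent(measured_spiked, measured_unspiked, amount_added) -> float:
    """Standard-addition recovery, 100 * (spiked - unspiked) / added."""
    s = np.asarray(measured_spiked, dtype=float)
    u = np.asarray(measured_unspiked, dtype=float)
    a = np.asarray(amount_added, dtype=float)
    if np.any(a <= 0):
        raise ValueError("amount_added must be positive")
    return float(100.0 * np.mean((s - u) / a))


def assay_statistics(
    replicates: pd.DataFrame,
    spiked: pd.DataFrame | None = None,
) -> dict:
    """Intra-/inter-assay CV, low/high accuracy and recovery.

    ``replicates`` needs columns ``plate``, ``nominal_pmol``,
    ``measured_pmol``: technical replicates of the same nominal amount
    within a plate drive the intra-assay CV, plate means across plates the
    inter-assay CV; per-level CVs are averaged.  Accuracy is evaluated at
    the lowest and highest nominal amounts.  ``spiked`` (optional) needs
    ``measured_spiked``, ``measured_unspiked``, ``added_pmol`` for
    standard-addition recovery.
    """
    required = {"plate", "nominal_pmol", "measured_pmol"}
    if not required.issubset(replicates.columns):
        raise ValueError(f"replicates needs columns {sorted(required)}")

    intra = [
        cv_percent(grp["measured_pmol"])
        for _, grp in replicates.groupby(["plate", "nominal_pmol"])
    ]
    plate_means = (
        replicates.groupby(["nominal_pmol", "plate"])["measured_pmol"].mean().reset_index()
    )
    inter = []
    for _, grp in plate_means.groupby("nominal_pmol"):
        if len(grp) >= 2:
            inter.append(cv_percent(grp["measured_pmol"]))
    lo = replicates["nominal_pmol"].min()
    hi = replicates["nominal_pmol"].max()
    sel_lo = replicates[replicates["nominal_pmol"] == lo]
    sel_hi = replicates[replicates["nominal_pmol"] == hi]

    out = {
        "intra_cv": float(np.mean(intra)),
        "inter_cv": float(np.mean(inter)) if inter else math.nan,
        "accuracy_low": accuracy_percent(sel_lo["measured_pmol"], lo),
        "accuracy_high": accuracy_percent(sel_hi["measured_pmol"], hi),
        "recovery": math.nan,
    }
    if spiked is not None:
        out["recovery"] = recovery_percent(
            spiked["measured_spiked"], spiked["measured_unspiked"], spiked["added_pmol"]
        )
    return out
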