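"""Synthetic progress curves and plates with known ground truth.

Every stage of the pipeline is testable without instrument data: curves
are forward evaluations of the single/double exponential models on an
acquisition schedule with additive Gaussian read noise, an optional flat
lag phase, and a matrix-inhibition factor that slows both rate constants
of sample wells without touching the amplitudes — emulating the central
property of real extracts, where matrix components slow the reaction but
leave the quantification readout (A1) intact.

Defaults reproduce the observed assay conditions: a blank reaction with a
single slow phase (k ~ 2e-4 s^-1), specific reactions with k1 ~ 2.5e-3 and
k2 ~ 1.1e-4 s^-1 around a plateau near 3.5e4 fluorescence units, total
amplitude ~3e4, a split-time schedule (100 cycles of 13 s then 200 of
80 s) and calibration amounts spanning 0.5-12 pmol in duplicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .binding import QuadraticBindingFit, eval_quadratic_binding
from .curves_io import (
    AcquisitionSchedule,
    PlateLayout,
    ProgressCurve,
    WellInfo,
    WellRole,
    expand_schedule,
)
from .kinetics import model_double, model_single

__all__ = ["PlateSpec", "synth_curve", "synth_plate"]

_DEFAULT_SCHEDULE = AcquisitionSchedule(((100, 13.0), (200, 80.0)))


@dataclass
class PlateSpec:
    """Ground-truth description of a synthetic 96-well plate.

    The calibration law maps amount -> A1 either linearly
    (``slope * amount + intercept``) or through quadratic-binding
    competition parameters (``binding_params``: A1 = relA1(amount) *
    total_amplitude).  In both cases A2 = total_amplitude - A1, mirroring
    the observed amplitude competition at constant total signal.
    ``matrix_factor`` scales k1 and k2 of sample wells only.
    """

    calibration_amounts: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0, 8.0, 12.0)
    calibration_replicates: int = 2
    n_blanks: int = 2
    sample_amounts: tuple[float, ...] = (1.5, 3.0, 6.0)
    sample_replicates: int = 2
    slope: float = 2100.0
    intercept: float = 0.0
    binding_params: QuadraticBindingFit | None = None
    total_amplitude: float = 29878.0
    F0: float = 35540.0
    k1: float = 2.5e-3
    k2: float = 1.1e-4
    k_jitter: float = 0.10
    blank_A: float = 28869.0
    blank_k: float = 2.0e-4
    blank_F0: float = 35978.0
    noise_sd: float | None = None
    noise_frac: float = 0.01
    lag_s: float = 0.0
    matrix_factor: float = 1.0
    schedule: AcquisitionSchedule = _DEFAULT_SCHEDULE
    seed: int = 0
    dntp_species: str = "dGTP"

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.calibration_amounts + self.sample_amounts):
            raise ValueError("amounts must be >= 0")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")
        if not (0 < self.matrix_factor <= 1):
            raise ValueError("matrix_factor must be in (0, 1]")
        if not isinstance(self.schedule, AcquisitionSchedule):
            self.schedule = AcquisitionSchedule(tuple(tuple(s) for s in self.schedule))

    @property
    def effective_noise_sd(self) -> float:
        if self.noise_sd is not None:
            return self.noise_sd
        return self.noise_frac * self.total_amplitude

    def a1_for_amount(self, amount_pmol: float) -> float:
        if self.binding_params is not None:
            rel = eval_quadratic_binding(self.binding_params, amount_pmol)
            a1 = rel * self.total_amplitude
        else:
            a1 = self.slope * amount_pmol + self.intercept
        if not (0 <= a1 < self.total_amplitude):
            raise ValueError(
                f"calibration law gives A1={a1:.1f} outside [0, total_amplitude) "
                f"for {amount_pmol} pmol"
            )
        return a1

    @classmethod
    def from_yaml(cls, path) -> "PlateSpec":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "schedule" in data:
            data["schedule"] = AcquisitionSchedule(
                tuple((int(n), float(s)) for n, s in data["schedule"])
            )
        if "binding_params" in data and data["binding_params"] is not None:
            data["binding_params"] = QuadraticBindingFit(**data["binding_params"])
        for key in ("calibration_amounts", "sample_amounts"):
            if key in data:
                data[key] = tuple(float(x) for x in data[key])
        known = set(cls.__dataclass_fields__)
        return cls(**{k: v for k, v in data.items() if k in known})


def synth_curve(
    well_id: str,
    params: Mapping[str, float],
    schedule: AcquisitionSchedule,
    noise_sd: float = 0.0,
    lag_s: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> ProgressCurve:
    """Forward-evaluate one model curve on a schedule, with noise and lag.

    ``params`` holds either (A, k, F0) for a single-exponential well or
    (A1, k1, A2, k2, F0) for a double one.  The lag holds the signal at
    F(0) for t < lag_s and shifts the model afterwards, the simplest shape
    consistent with the flat starts seen on raw curves.  Identical seeds
    give identical curves.
    """
    if noise_sd < 0:
        raise ValueError("noise SD must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    times = expand_schedule(schedule)
    if "A1" in params:
        def f(t):
            return model_double(t, params["A1"], params["k1"],
                                params["A2"], params["k2"], params["F0"])
    else:
        def f(t):
            return model_single(t, params["A"], params["k"], params["F0"])
    shifted = np.where(times < lag_s, 0.0, times - lag_s)
    values = f(shifted)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=times.size)
    return ProgressCurve(
        well_id=well_id, times_s=times, fluorescence=values,
        meta={"truth": dict(params), "lag_s": lag_s, "noise_sd": noise_sd},
    )


def _well_ids():
    for row in "ABCDEFGH":
        for col in range(1, 13):
            yield f"{row}{col}"


def synth_plate(spec: PlateSpec) -> tuple[list[ProgressCurve], PlateLayout, pd.DataFrame]:
    """Generate curves, layout and a truth table for a whole plate.

    Wells are laid out row-major: blanks, then calibration replicates,
    then sample replicates.  The truth table records every generating
    parameter, so any downstream estimate can be compared to its ground
    truth; all randomness flows from ``spec.seed``.
    """
    n_wells = (
        spec.n_blanks
        + len(spec.calibration_amounts) * spec.calibration_replicates
        + len(spec.sample_amounts) * spec.sample_replicates
    )
    if n_wells > 96:
        raise ValueError(f"{n_wells} wells exceed the 96-well plate")

    rng = np.random.default_rng(spec.seed)
    ids = _well_ids()
    noise_sd = spec.effective_noise_sd

    curves: list[ProgressCurve] = []
    wells: dict[str, WellInfo] = {}
    rows: list[dict] = []

    def jittered(k: float) -> float:
        return k * (1.0 + rng.uniform(-spec.k_jitter, spec.k_jitter))

    for _ in range(spec.n_blanks):
        wid = next(ids)
        params = {"A": spec.blank_A, "k": jittered(spec.blank_k), "F0": spec.blank_F0}
        curves.append(synth_curve(wid, params, spec.schedule, noise_sd, spec.lag_s, rng))
        wells[wid] = WellInfo(role=WellRole.BLANK)
        rows.append({"well": wid, "role": "blank", "amount_pmol": 0.0, "model": "single",
                     "A1": params["A"], "k1": params["k"], "A2": np.nan, "k2": np.nan,
                     "F0": params["F0"], "lag_s": spec.lag_s, "matrix_factor": 1.0,
                     "noise_sd": noise_sd})

    def double_params(amount: float, factor: float) -> dict:
        a1 = spec.a1_for_amount(amount)
        return {
            "A1": a1, "k1": jittered(spec.k1) * factor,
            "A2": spec.total_amplitude - a1, "k2": jittered(spec.k2) * factor,
            "F0": spec.F0,
        }

    for amount in spec.calibration_amounts:
        for _ in range(spec.calibration_replicates):
            wid = next(ids)
            params = double_params(amount, 1.0)
            curves.append(synth_curve(wid, params, spec.schedule, noise_sd, spec.lag_s, rng))
            wells[wid] = WellInfo(role=WellRole.CALIBRATION, amount_pmol=amount)
            rows.append({"well": wid, "role": "calibration", "amount_pmol": amount,
                         "model": "double", **params, "lag_s": spec.lag_s,
                         "matrix_factor": 1.0, "noise_sd": noise_sd})

    for i, amount in enumerate(spec.sample_amounts):
        for _ in range(spec.sample_replicates):
            wid = next(ids)
            params = double_params(amount, spec.matrix_factor)
            curves.append(synth_curve(wid, params, spec.schedule, noise_sd, spec.lag_s, rng))
            wells[wid] = WellInfo(
                role=WellRole.SAMPLE, sample_id=f"S{i + 1}",
                extract_volume_ul=50.0, assayed_volume_ul=10.0,
                cells_extracted=5e5, basis="per_1e6_cells",
            )
            rows.append({"well": wid, "role": "sample", "amount_pmol": amount,
                         "model": "double", **params, "lag_s": spec.lag_s,
                         "matrix_factor": spec.matrix_factor, "noise_sd": noise_sd})

    layout = PlateLayout(wells=wells, dntp_species=spec.dntp_species)
    truth = pd.DataFrame(rows)
    return curves, layout, truth
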