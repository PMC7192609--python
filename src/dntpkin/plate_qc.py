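"""Analysis checkpoints that invalidate unreliable wells.

Six checks mirror the failure modes of low-quality plate data: inseparable
kinetic phases (a single-exponential curve overfitted by the double model),
an A1 standard error exceeding A1 itself, a fast rate indistinguishable
from the plate's background-hydrolysis rates, an implausibly slow
background phase, an inverse (falling) run, and a total signal change less
than half that of the lowest calibration point.  Any flag removes the well
from calibration and quantification; the flag's explanation surfaces in the
report so the failure is transparent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .curves_io import PlateLayout, WellRole
from .kinetics import ExpFitResult

__all__ = ["Checkpoint", "QcFlags", "PlateContext", "apply_checkpoints"]

K2_SLOW_THRESHOLD = 1e-5  # s^-1; background hydrolysis slower than this is suspect


class Checkpoint(str, Enum):
    INSEPARABLE_PHASES = "INSEPARABLE_PHASES"
    A1_ERROR_EXCEEDS_VALUE = "A1_ERROR_EXCEEDS_VALUE"
    K1_WITHIN_K2_RANGE = "K1_WITHIN_K2_RANGE"
    K2_TOO_SLOW = "K2_TOO_SLOW"
    A1_NEGATIVE = "A1_NEGATIVE"
    SIGNAL_TOO_SMALL = "SIGNAL_TOO_SMALL"
    NOT_CONVERGED = "NOT_CONVERGED"


_EXPLANATIONS = {
    Checkpoint.INSEPARABLE_PHASES: (
        "single-exponential fit preferred: the specific and background "
        "phases could not be separated"
    ),
    Checkpoint.A1_ERROR_EXCEEDS_VALUE: "standard error of A1 exceeds A1 itself",
    Checkpoint.K1_WITHIN_K2_RANGE: (
        "k1obs falls within the error range of the plate-average k2obs"
    ),
    Checkpoint.K2_TOO_SLOW: "k2obs below 1e-5 s^-1",
    Checkpoint.A1_NEGATIVE: "fitted A1 negative (inverse run of the exponential)",
    Checkpoint.SIGNAL_TOO_SMALL: (
        "total signal change below 50% of the lowest calibration point's"
    ),
    Checkpoint.NOT_CONVERGED: "neither exponential model converged",
}


@dataclass
class QcFlags:
    """Checkpoint outcomes for one well; empty flags = usable well."""

    flags: dict[Checkpoint, str] = field(default_factory=dict)
    not_evaluated: tuple[str, ...] = ()

    @property
    def ok(self) -> bool:
        return not self.flags

    @property
    def codes(self) -> set[Checkpoint]:
        return set(self.flags)

    def explanation(self) -> str:
        return "; ".join(self.flags.values())

    def _add(self, code: Checkpoint) -> None:
        self.flags[code] = _EXPLANATIONS[code]


@dataclass
class PlateContext:
    """Plate-level statistics the checkpoints compare against.

    ``mean_k2obs``/``sd_k2obs`` summarize the background-hydrolysis rate of
    all converged double-model wells on the plate;
    ``lowest_calibration_total_amplitude`` is the fitted total signal change
    (A1 + A2) of the lowest calibration point, averaged over its replicates.
    Fields left ``None`` make the corresponding checkpoint unevaluable.
    """

    mean_k2obs: float | None = None
    sd_k2obs: float | None = None
    lowest_calibration_total_amplitude: float | None = None
    k2_sd_multiplier: float = 1.0

    @classmethod
    def from_plate(
        cls,
        fits: dict[str, ExpFitResult],
        layout: PlateLayout,
        k2_sd_multiplier: float = 1.0,
    ) -> "PlateContext":
        k2 = [
            f.k2obs for f in fits.values()
            if f is not None and f.model == "double" and f.converged
        ]
        mean_k2 = float(np.mean(k2)) if len(k2) >= 2 else None
        sd_k2 = float(np.std(k2, ddof=1)) if len(k2) >= 2 else None

        lowest_amp = None
        cal = layout.wells_with_role(WellRole.CALIBRATION)
        usable = {
            w: info for w, info in cal.items()
            if w in fits and fits[w] is not None
            and fits[w].model == "double" and fits[w].converged
        }
        if usable:
            lo = min(info.amount_pmol for info in usable.values())
            amps = [
                fits[w].total_amplitude
                for w, info in usable.items() if info.amount_pmol == lo
            ]
            lowest_amp = float(np.mean(amps))
        return cls(
            mean_k2obs=mean_k2,
            sd_k2obs=sd_k2,
            lowest_calibration_total_amplitude=lowest_amp,
            k2_sd_multiplier=k2_sd_multiplier,
        )


def apply_checkpoints(
    fit: ExpFitResult,
    ctx: PlateContext,
    role: WellRole = WellRole.SAMPLE,
) -> QcFlags:
    """Evaluate the six checkpoints on one fitted well.

    Blank wells are exempt from the inseparable-phases check (they are
    expected to be single-exponential).  Checkpoints whose plate context is
    missing are skipped and listed in ``not_evaluated``.  The boundary of
    the slow-background check is strict: k2obs exactly at 1e-5 s^-1 does
    not flag.
    """
    qc = QcFlags()
    if not fit.converged:
        qc._add(Checkpoint.NOT_CONVERGED)
        return qc

    expects_specific = role in (WellRole.CALIBRATION, WellRole.SAMPLE)

    # (i) inseparable kinetic phases
    if fit.model == "single" and expects_specific:
        qc._add(Checkpoint.INSEPARABLE_PHASES)

    if fit.model == "double":
        # (ii) error of the key parameter exceeds its value
        if math.isnan(fit.se_A1) or fit.se_A1 > fit.A1:
            qc._add(Checkpoint.A1_ERROR_EXCEEDS_VALUE)
        # (iii) fast rate within the error range of the plate-average slow rate
        if ctx.mean_k2obs is None or ctx.sd_k2obs is None:
            qc.not_evaluated += (Checkpoint.K1_WITHIN_K2_RANGE.value,)
        elif abs(fit.k1obs - ctx.mean_k2obs) <= ctx.k2_sd_multiplier * ctx.sd_k2obs:
            qc._add(Checkpoint.K1_WITHIN_K2_RANGE)
        # (iv) background phase implausibly slow (strictly below threshold)
        if fit.k2obs < K2_SLOW_THRESHOLD:
            qc._add(Checkpoint.K2_TOO_SLOW)
        # (v) inverse run: raw fast amplitude fitted negative
        if fit.raw_A1 is not None and fit.raw_A1 < 0:
            qc._add(Checkpoint.A1_NEGATIVE)

    # (vi) signal change under half the lowest calibration point's
    if ctx.lowest_calibration_total_amplitude is None:
        qc.not_evaluated += (Checkpoint.SIGNAL_TOO_SMALL.value,)
    elif fit.total_amplitude < 0.5 * ctx.lowest_calibration_total_amplitude:
        qc._add(Checkpoint.SIGNAL_TOO_SMALL)

    return qc
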