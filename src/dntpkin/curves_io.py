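"""Instrument-export parsing, plate layouts and report writing.

The assay records one fluorescence reading per thermal cycle in a 96-well
plate.  Exports from real-time PCR instruments are mapped onto a canonical
long table (well, time_s, fluorescence); cycle-indexed ("wide") exports are
converted using an :class:`AcquisitionSchedule` that describes the cycling
program, including split-time programs with short early cycles and long
late cycles.
"""

from __future__ import annotations

import ast
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "AcquisitionSchedule",
    "ProgressCurve",
    "WellRole",
    "WellInfo",
    "PlateLayout",
    "WellReadError",
    "expand_schedule",
    "read_plate_export",
    "read_layout",
    "write_curves",
    "write_report",
    "read_report",
]

_WELL_RE = re.compile(r"^[A-H](?:[1-9]|1[0-2])$")


def _check_well_id(well_id: str) -> str:
    well_id = str(well_id).strip().upper()
    # tolerate zero-padded instrument coordinates such as "A01"
    m = re.match(r"^([A-H])0?([1-9]|1[0-2])$", well_id)
    if not m:
        raise ValueError(f"not a plate coordinate (A1..H12): {well_id!r}")
    return f"{m.group(1)}{m.group(2)}"


@dataclass(frozen=True)
class AcquisitionSchedule:
    """Cycling program as (cycle_count, cycle_length_s) segments.

    Split-time acquisition uses a short cycle length early (to resolve the
    fast dNTP-incorporation phase) and a long one late (to reach the slow
    background-hydrolysis plateau), e.g. 100 cycles of 13 s followed by
    200 cycles of 80 s.
    """

    segments: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("schedule needs at least one segment")
        norm = []
        for count, length in self.segments:
            if int(count) != count or count <= 0:
                raise ValueError(f"cycle count must be a positive integer, got {count}")
            if not (length > 0):
                raise ValueError(f"cycle length must be positive seconds, got {length}")
            norm.append((int(count), float(length)))
        object.__setattr__(self, "segments", tuple(norm))

    @property
    def total_cycles(self) -> int:
        return sum(n for n, _ in self.segments)

    @classmethod
    def parse(cls, text: str) -> "AcquisitionSchedule":
        """Parse a compact ``"100x13,200x80"`` description (count x seconds)."""
        segments = []
        for part in text.split(","):
            count, _, length = part.strip().partition("x")
            segments.append((int(count), float(length)))
        return cls(tuple(segments))


def expand_schedule(schedule: AcquisitionSchedule) -> np.ndarray:
    """Absolute acquisition times (s) of each recorded cycle.

    The first recorded point is at t = 0 and cycle n sits at the cumulative
    acquisition time of the preceding cycles; any constant instrument offset
    is absorbed by the fitted amplitudes and plateau, so it never affects A1.
    """
    durations = np.concatenate(
        [np.full(count, length, dtype=float) for count, length in schedule.segments]
    )
    times = np.concatenate([[0.0], np.cumsum(durations[:-1])])
    return times


@dataclass
class ProgressCurve:
    """One well's time-ordered fluorescence record (arbitrary units)."""

    well_id: str
    times_s: np.ndarray
    fluorescence: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.well_id = _check_well_id(self.well_id)
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.times_s.ndim != 1 or self.times_s.shape != self.fluorescence.shape:
            raise ValueError("times_s and fluorescence must be 1-D and equal length")
        if self.times_s.size == 0:
            raise ValueError("empty curve")
        if not np.all(np.isfinite(self.times_s)):
            raise ValueError("non-finite time values")
        if not np.all(np.isfinite(self.fluorescence)):
            raise ValueError("missing or non-finite fluorescence values")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_points(self) -> int:
        return int(self.times_s.size)


class WellRole(str, Enum):
    BLANK = "blank"
    CALIBRATION = "calibration"
    SAMPLE = "sample"
    EXCLUDED = "excluded"


_BASES = {"per_1e6_cells": 1e6, "per_1e8_cfu": 1e8}


@dataclass
class WellInfo:
    """Role and quantification metadata for one plate well."""

    role: WellRole
    amount_pmol: float | None = None
    sample_id: str | None = None
    dilution_factor: float = 1.0
    extract_volume_ul: float | None = None
    assayed_volume_ul: float | None = None
    cells_extracted: float | None = None
    basis: str | None = None

    def __post_init__(self) -> None:
        self.role = WellRole(self.role)
        if self.role is WellRole.CALIBRATION:
            if self.amount_pmol is None or self.amount_pmol < 0:
                raise ValueError("calibration well needs amount_pmol >= 0")
            # a zero-dNTP "calibration" point is by definition a blank reaction
            if self.amount_pmol == 0:
                self.role = WellRole.BLANK
        if self.basis is not None and self.basis not in _BASES:
            raise ValueError(f"basis must be one of {sorted(_BASES)}")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")

    @property
    def has_normalization_meta(self) -> bool:
        return (
            self.role is WellRole.SAMPLE
            and self.extract_volume_ul is not None
            and self.assayed_volume_ul is not None
            and self.cells_extracted is not None
            and self.basis is not None
        )


@dataclass
class PlateLayout:
    """Per-well roles for one plate plus the limiting dNTP species."""

    wells: dict[str, WellInfo]
    dntp_species: str = "dGTP"

    def __post_init__(self) -> None:
        self.wells = {_check_well_id(w): info for w, info in self.wells.items()}
        if self.dntp_species not in {"dATP", "dCTP", "dGTP", "dTTP", "dUTP"}:
            raise ValueError(f"unknown dNTP species {self.dntp_species!r}")

    def wells_with_role(self, role: WellRole) -> dict[str, WellInfo]:
        return {w: i for w, i in self.wells.items() if i.role is role}

    def calibration_amounts(self) -> list[float]:
        return sorted({i.amount_pmol for i in self.wells_with_role(WellRole.CALIBRATION).values()})

    def require_quantifiable(self) -> None:
        if len(self.calibration_amounts()) < 2:
            raise ValueError("quantification needs >= 2 distinct calibration amounts")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        wells = {}
        for w, i in self.wells.items():
            d = {"role": i.role.value}
            for f in ("amount_pmol", "sample_id", "extract_volume_ul",
                      "assayed_volume_ul", "cells_extracted", "basis"):
                v = getattr(i, f)
                if v is not None:
                    d[f] = v
            if i.dilution_factor != 1.0:
                d["dilution_factor"] = i.dilution_factor
            wells[w] = d
        return {"dntp_species": self.dntp_species, "wells": wells}

    @classmethod
    def from_dict(cls, data: Mapping) -> "PlateLayout":
        wells = {w: WellInfo(**d) for w, d in data["wells"].items()}
        return cls(wells=wells, dntp_species=data.get("dntp_species", "dGTP"))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PlateLayout":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def from_csv(cls, path, dntp_species: str = "dGTP") -> "PlateLayout":
        """Layout from a CSV with columns well, role and optional metadata."""
        df = pd.read_csv(path)
        df.columns = [c.strip().lower() for c in df.columns]
        if "well" not in df.columns or "role" not in df.columns:
            raise ValueError("layout CSV needs 'well' and 'role' columns")
        fields = ("amount_pmol", "sample_id", "dilution_factor", "extract_volume_ul",
                  "assayed_volume_ul", "cells_extracted", "basis")
        wells = {}
        for _, row in df.iterrows():
            kwargs = {}
            for f in fields:
                if f in df.columns and not pd.isna(row[f]):
                    kwargs[f] = row[f]
            wells[str(row["well"])] = WellInfo(role=str(row["role"]).strip(), **kwargs)
        if "dntp_species" in df.columns and not df["dntp_species"].isna().all():
            dntp_species = str(df["dntp_species"].dropna().iloc[0])
        return cls(wells=wells, dntp_species=dntp_species)


def read_layout(path, dntp_species: str = "dGTP") -> PlateLayout:
    """Dispatch on extension: .yaml/.yml or .csv."""
    p = str(path)
    if p.endswith((".yaml", ".yml")):
        return PlateLayout.from_yaml(path)
    return PlateLayout.from_csv(path, dntp_species=dntp_species)


@dataclass
class WellReadError:
    """Per-well parse failure; the rest of the file is still usable."""

    well_id: str
    message: str


def _load_table(path) -> pd.DataFrame:
    p = str(path)
    if p.endswith((".xlsx", ".xls")):
        return pd.read_excel(path)
    return pd.read_csv(path, float_precision="round_trip")


def read_plate_export(
    path,
    dialect: str = "generic_long",
    schedule: AcquisitionSchedule | None = None,
) -> tuple[list[ProgressCurve], list[WellReadError]]:
    """Read an instrument export into per-well progress curves.

    ``generic_long`` expects columns (well, time_s, fluorescence) and is the
    canonical dialect; vendor exports are mapped onto it.  ``wide_cycles``
    expects one row per well with one column per recorded cycle, and needs a
    schedule to convert cycle indices to seconds.

    Unparseable wells become :class:`WellReadError` records; only a malformed
    header fails the whole file.
    """
    df = _load_table(path)
    df.columns = [str(c).strip().lower() for c in df.columns]
    if dialect == "generic_long":
        return _read_generic_long(df)
    if dialect == "wide_cycles":
        if schedule is None:
            raise ValueError("dialect 'wide_cycles' requires an acquisition schedule")
        return _read_wide_cycles(df, schedule)
    raise ValueError(f"unknown dialect {dialect!r}")


_TIME_ALIASES = ("time_s", "time", "seconds", "t")
_FLUOR_ALIASES = ("fluorescence", "rfu", "signal", "f")


def _pick_column(df: pd.DataFrame, aliases: Sequence[str], what: str) -> str:
    for a in aliases:
        if a in df.columns:
            return a
    raise ValueError(f"malformed header: no {what} column (tried {aliases})")


def _read_generic_long(df: pd.DataFrame) -> tuple[list[ProgressCurve], list[WellReadError]]:
    if "well" not in df.columns:
        raise ValueError("malformed header: no 'well' column")
    tcol = _pick_column(df, _TIME_ALIASES, "time")
    fcol = _pick_column(df, _FLUOR_ALIASES, "fluorescence")
    curves, errors = [], []
    for well, grp in df.groupby("well", sort=True):
        times = pd.to_numeric(grp[tcol], errors="coerce").to_numpy()
        fluor = pd.to_numeric(grp[fcol], errors="coerce").to_numpy()
        try:
            well_id = _check_well_id(str(well))
            if np.isnan(times).any() or np.isnan(fluor).any():
                raise ValueError("unparseable numeric cell")
            if pd.Series(times).duplicated().any():
                raise ValueError("duplicate well/time pair")
            curves.append(ProgressCurve(well_id=well_id, times_s=times, fluorescence=fluor))
        except ValueError as exc:
            errors.append(WellReadError(well_id=str(well), message=str(exc)))
    return curves, errors


def _read_wide_cycles(
    df: pd.DataFrame, schedule: AcquisitionSchedule
) -> tuple[list[ProgressCurve], list[WellReadError]]:
    if "well" not in df.columns:
        raise ValueError("malformed header: no 'well' column")
    cycle_cols = [c for c in df.columns if c != "well"]
    if len(cycle_cols) != schedule.total_cycles:
        raise ValueError(
            f"malformed header: {len(cycle_cols)} cycle columns but schedule "
            f"has {schedule.total_cycles} cycles"
        )
    times = expand_schedule(schedule)
    curves, errors = [], []
    for _, row in df.iterrows():
        well = str(row["well"])
        fluor = pd.to_numeric(row[cycle_cols], errors="coerce").to_numpy(dtype=float)
        try:
            well_id = _check_well_id(well)
            if np.isnan(fluor).any():
                raise ValueError("unparseable numeric cell")
            curves.append(ProgressCurve(well_id=well_id, times_s=times.copy(), fluorescence=fluor))
        except ValueError as exc:
            errors.append(WellReadError(well_id=well, message=str(exc)))
    return curves, errors


def write_curves(curves: Iterable[ProgressCurve], path) -> None:
    """Write curves as the canonical long CSV (well, time_s, fluorescence).

    Values are written with shortest round-trip float representation, so
    :func:`read_plate_export` recovers them bit-exactly.
    """
    with open(path, "w") as fh:
        fh.write("well,time_s,fluorescence\n")
        for c in curves:
            for t, f in zip(c.times_s, c.fluorescence):
                fh.write(f"{c.well_id},{float(t)!r},{float(f)!r}\n")


# ---------------------------------------------------------------------------
# reports


def _calibration_summary(result) -> dict:
    summary: dict[str, object] = {}
    calib = getattr(result, "calibration", None)
    if calib is None:
        return summary
    summary.update(
        dntp_species=calib.dntp_species,
        slope=calib.slope,
        intercept=calib.intercept,
        r_squared=calib.r_squared,
        range_lo_pmol=calib.fitted_range[0],
        range_hi_pmol=calib.fitted_range[1],
        lod_pmol=calib.lod_pmol,
        loq_pmol=calib.loq_pmol,
        n_calibration_points=sum(1 for p in calib.points if p.included),
    )
    return summary


def write_report(result, path, format: str = "xlsx") -> None:
    """Write the per-well analysis table plus a calibration summary.

    ``result`` is a :class:`dntpkin.pipeline.PlateResult` (anything with a
    ``to_frame()`` method and a ``calibration`` attribute works).  XLSX
    reports carry two sheets (``wells``, ``calibration``); CSV reports hold
    the well table followed by ``#``-prefixed summary lines so a single file
    round-trips.
    """
    wells = result.to_frame()
    summary = _calibration_summary(result)
    if format == "xlsx":
        with pd.ExcelWriter(path, engine="openpyxl") as writer:
            wells.to_excel(writer, sheet_name="wells", index=False)
            pd.DataFrame(
                {"parameter": list(summary), "value": list(summary.values())}
            ).to_excel(writer, sheet_name="calibration", index=False)
    elif format == "csv":
        with open(path, "w") as fh:
            wells.to_csv(fh, index=False)
            for key, value in summary.items():
                fh.write(f"# {key},{value!r}\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path) -> tuple[pd.DataFrame, dict]:
    """Re-parse a CSV report written by :func:`write_report`."""
    wells = pd.read_csv(path, comment="#")
    summary: dict[str, object] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("# "):
                key, _, value = line[2:].strip().partition(",")
                try:
                    summary[key] = ast.literal_eval(value)
                except (ValueError, SyntaxError):
                    summary[key] = value
    return wells, summary
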