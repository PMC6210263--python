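"""Exposure data model and the schedule-weighted exposure-concentration estimator.

A worker's chronic inhalation exposure to one agent is summarised by the
exposure concentration

    EC = Σ_i CA_i · ET_i · EF_i · ED / AT        [mg/m³]

where the sum runs over the workplaces the worker rotates through, CA_i is
the airborne concentration (mg/m³), ET_i the daily exposure time (h/day),
EF_i the yearly exposure frequency (day/year), ED the exposure duration in
years, and AT the averaging time in hours. With the exposure-period
averaging convention AT = ED·24·365, so ED cancels and

    EC = Σ_i CA_i · ET_i · EF_i / 8760.

An optional lifetime convention (AT = 70·24·365, ED kept in the numerator)
is available for lifetime-averaged cancer estimates.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, replace
from pathlib import Path
from typing import IO, Iterable, Sequence

from .registry import LimitType

__all__ = [
    "HOURS_PER_YEAR",
    "DEFAULT_ET_HOURS",
    "DEFAULT_EF_DAYS",
    "Averaging",
    "WorkplaceStay",
    "ExposureProfile",
    "MeasurementRecord",
    "exposure_concentration",
    "time_weighted_average",
    "profile_from_record",
    "read_measurements",
    "write_measurements",
]

HOURS_PER_YEAR = 24 * 365  # 8760

# Case-study schedule: the plant's printed daily exposure time, and the
# yearly frequency calibrated so the engine reproduces the printed hazard
# quotients exactly (≈ six-day weeks minus holidays). Both are config
# values, not constants: every consumer accepts overrides.
DEFAULT_ET_HOURS = 10.0
DEFAULT_EF_DAYS = 294.0

LIFETIME_YEARS = 70.0


class Averaging(enum.Enum):
    """Averaging-time convention for EC."""

    EXPOSURE_PERIOD = "exposure-period"  # AT = ED·24·365; EC independent of ED
    LIFETIME = "lifetime"  # AT = 70·24·365; EC scales with ED/70


@dataclass(frozen=True)
class WorkplaceStay:
    """One workplace's contribution to an exposure profile."""

    workplace_id: str
    ca: float  # airborne concentration, mg/m³
    et: float  # exposure time, h/day
    ef: float  # exposure frequency, day/year

    def __post_init__(self) -> None:
        if self.ca < 0:
            raise ValueError(f"{self.workplace_id}: ca must be >= 0, got {self.ca}")
        if not 0 < self.et <= 24:
            raise ValueError(f"{self.workplace_id}: et must be in (0, 24], got {self.et}")
        if not 0 < self.ef <= 365:
            raise ValueError(f"{self.workplace_id}: ef must be in (0, 365], got {self.ef}")


@dataclass(frozen=True)
class ExposureProfile:
    """All workplaces a worker is exposed to one agent in, plus duration ED (years).

    The averaging time AT is always derived (never stored): ED·24·365 h
    under the exposure-period convention.
    """

    agent: str
    stays: tuple[WorkplaceStay, ...]
    ed: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "stays", tuple(self.stays))
        if not self.stays:
            raise ValueError(f"{self.agent}: profile needs at least one stay")
        if not self.ed > 0:
            raise ValueError(f"{self.agent}: ed must be > 0, got {self.ed}")


@dataclass(frozen=True)
class MeasurementRecord:
    """One post × agent air measurement with its testing schedule."""

    post_id: str
    agent: str
    ca: float  # mg/m³
    limit_type: LimitType = LimitType.TWA
    et: float = DEFAULT_ET_HOURS
    ef: float = DEFAULT_EF_DAYS

    def __post_init__(self) -> None:
        if self.ca < 0:
            raise ValueError(f"{self.post_id}/{self.agent}: ca must be >= 0, got {self.ca}")
        if not isinstance(self.limit_type, LimitType):
            raise ValueError(f"{self.post_id}/{self.agent}: invalid limit_type {self.limit_type!r}")
        if not 0 < self.et <= 24:
            raise ValueError(f"{self.post_id}/{self.agent}: et must be in (0, 24]")
        if not 0 < self.ef <= 365:
            raise ValueError(f"{self.post_id}/{self.agent}: ef must be in (0, 365]")


def exposure_concentration(
    profile: ExposureProfile,
    averaging: Averaging = Averaging.EXPOSURE_PERIOD,
    lifetime_years: float = LIFETIME_YEARS,
) -> float:
    """Schedule-weighted average exposure concentration EC, mg/m³.

    Under the default exposure-period averaging, ED cancels:
    EC = Σ CA·ET·EF / 8760. Under lifetime averaging, EC is scaled by
    ED / ``lifetime_years``.
    """
    dose_rate = sum(s.ca * s.et * s.ef for s in profile.stays)  # mg·h / (m³·year)
    if averaging is Averaging.EXPOSURE_PERIOD:
        return dose_rate / HOURS_PER_YEAR
    if averaging is Averaging.LIFETIME:
        return dose_rate * profile.ed / (lifetime_years * HOURS_PER_YEAR)
    raise ValueError(f"unknown averaging convention: {averaging!r}")


def time_weighted_average(
    samples: Sequence[tuple[float, float]], shift_hours: float
) -> float:
    """C_TWA = Σ(c·t) / shift_hours; unsampled shift time contributes zero.

    ``samples`` is a sequence of (concentration mg/m³, duration h) pairs.
    """
    if not samples:
        raise ValueError("time_weighted_average needs at least one sample")
    if not shift_hours > 0:
        raise ValueError(f"shift_hours must be > 0, got {shift_hours}")
    for c, t in samples:
        if c < 0:
            raise ValueError(f"negative concentration {c}")
        if not t > 0:
            raise ValueError(f"sample duration must be > 0, got {t}")
    return sum(c * t for c, t in samples) / shift_hours


def profile_from_record(record: MeasurementRecord, ed: float = 1.0) -> ExposureProfile:
    """Single-stay profile for a fixed-post worker (the per-post assessment case)."""
    stay = WorkplaceStay(workplace_id=record.post_id, ca=record.ca, et=record.et, ef=record.ef)
    return ExposureProfile(agent=record.agent, stays=(stay,), ed=ed)


MEASUREMENT_COLUMNS = [
    "post_id",
    "agent",
    "ca_mg_m3",
    "limit_type",
    "et_h_per_day",
    "ef_day_per_year",
]


def read_measurements(source: str | Path | IO[str]) -> list[MeasurementRecord]:
    """Read the measurement CSV dialect (one row per post × agent)."""
    if hasattr(source, "read"):
        return _read_measurements_stream(source)  # type: ignore[arg-type]
    with open(source, newline="", encoding="utf-8") as fh:
        return _read_measurements_stream(fh)


def _read_measurements_stream(fh: IO[str]) -> list[MeasurementRecord]:
    reader = csv.DictReader(fh)
    if reader.fieldnames is None:
        raise ValueError("measurement file is empty (no header)")
    missing = [c for c in MEASUREMENT_COLUMNS if c not in reader.fieldnames]
    if missing:
        raise ValueError(f"measurement header missing columns: {missing}")
    records = []
    for rownum, row in enumerate(reader, start=2):
        try:
            records.append(
                MeasurementRecord(
                    post_id=row["post_id"].strip(),
                    agent=row["agent"].strip(),
                    ca=float(row["ca_mg_m3"]),
                    limit_type=LimitType(row["limit_type"].strip().upper()),
                    et=float(row["et_h_per_day"]),
                    ef=float(row["ef_day_per_year"]),
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"measurement row {rownum}: {exc}") from None
    return records


def write_measurements(
    records: Iterable[MeasurementRecord], dest: str | Path | IO[str]
) -> None:
    if hasattr(dest, "write"):
        _write_measurements_stream(records, dest)  # type: ignore[arg-type]
        return
    with open(dest, "w", newline="", encoding="utf-8") as fh:
        _write_measurements_stream(records, fh)


def _write_measurements_stream(records: Iterable[MeasurementRecord], fh: IO[str]) -> None:
    writer = csv.writer(fh)
    writer.writerow(MEASUREMENT_COLUMNS)
    for r in records:
        writer.writerow([r.post_id, r.agent, repr(r.ca), r.limit_type.value, repr(r.et), repr(r.ef)])


def with_schedule(
    records: Iterable[MeasurementRecord],
    et: float | None = None,
    ef: float | None = None,
) -> list[MeasurementRecord]:
    """Copies of ``records`` with the daily/yearly schedule overridden where given."""
    out = []
    for r in records:
        out.append(replace(r, et=et if et is not None else r.et, ef=ef if ef is not None else r.ef))
    return out
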