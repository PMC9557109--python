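"""Growing-degree-day (GDD) accounting over growth-stage intervals.

Daily thermal time is the mean of the daily maximum and minimum air
temperature minus a base temperature (10 °C for maize), clipped at zero;
accumulating it over the sowing→silking (R1) and silking→maturity (R6)
windows gives the "effective accumulated temperature" demand of a hybrid.

Conventions: day counts are plain calendar-date differences; accumulation
windows are start-exclusive and end-inclusive, so adjacent stage intervals
tile the season without double counting.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Iterable, Sequence

from .data_model_io import DomainError, InvariantError, StageRecord, WeatherDay

__all__ = [
    "DEFAULT_TBASE",
    "GapError",
    "StageDurations",
    "daily_gdd",
    "accumulate_gdd",
    "stage_durations",
    "yield_per_gdd",
]

DEFAULT_TBASE = 10.0  # °C, maize growth base temperature


class GapError(ValueError):
    """The weather series is missing days inside the accumulation window."""

    def __init__(self, missing: list[_dt.date]):
        self.missing = missing
        shown = ", ".join(d.isoformat() for d in missing[:5])
        more = "" if len(missing) <= 5 else f" (+{len(missing) - 5} more)"
        super().__init__(f"weather gap: missing {shown}{more}")


@dataclass(frozen=True)
class StageDurations:
    """Days and accumulated GDD before and after silking, with season totals."""

    year: str
    hybrid: str
    days_before_silking: int
    gdd_before_silking: float
    days_after_silking: int
    gdd_after_silking: float

    @property
    def total_days(self) -> int:
        return self.days_before_silking + self.days_after_silking

    @property
    def total_gdd(self) -> float:
        return self.gdd_before_silking + self.gdd_after_silking


def daily_gdd(day: WeatherDay, tbase: float = DEFAULT_TBASE) -> float:
    """Thermal time of one day: max(0, (tmax + tmin)/2 − tbase), in °C d."""
    if day.tmax < day.tmin:
        raise InvariantError(f"{day.date.isoformat()}: tmax {day.tmax} < tmin {day.tmin}")
    return max(0.0, (day.tmax + day.tmin) / 2.0 - tbase)


def accumulate_gdd(series: Iterable[WeatherDay], start: _dt.date, end: _dt.date,
                   tbase: float = DEFAULT_TBASE) -> float:
    """Sum daily GDD over the window (start, end] — start-exclusive, end-inclusive.

    Every calendar day in the window must be present in ``series``; a gap
    raises :class:`GapError` listing the missing dates.
    """
    if end < start:
        raise DomainError(f"end {end} before start {start}")
    by_date = {d.date: d for d in series}
    total = 0.0
    missing: list[_dt.date] = []
    day = start + _dt.timedelta(days=1)
    while day <= end:
        if day in by_date:
            total += daily_gdd(by_date[day], tbase)
        else:
            missing.append(day)
        day += _dt.timedelta(days=1)
    if missing:
        raise GapError(missing)
    return total


def stage_durations(rec: StageRecord, weather: Sequence[WeatherDay],
                    tbase: float = DEFAULT_TBASE) -> StageDurations:
    """Day counts and accumulated GDD for the pre- and post-silking windows of one year x hybrid."""
    return StageDurations(
        year=rec.year,
        hybrid=rec.hybrid,
        days_before_silking=(rec.r1 - rec.sowing).days,
        gdd_before_silking=accumulate_gdd(weather, rec.sowing, rec.r1, tbase),
        days_after_silking=(rec.r6 - rec.r1).days,
        gdd_after_silking=accumulate_gdd(weather, rec.r1, rec.r6, tbase),
    )


def yield_per_gdd(yield_kg_ha: float, gdd: float) -> float:
    """Grain yield per unit thermal time, kg ha⁻¹ (°C d)⁻¹."""
    if gdd <= 0:
        raise DomainError(f"gdd must be positive, got {gdd}")
    return yield_kg_ha / gdd
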