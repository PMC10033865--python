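"""Seeded synthetic daily visit series.

Daily counts are drawn from a Gamma-Poisson (negative-binomial) law with a
log-linear-style multiplicative mean: a base rate scaled by a calendar-month
multiplier, a day-of-week multiplier and an optional holiday dip.  For
dispersion ``phi`` the variance is ``mu * (1 + phi * mu)``; ``phi = 0``
gives plain Poisson counts.

The default outpatient configuration emulates one year (2020, 366 days) of
tertiary-hospital outpatient demand: annual mean near 1,239 visits/day,
median near 1,350 (weekend lows pull the mean below the weekday-dominated
median), Monday the busiest weekday, a February trough with a one-week
holiday dip.  The emergency configuration is a lower-rate series with a
flat weekday profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

from .beliefs import VisitSeries
from .errors import DomainError

__all__ = [
    "SeriesConfig",
    "generate_visit_series",
    "generate_emergency_series",
    "default_outpatient_config",
    "default_emergency_config",
]

# Calibrated so that one simulated year matches the reference outpatient
# series' annual mean (~1,238.9) and median (~1,350); Monday is the busiest
# weekday, weekends the quietest.
_OUTPATIENT_BASE = 1295.468
_OUTPATIENT_MONTH = (1.02, 0.72, 0.92, 0.98, 1.02, 1.05, 1.10, 1.08, 1.06, 1.04, 1.03, 1.02)
_OUTPATIENT_DOW = (1.14, 1.10, 1.07, 1.05, 1.03, 0.68, 0.62)  # Mon..Sun
_FEBRUARY_HOLIDAY = {(2, d): 0.65 for d in range(1, 8)}

_EMERGENCY_BASE = 150.0
_EMERGENCY_MONTH = (1.02, 0.90, 0.95, 0.98, 1.00, 1.02, 1.05, 1.05, 1.02, 1.00, 1.00, 1.02)
_FLAT_DOW = (1.0,) * 7


@dataclass(frozen=True)
class SeriesConfig:
    """Configuration of the synthetic count generator.

    ``dispersion`` is the Gamma-mixing variance parameter ``phi`` (0 =
    Poisson); ``holiday_dips`` maps ``(month, day)`` to a multiplicative
    factor applied on that calendar day.
    """

    start_date: date = date(2020, 1, 1)
    n_days: int = 366
    base_rate: float = _OUTPATIENT_BASE
    month_multipliers: tuple[float, ...] = _OUTPATIENT_MONTH
    weekday_multipliers: tuple[float, ...] = _OUTPATIENT_DOW
    dispersion: float = 0.003
    seed: int = 0
    holiday_dips: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise DomainError("n_days must be at least 1")
        if self.base_rate <= 0:
            raise DomainError("base_rate must be positive")
        if len(self.month_multipliers) != 12 or any(
            m <= 0 for m in self.month_multipliers
        ):
            raise DomainError("month_multipliers must be 12 positive reals")
        if len(self.weekday_multipliers) != 7 or any(
            w <= 0 for w in self.weekday_multipliers
        ):
            raise DomainError("weekday_multipliers must be 7 positive reals")
        if self.dispersion < 0:
            raise DomainError("dispersion must be non-negative")
        if any(f <= 0 for f in self.holiday_dips.values()):
            raise DomainError("holiday dip factors must be positive")


def _daily_means(config: SeriesConfig) -> tuple[pd.DatetimeIndex, np.ndarray]:
    dates = pd.date_range(config.start_date, periods=config.n_days, freq="D")
    mu = np.array(
        [
            config.base_rate
            * config.month_multipliers[d.month - 1]
            * config.weekday_multipliers[d.dayofweek]
            * config.holiday_dips.get((d.month, d.day), 1.0)
            for d in dates
        ]
    )
    return dates, mu


def generate_visit_series(config: SeriesConfig) -> VisitSeries:
    """Draw one seeded Gamma-Poisson visit series from a configuration.

    Identical configurations (including the seed) produce identical series.
    """
    dates, mu = _daily_means(config)
    rng = np.random.default_rng(config.seed)
    if config.dispersion == 0:
        counts = rng.poisson(mu)
    else:
        shape = 1.0 / config.dispersion
        rates = rng.gamma(shape, config.dispersion * mu)
        counts = rng.poisson(rates)
    return VisitSeries(dates, counts.astype(np.int64))


def default_outpatient_config(seed: int) -> SeriesConfig:
    """Calibrated one-year outpatient configuration (366 days from 2020-01-01)."""
    return SeriesConfig(seed=seed, holiday_dips=dict(_FEBRUARY_HOLIDAY))


def default_emergency_config(seed: int) -> SeriesConfig:
    """Lower-rate emergency configuration with a flat weekday profile."""
    return SeriesConfig(
        seed=seed,
        base_rate=_EMERGENCY_BASE,
        month_multipliers=_EMERGENCY_MONTH,
        weekday_multipliers=_FLAT_DOW,
    )


def generate_emergency_series(config: SeriesConfig | None = None, seed: int = 0) -> VisitSeries:
    """Generate an emergency-department series (default configuration if none)."""
    if config is None:
        config = default_emergency_config(seed)
    return generate_visit_series(config)
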