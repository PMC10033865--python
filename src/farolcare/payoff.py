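"""Composite healthcare payoff index and the expected-payoff series.

Service-quality indicators are standardised against national averages
(``standard value = instance / national``) and combined, via signed
indicator weights, into comprehensive indices whose category sums give the
gain ``H`` (favourable service dimensions) and loss ``L`` of a hospital
visit.  Given a daily belief ``p_t`` that the visit will be uncongested,
the anticipated net benefit is the affine map

    E_t = H * p_t - L * (1 - p_t)

which is applied literally to signed ``H`` and ``L`` (an empirically
negative ``L`` makes ``E`` positive for every ``p``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .beliefs import BeliefTrajectory
from .errors import DomainError

__all__ = [
    "IndicatorRecord",
    "PayoffIndex",
    "PayoffSeries",
    "standard_value",
    "comprehensive_index",
    "aggregate_payoffs",
    "expected_payoff",
    "payoff_trajectory",
]


@dataclass(frozen=True)
class IndicatorRecord:
    """One row of the composite index table.

    ``category`` is "H" (counts toward the gain) or "L" (toward the loss);
    ``comprehensive_index`` is either supplied directly (published mode) or
    derived as ``weight * standard_value`` when a signed weight is given.
    """

    name: str
    category: str
    national_value: float
    instance_value: float
    comprehensive_index: float | None = None
    weight: float | None = None

    def __post_init__(self) -> None:
        if self.category not in ("H", "L"):
            raise DomainError("category must be 'H' or 'L'")
        if self.national_value <= 0 or self.instance_value <= 0:
            raise DomainError("indicator values must be positive")
        if self.comprehensive_index is None and self.weight is None:
            raise DomainError(
                f"indicator {self.name!r} needs a comprehensive_index or a weight"
            )

    @property
    def standard_value(self) -> float:
        return self.instance_value / self.national_value

    def resolved_index(self) -> float:
        if self.comprehensive_index is not None:
            return self.comprehensive_index
        return self.weight * self.standard_value


@dataclass(frozen=True)
class PayoffIndex:
    """Aggregated gain ``H`` and loss ``L`` of a hospital visit."""

    gain: float
    loss: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.gain) and np.isfinite(self.loss)):
            raise DomainError("gain and loss must be finite")


@dataclass(frozen=True)
class PayoffSeries:
    """Daily expected payoffs with monthly means and the annual range."""

    dates: pd.DatetimeIndex
    expected_payoffs: np.ndarray
    monthly_means: pd.Series
    minimum: float
    maximum: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"date": self.dates, "E": self.expected_payoffs})


def standard_value(instance: float, national: float) -> float:
    """Evaluation standard value ``instance / national`` (raw ratio)."""
    if national <= 0:
        raise DomainError("national value must be positive")
    if instance <= 0:
        raise DomainError("instance value must be positive")
    return instance / national


def comprehensive_index(record: IndicatorRecord) -> float:
    """The record's comprehensive index (published or weight-derived)."""
    return record.resolved_index()


def aggregate_payoffs(records) -> PayoffIndex:
    """Sum comprehensive indices by category into the payoff pair (H, L)."""
    records = list(records)
    gain = [r.resolved_index() for r in records if r.category == "H"]
    loss = [r.resolved_index() for r in records if r.category == "L"]
    if not gain or not loss:
        raise DomainError("both an H-category and an L-category record are required")
    # math.fsum is exactly rounded, hence permutation-invariant
    return PayoffIndex(gain=math.fsum(gain), loss=math.fsum(loss))


def expected_payoff(p: float, index: PayoffIndex) -> float:
    """``E = H p - L (1 - p)`` for a single belief value."""
    if not 0 <= p <= 1:
        raise DomainError("p must lie in [0, 1]")
    return index.gain * p - index.loss * (1.0 - p)


def payoff_trajectory(traj: BeliefTrajectory, index: PayoffIndex) -> PayoffSeries:
    """Map a belief trajectory through the expected-payoff equation.

    ``E`` is affine in ``p`` with slope ``H + L``, so the daily payoff
    series is a rescaled copy of the belief series and its extrema occur at
    the extreme beliefs.
    """
    if len(traj) == 0:
        raise DomainError("trajectory is empty")
    values = index.gain * traj.p_values - index.loss * (1.0 - traj.p_values)
    frame = pd.DataFrame({"E": values}, index=traj.dates)
    monthly = frame.groupby(frame.index.to_period("M"))["E"].mean()
    monthly.index.name = "month"
    return PayoffSeries(
        dates=traj.dates,
        expected_payoffs=values,
        monthly_means=monthly,
        minimum=float(values.min()),
        maximum=float(values.max()),
    )
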