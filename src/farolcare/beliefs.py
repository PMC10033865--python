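"""Daily belief dynamics of hospital-seeking patients.

A representative patient keeps a probability ``p_t`` that a hospital visit
today would be uncongested (daily visits at or below a personal threshold
``c``).  After each day the belief is updated by the exponential balance
equation

    p_t = (1 - omega) * p_{t-1} + omega * signal_t

where ``omega`` in (0, 1] is the learning rate (weight of the newest
experience) and ``signal_t`` in [0, 1] summarizes the last ``d`` days of
observed visit counts.  The default signal is the fraction of the
observation window with counts at or below ``c``; conjunctive ("all") and
window-mean rules are available as alternatives.

The module also provides the analytic envelope of the update
(``belief_bounds``), summaries, monthly aggregation, the emergency-care
special case (prior 1, one observation day, threshold = annual mean), and
the parameter sweeps over the initial prior, the learning rate and the
congestion threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .errors import DataValidationError, DomainError

__all__ = [
    "VisitSeries",
    "BeliefParams",
    "BeliefTrajectory",
    "TrajectorySummary",
    "SIGNAL_RULES",
    "update_belief",
    "observation_signal",
    "belief_bounds",
    "run_belief_trajectory",
    "summarize_trajectory",
    "monthly_summary",
    "emergency_analysis",
    "rate_of_change_pct",
    "sweep_initial_p",
    "sweep_omega",
    "sweep_threshold",
    "round_half_up",
]

SIGNAL_RULES = ("fraction", "all", "mean")


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding (0.5 away from zero), as printed tables use."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class VisitSeries:
    """Consecutive daily visit counts.

    ``dates`` must advance by exactly one day; ``counts`` are non-negative
    integers (daily outpatient or emergency department totals).
    """

    dates: pd.DatetimeIndex
    counts: np.ndarray

    def __post_init__(self) -> None:
        dates = pd.DatetimeIndex(self.dates)
        counts = np.asarray(self.counts)
        if len(dates) == 0:
            raise DataValidationError("visit series must contain at least one day")
        if len(dates) != len(counts):
            raise DataValidationError("dates and counts must have equal length")
        deltas = np.diff(dates.view("int64"))
        one_day = pd.Timedelta(days=1).value
        if np.any(deltas != one_day):
            gaps = dates[:-1][deltas != one_day]
            raise DataValidationError(
                "dates must be consecutive days; gaps after: "
                + ", ".join(str(d.date()) for d in gaps[:5])
            )
        if not np.issubdtype(counts.dtype, np.integer):
            as_int = counts.astype(np.int64)
            if np.any(as_int != counts):
                raise DataValidationError("counts must be integers")
            counts = as_int
        if np.any(counts < 0):
            raise DataValidationError("counts must be non-negative")
        object.__setattr__(self, "dates", dates)
        object.__setattr__(self, "counts", counts)

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def mean(self) -> float:
        return float(self.counts.mean())

    @property
    def median(self) -> float:
        return float(np.median(self.counts))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"date": self.dates, "count": self.counts})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "VisitSeries":
        return cls(pd.DatetimeIndex(frame["date"]), frame["count"].to_numpy())


@dataclass(frozen=True)
class BeliefParams:
    """Parameters of the daily belief update.

    threshold
        Personal congestion threshold ``c`` (visits at or below it count as
        a favourable day).
    learning_rate
        ``omega`` in (0, 1], the weight of the newest signal.
    initial_p
        The day-0 prior; it is not itself reported.
    window_days
        Observation window ``d`` >= 1 (days of recent counts consulted).
    signal_rule
        "fraction" (default), "all" or "mean"; see :func:`observation_signal`.
    """

    threshold: int
    learning_rate: float = 0.2
    initial_p: float = 0.5
    window_days: int = 1
    signal_rule: str = "fraction"

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise DomainError("threshold must be non-negative")
        if not 0 < self.learning_rate <= 1:
            raise DomainError("learning rate must lie in (0, 1]")
        if not 0 <= self.initial_p <= 1:
            raise DomainError("initial_p must lie in [0, 1]")
        if self.window_days < 1:
            raise DomainError("window_days must be at least 1")
        if self.signal_rule not in SIGNAL_RULES:
            raise DomainError(f"signal_rule must be one of {SIGNAL_RULES}")


@dataclass(frozen=True)
class BeliefTrajectory:
    """Daily belief values ``p_t`` with the signals that produced them."""

    dates: pd.DatetimeIndex
    p_values: np.ndarray
    signals: np.ndarray
    params: BeliefParams

    def __len__(self) -> int:
        return len(self.p_values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"date": self.dates, "signal": self.signals, "p": self.p_values}
        )


@dataclass(frozen=True)
class TrajectorySummary:
    mean_p: float
    days_above_half: int
    fraction_above_half: float
    n_days: int


def update_belief(p_prev: float, learning_rate: float, signal: float) -> float:
    """One step of the balance equation, ``(1-w) p + w s``; stays in [0, 1]."""
    if not 0 <= p_prev <= 1:
        raise DomainError("p_prev must lie in [0, 1]")
    if not 0 < learning_rate <= 1:
        raise DomainError("learning rate must lie in (0, 1]")
    if not 0 <= signal <= 1:
        raise DomainError("signal must lie in [0, 1]")
    return (1.0 - learning_rate) * p_prev + learning_rate * signal


def observation_signal(window_counts, threshold: int, rule: str = "fraction") -> float:
    """Reduce a window of recent counts to a favourable-experience signal.

    * ``fraction`` — share of window days with count <= threshold (in [0,1]);
    * ``all``      — 1 iff every window day is <= threshold;
    * ``mean``     — 1 iff the window mean is <= threshold.
    """
    counts = np.asarray(window_counts)
    if counts.size == 0:
        raise DomainError("observation window must be non-empty")
    if threshold < 0:
        raise DomainError("threshold must be non-negative")
    if rule == "fraction":
        return float(np.mean(counts <= threshold))
    if rule == "all":
        return 1.0 if np.all(counts <= threshold) else 0.0
    if rule == "mean":
        return 1.0 if counts.mean() <= threshold else 0.0
    raise DomainError(f"signal_rule must be one of {SIGNAL_RULES}")


def belief_bounds(initial_p: float, learning_rate: float, t: int) -> tuple[float, float]:
    """Analytic envelope of the belief after ``t - 1`` updates of prior ``p``.

    Telescoping the balance equation gives
    ``(1-w)^(t-1) p  <=  p_t  <=  1 - (1-w)^(t-1) (1 - p)``: the lower bound
    is attained when every signal is 0, the upper when every signal is 1.
    """
    if t < 1:
        raise DomainError("t must be at least 1")
    if not 0 <= initial_p <= 1:
        raise DomainError("initial_p must lie in [0, 1]")
    if not 0 < learning_rate <= 1:
        raise DomainError("learning rate must lie in (0, 1]")
    decay = (1.0 - learning_rate) ** (t - 1)
    return decay * initial_p, 1.0 - decay * (1.0 - initial_p)


def run_belief_trajectory(series: VisitSeries, params: BeliefParams) -> BeliefTrajectory:
    """Run the daily balance equation over a visit series.

    Day ``t`` (1-indexed) observes the window of the most recent
    ``min(t, d)`` days ending at ``t`` (early days use what is available, so
    every day of the series is reported), computes the signal and applies
    the update.  The day-0 prior is not part of the output.
    """
    n = len(series)
    d = params.window_days
    p = params.initial_p
    p_values = np.empty(n)
    signals = np.empty(n)
    for t in range(1, n + 1):
        window = series.counts[max(0, t - d): t]
        s = observation_signal(window, params.threshold, params.signal_rule)
        p = update_belief(p, params.learning_rate, s)
        signals[t - 1] = s
        p_values[t - 1] = p
    return BeliefTrajectory(series.dates, p_values, signals, params)


def summarize_trajectory(traj: BeliefTrajectory) -> TrajectorySummary:
    """Mean belief and the (strict) count of days with ``p > 0.5``."""
    if len(traj) == 0:
        raise DomainError("trajectory is empty")
    n = len(traj)
    above = int(np.sum(traj.p_values > 0.5))
    return TrajectorySummary(
        mean_p=float(traj.p_values.mean()),
        days_above_half=above,
        fraction_above_half=above / n,
        n_days=n,
    )


def monthly_summary(traj: BeliefTrajectory) -> pd.Series:
    """Arithmetic mean of the daily ``p_t`` within each calendar month."""
    if len(traj) == 0:
        raise DomainError("trajectory is empty")
    frame = pd.DataFrame({"p": traj.p_values}, index=traj.dates)
    means = frame.groupby(frame.index.to_period("M"))["p"].mean()
    means.index.name = "month"
    return means


def emergency_analysis(series: VisitSeries, learning_rate: float = 0.2) -> pd.Series:
    """Monthly mean belief for emergency care.

    Emergency demand is treated as a special case with full initial trust
    (prior 1), a one-day observation window and the series' annual mean
    (rounded to the nearest integer) as the congestion threshold.
    """
    threshold = int(round_half_up(series.mean))
    params = BeliefParams(
        threshold=threshold,
        learning_rate=learning_rate,
        initial_p=1.0,
        window_days=1,
        signal_rule="fraction",
    )
    return monthly_summary(run_belief_trajectory(series, params))


def rate_of_change_pct(initial_p: float, mean_p: float) -> int:
    """Relative change ``(mean - p0) / p0`` as a half-up rounded percent."""
    if initial_p <= 0:
        raise DomainError("rate of change undefined for initial_p <= 0")
    return int(round_half_up(100.0 * (mean_p - initial_p) / initial_p))


def _with(params: BeliefParams, **kwargs) -> BeliefParams:
    fields = {
        "threshold": params.threshold,
        "learning_rate": params.learning_rate,
        "initial_p": params.initial_p,
        "window_days": params.window_days,
        "signal_rule": params.signal_rule,
    }
    fields.update(kwargs)
    return BeliefParams(**fields)


def sweep_initial_p(
    series: VisitSeries, params: BeliefParams, initial_values
) -> pd.DataFrame:
    """Mean updated belief and percent rate of change per starting prior."""
    rows = []
    for p0 in initial_values:
        if not 0 < p0 <= 1:
            raise DomainError("initial values must lie in (0, 1] for rate computation")
        traj = run_belief_trajectory(series, _with(params, initial_p=p0))
        mean_p = float(traj.p_values.mean())
        rows.append(
            {
                "initial_p": p0,
                "mean_p": mean_p,
                "rate_of_change_pct": rate_of_change_pct(p0, mean_p),
            }
        )
    return pd.DataFrame(rows)


def sweep_omega(
    series: VisitSeries,
    params: BeliefParams,
    omegas,
    windows: tuple[int, ...] = (1, 3, 5),
) -> pd.DataFrame:
    """Belief summaries over a grid of learning rates and window lengths."""
    rows = []
    for omega in omegas:
        if not 0 < omega <= 1:
            raise DomainError("learning rates must lie in (0, 1]")
        for d in windows:
            traj = run_belief_trajectory(
                series, _with(params, learning_rate=omega, window_days=d)
            )
            summary = summarize_trajectory(traj)
            rows.append(
                {
                    "omega": omega,
                    "window_days": d,
                    "mean_p": summary.mean_p,
                    "days_above_half": summary.days_above_half,
                }
            )
    return pd.DataFrame(rows)


def sweep_threshold(
    series: VisitSeries,
    params: BeliefParams,
    thresholds,
    windows: tuple[int, ...] = (1, 2, 3),
) -> pd.DataFrame:
    """Mean belief over a grid of congestion thresholds and window lengths.

    For a fixed series and rule the signal is pointwise non-decreasing in
    the threshold, so the mean belief is non-decreasing in ``c``.
    """
    rows = []
    for c in thresholds:
        if c < 0:
            raise DomainError("thresholds must be non-negative")
        for d in windows:
            traj = run_belief_trajectory(
                series, _with(params, threshold=int(c), window_days=d)
            )
            rows.append(
                {
                    "threshold": int(c),
                    "window_days": d,
                    "mean_p": float(traj.p_values.mean()),
                }
            )
    return pd.DataFrame(rows)
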