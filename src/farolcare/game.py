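"""Generalized El Farol bar game engine.

The El Farol bar problem is a congestion game: ``N`` players independently
decide how intensely to use a shared resource whose enjoyment flips from a
gain ``H`` to a loss ``L`` once aggregate use exceeds a capacity ``c``.  In
the generalized form each player picks an action ``j`` from ``{0, ..., k-1}``
(action 0 = stay out, payoff 0) and attendance payoffs are scaled by
per-player, per-action weights ``w_ij``.

This module provides

* exact Poisson-binomial tail probabilities (the attendance belief of a
  player facing independently mixing opponents),
* belief-based expected payoffs and best responses,
* discrete fictitious-play dynamics (binary and generalized),
* pure-Nash enumeration / verification, and
* the 2x2 hospital-vs-pharmacy payoff matrix used downstream.

All dynamics use simultaneous updating: every player best-responds to the
frequencies observed up to time ``t`` and all counters advance together.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, ResourceError

__all__ = [
    "GameSpec",
    "FictitiousPlayState",
    "PharmacyGameMatrix",
    "payoff_value",
    "indifference_threshold",
    "tail_probability",
    "poisson_binomial_pmf",
    "expected_payoff_binary",
    "best_response_binary",
    "fictitious_play_binary",
    "enumerate_pure_nash_binary",
    "aggregated_belief_pmf",
    "expected_payoff_generalized",
    "fictitious_play_generalized",
    "is_pure_nash_generalized",
    "pharmacy_game_matrix",
    "has_converged",
]

_PMF_TOL = 1e-12


@dataclass(frozen=True)
class GameSpec:
    """Parameters of a generalized El Farol bar game.

    Parameters
    ----------
    n_players
        Number of players ``N``.
    capacity
        Congestion threshold ``c``: total action at or below ``c`` pays
        ``w_ij * H``, above it pays ``-w_ij * L``.
    gain, loss
        Payoff magnitudes ``H > 0`` and ``L > 0``.
    n_actions
        Size ``k`` of the action set ``{0, ..., k-1}`` (``k = 2`` is the
        classic attend/stay-home game).
    weights
        Optional ``(N, k)`` array of positive action weights ``w_ij``.
        Defaults to 1 everywhere; the weight on action 0 is irrelevant.
    """

    n_players: int
    capacity: int
    gain: float = 1.0
    loss: float = 1.0
    n_actions: int = 2
    weights: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.n_players < 2:
            raise DomainError("need at least two players")
        if self.n_actions < 2:
            raise DomainError("need at least two actions")
        if self.gain <= 0 or self.loss <= 0:
            raise DomainError("gain H and loss L must be strictly positive")
        max_total = (self.n_players - 1) * (self.n_actions - 1)
        if not 1 <= self.capacity <= max_total:
            raise DomainError(
                f"capacity must lie in [1, {max_total}] for equilibrium analysis"
            )
        if self.weights is None:
            w = np.ones((self.n_players, self.n_actions))
        else:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (self.n_players, self.n_actions):
                raise DomainError(
                    f"weights must have shape {(self.n_players, self.n_actions)}"
                )
            if np.any(w[:, 1:] <= 0):
                raise DomainError("action weights must be positive")
        object.__setattr__(self, "weights", w)

    @property
    def indifference(self) -> float:
        """The threshold belief ``u = H / (H + L)``, strictly in (0, 1)."""
        return self.gain / (self.gain + self.loss)


@dataclass(frozen=True)
class FictitiousPlayState:
    """Snapshot of generalized fictitious play at time ``t``.

    ``action_counts[i, j]`` is the number of times player ``i`` has taken
    action ``j`` in rounds ``1..t``; ``beliefs[i]`` is the empirical action
    frequency ``A_ij(t) / t`` (the supplied prior at ``t = 0``).
    """

    time: int
    action_counts: np.ndarray
    beliefs: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.action_counts)
        if self.time > 0 and not np.all(counts.sum(axis=1) == self.time):
            raise DomainError("per-player action counts must sum to the time index")


@dataclass(frozen=True)
class PharmacyGameMatrix:
    """2x2 hospital-vs-pharmacy payoff matrix.

    The two binary choices (visit the hospital, visit the pharmacy) pay
    additively: nothing for staying home, ``e`` for pharmacy only, ``E`` for
    hospital only and ``E + e`` for doing both.
    """

    hospital_payoff: float
    pharmacy_payoff: float

    @property
    def matrix(self) -> dict[str, float]:
        return {
            "neither": 0.0,
            "pharmacy_only": self.pharmacy_payoff,
            "hospital_only": self.hospital_payoff,
            "both": self.hospital_payoff + self.pharmacy_payoff,
        }

    def as_array(self) -> np.ndarray:
        """Rows: hospital no/yes; columns: pharmacy no/yes."""
        e, E = self.pharmacy_payoff, self.hospital_payoff
        return np.array([[0.0, e], [E, E + e]])


def pharmacy_game_matrix(
    hospital_payoff: float, pharmacy_payoff: float
) -> PharmacyGameMatrix:
    """Construct the additive 2x2 hospital/pharmacy payoff matrix."""
    return PharmacyGameMatrix(float(hospital_payoff), float(pharmacy_payoff))


def payoff_value(player: int, action: int, total_actions: int, spec: GameSpec) -> float:
    """Realized payoff of ``player`` taking ``action`` given the action total.

    Action 0 always pays 0.  Otherwise the player gets ``w_ij * H`` when the
    sum of all actions is at most the capacity and ``-w_ij * L`` above it.
    """
    if not 0 <= action <= spec.n_actions - 1:
        raise DomainError(f"action {action} outside 0..{spec.n_actions - 1}")
    if total_actions < action:
        raise DomainError("total actions cannot be below the player's own action")
    if action == 0:
        return 0.0
    w = spec.weights[player, action]
    return w * spec.gain if total_actions <= spec.capacity else -w * spec.loss


def indifference_threshold(spec: GameSpec) -> float:
    """``u = H / (H + L)``: a player attends iff the congestion belief is <= u."""
    return spec.indifference


def _validate_probs(beliefs: np.ndarray) -> np.ndarray:
    beliefs = np.asarray(beliefs, dtype=float)
    if beliefs.ndim != 1:
        raise DomainError("beliefs must be a one-dimensional sequence")
    if np.any(beliefs < 0) or np.any(beliefs > 1):
        raise DomainError("attendance beliefs must lie in [0, 1]")
    return beliefs


def poisson_binomial_pmf(probs) -> np.ndarray:
    """Exact pmf of a sum of independent Bernoulli(p_k) variables.

    Computed by iterated convolution (dynamic programming); for ``m`` terms
    the result has support ``0..m``.  This is the distribution of opponent
    attendance under independent mixed strategies.
    """
    probs = _validate_probs(probs)
    pmf = np.array([1.0])
    for p in probs:
        pmf = np.convolve(pmf, [1.0 - p, p])
    return pmf


def tail_probability(beliefs, threshold: int) -> float:
    """``P(sum of independent Bernoulli(beliefs) >= threshold)``, exactly."""
    if threshold < 0:
        raise DomainError("threshold must be non-negative")
    pmf = poisson_binomial_pmf(beliefs)
    if threshold >= len(pmf):
        return 0.0
    return float(pmf[threshold:].sum())


def expected_payoff_binary(beliefs_excluding_i, spec: GameSpec) -> float:
    """Expected payoff of attending, ``H - (H+L) P(opponent attendance >= c)``.

    ``beliefs_excluding_i`` holds the N-1 opponents' attendance frequencies;
    the payoff of staying home is identically 0.
    """
    beliefs = _validate_probs(beliefs_excluding_i)
    if len(beliefs) != spec.n_players - 1:
        raise DomainError(
            f"expected {spec.n_players - 1} opponent beliefs, got {len(beliefs)}"
        )
    tail = tail_probability(beliefs, spec.capacity)
    return spec.gain - (spec.gain + spec.loss) * tail


def best_response_binary(beliefs_excluding_i, spec: GameSpec) -> int:
    """Best response in the binary game; ties (tail == u) go to attending."""
    beliefs = _validate_probs(beliefs_excluding_i)
    if len(beliefs) != spec.n_players - 1:
        raise DomainError(
            f"expected {spec.n_players - 1} opponent beliefs, got {len(beliefs)}"
        )
    tail = tail_probability(beliefs, spec.capacity)
    return 1 if tail <= spec.indifference else 0


def fictitious_play_binary(spec: GameSpec, horizon: int, init) -> np.ndarray:
    """Simultaneous-update fictitious play of the binary game.

    Each round every player best-responds to the others' empirical
    attendance frequencies and the balance equation
    ``(t+1) x_i(t+1) = t x_i(t) + I{attend}`` advances all counters at once.
    The supplied ``init`` is the time-0 prior (empirical frequencies are
    undefined at t = 0); counts accumulate from round 1.

    Returns an ``(horizon + 1, N)`` array of belief rows, row 0 = init.
    """
    if spec.n_actions != 2:
        raise DomainError("fictitious_play_binary requires a two-action game")
    if horizon < 1:
        raise DomainError("horizon must be at least 1")
    x = _validate_probs(init)
    if len(x) != spec.n_players:
        raise DomainError(f"init must have {spec.n_players} entries")
    traj = np.empty((horizon + 1, spec.n_players))
    traj[0] = x
    for t in range(horizon):
        responses = np.array(
            [
                best_response_binary(np.delete(x, i), spec)
                for i in range(spec.n_players)
            ],
            dtype=float,
        )
        x = (t * x + responses) / (t + 1)
        traj[t + 1] = x
    return traj


def _profile_payoffs(profile: tuple[int, ...], spec: GameSpec) -> np.ndarray:
    total = sum(profile)
    return np.array(
        [payoff_value(i, a, total, spec) for i, a in enumerate(profile)]
    )


def enumerate_pure_nash_binary(spec: GameSpec) -> set[tuple[int, ...]]:
    """All pure Nash profiles of the binary game by exhaustive 2^N scan.

    Every equilibrium has exactly ``c`` attendees: an extra attendee would
    tip the total over capacity and earn ``-L``, while with spare capacity a
    stay-at-home strictly gains by attending.
    """
    if spec.n_actions != 2:
        raise DomainError("binary enumeration requires a two-action game")
    if spec.n_players > 20:
        raise ResourceError(
            f"exhaustive scan over 2^{spec.n_players} profiles refused; N must be <= 20"
        )
    equilibria = set()
    for profile in itertools.product((0, 1), repeat=spec.n_players):
        if is_pure_nash_generalized(list(profile), spec):
            equilibria.add(profile)
    return equilibria


def _validate_pmf(pmf: np.ndarray) -> np.ndarray:
    pmf = np.asarray(pmf, dtype=float)
    if pmf.ndim != 1 or len(pmf) == 0:
        raise DomainError("a pmf must be a non-empty one-dimensional array")
    if np.any(pmf < -_PMF_TOL):
        raise DomainError("pmf entries must be non-negative")
    if abs(pmf.sum() - 1.0) > 1e-9:
        raise DomainError("pmf must sum to one")
    return np.clip(pmf, 0.0, None)


def aggregated_belief_pmf(opponent_pmfs) -> np.ndarray:
    """Pmf of aggregate opponent action ``Y_i = sum of opponents' actions``.

    Convolves the opponents' per-action pmfs; with ``N - 1`` opponents on
    ``k`` actions the support is ``0..(N-1)(k-1)``.
    """
    agg = np.array([1.0])
    for pmf in opponent_pmfs:
        agg = np.convolve(agg, _validate_pmf(pmf))
    return agg


def expected_payoff_generalized(
    action: int, agg: np.ndarray, player: int, spec: GameSpec
) -> float:
    """Expected payoff of ``action`` against an aggregate opponent belief.

    For ``j >= 1`` this is ``w_ij (H + L) (u - P(Y_i >= c - j + 1))`` with
    ``u = H/(H+L)``; action 0 pays 0.  The weak capacity rule (total <= c
    wins) is used throughout.
    """
    if not 0 <= action <= spec.n_actions - 1:
        raise DomainError(f"action {action} outside 0..{spec.n_actions - 1}")
    if action == 0:
        return 0.0
    agg = np.asarray(agg, dtype=float)
    lo = spec.capacity - action + 1
    tail = float(agg[max(lo, 0):].sum()) if lo < len(agg) else 0.0
    w = spec.weights[player, action]
    return w * (spec.gain + spec.loss) * (spec.indifference - tail)


def _best_action_generalized(beliefs: np.ndarray, player: int, spec: GameSpec) -> int:
    others = [beliefs[j] for j in range(spec.n_players) if j != player]
    agg = aggregated_belief_pmf(others)
    payoffs = np.array(
        [
            expected_payoff_generalized(a, agg, player, spec)
            for a in range(spec.n_actions)
        ]
    )
    return int(np.argmax(payoffs))  # ties break toward the lowest action index


def fictitious_play_generalized(
    spec: GameSpec, horizon: int, init
) -> list[FictitiousPlayState]:
    """Simultaneous-update fictitious play over the k-action game.

    ``init`` is an ``(N, k)`` array of prior action pmfs used at time 0.
    Each round every player adds one count to its expected-payoff argmax
    (ties to the lowest action) and empirical frequencies are re-derived as
    counts / t.  Returns the full state trajectory including the prior.
    """
    if horizon < 1:
        raise DomainError("horizon must be at least 1")
    init = np.asarray(init, dtype=float)
    if init.shape != (spec.n_players, spec.n_actions):
        raise DomainError(
            f"init must have shape {(spec.n_players, spec.n_actions)}"
        )
    for row in init:
        _validate_pmf(row)
    counts = np.zeros((spec.n_players, spec.n_actions), dtype=int)
    beliefs = init.copy()
    states = [FictitiousPlayState(0, counts.copy(), beliefs.copy())]
    for t in range(1, horizon + 1):
        chosen = [
            _best_action_generalized(beliefs, i, spec)
            for i in range(spec.n_players)
        ]
        for i, a in enumerate(chosen):
            counts[i, a] += 1
        beliefs = counts / t
        states.append(FictitiousPlayState(t, counts.copy(), beliefs.copy()))
    return states


def is_pure_nash_generalized(profile, spec: GameSpec) -> bool:
    """True iff no player can strictly improve by a unilateral deviation.

    With unit weights the pure equilibria are exactly the profiles whose
    actions sum to the capacity ``c``.
    """
    profile = list(profile)
    if len(profile) != spec.n_players:
        raise DomainError(f"profile must have {spec.n_players} entries")
    if any(not 0 <= a <= spec.n_actions - 1 for a in profile):
        raise DomainError("profile contains an out-of-range action")
    total = sum(profile)
    for i, a in enumerate(profile):
        current = payoff_value(i, a, total, spec)
        for alt in range(spec.n_actions):
            if alt == a:
                continue
            if payoff_value(i, alt, total - a + alt, spec) > current + _PMF_TOL:
                return False
    return True


def has_converged(
    trajectory: np.ndarray, tol: float = 1e-6, window: int = 100
) -> bool:
    """Flag convergence when beliefs moved less than ``tol`` over ``window`` steps."""
    traj = np.asarray(trajectory, dtype=float)
    if len(traj) <= window:
        return False
    return bool(np.max(np.abs(traj[-1] - traj[-1 - window])) < tol)
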