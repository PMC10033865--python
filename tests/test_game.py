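"""El Farol bar game engine: payoffs, beliefs, dynamics, equilibria."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from farolcare import (
    GameSpec,
    aggregated_belief_pmf,
    best_response_binary,
    enumerate_pure_nash_binary,
    expected_payoff_binary,
    expected_payoff_generalized,
    fictitious_play_binary,
    fictitious_play_generalized,
    indifference_threshold,
    is_pure_nash_generalized,
    payoff_value,
    pharmacy_game_matrix,
    tail_probability,
)
from farolcare.errors import DomainError, ResourceError
from farolcare.game import has_converged


def brute_force_tail(probs, threshold):
    """Independent oracle: enumerate all 2^m attendance outcomes."""
    total = 0.0
    for outcome in itertools.product((0, 1), repeat=len(probs)):
        if sum(outcome) >= threshold:
            prob = 1.0
            for p, x in zip(probs, outcome):
                prob *= p if x else 1 - p
            total += prob
    return total


class TestPayoffValue:
    @pytest.mark.parametrize(
        "action,total,expected",
        [
            (0, 100, 0.0),     # staying out always pays zero
            (1, 2, 2.0),       # at capacity: gain H
            (1, 3, -1.0),      # one over capacity: loss L
        ],
    )
    def test_capacity_rule(self, action, total, expected):
        spec = GameSpec(n_players=200, capacity=2, gain=2.0, loss=1.0)
        assert payoff_value(0, action, total, spec) == expected

    def test_weights_scale_attendance_payoffs(self):
        w = np.ones((3, 2))
        w[1, 1] = 2.5
        spec = GameSpec(n_players=3, capacity=1, gain=2.0, loss=1.0, weights=w)
        assert payoff_value(1, 1, 1, spec) == 5.0
        assert payoff_value(1, 1, 2, spec) == -2.5

    def test_out_of_range_action_rejected(self):
        spec = GameSpec(n_players=3, capacity=1)
        with pytest.raises(DomainError):
            payoff_value(0, 2, 2, spec)


class TestIndifferenceThreshold:
    @pytest.mark.parametrize(
        "gain,loss,expected", [(1, 1, 0.5), (3, 1, 0.75), (0.5, 1.5, 0.25)]
    )
    def test_ratio(self, gain, loss, expected):
        spec = GameSpec(n_players=3, capacity=1, gain=gain, loss=loss)
        assert indifference_threshold(spec) == pytest.approx(expected)

    @pytest.mark.parametrize("gain,loss", [(0, 1), (1, 0), (-1, 1)])
    def test_nonpositive_payoffs_rejected(self, gain, loss):
        with pytest.raises(DomainError):
            GameSpec(n_players=3, capacity=1, gain=gain, loss=loss)


class TestTailProbability:
    @pytest.mark.parametrize(
        "beliefs,threshold,expected",
        [
            ([0.5, 0.5, 0.5], 2, 0.5),   # 4 of 8 equally likely outcomes
            ([1.0, 1.0], 2, 1.0),
            ([0.0, 0.0, 0.0], 1, 0.0),
            ([0.3], 0, 1.0),
        ],
    )
    def test_known_values(self, beliefs, threshold, expected):
        assert tail_probability(beliefs, threshold) == pytest.approx(expected)

    def test_invalid_belief_rejected(self):
        with pytest.raises(DomainError):
            tail_probability([0.5, 1.2], 1)

    @settings(deadline=None, max_examples=100)
    @given(
        probs=st.lists(st.floats(0, 1), min_size=1, max_size=10),
        threshold=st.integers(0, 11),
    )
    def test_dp_equals_enumeration(self, probs, threshold):
        """The DP convolution must match full 2^m enumeration."""
        assert tail_probability(probs, threshold) == pytest.approx(
            brute_force_tail(probs, threshold), abs=1e-12
        )


class TestBinaryExpectedPayoffAndResponse:
    def test_half_beliefs_at_indifference(self):
        spec = GameSpec(n_players=4, capacity=2)
        assert expected_payoff_binary([0.5, 0.5, 0.5], spec) == pytest.approx(0.0)

    def test_empty_bar_pays_gain_full_bar_pays_loss(self):
        spec = GameSpec(n_players=4, capacity=2, gain=1.5, loss=2.5)
        assert expected_payoff_binary([0.0] * 3, spec) == pytest.approx(1.5)
        assert expected_payoff_binary([1.0] * 3, spec) == pytest.approx(-2.5)

    def test_wrong_length_rejected(self):
        spec = GameSpec(n_players=4, capacity=2)
        with pytest.raises(DomainError):
            expected_payoff_binary([0.5, 0.5], spec)

    def test_tie_goes_to_attending(self):
        # tail = 0.5 equals u = 0.5: the weak inequality favours action 1
        spec = GameSpec(n_players=4, capacity=2)
        assert best_response_binary([0.5, 0.5, 0.5], spec) == 1
        assert best_response_binary([1.0, 1.0, 1.0], spec) == 0
        assert best_response_binary([0.0, 0.0, 0.0], spec) == 1

    @settings(deadline=None, max_examples=50)
    @given(
        probs=st.lists(st.floats(0.01, 0.99), min_size=3, max_size=6),
        bump=st.floats(0.001, 0.01),
        data=st.data(),
    )
    def test_strictly_decreasing_in_opponent_attendance(self, probs, bump, data):
        spec = GameSpec(n_players=len(probs) + 1, capacity=len(probs) - 1)
        idx = data.draw(st.integers(0, len(probs) - 1))
        bumped = list(probs)
        bumped[idx] = min(bumped[idx] + bump, 1.0)
        if bumped[idx] > probs[idx]:
            assert expected_payoff_binary(bumped, spec) < expected_payoff_binary(
                probs, spec
            )


class TestFictitiousPlayBinary:
    def test_everyone_attends_an_empty_bar(self):
        spec = GameSpec(n_players=3, capacity=1)
        traj = fictitious_play_binary(spec, horizon=1, init=[0.0, 0.0, 0.0])
        assert np.allclose(traj[1], [1.0, 1.0, 1.0])

    def test_beliefs_stay_probabilities(self):
        spec = GameSpec(n_players=2, capacity=1)
        traj = fictitious_play_binary(spec, horizon=500, init=[0.3, 0.9])
        assert np.all(traj >= 0.0) and np.all(traj <= 1.0)

    def test_converges_to_pure_profile_filling_capacity(self):
        # asymmetric start: play sorts itself into c attendees and N-c abstainers
        spec = GameSpec(n_players=4, capacity=2)
        traj = fictitious_play_binary(spec, 10_000, init=[0.2, 0.4, 0.6, 0.8])
        final = traj[-1]
        rounded = np.round(final)
        assert np.max(np.abs(final - rounded)) < 0.05
        assert rounded.sum() == 2
        assert has_converged(traj)

    def test_horizon_must_be_positive(self):
        spec = GameSpec(n_players=3, capacity=1)
        with pytest.raises(DomainError):
            fictitious_play_binary(spec, 0, [0.5, 0.5, 0.5])


class TestPureNashBinary:
    def deviation_oracle(self, spec):
        """Brute force: a profile is Nash iff no unilateral flip helps."""
        eqs = set()
        for profile in itertools.product((0, 1), repeat=spec.n_players):
            total = sum(profile)

            def pay(a, t):
                return 0 if a == 0 else (spec.gain if t <= spec.capacity else -spec.loss)

            ok = True
            for i, a in enumerate(profile):
                alt = 1 - a
                if pay(alt, total - a + alt) > pay(a, total):
                    ok = False
                    break
            if ok:
                eqs.add(profile)
        return eqs

    @pytest.mark.parametrize("n,c", [(2, 1), (3, 2), (4, 2), (6, 3)])
    def test_matches_deviation_oracle(self, n, c):
        spec = GameSpec(n_players=n, capacity=c, gain=1.3, loss=0.7)
        assert enumerate_pure_nash_binary(spec) == self.deviation_oracle(spec)

    def test_equilibria_are_exactly_capacity_filling_profiles(self):
        """Every pure equilibrium has exactly c attendees, for all N <= 10."""
        for n in range(2, 11):
            for c in range(1, n):
                spec = GameSpec(n_players=n, capacity=c, gain=2.0, loss=0.5)
                expected = {
                    p
                    for p in itertools.product((0, 1), repeat=n)
                    if sum(p) == c
                }
                assert enumerate_pure_nash_binary(spec) == expected

    def test_large_n_refused(self):
        spec = GameSpec(n_players=21, capacity=5)
        with pytest.raises(ResourceError):
            enumerate_pure_nash_binary(spec)


class TestAggregatedBelief:
    def test_convolution_of_two_fair_coins(self):
        agg = aggregated_belief_pmf([[0.5, 0.5], [0.5, 0.5]])
        assert np.allclose(agg, [0.25, 0.5, 0.25])

    def test_identity_and_point_masses(self):
        assert np.allclose(aggregated_belief_pmf([[1.0]]), [1.0])
        agg = aggregated_belief_pmf([[0, 1]] * 3)
        assert np.allclose(agg, [0, 0, 0, 1])

    def test_invalid_pmf_rejected(self):
        with pytest.raises(DomainError):
            aggregated_belief_pmf([[0.5, 0.6]])


class TestGeneralizedExpectedPayoff:
    def test_empty_bar_and_full_bar(self):
        spec = GameSpec(n_players=2, capacity=1, n_actions=2)
        assert expected_payoff_generalized(1, np.array([1.0]), 0, spec) == pytest.approx(1.0)
        agg = np.zeros(2)
        agg[1] = 1.0  # opponents already fill capacity c = 1
        assert expected_payoff_generalized(1, agg, 0, spec) == pytest.approx(-1.0)

    def test_action_zero_pays_zero(self):
        spec = GameSpec(n_players=3, capacity=2, n_actions=3)
        assert expected_payoff_generalized(0, np.array([0.2, 0.5, 0.3]), 0, spec) == 0.0

    def test_action_out_of_range(self):
        spec = GameSpec(n_players=3, capacity=2, n_actions=3)
        with pytest.raises(DomainError):
            expected_payoff_generalized(3, np.array([1.0]), 0, spec)


class TestFictitiousPlayGeneralized:
    def test_two_action_game_reduces_to_binary_dynamics(self):
        spec = GameSpec(n_players=3, capacity=1, gain=1.0, loss=2.0)
        init_b = [0.3, 0.5, 0.7]
        traj_b = fictitious_play_binary(spec, 200, init_b)
        init_g = np.column_stack([1 - np.array(init_b), init_b])
        states = fictitious_play_generalized(spec, 200, init_g)
        freq_1 = np.array([s.beliefs[:, 1] for s in states])
        assert np.allclose(freq_1, traj_b)

    def test_converged_modal_actions_fill_capacity(self):
        # differentiated priors let play settle on a pure profile with sum c
        spec = GameSpec(n_players=3, capacity=2, n_actions=3)
        init = np.array([[0.9, 0.05, 0.05], [0.05, 0.9, 0.05], [0.05, 0.9, 0.05]])
        states = fictitious_play_generalized(spec, 3000, init)
        final = states[-1].beliefs
        assert final.argmax(axis=1).sum() == 2
        assert np.all(np.abs(np.sort(final, axis=1)[:, -1] - 1.0) < 0.05)

    def test_frequencies_are_pmfs_each_step(self):
        spec = GameSpec(n_players=3, capacity=2, n_actions=3)
        init = np.full((3, 3), 1 / 3)
        for s in fictitious_play_generalized(spec, 50, init):
            assert np.all(s.beliefs >= 0)
            assert np.allclose(s.beliefs.sum(axis=1), 1.0)
            if s.time:
                assert np.all(s.action_counts.sum(axis=1) == s.time)

    def test_zero_horizon_rejected(self):
        spec = GameSpec(n_players=3, capacity=2, n_actions=3)
        with pytest.raises(DomainError):
            fictitious_play_generalized(spec, 0, np.full((3, 3), 1 / 3))


class TestPureNashGeneralized:
    @settings(deadline=None, max_examples=80)
    @given(data=st.data())
    def test_capacity_sum_profiles_are_equilibria(self, data):
        n = data.draw(st.integers(2, 6))
        k = data.draw(st.integers(2, 4))
        c = data.draw(st.integers(1, (n - 1) * (k - 1)))
        spec = GameSpec(n_players=n, capacity=c, n_actions=k)
        profile = data.draw(
            st.lists(st.integers(0, k - 1), min_size=n, max_size=n).filter(
                lambda p: sum(p) == c
            )
        )
        assert is_pure_nash_generalized(profile, spec)

    def test_over_capacity_profile_is_not_equilibrium(self):
        spec = GameSpec(n_players=3, capacity=2, n_actions=3)
        assert not is_pure_nash_generalized([1, 1, 1], spec)  # sum c+1, attendee quits

    def test_all_zero_profile_is_not_equilibrium(self):
        spec = GameSpec(n_players=4, capacity=2, n_actions=3)
        assert not is_pure_nash_generalized([0, 0, 0, 0], spec)

    def test_invalid_profile_rejected(self):
        spec = GameSpec(n_players=3, capacity=2, n_actions=3)
        with pytest.raises(DomainError):
            is_pure_nash_generalized([0, 3, 0], spec)


class TestPharmacyMatrix:
    @pytest.mark.parametrize(
        "E,e", [(2.0, 1.0), (0.0, 0.0), (1.135, 0.2), (-0.5, 0.3)]
    )
    def test_additive_structure(self, E, e):
        m = pharmacy_game_matrix(E, e).matrix
        assert m["neither"] == 0.0
        assert m["both"] == pytest.approx(m["hospital_only"] + m["pharmacy_only"])
        assert m["hospital_only"] == pytest.approx(E)
        assert m["pharmacy_only"] == pytest.approx(e)

    def test_array_layout(self):
        arr = pharmacy_game_matrix(2.0, 1.0).as_array()
        assert arr[1, 1] == pytest.approx(3.0)
        assert arr[0, 0] == 0.0
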