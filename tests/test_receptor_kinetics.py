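"""Unit and property tests for the sequential-binding IP3R subunit model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from calwave.receptor_kinetics import (ChannelState, ClusterState,
                                       KineticParams, SubunitState,
                                       TimeStepError, channel_is_open,
                                       count_open,
                                       enumerate_channel_configurations,
                                       ignition_point,
                                       n_channel_configurations,
                                       open_probability,
                                       stationary_distribution, step_subunit,
                                       transition_rates)

X000, X100, X110, X111 = (SubunitState.X000, SubunitState.X100,
                          SubunitState.X110, SubunitState.X111)


class TestTransitionRates:
    @pytest.mark.parametrize("state,ca,expected", [
        # fully occupied subunit can only shed the inhibitory ion
        (X111, 0.7, {X110: 0.064}),
        (X111, 0.0, {X110: 0.064}),
        # zero calcium kills the activating on-rate
        (X100, 0.0, {X000: 32.0, X110: 0.0}),
        # IP3 binding at [IP3] = 0.5 uM: 24.0 * 0.5
        (X000, 1.0, {X100: 12.0}),
    ])
    def test_printed_rates(self, kinetics, state, ca, expected):
        assert transition_rates(state, ca, kinetics) == expected

    def test_chain_is_sequential(self, kinetics):
        # each state only reaches its chain neighbours
        succ = {s: set(transition_rates(s, 0.5, kinetics))
                for s in SubunitState}
        assert succ[X000] == {X100}
        assert succ[X100] == {X000, X110}
        assert succ[X110] == {X100, X111}
        assert succ[X111] == {X110}

    def test_negative_calcium_rejected(self, kinetics):
        with pytest.raises(ValueError):
            transition_rates(X000, -0.1, kinetics)


class TestStepSubunit:
    def test_stay_probability_single_exit(self, kinetics, rng):
        """X111 at zero calcium exits at rate k_3 only: the linearized
        stay probability is 1 - 0.064 * 0.0005."""
        n = 200_000
        stays = sum(step_subunit(X111, 0.0, 0.0005, rng, kinetics) == X111
                    for _ in range(n))
        p_stay = 1.0 - 0.064 * 0.0005
        se = np.sqrt(p_stay * (1 - p_stay) / n)
        assert abs(stays / n - p_stay) < 3 * se

    def test_no_rates_means_no_move(self, rng):
        # an X000 subunit with zero IP3 has zero total exit rate
        params = KineticParams(ip3=0.0)
        assert step_subunit(X000, 0.0, 0.0005, rng, params) == X000

    def test_transition_frequencies_match_linearized_probs(self, kinetics):
        """Empirical one-step transition frequencies agree with rate*dt
        within 3 binomial standard errors (both exits of X100)."""
        rng = np.random.default_rng(5)
        dt, ca, n = 0.0005, 1.0, 1_000_000
        counts = {X000: 0, X110: 0, X100: 0}
        for _ in range(n):
            counts[step_subunit(X100, ca, dt, rng, kinetics)] += 1
        for succ, rate in transition_rates(X100, ca, kinetics).items():
            p = rate * dt
            se = np.sqrt(p * (1 - p) / n)
            assert abs(counts[succ] / n - p) <= 3 * se

    def test_oversized_step_rejected(self, kinetics, rng):
        with pytest.raises(TimeStepError):
            step_subunit(X100, 10.0, 1.0, rng, kinetics)

    def test_reachability_closed(self, kinetics, rng):
        state = X000
        for _ in range(5000):
            state = step_subunit(state, 0.5, 0.0005, rng, kinetics)
            assert state in set(SubunitState)


class TestChannelAndCluster:
    @pytest.mark.parametrize("subunits,is_open", [
        ((X110,) * 4, True),
        ((X110, X110, X110, X100), True),
        ((X110, X110, X100, X100), False),
        ((X000,) * 4, False),
        ((X111,) * 4, False),   # inhibited subunits are not active
    ])
    def test_three_of_four_rule(self, subunits, is_open):
        assert channel_is_open(ChannelState(subunits)) is is_open

    def test_count_open(self):
        closed = ChannelState((X000,) * 4)
        opened = ChannelState((X110,) * 4)
        assert count_open(ClusterState.all_closed(64)) == 0
        assert count_open(ClusterState([opened] * 64)) == 64
        assert count_open(ClusterState([opened] * 3 + [closed] * 61)) == 3

    def test_channel_size_enforced(self):
        with pytest.raises(ValueError):
            ChannelState((X000, X000, X000))

    def test_tetramer_configuration_count(self):
        configs = enumerate_channel_configurations()
        assert len(set(configs)) == 256
        assert n_channel_configurations() == 256


class TestStationaryDistribution:
    def test_zero_calcium_blocks_ca_states(self, kinetics):
        pi = stationary_distribution(0.0, kinetics)
        assert pi[X110] == 0.0 and pi[X111] == 0.0
        assert pi.sum() == pytest.approx(1.0)

    @given(ca=st.floats(0.0, 10.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_normalization_and_detailed_balance(self, ca):
        params = KineticParams()
        pi = stationary_distribution(ca, params)
        assert pi.sum() == pytest.approx(1.0)
        assert np.all(pi >= 0)
        # detailed balance across each edge of the chain
        assert pi[X100] * params.k_1 == pytest.approx(
            pi[X000] * params.k1 * params.ip3)
        assert pi[X110] * params.k_2 == pytest.approx(pi[X100] * params.k2 * ca)
        assert pi[X111] * params.k_3 == pytest.approx(pi[X110] * params.k3 * ca)

    @pytest.mark.parametrize("ca", [0.05, 0.3, 1.0])
    def test_ergodic_agreement(self, kinetics, ca):
        """Long-run occupancy of the simulated chain matches the
        detailed-balance solution within 3 standard errors.

        Many chains are run in parallel and sampled at intervals longer
        than the slowest mixing time (1/k_3 ~ 16 s) so the snapshots are
        effectively independent.
        """
        dt = 0.0005
        n_chains, burn_s, gap_s, n_snap = 400, 32.0, 20.0, 3
        rng = np.random.default_rng(99)
        fwd_const = np.array([kinetics.k1 * kinetics.ip3, 0.0, 0.0, 0.0])
        fwd_ca = np.array([0.0, kinetics.k2, kinetics.k3, 0.0])
        bwd = np.array([0.0, kinetics.k_1, kinetics.k_2, kinetics.k_3])
        states = np.zeros(n_chains, dtype=np.int8)
        counts = np.zeros(4)
        total_steps = int((burn_s + gap_s * n_snap) / dt)
        snap_steps = {int((burn_s + gap_s * (k + 1)) / dt)
                      for k in range(n_snap)}
        for step in range(1, total_steps + 1):
            p_f = (fwd_const[states] + fwd_ca[states] * ca) * dt
            p_b = bwd[states] * dt
            u = rng.random(n_chains)
            states = (states + ((u >= p_b) & (u < p_b + p_f)).astype(np.int8)
                      - (u < p_b).astype(np.int8))
            if step in snap_steps:
                counts += np.bincount(states, minlength=4)
        n = counts.sum()
        emp = counts / n
        pi = stationary_distribution(ca, kinetics)
        for s in SubunitState:
            se = np.sqrt(max(pi[s] * (1 - pi[s]), 1e-12) / n)
            assert abs(emp[s] - pi[s]) <= 3 * se + 1e-9, (s, emp, pi)


class TestOpenProbability:
    def test_limits(self, kinetics):
        assert open_probability(0.0, kinetics) == 0.0

    def test_matches_binomial_composition(self, kinetics):
        for ca in (0.02, 0.1, 1.0):
            pa = stationary_distribution(ca, kinetics)[X110]
            expected = pa ** 4 + 4 * pa ** 3 * (1 - pa)
            assert open_probability(ca, kinetics) == pytest.approx(expected)

    def test_bell_shape_single_interior_maximum(self, kinetics):
        ca_grid = np.linspace(1e-4, 10.0, 2000)
        p = np.array([open_probability(c, kinetics) for c in ca_grid])
        i_max = int(np.argmax(p))
        assert 0 < i_max < len(ca_grid) - 1
        # rises before the peak, falls after: exactly one sign change
        d = np.diff(p)
        assert np.all(d[:i_max] > 0) and np.all(d[i_max + 1:] < 0)

    def test_ignition_point_is_the_argmax(self, kinetics):
        ca0 = ignition_point(kinetics)
        assert 0.0 < ca0 < 1.0
        for delta in (-0.01, 0.01):
            assert open_probability(ca0 + delta, kinetics) <= \
                open_probability(ca0, kinetics)


def test_exit_probability_bookkeeping(kinetics):
    """Total one-step exit probability stays below 5% at dt = 0.0005 s for
    every state over the physiological calcium range."""
    dt = 0.0005
    for ca in np.linspace(0.0, 1.6, 33):
        for state in SubunitState:
            total = sum(transition_rates(state, ca, kinetics).values())
            assert total * dt < 0.05
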