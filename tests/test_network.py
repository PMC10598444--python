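"""Core dynamics: stepping, attractor enumeration, sampling, essential reduction."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import boolmod as bm
from boolmod.network import _bit

from conftest import attractor_tuples, brute_attractors, random_test_network


def s(string: str) -> int:
    return bm.string_to_state(string)


class TestSynchronousStep:
    @pytest.mark.parametrize(
        "start, expected",
        [("010", "101"), ("110", "100"), ("100", "000"), ("000", "000"), ("111", "010")],
    )
    def test_worked_example_transitions(self, fig1, start, expected):
        assert fig1.state_string(bm.synchronous_step(fig1, s(start))) == expected

    def test_agrees_with_direct_logic_on_all_states(self, fig1, fig1_oracle_step):
        for state in range(8):
            bits = tuple(_bit(state, i, 3) for i in range(3))
            expected = int("".join(map(str, fig1_oracle_step(bits))), 2)
            assert bm.synchronous_step(fig1, state) == expected

    def test_identity_network_fixes_every_state(self):
        net = bm.parse_rules("a, a\nb, b\nc, c\n")
        for state in range(8):
            assert bm.synchronous_step(net, state) == state

    def test_external_inputs_required_iff_declared(self, fig1, product_factors):
        _, G, _ = product_factors
        with pytest.raises(ValueError):
            bm.synchronous_step(G, 0)
        with pytest.raises(ValueError):
            bm.synchronous_step(fig1, 0, {"u": 1})
        # y1'=u1|(u2&y2)=1, y2'=!u2&y1=1 from (y1,y2)=(1,0), u=(1,0)
        assert bm.synchronous_step(G, s("10"), {"u1": 1, "u2": 0}) == s("11")

    def test_transition_table_matches_stepping(self, fig1):
        T = bm.transition_table(fig1)
        assert [int(T[x]) for x in range(8)] == [
            bm.synchronous_step(fig1, x) for x in range(8)
        ]


class TestEnumerateAttractors:
    def test_worked_example_attractor_set(self, fig1):
        aset = bm.enumerate_attractors(fig1)
        assert attractor_tuples(aset) == {(s("000"),), (s("011"),), (s("010"), s("101"))}
        sizes = aset.basin_sizes()
        assert sizes[bm.Attractor((s("000"),), 3)] == 3
        assert sizes[bm.Attractor((s("010"), s("101")), 3)] == 4

    def test_constant_network_single_global_basin(self):
        net = bm.parse_rules("a, 0\nb, 0\nc, 0\n")
        aset = bm.enumerate_attractors(net)
        assert attractor_tuples(aset) == {(0,)}
        assert aset.basin_sizes()[bm.Attractor((0,), 3)] == 8

    def test_coupled_example_six_attractors(self, coupled_net):
        aset = bm.enumerate_attractors(coupled_net)
        expected = {
            (s("0000"),), (s("1100"),), (s("1111"),),
            (s("1101"), s("1110")), (s("0100"), s("1000")), (s("0101"), s("1010")),
        }
        assert attractor_tuples(aset) == expected

    def test_refuses_external_parameters(self, product_factors):
        _, G, _ = product_factors
        with pytest.raises(ValueError):
            bm.enumerate_attractors(G)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_and_partitions_space(self, seed):
        rng = np.random.default_rng(seed)
        net = random_test_network(rng, n=6, k=2)
        aset = bm.enumerate_attractors(net)
        T = bm.transition_table(net)
        assert attractor_tuples(aset) == brute_attractors(lambda x: int(T[x]), 6)
        assert sum(aset.basin_sizes().values()) == 64
        # stepping around each cycle returns to the start
        for att in aset:
            states = att.states
            for i, x in enumerate(states):
                assert bm.synchronous_step(net, x) == states[(i + 1) % len(states)]


class TestIterateToAttractor:
    @pytest.mark.parametrize(
        "start, att_states, transient",
        [("110", ("000",), 2), ("000", ("000",), 0), ("111", ("010", "101"), 1)],
    )
    def test_transient_lengths(self, fig1, start, att_states, transient):
        att, steps = bm.iterate_to_attractor(fig1, s(start))
        assert att == bm.Attractor(tuple(s(x) for x in att_states), 3)
        assert steps == transient


class TestSampleAttractors:
    def test_finds_all_three_with_many_samples(self, fig1):
        aset = bm.sample_attractors(fig1, 500, seed=0)
        assert aset.as_set() == bm.enumerate_attractors(fig1).as_set()

    def test_single_sample_yields_single_attractor(self, fig1):
        assert len(bm.sample_attractors(fig1, 1, seed=0)) == 1

    def test_deterministic_given_seed(self, coupled_net):
        a = bm.sample_attractors(coupled_net, 50, seed=42)
        b = bm.sample_attractors(coupled_net, 50, seed=42)
        assert a.as_set() == b.as_set() and a.basin == b.basin

    @pytest.mark.parametrize("seed", range(5))
    def test_always_subset_of_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        net = random_test_network(rng, n=8, k=2)
        sampled = bm.sample_attractors(net, 20, seed=seed)
        assert sampled.as_set() <= bm.enumerate_attractors(net).as_set()


class TestEssentialReduction:
    def test_tautological_regulator_removed(self):
        # f = x1 | (x2 & !x2) == x1
        net = bm.parse_rules("x1, x1 | (x2 & !x2)\nx2, x1\n")
        red = bm.reduce_to_essential_regulators(net)
        assert red.rules[0] == bm.Rule(("x1",), (0, 1))

    def test_fully_essential_rule_unchanged(self, fig1):
        assert bm.reduce_to_essential_regulators(fig1) == fig1

    @pytest.mark.parametrize("seed", range(5))
    def test_planted_dummy_removed_and_dynamics_preserved(self, seed):
        rng = np.random.default_rng(seed)
        net = random_test_network(rng, n=8, k=2)
        # plant a dummy regulator on variable 0: duplicate the table along a new axis
        rule = net.rules[0]
        dummy = next(v for v in net.variables if v not in rule.regulators)
        fat = bm.Rule(rule.regulators + (dummy,),
                      tuple(v for v in rule.table for _ in range(2)))
        planted = bm.BooleanNetwork(net.variables, (fat,) + net.rules[1:])
        red = bm.reduce_to_essential_regulators(planted)
        assert dummy not in red.rules[0].regulators
        assert np.array_equal(bm.transition_table(red), bm.transition_table(planted))
        # idempotent
        assert bm.reduce_to_essential_regulators(red) == red

    @given(st.integers(0, 2**8 - 1))
    def test_reduction_preserves_three_input_rule_semantics(self, bits):
        table = tuple((bits >> i) & 1 for i in range(8))
        net = bm.BooleanNetwork(
            ("a", "b", "c"),
            (bm.Rule(("a", "b", "c"), table), bm.Rule(("a",), (0, 1)), bm.Rule(("b",), (0, 1))),
        )
        red = bm.reduce_to_essential_regulators(net)
        assert np.array_equal(bm.transition_table(red), bm.transition_table(net))


class TestStateText:
    def test_round_trip_and_convention(self):
        # "010" means x1=0, x2=1, x3=0
        assert bm.string_to_state("010") == 2
        assert bm.state_to_string(2, 3) == "010"
        with pytest.raises(ValueError):
            bm.state_to_string(8, 3)

    def test_attractor_canonical_rotation(self):
        a = bm.Attractor((5, 2), 3)
        b = bm.Attractor((2, 5), 3)
        assert a == b and a.states[0] == 2
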