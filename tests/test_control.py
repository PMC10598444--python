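"""Control actions, stabilization verification, modular control composition."""

import pytest

import boolmod as bm
from boolmod.control import delete_edge, delete_node, fix_edge, pin


def s(string: str) -> int:
    return bm.string_to_state(string)


def steady(string: str) -> bm.Attractor:
    return bm.Attractor((s(string),), len(string))


class TestApplyControls:
    def test_pinning_two_nodes_collapses_to_single_steady_state(self, coupled_net):
        controlled = bm.apply_controls(coupled_net, [pin("x1", 1), pin("x3", 1)])
        aset = bm.enumerate_attractors(controlled)
        assert aset.as_set() == {steady("1111")}

    def test_empty_control_set_is_identity_up_to_reduction(self, fig1):
        assert bm.apply_controls(fig1, []) == bm.reduce_to_essential_regulators(fig1)

    def test_pinning_every_node_gives_the_pinned_vector(self, fig1):
        mu = [pin("x1", 1), pin("x2", 0), pin("x3", 1)]
        aset = bm.enumerate_attractors(bm.apply_controls(fig1, mu))
        assert aset.as_set() == {steady("101")}

    def test_node_deletion_substitutes_zero_everywhere(self, fig1):
        controlled = bm.apply_controls(fig1, [delete_node("x2")])
        # x2 pinned to 0; f1 = 0 & !x3 -> 0, f3 = !x1 & 0 -> 0
        assert controlled.rule_of("x1") == bm.Rule((), (0,))
        assert controlled.rule_of("x2") == bm.Rule((), (0,))
        assert controlled.rule_of("x3") == bm.Rule((), (0,))

    def test_edge_controls_touch_only_the_target_rule(self, fig1):
        controlled = bm.apply_controls(fig1, [fix_edge("x3", "x1", 0)])
        # f1 = x2 & !0 = x2; f2 still reads x3
        assert controlled.rule_of("x1") == bm.Rule(("x2",), (0, 1))
        assert controlled.rule_of("x2") == bm.Rule(("x3",), (0, 1))
        deleted = bm.apply_controls(fig1, [delete_edge("x3", "x1")])
        assert deleted.rule_of("x1") == controlled.rule_of("x1")

    def test_conflicting_pins_rejected(self, fig1):
        with pytest.raises(ValueError):
            bm.apply_controls(fig1, [pin("x1", 0), pin("x1", 1)])

    def test_missing_edge_rejected(self, fig1):
        with pytest.raises(ValueError):
            bm.apply_controls(fig1, [fix_edge("x1", "x2", 1)])


class TestVerifyStabilization:
    def test_toy_example_stabilized(self, coupled_net):
        assert bm.verify_stabilization(
            coupled_net, [pin("x1", 1), pin("x3", 1)], steady("1111")
        )

    def test_empty_controls_on_multistable_network(self, coupled_net):
        assert not bm.verify_stabilization(coupled_net, [], steady("0000"))

    def test_inconsistent_pin_fails(self, coupled_net):
        assert not bm.verify_stabilization(
            coupled_net, [pin("x1", 0), pin("x3", 1)], steady("1111")
        )


class TestComposeModuleControls:
    def test_toy_example_composition(self, coupled_net):
        dec = bm.structural_decompose(coupled_net)
        mu, C = bm.compose_module_controls(
            dec, [([pin("x1", 1)], steady("11")), ([pin("x3", 1)], steady("11"))]
        )
        assert C == steady("1111")
        assert bm.verify_stabilization(coupled_net, mu, C)

    def test_single_module_passthrough(self, fig1):
        dec = bm.structural_decompose(fig1)
        mu, C = bm.compose_module_controls(dec, [([pin("x2", 1), pin("x3", 1)],
                                                  steady("011"))])
        assert C == steady("011") and bm.verify_stabilization(fig1, mu, C)

    def test_independent_modules_with_steady_targets(self):
        net = bm.parse_rules("a, b\nb, a\np, q\nq, p\n")
        dec = bm.structural_decompose(net)
        mu, C = bm.compose_module_controls(
            dec, [([pin("a", 1)], steady("11")), ([pin("p", 0)], steady("00"))]
        )
        assert C == steady("1100")

    def test_cycle_cycle_targets_refused(self):
        # each factor is a 4-cycle oscillator with a single attractor, so the
        # module controls (none needed) are valid but both targets are cyclic
        net = bm.parse_rules("a, !b\nb, a\np, !q\nq, p\n")
        dec = bm.structural_decompose(net)
        cyc = bm.enumerate_attractors(bm.parse_rules("a, !b\nb, a\n")).attractors[0]
        cyc2 = bm.enumerate_attractors(bm.parse_rules("p, !q\nq, p\n")).attractors[0]
        assert len(cyc) == 4
        with pytest.raises(bm.CompositionError):
            bm.compose_module_controls(dec, [([], cyc), ([], cyc2)])

    def test_bad_module_controls_rejected(self, coupled_net):
        dec = bm.structural_decompose(coupled_net)
        with pytest.raises(ValueError):
            bm.compose_module_controls(
                dec, [([], steady("11")), ([pin("x3", 1)], steady("11"))]
            )

    @pytest.mark.parametrize("seed", range(25))
    def test_theorem_on_random_two_module_networks(self, seed):
        """Union of module controls stabilizes the whole network."""
        net, _ = bm.generate_modular_network(bm.GeneratorConfig(8, 2, 2, seed=seed))
        dec = bm.structural_decompose(net)
        F1, F2 = dec.modules
        # pick a steady target for module 1: pin everything to an arbitrary vector
        target1 = steady("1" * F1.n)
        mu1 = [pin(v, 1) for v in F1.variables]
        # drive module 2 by the stabilized upstream and stabilize it likewise
        target2 = steady("0" * F2.n)
        mu2 = [pin(v, 0) for v in F2.variables]
        mu, C = bm.compose_module_controls(dec, [(mu1, target1), (mu2, target2)])
        assert bm.verify_stabilization(net, mu, C)

    @pytest.mark.parametrize("seed", range(10))
    def test_module_by_module_search_composes_correctly(self, seed):
        net, _ = bm.generate_modular_network(bm.GeneratorConfig(8, 2, 2, seed=100 + seed))
        target = steady("1" * net.n)
        sols = bm.search_minimal_controls(net, target, max_size=net.n, mode="modular")
        assert sols
        assert bm.verify_stabilization(net, sols[0], target)


class TestSearchMinimalControls:
    def test_toy_example_minimal_size_two(self, coupled_net):
        sols = bm.search_minimal_controls(coupled_net, steady("1111"), max_size=2)
        assert sols and all(len(sol) == 2 for sol in sols)
        assert frozenset([pin("x1", 1), pin("x3", 1)]) in sols
        for sol in sols:
            assert bm.verify_stabilization(coupled_net, sol, steady("1111"))

    def test_already_stable_network_needs_nothing(self):
        net = bm.parse_rules("a, b\nb, 1\n")
        sols = bm.search_minimal_controls(net, steady("11"), max_size=2)
        assert sols == [frozenset()]

    def test_modular_and_global_agree_on_toy_example(self, coupled_net):
        target = steady("1111")
        global_sols = bm.search_minimal_controls(coupled_net, target, max_size=2,
                                                 mode="global")
        modular_sols = bm.search_minimal_controls(coupled_net, target, max_size=2,
                                                  mode="modular")
        assert modular_sols and global_sols
        assert len(modular_sols[0]) == len(global_sols[0])
        assert modular_sols[0] in global_sols

    def test_exhausted_budget_returns_empty(self, coupled_net):
        sols = bm.search_minimal_controls(coupled_net, steady("1111"), max_size=1)
        assert sols == []

    def test_consistent_extra_pin_never_unstabilizes(self, coupled_net):
        base = frozenset([pin("x1", 1), pin("x3", 1)])
        extra = base | {pin("x2", 1)}
        assert bm.verify_stabilization(coupled_net, extra, steady("1111"))
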