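"""Node and edge controls, stabilization checks, and modular composition.

A *control action* intervenes on a network: pinning a node to a constant,
deleting a node (pinned to a configurable constant, default 0, and
substituted out of every rule), fixing an edge (the source variable replaced
by a constant inside the target's rule only), or deleting an edge (edge
fixed to a constant, default 0).  A control set *stabilizes* a network at an
attractor C when the controlled network has C as its only attractor.

The modular composition result: for a decomposable network
``F = F1 |x_P F2``, controls stabilizing the upstream module at ``C1``
together with controls stabilizing the driven downstream module at ``C2``
stabilize the whole network at ``C1 (+) C2`` — provided at least one of
``C1``, ``C2`` is a steady state.  ``compose_module_controls`` applies this
pairwise along a decomposition and refuses when the hypothesis fails.
"""

from __future__ import annotations

from itertools import combinations
from dataclasses import dataclass
from typing import Iterable, Sequence

from .decomposition import Decomposition, wiring_diagram
from .dynamics import InputTrajectory, compose_attractor, nonautonomous_attractors
from .network import (
    Attractor,
    BooleanNetwork,
    Rule,
    enumerate_attractors,
    reduce_to_essential_regulators,
)

__all__ = [
    "ControlAction",
    "pin",
    "delete_node",
    "fix_edge",
    "delete_edge",
    "apply_controls",
    "verify_stabilization",
    "compose_module_controls",
    "search_minimal_controls",
    "CompositionError",
]

_KINDS = {"node-constant", "node-deletion", "edge-constant", "edge-deletion"}


class CompositionError(ValueError):
    """The steady-state hypothesis of the composition theorem is unmet."""


@dataclass(frozen=True, order=True)
class ControlAction:
    kind: str
    target: str
    source: str | None = None
    value: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown control kind {self.kind!r}")
        if self.kind.startswith("edge") and self.source is None:
            raise ValueError("edge controls need a source variable")
        if self.kind.startswith("node") and self.source is not None:
            raise ValueError("node controls take no source variable")
        if self.kind.endswith("constant") and self.value not in (0, 1):
            raise ValueError("constant controls need a bit value")


def pin(target: str, value: int) -> ControlAction:
    return ControlAction("node-constant", target, value=value)


def delete_node(target: str) -> ControlAction:
    return ControlAction("node-deletion", target)


def fix_edge(source: str, target: str, value: int) -> ControlAction:
    return ControlAction("edge-constant", target, source=source, value=value)


def delete_edge(source: str, target: str) -> ControlAction:
    return ControlAction("edge-deletion", target, source=source)


def _check_conflicts(actions: Iterable[ControlAction]) -> list[ControlAction]:
    acts = sorted(set(actions))
    node_vals: dict[str, int] = {}
    for a in acts:
        if a.kind.startswith("node"):
            val = a.value if a.kind == "node-constant" else 0
            if a.target in node_vals and node_vals[a.target] != val:
                raise ValueError(f"conflicting pins on {a.target}")
            node_vals[a.target] = val
    return acts


def apply_controls(
    net: BooleanNetwork,
    actions: Iterable[ControlAction],
    deletion_value: int = 0,
) -> BooleanNetwork:
    """The network obtained by applying a control set.

    Controlled nodes remain variables (pinned to their constant), so the
    state space is unchanged and attractors of the controlled network are
    directly comparable with attractors of the free network.  The result is
    reduced to essential regulators.
    """
    acts = _check_conflicts(actions)
    known = set(net.variables)
    rules = {v: r for v, r in zip(net.variables, net.rules)}
    for a in acts:
        if a.target not in known:
            raise ValueError(f"unknown control target {a.target!r}")
        if a.kind in ("edge-constant", "edge-deletion"):
            rule = rules[a.target]
            if a.source not in rule.regulators:
                raise ValueError(f"no edge {a.source} -> {a.target} to control")
            val = a.value if a.kind == "edge-constant" else deletion_value
            rules[a.target] = rule.restrict(a.source, val)
        elif a.kind == "node-constant":
            rules[a.target] = Rule((), (a.value,))
        else:  # node-deletion: pin and substitute out of every rule
            rules[a.target] = Rule((), (deletion_value,))
            for v in rules:
                rules[v] = rules[v].restrict(a.target, deletion_value)
    out = BooleanNetwork(
        net.variables, tuple(rules[v] for v in net.variables), net.external
    )
    return reduce_to_essential_regulators(out)


def verify_stabilization(
    net: BooleanNetwork, actions: Iterable[ControlAction], C: Attractor
) -> bool:
    """True iff the controlled network has exactly ``{C}`` as attractor set."""
    if C.n != net.n:
        raise ValueError("attractor dimension does not match the network")
    controlled = apply_controls(net, actions)
    aset = enumerate_attractors(controlled)
    return aset.as_set() == {C}


# ---------------------------------------------------------------------------
# modular composition
# ---------------------------------------------------------------------------

def _identity_trajectory(combined: Attractor, upstream_vars: Sequence[str],
                         params: Sequence[str]) -> InputTrajectory:
    from .dynamics import input_trajectory

    P = {p: p for p in params}
    return input_trajectory(combined, P, upstream_vars)


def compose_module_controls(
    decomp: Decomposition,
    targets: Sequence[tuple[Iterable[ControlAction], Attractor]],
) -> tuple[frozenset[ControlAction], Attractor]:
    """Union module-wise controls into a control set for the whole network.

    ``targets[i]`` is the pair (controls, attractor) for module ``i`` in the
    decomposition's topological order; module ``i``'s controls must stabilize
    it *as driven by the already-stabilized upstream attractor*.  At every
    pairwise composition at least one side must be a steady state, otherwise
    :class:`CompositionError` is raised.  The returned set is re-verified on
    the recomposed full network.
    """
    if len(targets) != decomp.m:
        raise ValueError("need one (controls, attractor) pair per module")
    mod0 = decomp.modules[0]
    mu0, C0 = targets[0]
    if mod0.external:
        raise ValueError("topologically first module must be autonomous")
    if not verify_stabilization(mod0, mu0, C0):
        raise ValueError("module 1 controls do not stabilize it at its target")
    combined = C0
    upstream_vars: tuple[str, ...] = mod0.variables
    all_controls: set[ControlAction] = set(mu0)
    for i in range(1, decomp.m):
        module = decomp.modules[i]
        mu_i, C_i = targets[i]
        if not (combined.is_steady or C_i.is_steady):
            raise CompositionError(
                "composition theorem requires a steady state on one side"
            )
        controlled = apply_controls(module, mu_i)
        traj = _identity_trajectory(combined, upstream_vars, controlled.external)
        phased = nonautonomous_attractors(controlled, traj)
        if len(phased) != 1 or not phased[0].attractor.matches(C_i):
            raise ValueError(
                f"module {i + 1} controls do not stabilize it at its target"
            )
        combined = compose_attractor(
            combined, phased[0], upstream_vars, module.variables
        )
        upstream_vars = upstream_vars + module.variables
        all_controls |= set(mu_i)
    full = decomp.recompose()
    order = full.variables
    m = len(order)
    states = tuple(
        sum(((s >> (m - 1 - upstream_vars.index(v))) & 1) << (m - 1 - j)
            for j, v in enumerate(order))
        for s in combined.states
    )
    final = Attractor(states, m)
    controls = frozenset(all_controls)
    if not verify_stabilization(full, controls, final):  # pragma: no cover
        raise AssertionError("composed controls failed full-network verification")
    return controls, final


# ---------------------------------------------------------------------------
# brute-force search
# ---------------------------------------------------------------------------

def _candidate_actions(
    net: BooleanNetwork, C: Attractor, kinds: Sequence[str]
) -> list[ControlAction]:
    """Actions consistent with the target attractor C.

    A node may only be pinned to a value it holds constantly along C; edge
    controls are offered for every existing wiring edge and both constants.
    """
    n = net.n
    const: dict[str, int] = {}
    for i, v in enumerate(net.variables):
        vals = {(s >> (n - 1 - i)) & 1 for s in C.states}
        if len(vals) == 1:
            const[v] = vals.pop()
    out: list[ControlAction] = []
    for kind in kinds:
        if kind == "node-constant":
            out.extend(pin(v, val) for v, val in const.items())
        elif kind == "node-deletion":
            out.extend(delete_node(v) for v, val in const.items() if val == 0)
        elif kind in ("edge-constant", "edge-deletion"):
            wd = wiring_diagram(net)
            for u, v in sorted(wd.edges()):
                if u in wd.external:
                    continue
                if kind == "edge-deletion":
                    out.append(delete_edge(u, v))
                else:
                    out.extend(fix_edge(u, v, b) for b in (0, 1))
        else:
            raise ValueError(f"unknown control kind {kind!r}")
    return out


def search_minimal_controls(
    net: BooleanNetwork,
    C: Attractor,
    max_size: int = 3,
    kinds: Sequence[str] = ("node-constant",),
    mode: str = "global",
) -> list[frozenset[ControlAction]]:
    """All smallest control sets stabilizing the network at ``C``.

    ``mode='global'`` searches the full network directly; ``mode='modular'``
    works module by module in topological order (cheaper on decomposable
    networks, occasionally larger than the global optimum).  Returns an empty
    list when no set of size <= ``max_size`` works.
    """
    if mode == "global":
        cands = _candidate_actions(net, C, kinds)
        for size in range(max_size + 1):
            sols = [
                frozenset(combo)
                for combo in combinations(cands, size)
                if _consistent(combo) and verify_stabilization(net, combo, C)
            ]
            if sols:
                return sols
        return []
    if mode != "modular":
        raise ValueError(f"unknown mode {mode!r}")
    from .decomposition import structural_decompose

    decomp = structural_decompose(net)
    n = net.n
    combined: Attractor | None = None
    upstream: tuple[str, ...] = ()
    union: set[ControlAction] = set()
    from .dynamics import DrivenAttractor

    for i, module in enumerate(decomp.modules):
        idxs = [net.index[v] for v in module.variables]
        proj = [
            sum(((s >> (n - 1 - j)) & 1) << (len(idxs) - 1 - jj)
                for jj, j in enumerate(idxs))
            for s in C.states
        ]
        # downstream projections may revisit states at different phases
        C_i = DrivenAttractor(tuple(proj), len(idxs))
        if i == 0:
            C_i = Attractor(C_i.states, len(idxs))
        if i > 0 and not (combined.is_steady or C_i.is_steady):
            raise CompositionError(
                "modular search requires a steady state on one side"
            )
        found = None
        cands = _candidate_actions(module, C_i, kinds)
        for size in range(max_size + 1):
            for combo in combinations(cands, size):
                if not _consistent(combo):
                    continue
                controlled = apply_controls(module, combo)
                if i == 0:
                    ok = enumerate_attractors(controlled).as_set() == {C_i}
                else:
                    traj = _identity_trajectory(combined, upstream, controlled.external)
                    phased = nonautonomous_attractors(controlled, traj)
                    ok = len(phased) == 1 and phased[0].attractor.matches(C_i)
                if ok:
                    found = (combo, C_i)
                    break
            if found:
                break
        if not found:
            return []
        combo, C_i = found
        union |= set(combo)
        if i == 0:
            combined = C_i
        else:
            traj = _identity_trajectory(combined, upstream,
                                        apply_controls(module, combo).external)
            phased = nonautonomous_attractors(apply_controls(module, combo), traj)
            combined = compose_attractor(combined, phased[0], upstream, module.variables)
        upstream = upstream + module.variables
    return [frozenset(union)] if verify_stabilization(net, union, C) else []


def _consistent(actions: Iterable[ControlAction]) -> bool:
    try:
        _check_conflicts(actions)
        return True
    except ValueError:
        return False
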