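"""Non-autonomous dynamics and the dynamic decomposition of attractors.

When a network ``F`` factors as ``F1 |x_P F2`` (semi-direct product), each
attractor ``C1`` of the upstream factor drives the downstream factor through
a periodic input trajectory ``g(t)`` — the trace of ``C1`` projected onto the
coupled parameters.  The driven system ``y(t+1) = F2(g(t), y(t))`` is a
non-autonomous Boolean network; its attractors are the cycles of the finite
deterministic *product automaton* on pairs ``(t mod r, y)``.  Pairing an
upstream attractor with a driven attractor at its phase yields a combined
attractor of length ``lcm(|C1|, |C2|)``, and ranging over all upstream
attractors and all driven cycles yields *every* attractor of the combined
network.  ``dynamic_decompose`` applies this recursively, peeling one
topologically-first module at a time, and agrees exactly with exhaustive
enumeration.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lcm
from typing import Mapping, Sequence

from .decomposition import module_dag, restriction
from .network import (
    ENUMERATION_GUARD,
    Attractor,
    AttractorSet,
    BooleanNetwork,
    transition_table,
)

__all__ = [
    "InputTrajectory",
    "DrivenAttractor",
    "PhasedAttractor",
    "input_trajectory",
    "nonautonomous_attractors",
    "compose_attractor",
    "dynamic_decompose",
]


@dataclass(frozen=True)
class InputTrajectory:
    """Periodic bit-vector inputs for the external parameters of a network.

    ``values[t]`` assigns one bit per name in ``params``; time indices wrap
    modulo the period ``len(values)``.
    """

    params: tuple[str, ...]
    values: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        if not self.values:
            raise ValueError("trajectory needs at least one time step")
        if any(len(row) != len(self.params) for row in self.values):
            raise ValueError("each value row must cover every parameter")

    @property
    def period(self) -> int:
        return len(self.values)

    def value_dict(self, t: int) -> dict[str, int]:
        row = self.values[t % self.period]
        return dict(zip(self.params, row))

    def project(self, params: Sequence[str]) -> "InputTrajectory":
        cols = [self.params.index(p) for p in params]
        return InputTrajectory(
            tuple(params), tuple(tuple(row[c] for c in cols) for row in self.values)
        )

    @classmethod
    def constant(cls, assignment: Mapping[str, int]) -> "InputTrajectory":
        return cls(tuple(assignment), (tuple(assignment.values()),))


def input_trajectory(
    C1: Attractor, P: Mapping[str, str], upstream_vars: Sequence[str]
) -> InputTrajectory:
    """Trace of an upstream attractor on the coupled parameters.

    ``P`` maps downstream parameter names to upstream variable names; the
    trajectory has period ``|C1|`` and starts at the canonical rotation.
    """
    pos = {v: i for i, v in enumerate(upstream_vars)}
    missing = [v for v in P.values() if v not in pos]
    if missing:
        raise ValueError(f"coupling targets not upstream variables: {missing}")
    n = len(upstream_vars)
    params = tuple(P)
    values = tuple(
        tuple((s >> (n - 1 - pos[P[p]])) & 1 for p in params) for s in C1.states
    )
    return InputTrajectory(params, values)


@dataclass(frozen=True)
class DrivenAttractor:
    """Periodic state trajectory of a driven (non-autonomous) network.

    Unlike an autonomous :class:`~boolmod.network.Attractor`, a driven
    trajectory may revisit the same state at different input phases, so
    states need not be distinct.  Canonical form: minimal period, rotated to
    the lexicographically smallest rotation.
    """

    states: tuple[int, ...]
    n: int

    def __post_init__(self) -> None:
        if not self.states:
            raise ValueError("trajectory must contain at least one state")
        seq = list(self.states)
        d = _minimal_period(seq)
        seq = seq[:d]
        best = min(tuple(seq[j:] + seq[:j]) for j in range(d))
        object.__setattr__(self, "states", best)

    def __len__(self) -> int:
        return len(self.states)

    @property
    def is_steady(self) -> bool:
        return len(self.states) == 1

    def strings(self) -> tuple[str, ...]:
        from .network import state_to_string

        return tuple(state_to_string(s, self.n) for s in self.states)

    def matches(self, other: "Attractor | DrivenAttractor") -> bool:
        """Same periodic state sequence, regardless of container type."""
        return self.n == other.n and self.states == DrivenAttractor(
            tuple(other.states), other.n
        ).states


@dataclass(frozen=True)
class PhasedAttractor:
    """A driven attractor together with its phase in the input trajectory.

    ``cycle`` is the full product-automaton cycle ``((t, y), ...)`` rotated to
    its smallest pair; ``phase`` is the time index of that first entry, and
    ``attractor`` the minimal-period y-projection.
    """

    attractor: DrivenAttractor
    phase: int
    cycle: tuple[tuple[int, int], ...]

    def __len__(self) -> int:
        return len(self.cycle)


def _minimal_period(seq: Sequence[int]) -> int:
    L = len(seq)
    for d in range(1, L + 1):
        if L % d == 0 and all(seq[i] == seq[(i + d) % L] for i in range(L)):
            return d
    return L  # pragma: no cover


def _rotate_min(cycle: list[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    j = cycle.index(min(cycle))
    return tuple(cycle[j:] + cycle[:j])


def _product_cycles(
    net: BooleanNetwork, traj: InputTrajectory, guard: int = ENUMERATION_GUARD
) -> list[tuple[tuple[int, int], ...]]:
    """All cycles of the map ``(t, y) -> (t+1 mod r, F(g(t), y))``.

    Each cycle is reported once, rotated to its smallest ``(t, y)`` pair.
    """
    if set(traj.params) != set(net.external):
        raise ValueError(
            f"trajectory covers {traj.params}, network needs {net.external}"
        )
    r = traj.period
    n = net.n
    size = 1 << n
    tables = [transition_table(net, traj.value_dict(t) or None, guard=guard) for t in range(r)]
    labels: dict[int, int] = {}
    cycles: list[tuple[tuple[int, int], ...]] = []
    for start in range(r * size):
        if start in labels:
            continue
        path: list[int] = []
        on_path: dict[int, int] = {}
        s = start
        while s not in labels and s not in on_path:
            on_path[s] = len(path)
            path.append(s)
            t, y = divmod(s, size)
            s = ((t + 1) % r) * size + int(tables[t][y])
        if s in on_path:
            i = on_path[s]
            cyc = [divmod(p, size) for p in path[i:]]
            cycles.append(_rotate_min(cyc))
            lab = len(cycles) - 1
        else:
            lab = labels[s]
        for p in path:
            labels[p] = lab
    return cycles


def _phased(cycle: tuple[tuple[int, int], ...], n: int) -> PhasedAttractor:
    ys = tuple(y for _, y in cycle)
    return PhasedAttractor(DrivenAttractor(ys, n), cycle[0][0], cycle)


def nonautonomous_attractors(
    G: BooleanNetwork,
    g: InputTrajectory,
    constants: Mapping[str, int] | None = None,
    guard: int = ENUMERATION_GUARD,
) -> tuple[PhasedAttractor, ...]:
    """Attractors of ``y(t+1) = G(g(t), y(t))`` with their phases.

    ``g`` must cover G's driven parameters; any remaining external parameter
    needs a constant in ``constants``.
    """
    params = set(g.params)
    extra = dict(constants or {})
    missing = [p for p in G.external if p not in params and p not in extra]
    if missing:
        raise ValueError(f"no input supplied for external parameters {missing}")
    if extra:
        full_params = g.params + tuple(p for p in extra if p not in params)
        values = tuple(
            row + tuple(extra[p] for p in full_params[len(g.params):])
            for row in g.values
        )
        g = InputTrajectory(full_params, values)
    cycles = _product_cycles(G, g.project(G.external), guard=guard)
    return tuple(sorted((_phased(c, G.n) for c in cycles),
                        key=lambda pa: (pa.attractor.states, pa.phase)))


def _merge_state(
    y1: int, vars1: Sequence[str], y2: int, vars2: Sequence[str],
    order: Sequence[str],
) -> int:
    n1, n2, n = len(vars1), len(vars2), len(order)
    bits = {v: (y1 >> (n1 - 1 - i)) & 1 for i, v in enumerate(vars1)}
    bits.update({v: (y2 >> (n2 - 1 - i)) & 1 for i, v in enumerate(vars2)})
    out = 0
    for v in order:
        out = (out << 1) | bits[v]
    return out


def compose_attractor(
    C1: Attractor,
    pa: PhasedAttractor,
    upstream_vars: Sequence[str],
    downstream_vars: Sequence[str],
    order: Sequence[str] | None = None,
) -> Attractor:
    """Combined attractor ``C1 (+) C2``: pair upstream and driven states.

    The result has length ``lcm(|C1|, |C2|)`` and is canonicalized.  ``order``
    defaults to upstream followed by downstream variables.
    """
    if order is None:
        order = tuple(upstream_vars) + tuple(downstream_vars)
    r = len(C1)
    states = [
        _merge_state(C1.states[t % r], upstream_vars, y, downstream_vars, order)
        for t, y in pa.cycle
    ]
    att = Attractor(tuple(states), len(order))
    assert len(att) == lcm(len(C1), len(pa.attractor))
    return att


def _driven_cycles(
    net: BooleanNetwork, traj: InputTrajectory, guard: int
) -> list[tuple[tuple[int, int], ...]]:
    """Cycles of the product automaton of ``net`` under ``traj``, recursively.

    Single-module networks are handled directly; otherwise the
    topologically-first module is peeled off, each of its cycles induces a
    periodic trajectory for the remainder, and the sub-cycles are re-phased
    and merged.
    """
    dag = module_dag(net)
    if dag.m == 1:
        return _product_cycles(net, traj.project(net.external), guard=guard)
    y1_vars = set(dag.module_vars[0])
    F1 = restriction(net, dag.module_vars[0])
    F2 = restriction(net, [v for v in net.variables if v not in y1_vars])
    i1 = {v: i for i, v in enumerate(F1.variables)}
    n1 = F1.n
    out: list[tuple[tuple[int, int], ...]] = []
    for c1 in _driven_cycles(F1, traj.project(F1.external), guard):
        L1 = len(c1)
        rows = []
        for t, y1 in c1:
            base = traj.value_dict(t)
            rows.append(
                tuple(
                    (y1 >> (n1 - 1 - i1[p])) & 1 if p in i1 else base[p]
                    for p in F2.external
                )
            )
        traj2 = InputTrajectory(F2.external, tuple(rows))
        for c2 in _driven_cycles(F2, traj2, guard):
            merged = []
            for s, y2 in c2:
                t, y1 = c1[s % L1]
                merged.append(
                    (t, _merge_state(y1, F1.variables, y2, F2.variables, net.variables))
                )
            out.append(_rotate_min(merged))
    return out


def dynamic_decompose(
    net: BooleanNetwork, guard: int = ENUMERATION_GUARD
) -> AttractorSet:
    """All attractors of a network, computed module-by-module.

    Equals :func:`boolmod.network.enumerate_attractors` as a set (no basin
    map is produced), but only ever sweeps one module's state space at a
    time against the driving trajectories of its upstream attractors.
    """
    if net.external:
        raise ValueError("network has external parameters; supply a trajectory")
    empty = InputTrajectory((), ((),))
    cycles = _driven_cycles(net, empty, guard)
    atts = []
    for c in cycles:
        ys = [y for _, y in c]
        d = _minimal_period(ys)
        atts.append(Attractor(tuple(ys[:d]), net.n))
    return AttractorSet(tuple(atts))
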