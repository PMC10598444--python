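"""Synchronous Boolean networks: representation, dynamics and attractors.

A Boolean network on variables ``x_1, ..., x_n`` is a map
``F : {0,1}^n -> {0,1}^n`` given coordinate-wise by update rules ``f_i``,
applied synchronously.  States are stored as integer bitmasks; the textual
form is the big-endian bit string in declaration order, so ``"010"`` means
``x1=0, x2=1, x3=0`` and lexicographic order on strings equals numeric order
on the bitmask.

A network may declare *external parameters*: input symbols that appear as
regulators but are not themselves updated.  Such networks arise as
restrictions of larger networks to subsets of variables and are the building
blocks of the modular decomposition (see :mod:`boolmod.decomposition`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Rule",
    "BooleanNetwork",
    "Attractor",
    "AttractorSet",
    "state_to_string",
    "string_to_state",
    "synchronous_step",
    "transition_table",
    "enumerate_attractors",
    "iterate_to_attractor",
    "sample_attractors",
    "reduce_to_essential_regulators",
    "ENUMERATION_GUARD",
]

#: Default cap on exhaustive 2^n sweeps (memory ~ 2^n int64); overridable.
ENUMERATION_GUARD = 24


def state_to_string(state: int, n: int) -> str:
    """Bit string of ``state`` in variable order (variable 1 leftmost)."""
    if not 0 <= state < (1 << n):
        raise ValueError(f"state {state} out of range for {n} variables")
    return format(state, f"0{n}b")


def string_to_state(s: str) -> int:
    if not s or set(s) - {"0", "1"}:
        raise ValueError(f"not a bit string: {s!r}")
    return int(s, 2)


def _bit(state: int, pos: int, n: int) -> int:
    """Value of variable at index ``pos`` (0-based, declaration order)."""
    return (state >> (n - 1 - pos)) & 1


@dataclass(frozen=True)
class Rule:
    """One update rule: regulator names plus a flat truth table.

    The table is indexed by the regulator value tuple in declaration order,
    first regulator most significant: row ``r1 r2 ... rk`` (as bits) holds the
    output for that input combination.  A rule with no regulators is a
    constant (table of length 1).
    """

    regulators: tuple[str, ...]
    table: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(set(self.regulators)) != len(self.regulators):
            raise ValueError(f"duplicate regulators in {self.regulators}")
        if len(self.table) != 1 << len(self.regulators):
            raise ValueError(
                f"truth table length {len(self.table)} != 2^{len(self.regulators)}"
            )
        if any(v not in (0, 1) for v in self.table):
            raise ValueError("truth table entries must be 0/1")

    @property
    def k(self) -> int:
        return len(self.regulators)

    def as_array(self) -> np.ndarray:
        return np.array(self.table, dtype=np.int64)

    def restrict(self, name: str, value: int) -> "Rule":
        """Partial-evaluate a regulator to a constant (drops it)."""
        if name not in self.regulators:
            return self
        j = self.regulators.index(name)
        arr = self.as_array().reshape((2,) * self.k)
        sub = np.take(arr, value, axis=j)
        regs = tuple(r for r in self.regulators if r != name)
        return Rule(regs, tuple(int(v) for v in sub.reshape(-1)))

    def rename(self, mapping: Mapping[str, str]) -> "Rule":
        return Rule(tuple(mapping.get(r, r) for r in self.regulators), self.table)


@dataclass(frozen=True)
class BooleanNetwork:
    """An ordered collection of update rules, optionally with external inputs.

    Parameters
    ----------
    variables:
        Unique names; the order fixes state-vector coordinates.
    rules:
        One :class:`Rule` per variable, aligned with ``variables``.
    external:
        Names of external parameters (disjoint from ``variables``); if
        non-empty the network is non-autonomous and stepping requires an
        input assignment.
    """

    variables: tuple[str, ...]
    rules: tuple[Rule, ...]
    external: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.variables)) != len(self.variables):
            raise ValueError("duplicate variable names")
        if len(self.rules) != len(self.variables):
            raise ValueError("need exactly one rule per variable")
        if set(self.variables) & set(self.external):
            raise ValueError("external parameters must be disjoint from variables")
        if len(set(self.external)) != len(self.external):
            raise ValueError("duplicate external parameter names")
        known = set(self.variables) | set(self.external)
        for v, rule in zip(self.variables, self.rules):
            for r in rule.regulators:
                if r not in known:
                    raise ValueError(f"rule of {v}: unknown regulator {r!r}")

    # -- conveniences -----------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.variables)

    @property
    def index(self) -> dict[str, int]:
        return {v: i for i, v in enumerate(self.variables)}

    def rule_of(self, name: str) -> Rule:
        return self.rules[self.index[name]]

    @classmethod
    def from_rules(
        cls,
        rules: Mapping[str, Rule] | Sequence[tuple[str, Rule]],
        external: Iterable[str] = (),
        order: Sequence[str] | None = None,
    ) -> "BooleanNetwork":
        items = dict(rules)
        names = tuple(order) if order is not None else tuple(items)
        return cls(names, tuple(items[v] for v in names), tuple(external))

    def reorder(self, order: Sequence[str]) -> "BooleanNetwork":
        """Same network with variables permuted to ``order``."""
        if sorted(order) != sorted(self.variables):
            raise ValueError("order must be a permutation of the variables")
        rules = {v: r for v, r in zip(self.variables, self.rules)}
        return BooleanNetwork(tuple(order), tuple(rules[v] for v in order), self.external)

    def state_string(self, state: int) -> str:
        return state_to_string(state, self.n)


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------

def synchronous_step(
    net: BooleanNetwork, state: int, inputs: Mapping[str, int] | None = None
) -> int:
    """One synchronous update ``x -> (f_1(x), ..., f_n(x))``.

    ``inputs`` must assign a bit to every external parameter, and must be
    omitted (or empty) when the network has none.
    """
    n = net.n
    if not 0 <= state < (1 << n):
        raise ValueError(f"state {state} out of range for {n} variables")
    if net.external:
        if inputs is None or any(p not in inputs for p in net.external):
            raise ValueError(f"inputs required for external parameters {net.external}")
    elif inputs:
        raise ValueError("network has no external parameters; inputs not allowed")
    idx = net.index
    out = 0
    for rule in net.rules:
        row = 0
        for r in rule.regulators:
            j = idx.get(r)
            b = _bit(state, j, n) if j is not None else int(inputs[r])  # type: ignore[index]
            row = (row << 1) | b
        out = (out << 1) | rule.table[row]
    return out


def transition_table(
    net: BooleanNetwork,
    inputs: Mapping[str, int] | None = None,
    guard: int = ENUMERATION_GUARD,
) -> np.ndarray:
    """Image of every state under one synchronous step, as an int64 array.

    Vectorized over the full state space; refuses ``n > guard``.
    """
    n = net.n
    if n > guard:
        raise ValueError(f"n={n} exceeds exhaustive guard {guard}")
    if net.external and (inputs is None or any(p not in inputs for p in net.external)):
        raise ValueError(f"inputs required for external parameters {net.external}")
    states = np.arange(1 << n, dtype=np.int64)
    bits = {v: (states >> (n - 1 - i)) & 1 for i, v in enumerate(net.variables)}
    out = np.zeros(1 << n, dtype=np.int64)
    for i, rule in enumerate(net.rules):
        row = np.zeros(1 << n, dtype=np.int64)
        for r in rule.regulators:
            b = bits[r] if r in bits else int(inputs[r])  # type: ignore[index]
            row = (row << 1) | b
        out |= rule.as_array()[row] << (n - 1 - i)
    return out


# ---------------------------------------------------------------------------
# attractors
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class Attractor:
    """A canonical cyclic state sequence; ``len == 1`` is a steady state.

    The stored rotation starts at the numerically (= lexicographically)
    smallest member, so equal attractors compare equal regardless of the
    rotation they were discovered in.
    """

    states: tuple[int, ...]
    n: int

    def __post_init__(self) -> None:
        if not self.states:
            raise ValueError("attractor must contain at least one state")
        if len(set(self.states)) != len(self.states):
            raise ValueError("attractor states must be distinct")
        j = self.states.index(min(self.states))
        object.__setattr__(self, "states", self.states[j:] + self.states[:j])

    def __len__(self) -> int:
        return len(self.states)

    @property
    def is_steady(self) -> bool:
        return len(self.states) == 1

    def strings(self) -> tuple[str, ...]:
        return tuple(state_to_string(s, self.n) for s in self.states)

    def __repr__(self) -> str:  # compact, Fig-style
        body = ", ".join(self.strings())
        return body if self.is_steady else f"({body})"


@dataclass(frozen=True)
class AttractorSet:
    """Attractors of a network, optionally with basin bookkeeping.

    ``basin`` is either a full int array (state -> attractor index) from
    exhaustive enumeration, a partial ``dict`` from sampling, or ``None``.
    """

    attractors: tuple[Attractor, ...]
    basin: object = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "attractors", tuple(sorted(set(self.attractors))))

    def __len__(self) -> int:
        return len(self.attractors)

    def __iter__(self):
        return iter(self.attractors)

    def as_set(self) -> frozenset[Attractor]:
        return frozenset(self.attractors)

    def basin_sizes(self) -> dict[Attractor, int]:
        if self.basin is None:
            raise ValueError("no basin map available")
        if isinstance(self.basin, dict):
            counts: dict[int, int] = {}
            for lab in self.basin.values():
                counts[lab] = counts.get(lab, 0) + 1
        else:
            arr = np.asarray(self.basin)
            counts = {int(i): int(c) for i, c in zip(*np.unique(arr, return_counts=True))}
        return {self.attractors[i]: c for i, c in counts.items()}


def _trace_cycles(T: np.ndarray, starts: Iterable[int], labels: dict[int, int],
                  attractors: list[Attractor], n: int) -> None:
    """Follow forward orbits through ``T``, labelling states by attractor."""
    for s0 in starts:
        s = int(s0)
        if s in labels:
            continue
        path: list[int] = []
        on_path: dict[int, int] = {}
        while s not in labels and s not in on_path:
            on_path[s] = len(path)
            path.append(s)
            s = int(T[s])
        if s in on_path:  # new cycle discovered on this path
            i = on_path[s]
            attractors.append(Attractor(tuple(path[i:]), n))
            lab = len(attractors) - 1
        else:
            lab = labels[s]
        for p in path:
            labels[p] = lab


def enumerate_attractors(net: BooleanNetwork, guard: int = ENUMERATION_GUARD) -> AttractorSet:
    """All attractors plus a total basin map, by full state-space sweep."""
    if net.external:
        raise ValueError(
            "network has external parameters; use nonautonomous_attractors"
        )
    n = net.n
    T = transition_table(net, guard=guard)
    labels: dict[int, int] = {}
    attractors: list[Attractor] = []
    _trace_cycles(T, range(1 << n), labels, attractors, n)
    basin = np.empty(1 << n, dtype=np.int64)
    order = np.argsort([min(a.states) for a in attractors], kind="stable")
    rank = np.empty(len(order), dtype=np.int64)
    rank[order] = np.arange(len(order))
    for s, lab in labels.items():
        basin[s] = rank[lab]
    return AttractorSet(tuple(attractors[i] for i in order), basin)


def iterate_to_attractor(
    net: BooleanNetwork, start: int
) -> tuple[Attractor, int]:
    """Forward orbit until a state recurs; returns (attractor, transient length).

    The transient length is the number of steps taken before the first
    attractor state is entered (0 if ``start`` already lies on its attractor).
    """
    if net.external:
        raise ValueError("network has external parameters")
    seen: dict[int, int] = {}
    seq: list[int] = []
    s = start
    while s not in seen:
        seen[s] = len(seq)
        seq.append(s)
        s = synchronous_step(net, s)
    i = seen[s]
    return Attractor(tuple(seq[i:]), net.n), i


def sample_attractors(
    net: BooleanNetwork,
    n_samples: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    guard: int = ENUMERATION_GUARD,
) -> AttractorSet:
    """Attractors reached from uniform random initial states (lower bound).

    Initial states are drawn with replacement.  Deterministic given the seed.
    The returned set carries a partial basin map (sampled state -> attractor
    index into the returned, sorted tuple).
    """
    if net.external:
        raise ValueError("network has external parameters")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = net.n
    draws = [int(x) for x in rng.integers(0, 1 << n, size=n_samples, dtype=np.uint64)]
    labels: dict[int, int] = {}
    attractors: list[Attractor] = []
    if n <= guard:
        T = transition_table(net, guard=guard)
        _trace_cycles(T, draws, labels, attractors, n)
    else:
        for s in draws:
            if s in labels:
                continue
            att, _ = iterate_to_attractor(net, s)
            try:
                lab = attractors.index(att)
            except ValueError:
                attractors.append(att)
                lab = len(attractors) - 1
            labels[s] = lab
    ordered = sorted(range(len(attractors)), key=lambda i: attractors[i])
    rank = {old: new for new, old in enumerate(ordered)}
    basin = {s: rank[labels[s]] for s in draws}
    return AttractorSet(tuple(attractors[i] for i in ordered), basin)


# ---------------------------------------------------------------------------
# essential regulators
# ---------------------------------------------------------------------------

def _essential_mask(rule: Rule) -> list[bool]:
    arr = rule.as_array().reshape((2,) * rule.k)
    return [
        bool(np.any(np.take(arr, 0, axis=j) != np.take(arr, 1, axis=j)))
        for j in range(rule.k)
    ]


def reduce_to_essential_regulators(net: BooleanNetwork) -> BooleanNetwork:
    """Drop regulators whose value never changes a rule's output.

    The returned network is state-by-state identical in its dynamics and the
    operation is idempotent.
    """
    new_rules = []
    for rule in net.rules:
        ess = _essential_mask(rule)
        if all(ess):
            new_rules.append(rule)
            continue
        arr = rule.as_array().reshape((2,) * rule.k)
        sel = tuple(slice(None) if e else 0 for e in ess)
        sub = arr[sel]
        regs = tuple(r for r, e in zip(rule.regulators, ess) if e)
        new_rules.append(Rule(regs, tuple(int(v) for v in sub.reshape(-1))))
    return BooleanNetwork(net.variables, tuple(new_rules), net.external)
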