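"""Structural decomposition: wiring diagrams, SCC modules, semi-direct products.

The wiring diagram of a network has an edge ``u -> v`` when the (reduced)
rule of ``v`` depends essentially on ``u``.  Its strongly connected
components define the *modules*: restrictions of the network to each SCC,
with outside regulators kept as external parameters.  The condensation of
the wiring diagram is an acyclic graph Q on the modules, and the network
factors as an iterated semi-direct product of its modules along any
topological order of Q.  Recomposing the factors reproduces the original
network truth-table exactly.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx

from .network import BooleanNetwork, reduce_to_essential_regulators

__all__ = [
    "WiringDiagram",
    "ModuleDAG",
    "Decomposition",
    "wiring_diagram",
    "module_dag",
    "restriction",
    "modules",
    "semidirect_product",
    "cross_product",
    "structural_decompose",
]


@dataclass(frozen=True)
class WiringDiagram:
    """Directed dependency graph; external parameters are source-only nodes."""

    graph: nx.DiGraph

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(
            v for v, d in self.graph.nodes(data=True) if not d.get("external", False)
        )

    @property
    def external(self) -> tuple[str, ...]:
        return tuple(
            v for v, d in self.graph.nodes(data=True) if d.get("external", False)
        )

    def edges(self) -> frozenset[tuple[str, str]]:
        return frozenset(self.graph.edges())


def wiring_diagram(net: BooleanNetwork) -> WiringDiagram:
    """Essential-dependency graph of the network.

    Non-essential regulators are removed first, so the edge set reflects
    genuine dependencies only.
    """
    red = reduce_to_essential_regulators(net)
    g = nx.DiGraph()
    for v in red.variables:
        g.add_node(v, external=False)
    for p in red.external:
        g.add_node(p, external=True)
    for v, rule in zip(red.variables, red.rules):
        for r in rule.regulators:
            g.add_edge(r, v)
    return WiringDiagram(g)


@dataclass(frozen=True)
class ModuleDAG:
    """SCC condensation: disjoint variable blocks plus acyclic edges Q.

    ``module_vars`` is in a deterministic topological order (ties broken by
    the smallest contained variable index in declaration order), so module
    indices are stable across runs.  A module is *non-trivial* when it
    contains more than one variable; a self-loop on a singleton does not make
    it non-trivial.
    """

    module_vars: tuple[tuple[str, ...], ...]
    edges: frozenset[tuple[int, int]]

    @property
    def m(self) -> int:
        return len(self.module_vars)

    def nontrivial(self) -> tuple[int, ...]:
        return tuple(i for i, ys in enumerate(self.module_vars) if len(ys) > 1)


def module_dag(net_or_wd: BooleanNetwork | WiringDiagram) -> ModuleDAG:
    """Condense the wiring diagram into its SCC DAG Q."""
    wd = net_or_wd if isinstance(net_or_wd, WiringDiagram) else wiring_diagram(net_or_wd)
    variables = wd.variables
    pos = {v: i for i, v in enumerate(variables)}
    sub = wd.graph.subgraph(variables)
    comps = [tuple(sorted(c, key=pos.__getitem__)) for c in nx.strongly_connected_components(sub)]
    comp_of = {v: i for i, c in enumerate(comps) for v in c}
    raw_edges = set()
    for u, v in sub.edges():
        cu, cv = comp_of[u], comp_of[v]
        if cu != cv:
            raw_edges.add((cu, cv))
    # deterministic topological order, ties by smallest member variable index
    indeg = {i: 0 for i in range(len(comps))}
    succ: dict[int, list[int]] = {i: [] for i in range(len(comps))}
    for a, b in raw_edges:
        indeg[b] += 1
        succ[a].append(b)
    heap = [(pos[comps[i][0]], i) for i in indeg if indeg[i] == 0]
    heapq.heapify(heap)
    order: list[int] = []
    while heap:
        _, i = heapq.heappop(heap)
        order.append(i)
        for j in succ[i]:
            indeg[j] -= 1
            if indeg[j] == 0:
                heapq.heappush(heap, (pos[comps[j][0]], j))
    rank = {old: new for new, old in enumerate(order)}
    return ModuleDAG(
        tuple(comps[i] for i in order),
        frozenset((rank[a], rank[b]) for a, b in raw_edges),
    )


def restriction(net: BooleanNetwork, subset: Iterable[str]) -> BooleanNetwork:
    """Restriction ``F|_S``: rules of S kept, outside regulators made external.

    Variable order follows the parent network's declaration order.  External
    parameters are named after the outside regulator they stand for, so a
    later semi-direct product along the identity coupling undoes the
    restriction exactly.
    """
    want = set(subset)
    if not want:
        raise ValueError("restriction subset must be non-empty")
    if not want <= set(net.variables):
        raise ValueError(f"not variables of the network: {want - set(net.variables)}")
    vars_ = tuple(v for v in net.variables if v in want)
    rules = tuple(net.rules[net.index[v]] for v in vars_)
    ext: list[str] = []
    for rule in rules:
        for r in rule.regulators:
            if r not in want and r not in ext:
                ext.append(r)
    return BooleanNetwork(vars_, rules, tuple(ext))


def modules(net: BooleanNetwork) -> list[BooleanNetwork]:
    """The modules of the network, in topological order of Q."""
    dag = module_dag(net)
    return [restriction(net, ys) for ys in dag.module_vars]


def semidirect_product(
    F: BooleanNetwork, G: BooleanNetwork, P: Mapping[str, str]
) -> BooleanNetwork:
    """Couple upstream ``F`` into the external parameters of ``G`` via ``P``.

    ``P`` maps a subset of G's external parameters to variables of F; mapped
    parameters are substituted by the assigned upstream variable, unmapped
    ones stay external.  With ``P`` empty this is the cross product.
    """
    if set(F.variables) & set(G.variables):
        raise ValueError("variable names of the factors must be disjoint")
    if not set(P) <= set(G.external):
        raise ValueError(f"unknown coupling keys: {set(P) - set(G.external)}")
    if not set(P.values()) <= set(F.variables):
        raise ValueError("coupling values must be upstream variables")
    variables = F.variables + G.variables
    g_rules = tuple(rule.rename(P) for rule in G.rules)
    ext = list(F.external)
    for p in G.external:
        if p not in P and p not in ext:
            ext.append(p)
    if set(ext) & set(variables):
        raise ValueError("external parameter name collides with a variable")
    return BooleanNetwork(variables, F.rules + g_rules, tuple(ext))


def cross_product(F: BooleanNetwork, G: BooleanNetwork) -> BooleanNetwork:
    """Uncoupled product ``F x G`` (empty coupling scheme)."""
    return semidirect_product(F, G, {})


@dataclass(frozen=True)
class Decomposition:
    """Modules F1..Fm, coupling schemes P1..P(m-1), and the DAG Q.

    Schemes are identity-on-names maps: ``P_i`` sends each external parameter
    of the downstream composite that names a variable of ``F_i`` to that very
    variable.  ``recompose`` right-folds the semi-direct products and restores
    the original variable order, reproducing the input network exactly.
    """

    modules: tuple[BooleanNetwork, ...]
    schemes: tuple[dict[str, str], ...]
    dag: ModuleDAG
    variable_order: tuple[str, ...]
    external: tuple[str, ...] = ()

    @property
    def m(self) -> int:
        return len(self.modules)

    def recompose(self) -> BooleanNetwork:
        net = self.modules[-1]
        for i in range(self.m - 2, -1, -1):
            upstream_vars = set(self.modules[i].variables)
            P = {p: p for p in net.external if p in upstream_vars}
            net = semidirect_product(self.modules[i], net, P)
        net = net.reorder(self.variable_order)
        if tuple(net.external) != tuple(self.external):
            # same set, possibly different order after folding
            net = BooleanNetwork(net.variables, net.rules, self.external)
        return net


def structural_decompose(net: BooleanNetwork) -> Decomposition:
    """Factor a network into its modules along the condensation DAG.

    Returns one module when the wiring diagram is strongly connected.
    """
    dag = module_dag(net)
    mods = tuple(restriction(net, ys) for ys in dag.module_vars)
    schemes: list[dict[str, str]] = []
    comp = mods[-1]
    for i in range(len(mods) - 2, -1, -1):
        upstream_vars = set(mods[i].variables)
        P = {p: p for p in comp.external if p in upstream_vars}
        schemes.append(P)
        comp = semidirect_product(mods[i], comp, P)
    schemes.reverse()
    return Decomposition(mods, tuple(schemes), dag, net.variables, net.external)
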