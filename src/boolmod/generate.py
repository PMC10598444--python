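"""Random modular nested-canalizing Boolean networks.

The generator emulates the construction used in the simulation study:

* every update rule is a *nested canalizing function* (NCF) that depends
  essentially on all of its inputs — the rule family overwhelmingly observed
  in published gene regulatory network models;
* every node has exactly ``in_degree`` distinct regulators and no self-loop;
* a network with ``m`` modules consists of ``m`` blocks of ``N/m`` nodes,
  each block's wiring drawn by rejection until it is strongly connected;
* the module DAG is a uniformly random weakly connected lower-triangular
  binary matrix ``D`` with unit diagonal, and each off-diagonal 1 contributes
  exactly one cross-module edge, which *replaces* one intra-module regulator
  of the target node (resampled if the replacement would break the target
  module's internal strong connectivity), so the in-degree stays constant.

All randomness flows through a single :class:`numpy.random.Generator`, so a
configuration plus a seed reproduces the network bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .network import BooleanNetwork, Rule

__all__ = [
    "GeneratorConfig",
    "GenerationError",
    "random_nested_canalizing_rule",
    "is_nested_canalizing",
    "depends_on_all_inputs",
    "random_strongly_connected_wiring",
    "random_module_dag",
    "generate_modular_network",
]


class GenerationError(RuntimeError):
    """Raised when a rejection-sampling budget is exhausted."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the modular network generator.

    ``N`` total nodes split into ``m`` modules of equal size; ``in_degree``
    regulators per node.  The study conditions of record are N=60,
    in_degree=3, m=1..6; desk-scale replications shrink N, not the rules.
    """

    N: int
    m: int
    in_degree: int = 3
    seed: int | None = None
    max_rejections: int = 100_000

    def __post_init__(self) -> None:
        if self.m < 1 or self.N < 1 or self.in_degree < 1:
            raise ValueError("N, m, in_degree must be positive")
        if self.N % self.m:
            raise ValueError(f"m={self.m} must divide N={self.N}")
        if self.N // self.m <= self.in_degree:
            raise ValueError("module size must exceed the in-degree")


# ---------------------------------------------------------------------------
# nested canalizing rules
# ---------------------------------------------------------------------------

def random_nested_canalizing_rule(
    k: int, rng: np.random.Generator | None = None, seed: int | None = None
) -> tuple[int, ...]:
    """Truth table of a random NCF on ``k`` inputs, essential in all of them.

    A uniform input order, uniform canalizing input values and uniform
    canalized outputs are drawn; the default output of the innermost layer is
    the complement of its canalized output, which makes every input
    essential.  For ``k = 1`` this yields the two literals with equal
    probability.
    """
    if k < 1:
        raise ValueError("an NCF needs at least one input")
    if rng is None:
        rng = np.random.default_rng(seed)
    order = [int(v) for v in rng.permutation(k)]
    a = [int(v) for v in rng.integers(0, 2, size=k)]
    b = [int(v) for v in rng.integers(0, 2, size=k)]
    default = 1 - b[-1]
    table = []
    for row in range(1 << k):
        bits = [(row >> (k - 1 - j)) & 1 for j in range(k)]
        out = default
        for depth, var in enumerate(order):
            if bits[var] == a[depth]:
                out = b[depth]
                break
        table.append(out)
    return tuple(table)


def depends_on_all_inputs(table: tuple[int, ...]) -> bool:
    k = (len(table) - 1).bit_length()
    arr = np.asarray(table).reshape((2,) * k)
    return all(
        bool(np.any(np.take(arr, 0, axis=j) != np.take(arr, 1, axis=j)))
        for j in range(k)
    )


def is_nested_canalizing(table: tuple[int, ...]) -> bool:
    """Recursive-definition NCF test by exhaustive variable search.

    A one-input function is nested canalizing iff it is a literal; a
    ``k``-input function is nested canalizing iff some input at some value
    forces a constant output and the restriction to the opposite value is
    again nested canalizing.  Feasible up to k ~ 4-5 inputs.
    """
    arr = np.asarray(table)
    k = (arr.size - 1).bit_length()
    if arr.size != 1 << k or k == 0:
        return False

    def rec(a: np.ndarray, kk: int) -> bool:
        if kk == 1:
            return a[0] != a[1]
        a = a.reshape((2,) * kk)
        for j in range(kk):
            for val in (0, 1):
                side = np.take(a, val, axis=j)
                if side.min() == side.max():
                    if rec(np.take(a, 1 - val, axis=j).reshape(-1), kk - 1):
                        return True
        return False

    return rec(arr.reshape(-1), k)


# ---------------------------------------------------------------------------
# wiring
# ---------------------------------------------------------------------------

def _strongly_connected(regulators: np.ndarray, size: int) -> bool:
    """Strong connectivity of edge set regulator -> node (scipy condensation)."""
    k = regulators.shape[1]
    dst = np.repeat(np.arange(size), k)
    src = regulators.reshape(-1)
    adj = sp.csr_matrix(
        (np.ones(src.size, dtype=np.int8), (src, dst)), shape=(size, size)
    )
    ncomp, _ = connected_components(adj, directed=True, connection="strong")
    return ncomp == 1


def _draw_regulators(size: int, in_degree: int, rng: np.random.Generator) -> np.ndarray:
    """Each node gets ``in_degree`` distinct regulators among the others."""
    noise = rng.random((size, size - 1))
    picks = np.argpartition(noise, in_degree - 1, axis=1)[:, :in_degree]
    # skip the node itself: indices >= own index shift up by one
    return picks + (picks >= np.arange(size)[:, None])


def random_strongly_connected_wiring(
    size: int,
    in_degree: int,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    max_rejections: int = 100_000,
) -> tuple[np.ndarray, int]:
    """Rejection-sample a fixed-in-degree wiring until strongly connected.

    Returns ``(regulators, iterations)`` where ``regulators[i]`` lists the
    ``in_degree`` distinct regulators of node ``i`` (no self-loops) and
    ``iterations`` counts the draws consumed, including the successful one.
    """
    if size <= in_degree:
        raise ValueError("size must exceed in_degree")
    if rng is None:
        rng = np.random.default_rng(seed)
    for it in range(1, max_rejections + 1):
        regs = _draw_regulators(size, in_degree, rng)
        if _strongly_connected(regs, size):
            return regs, it
    raise GenerationError(
        f"no strongly connected wiring in {max_rejections} draws "
        f"(size={size}, in_degree={in_degree})"
    )


def random_module_dag(
    m: int, rng: np.random.Generator | None = None, seed: int | None = None
) -> np.ndarray:
    """Uniform weakly connected lower-triangular binary matrix, unit diagonal.

    Off-diagonal entry ``D[i, j] = 1`` (i > j) places a single regulating
    edge from module ``j`` (upstream) to module ``i`` (downstream), so module
    indices are already a topological order of the module DAG.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    eye = np.eye(m, dtype=np.int8)
    if m == 1:
        return eye
    # rejection: keep only matrices whose off-diagonal pattern is weakly connected
    while True:
        D = np.tril(rng.integers(0, 2, size=(m, m), dtype=np.int8), -1) + eye
        off = sp.csr_matrix(np.tril(D, -1))
        ncomp, _ = connected_components(off, directed=False)
        if ncomp == 1:
            return D


# ---------------------------------------------------------------------------
# full generator
# ---------------------------------------------------------------------------

def generate_modular_network(
    cfg: GeneratorConfig, rng: np.random.Generator | None = None
) -> tuple[BooleanNetwork, dict]:
    """A random NCF network with exactly ``cfg.m`` strongly connected modules.

    Returns the network plus metadata: the module DAG matrix ``D``, the
    per-module variable blocks, the rejection iterations spent on each
    module's wiring, and the cross-module edges inserted.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    size = cfg.N // cfg.m
    k = cfg.in_degree
    D = random_module_dag(cfg.m, rng)
    blocks = [range(i * size, (i + 1) * size) for i in range(cfg.m)]
    regulators: list[set[int]] = []
    iterations: list[int] = []
    for i in range(cfg.m):
        regs, it = random_strongly_connected_wiring(
            size, k, rng, max_rejections=cfg.max_rejections
        )
        iterations.append(it)
        base = i * size
        regulators.extend({base + int(r) for r in row} for row in regs)

    def intra_ok(mod: int, skip_edge: tuple[int, int]) -> bool:
        base = mod * size
        src, dst, data = [], [], []
        for node in blocks[mod]:
            for r in regulators[node]:
                if base <= r < base + size and (r, node) != skip_edge:
                    src.append(r - base)
                    dst.append(node - base)
                    data.append(1)
        adj = sp.csr_matrix((data, (src, dst)), shape=(size, size))
        ncomp, _ = connected_components(adj, directed=True, connection="strong")
        return ncomp == 1

    dag_edges = [
        (up, down)
        for down in range(cfg.m)
        for up in range(down)
        if D[down, up]
    ]
    intra_backup = [set(r) for r in regulators]
    budget = cfg.max_rejections
    cross_edges: list[tuple[int, int]] = []
    while True:
        # a greedy pass can dead-end (earlier placements starve a later edge),
        # so an unplaceable edge restarts the whole cross-edge phase
        regulators = [set(r) for r in intra_backup]
        cross_edges = []
        dead_end = False
        for up, down in dag_edges:
            placed = False
            for _ in range(20 * size):
                budget -= 1
                if budget < 0:
                    raise GenerationError("cross-edge rejection budget exhausted")
                src = int(rng.integers(0, size)) + up * size
                tgt = int(rng.integers(0, size)) + down * size
                intra = sorted(
                    r for r in regulators[tgt] if down * size <= r < (down + 1) * size
                )
                if src in regulators[tgt] or not intra:
                    continue
                drop = intra[int(rng.integers(0, len(intra)))]
                if not intra_ok(down, (drop, tgt)):
                    continue
                regulators[tgt].remove(drop)
                regulators[tgt].add(src)
                cross_edges.append((src, tgt))
                placed = True
                break
            if not placed:
                dead_end = True
                break
        if not dead_end:
            break

    names = tuple(f"x{i + 1}" for i in range(cfg.N))
    rules = []
    for node in range(cfg.N):
        regs = tuple(names[r] for r in sorted(regulators[node]))
        rules.append(Rule(regs, random_nested_canalizing_rule(k, rng)))
    net = BooleanNetwork(names, tuple(rules))
    meta = {
        "D": D,
        "modules": [tuple(names[i] for i in b) for b in blocks],
        "scc_iterations": iterations,
        "cross_edges": [(names[s], names[t]) for s, t in cross_edges],
    }
    return net, meta
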