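"""Shared fixtures: worked-example networks and independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import boolmod as bm

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

FIG1_TEXT = """\
x1, x2 & !x3
x2, x3
x3, !x1 & x2
"""


@pytest.fixture
def fig1() -> bm.BooleanNetwork:
    """Three-node example: F = (x2 AND NOT x3, x3, NOT x1 AND x2)."""
    return bm.parse_rules(FIG1_TEXT)


@pytest.fixture
def fig1_oracle_step():
    """Direct logic evaluation, independent of the truth-table machinery."""

    def step(bits: tuple[int, ...]) -> tuple[int, ...]:
        x1, x2, x3 = bits
        return (x2 & (1 - x3), x3, (1 - x1) & x2)

    return step


@pytest.fixture
def product_factors():
    """Upstream swap F=(x2,x1) and downstream G=(u1|(u2&y2), !u2&y1)."""
    F = bm.parse_rules("x1, x2\nx2, x1\n")
    G = bm.parse_rules("# inputs: u1 u2\ny1, u1 | (u2 & y2)\ny2, !u2 & y1\n")
    return F, G, {"u1": "x1", "u2": "x2"}


@pytest.fixture
def cross_product_net() -> bm.BooleanNetwork:
    """Two decoupled swaps: F(x1,x2,x3,x4) = (x2, x1, x4, x3)."""
    return bm.parse_rules("x1, x2\nx2, x1\nx3, x4\nx4, x3\n")


@pytest.fixture
def coupled_net() -> bm.BooleanNetwork:
    """Coupled variant: F(x1,x2,x3,x4) = (x2, x1, x2 AND x4, x3)."""
    return bm.parse_rules("x1, x2\nx2, x1\nx3, x2 & x4\nx4, x3\n")


def brute_attractors(step, n: int) -> set[tuple[int, ...]]:
    """Exhaustive orbit-following on integer states; canonical cycles as tuples."""
    out: set[tuple[int, ...]] = set()
    for s0 in range(1 << n):
        seen: dict[int, int] = {}
        seq: list[int] = []
        s = s0
        while s not in seen:
            seen[s] = len(seq)
            seq.append(s)
            s = step(s)
        cyc = seq[seen[s]:]
        j = cyc.index(min(cyc))
        out.add(tuple(cyc[j:] + cyc[:j]))
    return out


def attractor_tuples(aset) -> set[tuple[int, ...]]:
    return {a.states for a in aset}


def random_test_network(rng: np.random.Generator, n: int, k: int = 2) -> bm.BooleanNetwork:
    """Small random network with arbitrary (not necessarily NCF) rules."""
    names = tuple(f"v{i}" for i in range(n))
    rules = []
    for i in range(n):
        regs = tuple(names[j] for j in sorted(rng.choice(n, size=min(k, n), replace=False)))
        table = tuple(int(b) for b in rng.integers(0, 2, size=1 << len(regs)))
        rules.append(bm.Rule(regs, table))
    return bm.BooleanNetwork(names, tuple(rules))
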