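"""Phenotypical robustness, Derrida value, and dynamical complexity.

Label every vertex of the Boolean hypercube ``{0,1}^n`` by the attractor its
forward orbit reaches.  The *phenotypical robustness* ``r(F)`` is the
fraction of hypercube edges whose two endpoints carry the same label — the
probability that a single-bit perturbation of a random state leaves the
eventual phenotype unchanged.  ``r(F) = 1`` exactly when the network has a
single attractor, and it decreases as attractors multiply, so robustness
trades off against *dynamical complexity* (the number of attractors).

For networks too large to sweep, both quantities are estimated from uniform
random initial states: complexity as the number of distinct attractors
found, robustness as the fraction of sampled (state, one-bit flip) pairs
landing in the same attractor — so sampled estimates are multiples of
``1/n_samples``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import (
    ENUMERATION_GUARD,
    Attractor,
    AttractorSet,
    BooleanNetwork,
    enumerate_attractors,
    transition_table,
    _trace_cycles,
)

__all__ = [
    "RobustnessReport",
    "exact_robustness",
    "sampled_robustness",
    "sampled_analysis",
    "derrida_value",
    "dynamical_complexity",
    "detection_probability",
]


@dataclass(frozen=True)
class RobustnessReport:
    """Robustness estimate plus the provenance needed to reproduce it."""

    r_estimate: float
    method: str  # "exact" | "sampled"
    n_samples: int
    n_attractors_found: int
    seed: int | None = None


class _LazyStep:
    """Transition-table stand-in for networks beyond the exhaustive guard."""

    def __init__(self, net: BooleanNetwork):
        self._net = net

    def __getitem__(self, s: int) -> int:
        from .network import synchronous_step

        return synchronous_step(self._net, int(s))


def exact_robustness(net: BooleanNetwork, guard: int = ENUMERATION_GUARD) -> RobustnessReport:
    """Exact r(F) from the full basin map.

    Counts each unordered hypercube edge once (denominator ``n * 2^(n-1)``);
    by symmetry of the same-attractor indicator this equals the ordered-pair
    form with denominator ``n * 2^n``.
    """
    if net.external:
        raise ValueError("network has external parameters")
    n = net.n
    aset = enumerate_attractors(net, guard=guard)
    labels = np.asarray(aset.basin)
    states = np.arange(1 << n, dtype=np.int64)
    same = 0
    for i in range(n):
        b = 1 << (n - 1 - i)
        lower = states[(states & b) == 0]
        same += int(np.count_nonzero(labels[lower] == labels[lower | b]))
    total = n * (1 << (n - 1))
    return RobustnessReport(same / total, "exact", 1 << n, len(aset))


def _sampled_pairs(
    net: BooleanNetwork,
    n_samples: int,
    rng: np.random.Generator,
    guard: int,
) -> tuple[list[Attractor], dict[int, int], list[int], list[int]]:
    """Shared draw: x0 states first, then the flipped-bit indices.

    Drawing the initial states before the bit indices keeps the x0 stream
    identical to :func:`boolmod.network.sample_attractors` under the same
    generator state, so complexity and robustness use the same states.
    """
    n = net.n
    x0 = [int(x) for x in rng.integers(0, 1 << n, size=n_samples, dtype=np.uint64)]
    bits = [int(b) for b in rng.integers(0, n, size=n_samples)]
    y0 = [x ^ (1 << (n - 1 - b)) for x, b in zip(x0, bits)]
    T = transition_table(net, guard=guard) if n <= guard else _LazyStep(net)
    labels: dict[int, int] = {}
    attractors: list[Attractor] = []
    _trace_cycles(T, x0 + y0, labels, attractors, n)
    return attractors, labels, x0, y0


def sampled_robustness(
    net: BooleanNetwork,
    n_samples: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    guard: int = ENUMERATION_GUARD,
) -> RobustnessReport:
    """Monte-Carlo r(F): fraction of one-bit perturbations preserving the attractor."""
    report, _ = sampled_analysis(net, n_samples, seed=seed, rng=rng, guard=guard)
    return report


def sampled_analysis(
    net: BooleanNetwork,
    n_samples: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    guard: int = ENUMERATION_GUARD,
) -> tuple[RobustnessReport, AttractorSet]:
    """Joint estimate of robustness and complexity from one state sample.

    The robustness score and the attractor count are computed from the same
    ``n_samples`` initial states; the perturbed partners contribute to the
    robustness score only, so the complexity count stays a conservative
    lower bound on the number of attractors.
    """
    if net.external:
        raise ValueError("network has external parameters")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    attractors, labels, x0, y0 = _sampled_pairs(net, n_samples, rng, guard)
    hits = sum(labels[x] == labels[y] for x, y in zip(x0, y0))
    found = sorted({labels[x] for x in x0})
    rank = {lab: i for i, lab in enumerate(
        sorted(found, key=lambda lab: attractors[lab]))}
    aset = AttractorSet(
        tuple(attractors[lab] for lab in found),
        {x: rank[labels[x]] for x in x0},
    )
    report = RobustnessReport(
        hits / n_samples, "sampled", n_samples, len(aset), seed
    )
    return report, aset


def derrida_value(
    net: BooleanNetwork,
    method: str = "exact",
    n_samples: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    guard: int = ENUMERATION_GUARD,
) -> float:
    """Mean Hamming distance after one step, from states one bit apart."""
    if net.external:
        raise ValueError("network has external parameters")
    n = net.n
    if method == "exact":
        T = transition_table(net, guard=guard)
        states = np.arange(1 << n, dtype=np.int64)
        total = 0
        for i in range(n):
            b = 1 << (n - 1 - i)
            total += int(np.bitwise_count((T ^ T[states ^ b]).astype(np.uint64)).sum())
        return total / (n * (1 << n))
    if method == "sampled":
        if rng is None:
            rng = np.random.default_rng(seed)
        x = rng.integers(0, 1 << n, size=n_samples, dtype=np.uint64).astype(np.int64)
        bits = rng.integers(0, n, size=n_samples)
        y = x ^ (np.int64(1) << (n - 1 - bits))
        T = transition_table(net, guard=guard)
        return float(np.bitwise_count((T[x] ^ T[y]).astype(np.uint64)).mean())
    raise ValueError(f"unknown method {method!r}")


def dynamical_complexity(
    net: BooleanNetwork,
    n_samples: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    guard: int = ENUMERATION_GUARD,
) -> int:
    """Lower bound on the number of attractors from sampled initial states."""
    from .network import sample_attractors

    return len(sample_attractors(net, n_samples, seed=seed, rng=rng, guard=guard))


def detection_probability(basin_fraction: float, n_samples: int) -> float:
    """Chance that sampling finds an attractor whose basin covers the given fraction.

    With states drawn uniformly (with replacement), an attractor attracting a
    fraction ``p`` of the state space is missed with probability
    ``(1-p)^n_samples``.
    """
    if not 0.0 <= basin_fraction <= 1.0:
        raise ValueError("basin_fraction must lie in [0, 1]")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    return 1.0 - (1.0 - basin_fraction) ** n_samples
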