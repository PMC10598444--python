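# Methods

## Model and scope

`boolmod` works with synchronous Boolean networks: an ordered variable list
`x1..xn`, one update rule per variable given as a truth table over its
regulators, and the canonical map `F(x) = (f1(x), ..., fn(x))` applied to
all coordinates at once. Asynchronous and multi-valued schemes are out of
scope. A network may declare *external parameters* — input symbols that are
read but never updated — which is how subnetworks keep their upstream
regulations when a network is restricted to a variable subset.

States are stored as integer bitmasks with variable order equal to
declaration order; the textual form is the big-endian bit string in that
order (`"010"` means `x1=0, x2=1, x3=0`), so lexicographic order on strings
coincides with numeric order on masks. Truth tables are flat arrays indexed
by the regulator-value tuple in declaration order (first regulator most
significant), which gives O(1) rule evaluation and exact, order-stable
serialization.

## Modules and structural decomposition

The wiring diagram has an edge `u -> v` when the rule of `v` depends
*essentially* on `u`; non-essential regulators (those whose toggling never
changes the output) are removed first, so cosmetic dependencies cannot
create or merge modules. Modules are the restrictions of the network to the
SCCs of this diagram. SCC condensation uses networkx; the module order is a
topological order of the condensation with ties broken by the smallest
contained variable index, making module indices deterministic across runs.

The semi-direct product `F ⋊_P G` substitutes upstream variables of `F` for
external parameters of `G` according to the coupling scheme `P`. When
`structural_decompose` manufactures a module's external parameters it names
them after the upstream variable they stand for, so every coupling scheme
is an identity-on-names map and the right fold of semi-direct products
reproduces the original network *truth-table exactly* (the round trip is
asserted in tests on generated networks, and bracketing is associative).
One upstream variable may feed several parameters; nothing in the
construction forbids it.

## Dynamic decomposition

For an upstream attractor `C1` the downstream module becomes a
non-autonomous network `y(t+1) = F2(g(t), y(t))`, where `g` is the trace of
`C1` on the coupled parameters, anchored at the canonical rotation of `C1`
(the rotation starting at the numerically smallest state). Its attractors
are computed as the cycles of the deterministic *product automaton*
`(t mod r, y) -> ((t+1) mod r, F2(g(t), y))`; this makes phase handling
unambiguous and provably exhaustive, and each cycle is reported once,
rotated to its smallest `(t, y)` pair. A driven attractor is a periodic
trajectory whose states may repeat at different phases, so it is represented
by its own type (`DrivenAttractor`, minimal period, smallest rotation)
rather than the distinct-state autonomous `Attractor`.

Pairing `C1` with a driven cycle yields a combined attractor of length
`lcm(|C1|, |C2|)`; the combined states are always distinct because the
upstream state determines the phase. `dynamic_decompose` recurses by
peeling the topologically first module, converting each of its (possibly
driven) cycles into a periodic input trajectory for the remainder; the
recursion bottoms out at single modules, where the product automaton is run
directly. The result equals exhaustive enumeration as a set — this is the
central correctness property and is tested against brute force on a
hundred generated networks plus the worked four-node pair (10 attractors
for the decoupled product, 6 for the coupled variant).

Exhaustive sweeps are guarded at `n ≤ 24` (memory grows as `2^n` int64);
larger networks must use sampling or decomposition.

## Robustness and complexity

Phenotypical robustness `r(F)` is implemented in its unordered form: the
fraction of the `n·2^(n-1)` hypercube edges whose endpoints map to the same
attractor. The ordered form (normalizer `n·2^n`) is equal because the
same-attractor indicator is symmetric; the unordered form is half the work.
`r(F) = 1` iff the network has exactly one attractor (any two basins are
joined by a hypercube edge), asserted as a property test.

The sampled estimator follows the study protocol: uniform initial states
(drawn **with replacement** — at realistic state-space sizes collisions are
negligible, and the paper-scale protocol does not specify otherwise), one
uniformly chosen bit flipped per state, both states run to their attractors,
attractors compared after canonicalization (limit cycles up to rotation).
Estimates are therefore multiples of `1/n_samples`. When robustness and
complexity are requested together (`sampled_analysis`) the same initial
states serve both, as in the original protocol; the attractor count from
`n` samples is a lower bound on the dynamical complexity, and the chance of
finding an attractor whose basin covers a fraction `p` is
`1 − (1−p)^n_samples` (`detection_probability`).

The Derrida value is the mean Hamming distance after one synchronous step
between states one bit apart, exact (all `n·2^n` ordered pairs) or sampled.

## Random modular networks

The generator reproduces the simulation-study construction:

* **Rules** are nested canalizing functions (NCFs) essential in all inputs:
  a uniform input order, uniform canalizing values and uniform canalized
  outputs are drawn, with the innermost default output complementing the
  last canalized output — that constraint alone makes every input essential.
  The literature defines the family but no sampling law; this sampler is the
  natural uniform-parameter choice and every emitted table is validated by
  an independent recursive checker in the tests. For one input it yields the
  two literals with equal probability; for two inputs, the eight fully
  essential AND/OR-type functions.
* **Wiring** gives every node exactly `in_degree` distinct regulators drawn
  uniformly among the other nodes (no self-loops — they would inflate
  intra-module connectivity without creating genuine feedback), rejected
  until strongly connected. At the sparsest published condition (60 nodes,
  in-degree 3) this costs about 22 draws on average; the acceptance script
  measures exactly this.
* **Module DAG**: a uniform weakly connected lower-triangular binary matrix
  `D` with unit diagonal, sampled by rejection. An off-diagonal 1 is
  oriented from the lower-indexed (upstream) to the higher-indexed
  (downstream) module, so module indices are already topological; the
  distribution is unchanged by this labeling convention.
* **Cross edges**: each off-diagonal 1 contributes exactly one edge from a
  uniform node of the upstream module to a uniform node of the downstream
  module, *replacing* one uniformly chosen intra-module regulator of the
  target (re-drawn if the removal would break the target module's internal
  strong connectivity). Replacement is the only reading that keeps the
  global fixed in-degree while adding inter-module regulation; raising the
  in-degree instead would confound the module-count comparison. A greedy
  pass can dead-end when a small module receives several cross edges, so an
  unplaceable edge restarts the cross-edge phase from the pristine intra
  wiring rather than looping forever.

All randomness flows through one `numpy` generator per top-level call;
a configuration plus seed reproduces a network bit for bit.

## Control

Four action kinds are supported. Node pinning replaces a rule by a
constant; node deletion pins to a configurable constant (default 0) and
substitutes that constant into every rule; edge fixing/deletion substitutes
a constant for the source variable inside the target rule only (deletion
uses the constant 0). These conventions follow the common edge/node control
framework and are applied consistently; controlled nodes remain variables,
so the controlled state space stays comparable with the free one.
Verification enumerates the controlled network's attractors and demands
exactly the target.

Modular composition accepts per-module (controls, target) pairs in
topological order, verifies each module *as driven by the already-stabilized
upstream attractor* via the product automaton, and refuses — rather than
guessing — whenever neither side of a pairwise composition is a steady
state, since that is the hypothesis of the composition theorem. The
brute-force `search_minimal_controls` enumerates candidate sets by
increasing size, either globally or module by module; candidates are
restricted to actions consistent with the target (a node is only pinned to
a value it holds constantly along the target attractor).

## Simulation study

`run_experiment` generates networks per module count, estimates complexity
and robustness from shared sampled initial states, and streams records to
CSV; each network receives an independent child seed spawned from the
experiment seed. Defaults are desk scale: `N = 16`, in-degree 3, `m ∈
{1, 2, 4}`, 200 networks per condition, 500 sampled states per network
(the published experiment used `N = 60` and 50 000 networks per condition —
cluster scale; the in-degree, rule family and 500-state sampling protocol
are kept, and the qualitative orderings survive the size reduction).
At this scale the experiment shows: mean attractor count increasing with
module count; at fixed attractor count, higher mean robustness for more
modular networks in most populated bins; and Spearman-negative association
between complexity and robustness within every stratum. These orderings are
statistical tendencies over a population, not per-seed guarantees.

`fit_robustness_decay` fits `y = α + (1 − α) e^(−k(x−1))` to the mean
robustness per attractor count by bounded least squares
(`scipy.optimize.curve_fit`, `α ∈ [0,1]`, `k ≥ 0`, start `(0.5, 0.5)`);
the functional form enforces `y(1) = 1`. Attractor-count bins with fewer
than five networks are excluded — the fit targets means, and near-empty
bins destabilize it. Means pool per-network robustness estimates within a
`(m, attractor-count)` cell. The published study reports its fit only
graphically, so no numerical comparison is attempted; the fit is validated
by planted-parameter recovery instead.

## File formats and auditing

Rule files are BoolNet-style `name, expression` lines with `& | ! + ( )`
and constants `0/1` (`+` is XOR, precedence `! > & > + > |`), plus a
`# inputs:` header for external parameters. Expressions are tokenized,
validated, and evaluated over boolean arrays through Python's own
expression grammar — no hand-rolled parser. Serialization emits minterm
disjunctions over the stored regulators, so parse → serialize → parse is
the identity on essential-reduced networks. `audit` reports per-model size,
mean essential connectivity and SCC statistics for a directory of rule
files; a non-trivial SCC is one with more than one node, and a self-loop on
a singleton does not make it non-trivial.

## Known limitations

* Exhaustive operations (enumeration, exact robustness, verification) are
  limited by the `2^n` sweep; the decomposition helps only as much as the
  largest module allows.
* Attractor detection is explicit-state; no BDD/SAT symbolic back end.
* The generator's rule family is fixed to fully essential NCFs; threshold
  or scale-free families are out of scope.
* Sampled complexity is a lower bound, and sampled robustness inherits the
  binomial noise of its sample size; both are reported with their seeds for
  reproducibility.
* The synthetic generator emulates the wiring and rule statistics of
  curated models (NCF rules, small fixed in-degree, few modules), not their
  biological semantics: passing tests demonstrate the mathematics of the
  decomposition, not the fidelity of any particular biological model.
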