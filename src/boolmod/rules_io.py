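"""Rule files, graph exports, and wiring-diagram audits.

Rule files are BoolNet-style text: one ``name, expression`` line per
variable, expressions over variable names with ``&`` (and), ``|`` (or),
``!`` (not), ``+`` (xor, for linear examples), parentheses and the
constants ``0``/``1``.  Operator precedence is ``!`` > ``&`` > ``+`` > ``|``.
External parameters are declared on a header line ``# inputs: u1 u2``;
any other ``#`` line is a comment.  Serialization emits each non-constant
rule as a disjunction of minterms over its stored regulators, so
parse -> serialize -> parse is the identity on essential-reduced networks.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import networkx as nx

from .decomposition import ModuleDAG, WiringDiagram, module_dag, wiring_diagram
from .network import (
    BooleanNetwork,
    Rule,
    reduce_to_essential_regulators,
    transition_table,
)

__all__ = [
    "RuleParseError",
    "parse_rules",
    "load_rules",
    "serialize_rules",
    "save_rules",
    "export_dot_wiring",
    "export_dot_state_space",
    "export_dot_module_dag",
    "export_graphml",
    "audit_network",
    "audit_directory",
]


class RuleParseError(ValueError):
    def __init__(self, message: str, line: int | None = None):
        super().__init__(f"line {line}: {message}" if line else message)
        self.line = line


_NAME_RE = r"[A-Za-z_][A-Za-z0-9_.]*"
_TOKEN_RE = re.compile(rf"\s*(?:(?P<name>{_NAME_RE})|(?P<op>[&|!+()01]))")


def _compile_expression(expr: str, known: set[str], lineno: int) -> Rule:
    """Tokenize, validate and evaluate an expression into a truth table."""
    pos = 0
    pieces: list[str] = []
    regulators: list[str] = []
    safe: dict[str, str] = {}
    while pos < len(expr):
        m = _TOKEN_RE.match(expr, pos)
        if not m:
            if expr[pos:].strip():
                raise RuleParseError(f"unexpected token at {expr[pos:]!r}", lineno)
            break
        pos = m.end()
        if m.group("name"):
            name = m.group("name")
            if name not in known:
                raise RuleParseError(f"unknown name {name!r}", lineno)
            if name not in safe:
                safe[name] = f"v{len(regulators)}"
                regulators.append(name)
            pieces.append(safe[name])
        else:
            op = m.group("op")
            pieces.append({"!": "~", "+": "^", "0": "_ZERO", "1": "_ONE"}.get(op, op))
    source = " ".join(pieces)
    if not source.strip():
        raise RuleParseError("empty expression", lineno)
    k = len(regulators)
    rows = np.arange(1 << k)
    env = {
        safe[r]: ((rows >> (k - 1 - j)) & 1).astype(bool)
        for j, r in enumerate(regulators)
    }
    env["_ZERO"] = np.zeros(1 << k, dtype=bool)
    env["_ONE"] = np.ones(1 << k, dtype=bool)
    try:
        result = eval(compile(source, "<rule>", "eval"), {"__builtins__": {}}, env)
    except SyntaxError as exc:
        raise RuleParseError(f"malformed expression: {expr.strip()!r}", lineno) from exc
    table = np.broadcast_to(np.asarray(result, dtype=bool), (1 << k,))
    return Rule(tuple(regulators), tuple(int(b) for b in table))


def parse_rules(text: str) -> BooleanNetwork:
    """Parse a rule file into a network (declaration order preserved)."""
    inputs: list[str] = []
    raw: list[tuple[int, str, str]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            m = re.match(r"#\s*inputs\s*:\s*(.*)$", stripped, flags=re.I)
            if m:
                for name in m.group(1).split():
                    if not re.fullmatch(_NAME_RE, name):
                        raise RuleParseError(f"bad input name {name!r}", lineno)
                    inputs.append(name)
            continue
        if "," not in stripped:
            raise RuleParseError("expected 'name, expression'", lineno)
        name, expr = stripped.split(",", 1)
        name = name.strip()
        if not re.fullmatch(_NAME_RE, name):
            raise RuleParseError(f"bad variable name {name!r}", lineno)
        raw.append((lineno, name, expr))
    if not raw:
        raise RuleParseError("no rules found")
    names = [name for _, name, _ in raw]
    if len(set(names)) != len(names):
        dup = next(n for n in names if names.count(n) > 1)
        raise RuleParseError(f"duplicate variable {dup!r}")
    if set(names) & set(inputs):
        raise RuleParseError("declared input is also a variable")
    known = set(names) | set(inputs)
    rules = tuple(_compile_expression(expr, known, lineno) for lineno, _, expr in raw)
    return BooleanNetwork(tuple(names), rules, tuple(inputs))


def load_rules(path: str | Path) -> BooleanNetwork:
    return parse_rules(Path(path).read_text())


def _expression(rule: Rule) -> str:
    if rule.k == 0:
        return str(rule.table[0])
    if all(v == rule.table[0] for v in rule.table):
        return str(rule.table[0])
    terms = []
    for row, out in enumerate(rule.table):
        if not out:
            continue
        lits = []
        for j, r in enumerate(rule.regulators):
            bit = (row >> (rule.k - 1 - j)) & 1
            lits.append(r if bit else f"!{r}")
        terms.append(" & ".join(lits) if len(lits) == 1 else "(" + " & ".join(lits) + ")")
    return " | ".join(terms)


def serialize_rules(net: BooleanNetwork) -> str:
    lines = []
    if net.external:
        lines.append("# inputs: " + " ".join(net.external))
    for v, rule in zip(net.variables, net.rules):
        lines.append(f"{v}, {_expression(rule)}")
    return "\n".join(lines) + "\n"


def save_rules(net: BooleanNetwork, path: str | Path) -> None:
    Path(path).write_text(serialize_rules(net))


# ---------------------------------------------------------------------------
# graph exports
# ---------------------------------------------------------------------------

def export_dot_wiring(wd: WiringDiagram) -> str:
    lines = ["digraph wiring {"]
    for v in wd.variables:
        lines.append(f'  "{v}";')
    for p in wd.external:
        lines.append(f'  "{p}" [shape=box, style=dashed];')
    for u, v in sorted(wd.edges()):
        lines.append(f'  "{u}" -> "{v}";')
    lines.append("}")
    return "\n".join(lines) + "\n"


def export_dot_state_space(net: BooleanNetwork, guard: int = 10) -> str:
    if net.n > guard:
        raise ValueError(f"state-space export capped at n <= {guard}")
    T = transition_table(net)
    lines = ["digraph statespace {"]
    for s in range(1 << net.n):
        lines.append(f'  "{net.state_string(s)}" -> "{net.state_string(int(T[s]))}";')
    lines.append("}")
    return "\n".join(lines) + "\n"


def export_dot_module_dag(dag: ModuleDAG) -> str:
    """Condensation rendering: size labels, non-trivial modules highlighted."""
    lines = ["digraph modules {"]
    for i, ys in enumerate(dag.module_vars):
        label = str(len(ys))
        color = "red" if len(ys) > 1 else "grey"
        lines.append(f'  m{i} [label="{label}", color={color}];')
    for a, b in sorted(dag.edges):
        lines.append(f"  m{a} -> m{b};")
    lines.append("}")
    return "\n".join(lines) + "\n"


def export_graphml(wd_or_dag: WiringDiagram | ModuleDAG) -> str:
    if isinstance(wd_or_dag, WiringDiagram):
        g = wd_or_dag.graph
    else:
        g = nx.DiGraph()
        for i, ys in enumerate(wd_or_dag.module_vars):
            g.add_node(i, size=len(ys), nontrivial=len(ys) > 1)
        g.add_edges_from(wd_or_dag.edges)
    return "\n".join(nx.generate_graphml(g)) + "\n"


# ---------------------------------------------------------------------------
# audits
# ---------------------------------------------------------------------------

def audit_network(net: BooleanNetwork) -> dict:
    """Size, mean essential connectivity, and SCC statistics of one model.

    A module is counted as non-trivial when it has more than one node; a
    self-loop on a singleton does not count.
    """
    red = reduce_to_essential_regulators(net)
    dag = module_dag(red)
    sizes = sorted((len(ys) for ys in dag.module_vars), reverse=True)
    wd = wiring_diagram(red)
    return {
        "size": net.n,
        "n_edges": len(wd.edges()),
        "mean_connectivity": float(np.mean([r.k for r in red.rules])),
        "n_scc": dag.m,
        "scc_sizes": tuple(sizes),
        "n_nontrivial_scc": sum(1 for s in sizes if s > 1),
    }


def audit_directory(path: str | Path, patterns: Iterable[str] = ("*.bnet", "*.txt")) -> pd.DataFrame:
    """Audit every rule file in a directory (the meta-analysis statistics)."""
    path = Path(path)
    files = sorted({f for pat in patterns for f in path.glob(pat)})
    rows = []
    for f in files:
        stats = audit_network(load_rules(f))
        stats["model"] = f.name
        stats["scc_sizes"] = ",".join(map(str, stats["scc_sizes"]))
        rows.append(stats)
    cols = ["model", "size", "n_edges", "mean_connectivity", "n_scc",
            "n_nontrivial_scc", "scc_sizes"]
    return pd.DataFrame(rows, columns=cols)
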