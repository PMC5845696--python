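"""Query-file parsing, network serialization, and fixture generation.

Query grammar (versioned in the header comment of written files):

    variables: a b c
    topology:
        a -> b : MPU
        c -> b : OPU
    constraints:
        fixed_point 01*
        fixed_point 011 mutant a=0
        prohibit_fixed_point 1**
        transition 010 -> 101
    options:
        forbid_cyclic_attractors = true
        max_solutions = 100

Sections may appear in any order; ``topology``, ``constraints`` and
``options`` are optional.  Unknown option keys and malformed lines are
rejected with line-numbered messages, all collected before raising.
"""

from __future__ import annotations

import json
import random
import re
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from .core import (
    BooleanNetwork,
    ConstraintSpec,
    Mutation,
    PatternConstraint,
    Problem,
    RGraph,
    RLabel,
    SolverOptions,
    Subspace,
    parse_state,
)
from .regulation import lift, regulation_graph_of

__all__ = [
    "QuerySyntaxError",
    "parse_query",
    "write_query",
    "write_network",
    "read_network",
    "parse_bnet",
    "generate_fixture",
]

QUERY_VERSION = "bninfer query v1"

_BOOL_OPTIONS = {
    "exact_fixed_point_set",
    "forbid_cyclic_attractors",
    "injective_matching",
    "learn_all_violations",
}
_INT_OPTIONS = {
    "seed",
    "radius_min",
    "radius_max",
    "explicit_limit",
    "static_prohibition_limit",
    "max_iterations",
}


class QuerySyntaxError(ValueError):
    """All syntax problems of one query file, each with its line number."""

    def __init__(self, errors: Sequence[Tuple[int, str]]):
        self.errors = list(errors)
        msg = "; ".join(f"line {ln}: {m}" for ln, m in self.errors)
        super().__init__(msg)


def _parse_mutation(text: str, var_index: Dict[str, int], errors, ln):
    pairs = []
    for item in text.split(","):
        m = re.fullmatch(r"\s*(\w+)\s*=\s*([01])\s*", item)
        if not m:
            errors.append((ln, f"bad mutant assignment {item.strip()!r}"))
            return None
        name, val = m.group(1), int(m.group(2))
        if name not in var_index:
            errors.append((ln, f"undeclared variable {name!r} in mutant"))
            return None
        pairs.append((var_index[name] + 1, val))
    return Mutation(tuple(p for p, _ in pairs), tuple(v for _, v in pairs))


def parse_query(text: str) -> Problem:
    """Parse query text into a Problem, or raise QuerySyntaxError."""
    errors: List[Tuple[int, str]] = []
    variables: List[str] = []
    var_index: Dict[str, int] = {}
    edges: List[Tuple[int, RLabel, int]] = []
    edge_pairs = set()
    required: List[PatternConstraint] = []
    prohibited: List[PatternConstraint] = []
    transitions: List[Tuple[tuple, tuple]] = []
    opt_kwargs: dict = {}
    section = None

    def check_pattern(pat: str, ln: int) -> Optional[Subspace]:
        if variables and len(pat) != len(variables):
            errors.append((
                ln,
                f"pattern {pat!r} has length {len(pat)}, expected "
                f"{len(variables)} (one symbol per declared variable)",
            ))
            return None
        try:
            return Subspace(pat)
        except ValueError as e:
            errors.append((ln, str(e)))
            return None

    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        header = re.fullmatch(r"(variables|topology|constraints|options)\s*:(.*)",
                              line)
        if header:
            section = header.group(1)
            rest = header.group(2).strip()
            if rest and section != "variables":
                errors.append((ln, f"unexpected text after '{section}:'"))
            if section == "variables" and rest:
                for name in rest.split():
                    if name in var_index:
                        errors.append((ln, f"duplicate variable {name!r}"))
                    else:
                        var_index[name] = len(variables)
                        variables.append(name)
            continue
        if section == "variables":
            for name in line.split():
                if name in var_index:
                    errors.append((ln, f"duplicate variable {name!r}"))
                else:
                    var_index[name] = len(variables)
                    variables.append(name)
        elif section == "topology":
            m = re.fullmatch(r"(\w+)\s*->\s*(\w+)\s*:\s*(\w+)", line)
            if not m:
                errors.append((ln, f"malformed edge line {line!r}"))
                continue
            src, dst, labtext = m.groups()
            ok = True
            for name in (src, dst):
                if name not in var_index:
                    errors.append((ln, f"undeclared variable {name!r}"))
                    ok = False
            try:
                lab = RLabel.from_acronym(labtext)
            except ValueError as e:
                errors.append((ln, str(e)))
                ok = False
            if not ok:
                continue
            pair = (var_index[src], var_index[dst])
            if pair in edge_pairs:
                errors.append(
                    (ln, f"duplicate edge for ordered pair {src}->{dst}")
                )
                continue
            edge_pairs.add(pair)
            edges.append((pair[0], lab, pair[1]))
        elif section == "constraints":
            m = re.fullmatch(
                r"(fixed_point|prohibit_fixed_point)\s+([01*]+)"
                r"(?:\s+mutant\s+(.+))?",
                line,
            )
            if m:
                kind, pat, muttext = m.groups()
                sub = check_pattern(pat, ln)
                mut = (
                    _parse_mutation(muttext, var_index, errors, ln)
                    if muttext else None
                )
                if sub is None or (muttext and mut is None):
                    continue
                try:
                    pc = PatternConstraint(sub, mut)
                except ValueError as e:
                    errors.append((ln, str(e)))
                    continue
                (required if kind == "fixed_point" else prohibited).append(pc)
                continue
            m = re.fullmatch(r"transition\s+([01]+)\s*->\s*([01]+)", line)
            if m:
                x, y = m.groups()
                if variables and (
                    len(x) != len(variables) or len(y) != len(variables)
                ):
                    errors.append((ln, "transition state length mismatch"))
                    continue
                transitions.append((parse_state(x), parse_state(y)))
                continue
            errors.append((ln, f"malformed constraint line {line!r}"))
        elif section == "options":
            m = re.fullmatch(r"(\w+)\s*=\s*(\S+)", line)
            if not m:
                errors.append((ln, f"malformed option line {line!r}"))
                continue
            key, val = m.groups()
            if key in _BOOL_OPTIONS:
                if val.lower() not in ("true", "false"):
                    errors.append((ln, f"option {key} expects true/false"))
                    continue
                opt_kwargs[key] = val.lower() == "true"
            elif key in _INT_OPTIONS:
                try:
                    opt_kwargs[key] = int(val)
                except ValueError:
                    errors.append((ln, f"option {key} expects an integer"))
            elif key == "max_solutions":
                if val.lower() == "all":
                    opt_kwargs[key] = None
                else:
                    try:
                        opt_kwargs[key] = int(val)
                    except ValueError:
                        errors.append(
                            (ln, "max_solutions expects an integer or 'all'")
                        )
            elif key == "strategy":
                if val not in ("whole", "radial"):
                    errors.append((ln, "strategy expects whole|radial"))
                else:
                    opt_kwargs[key] = val
            else:
                errors.append((ln, f"unknown option {key!r}"))
        else:
            errors.append((ln, f"content before any section: {line!r}"))

    if not variables:
        errors.append((1, "no variables declared"))
    if errors:
        raise QuerySyntaxError(errors)

    spec_keys = {
        "exact_fixed_point_set", "forbid_cyclic_attractors",
        "injective_matching",
    }
    spec = ConstraintSpec(
        required_fixed_points=tuple(required),
        prohibited_fixed_points=tuple(prohibited),
        required_transitions=tuple(transitions),
        **{k: v for k, v in opt_kwargs.items() if k in spec_keys},
    )
    options = SolverOptions(
        **{k: v for k, v in opt_kwargs.items() if k not in spec_keys}
    )
    return Problem(RGraph(tuple(variables), tuple(edges)), spec, options)


def write_query(problem: Problem) -> str:
    """Render a Problem back to query text (parse/write round-trips)."""
    g = problem.rgraph
    spec = problem.constraints
    opts = problem.options
    lines = [f"# {QUERY_VERSION}", "variables: " + " ".join(g.variables)]
    if g.edges:
        lines.append("topology:")
        for u, lab, v in g.edges:
            name = "False" if lab is RLabel.FALSE else (
                "True" if lab is RLabel.TRUE else lab.name
            )
            lines.append(f"    {g.variables[u]} -> {g.variables[v]} : {name}")
    entries = []
    for kind, pcs in (
        ("fixed_point", spec.required_fixed_points),
        ("prohibit_fixed_point", spec.prohibited_fixed_points),
    ):
        for pc in pcs:
            suffix = ""
            if pc.mutation is not None:
                parts = ",".join(
                    f"{g.variables[p - 1]}={v}"
                    for p, v in zip(pc.mutation.positions, pc.mutation.values)
                )
                suffix = f" mutant {parts}"
            entries.append(f"    {kind} {pc.pattern}{suffix}")
    for x, y in spec.required_transitions:
        entries.append(
            "    transition "
            + "".join(map(str, x)) + " -> " + "".join(map(str, y))
        )
    if entries:
        lines.append("constraints:")
        lines.extend(entries)
    defaults = SolverOptions()
    opt_lines = []
    for key in (
        "exact_fixed_point_set", "forbid_cyclic_attractors",
        "injective_matching",
    ):
        val = getattr(spec, key)
        if val:
            opt_lines.append(f"    {key} = true")
    for key in ("max_solutions", "seed", "strategy", "radius_min",
                "radius_max", "explicit_limit", "static_prohibition_limit",
                "learn_all_violations", "max_iterations"):
        val = getattr(opts, key)
        if val != getattr(defaults, key):
            if isinstance(val, bool):
                val = "true" if val else "false"
            opt_lines.append(f"    {key} = {val}")
    if opt_lines:
        lines.append("options:")
        lines.extend(opt_lines)
    return "\n".join(lines) + "\n"


# ----------------------------------------------------------------------
# network serialization


def _sop_expression(f: BooleanNetwork, j: int) -> str:
    regs = f.regulators[j]
    tab = f.tables[j]
    if not regs:
        return str(tab[0])
    terms = []
    d = len(regs)
    for row, out in enumerate(tab):
        if not out:
            continue
        lits = []
        for k, r in enumerate(regs):
            bit = (row >> (d - 1 - k)) & 1
            name = f.variables[r]
            lits.append(name if bit else f"!{name}")
        terms.append("(" + " & ".join(lits) + ")")
    return " | ".join(terms) if terms else "0"


def write_network(f: BooleanNetwork, fmt: str = "bnet") -> str:
    """Serialize a network: BoolNet-style rules, JSON, or raw tables.

    The bnet factors are unminimized sums of products over the full
    regulator minterms, so the declared regulator list survives the round
    trip whenever the node's table is not identically zero (a constant-0
    node reads back as the constant).  JSON and truth-table text
    round-trip bit-exactly always.
    """
    if fmt == "json":
        return json.dumps(
            {
                "variables": list(f.variables),
                "regulators": [
                    [r + 1 for r in regs] for regs in f.regulators
                ],
                "tables": ["".join(map(str, t)) for t in f.tables],
            },
            indent=1,
        ) + "\n"
    if fmt == "truthtable":
        lines = []
        for j, name in enumerate(f.variables):
            regs = " ".join(f.variables[r] for r in f.regulators[j])
            bits = "".join(map(str, f.tables[j]))
            lines.append(f"{name}\t{regs}\t{bits}")
        return "\n".join(lines) + "\n"
    if fmt == "bnet":
        lines = ["targets, factors"]
        for j, name in enumerate(f.variables):
            lines.append(f"{name}, {_sop_expression(f, j)}")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown network format {fmt!r}")


class _ExprParser:
    """Recursive-descent parser for BoolNet-style rule expressions."""

    def __init__(self, text: str):
        self.tokens = re.findall(r"[A-Za-z_]\w*|[01()!&|]", text)
        if "".join(self.tokens).replace(" ", "") != re.sub(r"\s+", "", text):
            raise ValueError(f"cannot tokenize expression {text!r}")
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self, expected=None):
        tok = self.peek()
        if tok is None or (expected is not None and tok != expected):
            raise ValueError(
                f"expected {expected or 'token'}, found {tok!r}"
            )
        self.pos += 1
        return tok

    def parse(self):
        node = self._or()
        if self.peek() is not None:
            raise ValueError(f"trailing tokens from {self.peek()!r}")
        return node

    def _or(self):
        node = self._and()
        while self.peek() == "|":
            self.take("|")
            node = ("or", node, self._and())
        return node

    def _and(self):
        node = self._unary()
        while self.peek() == "&":
            self.take("&")
            node = ("and", node, self._unary())
        return node

    def _unary(self):
        tok = self.peek()
        if tok == "!":
            self.take("!")
            return ("not", self._unary())
        if tok == "(":
            self.take("(")
            node = self._or()
            self.take(")")
            return node
        if tok in ("0", "1"):
            self.take()
            return ("const", int(tok))
        if tok is None:
            raise ValueError("unexpected end of expression")
        self.take()
        return ("var", tok)


def _expr_vars(node, acc: List[str]):
    kind = node[0]
    if kind == "var" and node[1] not in acc:
        acc.append(node[1])
    for child in node[1:]:
        if isinstance(child, tuple):
            _expr_vars(child, acc)


def _expr_eval(node, env: Dict[str, int]) -> int:
    kind = node[0]
    if kind == "const":
        return node[1]
    if kind == "var":
        return env[node[1]]
    if kind == "not":
        return 1 - _expr_eval(node[1], env)
    a, b = _expr_eval(node[1], env), _expr_eval(node[2], env)
    return (a & b) if kind == "and" else (a | b)


def parse_bnet(text: str) -> BooleanNetwork:
    """Read a BoolNet-style file back into a network."""
    rules: List[Tuple[str, tuple]] = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line or line.lower().startswith("targets"):
            continue
        if "," not in line:
            raise ValueError(f"malformed rule line {line!r}")
        name, expr = line.split(",", 1)
        rules.append((name.strip(), _ExprParser(expr.strip()).parse()))
    variables = tuple(name for name, _ in rules)
    index = {name: i for i, name in enumerate(variables)}
    regulators = []
    tables = []
    for name, node in rules:
        acc: List[str] = []
        _expr_vars(node, acc)
        for v in acc:
            if v not in index:
                raise ValueError(f"rule for {name} uses unknown variable {v}")
        regs = tuple(index[v] for v in acc)
        d = len(regs)
        tab = []
        for row in range(1 << d):
            env = {
                acc[k]: (row >> (d - 1 - k)) & 1 for k in range(d)
            }
            tab.append(_expr_eval(node, env))
        regulators.append(regs)
        tables.append(tuple(tab))
    return BooleanNetwork(variables, tuple(regulators), tuple(tables))


def read_network(text: str, fmt: str = "json") -> BooleanNetwork:
    if fmt == "json":
        data = json.loads(text)
        return BooleanNetwork(
            tuple(data["variables"]),
            tuple(tuple(r - 1 for r in regs) for regs in data["regulators"]),
            tuple(tuple(int(c) for c in t) for t in data["tables"]),
        )
    if fmt == "truthtable":
        variables, regnames, bits = [], [], []
        for line in text.splitlines():
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"malformed truth-table line {line!r}")
            variables.append(parts[0])
            regnames.append(parts[1].split())
            bits.append(parts[2])
        index = {v: i for i, v in enumerate(variables)}
        return BooleanNetwork(
            tuple(variables),
            tuple(tuple(index[r] for r in regs) for regs in regnames),
            tuple(tuple(int(c) for c in t) for t in bits),
        )
    if fmt == "bnet":
        return parse_bnet(text)
    raise ValueError(f"unknown network format {fmt!r}")


# ----------------------------------------------------------------------
# fixtures


def generate_fixture(n: int, degrees: Sequence[int], seed: int
                     ) -> Tuple[BooleanNetwork, RGraph]:
    """A reproducible random network plus the exact-label generalized
    graph lifted from its own regulation graph.

    The returned graph is satisfied by the returned network (so every
    fixture query is satisfiable), and the same seed always produces the
    same pair.
    """
    if len(degrees) != n:
        raise ValueError("need one in-degree per node")
    if any(not 0 <= d <= n for d in degrees):
        raise ValueError("in-degrees must lie in [0, n]")
    rng = random.Random(seed)
    variables = tuple(f"v{i + 1}" for i in range(n))
    regulators = []
    tables = []
    for d in degrees:
        regs = tuple(sorted(rng.sample(range(n), d)))
        regulators.append(regs)
        tables.append(tuple(rng.randrange(2) for _ in range(1 << d)))
    f = BooleanNetwork(variables, tuple(regulators), tuple(tables))
    return f, lift(regulation_graph_of(f))
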