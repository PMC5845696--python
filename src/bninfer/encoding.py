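"""Propositional encoding of network-inference queries.

The unknowns are the truth tables of the update functions: one Boolean
variable T[j, r] per node j and table row r (sum over nodes of 2^d_j in
total, where d_j counts the node's potential regulators).  Per labeled
edge i -> j, two regulation variables R+[i, j] and R-[i, j] are defined
from the tables by an equisatisfiable biconditional (one switching
variable per regulator context), and the edge label's formula over
(R+, R-) is conjoined as clauses.  Static dynamic constraints (fixed
points, wildcard fixed points, prohibitions, transitions, and their
mutant-scoped versions) are clauses over the T variables; exclusion of
whole attractor sets is deliberately left to the engine's runtime
clause learning.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .core import (
    BooleanNetwork,
    ConstraintSpec,
    Mutation,
    PatternConstraint,
    RGraph,
    RLabel,
    State,
    Subspace,
)

__all__ = [
    "VariableMap",
    "Formula",
    "encode_regulations",
    "encode_constraints",
    "encode_fixed_point",
    "encode_prohibited_fixed_point",
    "encode_transition",
    "decode_model",
    "export_dimacs",
    "parse_dimacs",
]


@dataclass
class VariableMap:
    """Dense numbering of the propositional variables of one query."""

    rgraph: RGraph
    table_vars: Dict[Tuple[int, int], int] = field(default_factory=dict)
    reg_vars: Dict[Tuple[str, int, int], int] = field(default_factory=dict)
    aux_count: int = 0
    wildcard_count: int = 0
    _next: int = 0

    def __post_init__(self) -> None:
        g = self.rgraph
        for j in range(g.n):
            d = len(g.potential_regulators(j))
            for r in range(1 << d):
                self._next += 1
                self.table_vars[(j, r)] = self._next

    def fresh_aux(self) -> int:
        self._next += 1
        self.aux_count += 1
        return self._next

    def fresh_wildcard(self) -> int:
        self._next += 1
        self.wildcard_count += 1
        return self._next

    def reg_var(self, sign: str, i: int, j: int) -> int:
        key = (sign, i, j)
        if key not in self.reg_vars:
            self._next += 1
            self.reg_vars[key] = self._next
        return self.reg_vars[key]

    @property
    def num_vars(self) -> int:
        return self._next

    @property
    def table_var_count(self) -> int:
        return len(self.table_vars)

    @property
    def reg_var_count(self) -> int:
        return len(self.reg_vars)

    def table_literal(self, j: int, row: int, bit: int) -> int:
        v = self.table_vars[(j, row)]
        return v if bit else -v


@dataclass
class Formula:
    """Integer-literal clauses plus the variable map that reads them."""

    varmap: VariableMap
    clauses: List[List[int]] = field(default_factory=list)

    def add(self, clause: Sequence[int]) -> None:
        self.clauses.append(list(clause))

    def extend(self, clauses) -> None:
        for c in clauses:
            self.add(c)


def _row_of(regs: Sequence[int], bits: Dict[int, int]) -> int:
    """Table row index for a full assignment ``bits`` of the regulators."""
    r = 0
    for k in regs:
        r = (r << 1) | bits[k]
    return r


def _define_reg_var(formula: Formula, sign: str, i: int, j: int) -> int:
    """Define R+[i,j] or R-[i,j] from node j's table, both directions.

    R+ holds iff some context of j's other regulators has the table row
    with i=1 on and the row with i=0 off (and dually for R-).  One
    switching variable per context keeps the clause form equisatisfiable.
    """
    vm = formula.varmap
    g = vm.rgraph
    regs = g.potential_regulators(j)
    rvar = vm.reg_var(sign, i, j)
    others = [k for k in regs if k != i]
    disjuncts = []
    for ctx in itertools.product((0, 1), repeat=len(others)):
        bits = dict(zip(others, ctx))
        bits[i] = 1
        r1 = _row_of(regs, bits)
        bits[i] = 0
        r0 = _row_of(regs, bits)
        t1 = vm.table_vars[(j, r1)]
        t0 = vm.table_vars[(j, r0)]
        a = vm.fresh_aux()
        if sign == "+":  # a <-> (t1 & ~t0)
            formula.add([-a, t1])
            formula.add([-a, -t0])
            formula.add([a, -t1, t0])
        else:  # a <-> (~t1 & t0)
            formula.add([-a, -t1])
            formula.add([-a, t0])
            formula.add([a, t1, -t0])
        disjuncts.append(a)
    # rvar <-> OR(disjuncts)
    formula.add([-rvar] + disjuncts)
    for a in disjuncts:
        formula.add([-a, rvar])
    return rvar


def encode_regulations(g: RGraph) -> Formula:
    """Formula whose models (projected to table vars) are the candidate
    networks consistent with every edge label of the generalized graph."""
    vm = VariableMap(g)
    formula = Formula(vm)
    for u, lab, v in g.edges:
        if lab is RLabel.NR:
            continue
        if not lab.sat_pairs:  # contradictory label: immediately unsat
            formula.add([])
            continue
        rp = _define_reg_var(formula, "+", u, v)
        rm = _define_reg_var(formula, "-", u, v)
        # conjoin h(R+, R-): one clause per excluded sign pair
        for a, b in ((0, 0), (0, 1), (1, 0), (1, 1)):
            if (a, b) not in lab.sat_pairs:
                formula.add([
                    -rp if a else rp,
                    -rm if b else rm,
                ])
    return formula


def _active_nodes(g: RGraph, mutation: Optional[Mutation]):
    """Node indices whose update function is constrained (not clamped)."""
    clamped = set() if mutation is None else set(mutation.as_dict())
    return [j for j in range(g.n) if j not in clamped]


def encode_fixed_point(formula: Formula, pc: PatternConstraint) -> None:
    """Require a fixed point matching the (possibly wildcard) pattern.

    Without wildcards each active node contributes a unit literal.  Each
    wildcard position gets a fresh choice variable; for node j only the
    wildcards among j's regulators need enumerating, so the cost is
    2^(#wildcard regulators of j) clauses per node, not 2^(#wildcards).
    In a mutant background only unclamped nodes are constrained (clamped
    positions were checked against the pattern when the constraint was
    built).
    """
    vm = formula.varmap
    g = vm.rgraph
    pattern = pc.resolved_pattern()
    if pattern.n != g.n:
        raise ValueError("pattern length does not match variable count")
    wc_positions = [k for k, c in enumerate(pattern.pattern) if c == "*"]
    wc_var = {k: vm.fresh_wildcard() for k in wc_positions}
    fixed = {k: int(c) for k, c in enumerate(pattern.pattern) if c != "*"}

    for j in _active_nodes(g, pc.mutation):
        regs = g.potential_regulators(j)
        wc_regs = [k for k in regs if k in wc_var]
        for ctx in itertools.product((0, 1), repeat=len(wc_regs)):
            bits = {k: fixed[k] for k in regs if k in fixed}
            bits.update(dict(zip(wc_regs, ctx)))
            row = _row_of(regs, bits)
            tvar = vm.table_vars[(j, row)]
            # antecedent: this completion of the wildcard regulators
            ante = [
                -wc_var[k] if b else wc_var[k]
                for k, b in zip(wc_regs, ctx)
            ]
            if j in fixed:
                formula.add(ante + [tvar if fixed[j] else -tvar])
            else:
                w = wc_var[j]
                formula.add(ante + [-w, tvar])
                formula.add(ante + [w, -tvar])


def encode_prohibited_fixed_point(
    formula: Formula, pc: PatternConstraint,
    static_limit: int = 8,
) -> bool:
    """Forbid any fixed point matching the pattern; returns True when the
    prohibition was encoded statically.

    One clause per concrete matching state: some active node's selected
    table row must disagree with the state.  Patterns freer than
    ``static_limit`` wildcards are left to the runtime verifier (same
    semantics, enforced lazily) and reported with a False return.
    """
    vm = formula.varmap
    g = vm.rgraph
    if pc.pattern.n != g.n:
        raise ValueError("pattern length does not match variable count")
    if pc.pattern.n_free > static_limit:
        return False
    clamp = {} if pc.mutation is None else pc.mutation.as_dict()
    active = _active_nodes(g, pc.mutation)
    for x in pc.pattern.states():
        if any(x[k] != v for k, v in clamp.items()):
            continue  # can never be stationary in this mutant
        clause = []
        for j in active:
            regs = g.potential_regulators(j)
            row = _row_of(regs, {k: x[k] for k in regs})
            clause.append(vm.table_literal(j, row, 1 - x[j]))
        formula.add(clause)
    return True


def encode_transition(formula: Formula, x: State, y: State) -> None:
    """Require f(x) = y: one unit literal per node."""
    g = formula.varmap.rgraph
    if len(x) != g.n or len(y) != g.n:
        raise ValueError("transition state length mismatch")
    for j in range(g.n):
        regs = g.potential_regulators(j)
        row = _row_of(regs, {k: x[k] for k in regs})
        formula.add([formula.varmap.table_literal(j, row, y[j])])


def encode_constraints(formula: Formula, spec: ConstraintSpec,
                       static_prohibition_limit: int = 8):
    """Encode all statically encodable constraints; return the prohibition
    constraints deferred to runtime verification."""
    deferred = []
    for pc in spec.required_fixed_points:
        encode_fixed_point(formula, pc)
    for pc in spec.prohibited_fixed_points:
        if not encode_prohibited_fixed_point(
            formula, pc, static_prohibition_limit
        ):
            deferred.append(pc)
    for x, y in spec.required_transitions:
        encode_transition(formula, x, y)
    return deferred


def decode_model(model: Dict[int, bool], varmap: VariableMap) -> BooleanNetwork:
    """Read the table variables of a model back into a concrete network."""
    g = varmap.rgraph
    regulators = []
    tables = []
    for j in range(g.n):
        regs = g.potential_regulators(j)
        regulators.append(regs)
        tab = []
        for r in range(1 << len(regs)):
            var = varmap.table_vars[(j, r)]
            if var not in model:
                raise ValueError(f"model does not assign table variable {var}")
            tab.append(int(model[var]))
        tables.append(tuple(tab))
    return BooleanNetwork(g.variables, tuple(regulators), tuple(tables))


def export_dimacs(formula: Formula) -> str:
    """Standard DIMACS CNF text, with the variable map in comment lines."""
    vm = formula.varmap
    lines = []
    for (j, r), v in sorted(vm.table_vars.items()):
        lines.append(f"c T node={j + 1} row={r} var={v}")
    for (sign, i, j), v in sorted(vm.reg_vars.items()):
        lines.append(f"c R{sign} {i + 1}->{j + 1} var={v}")
    nv = max(
        [vm.num_vars] + [abs(l) for cl in formula.clauses for l in cl]
    )
    lines.append(f"p cnf {nv} {len(formula.clauses)}")
    for cl in formula.clauses:
        lines.append(" ".join(str(l) for l in cl) + " 0")
    return "\n".join(lines) + "\n"


def parse_dimacs(text: str) -> List[List[int]]:
    """Clause list from DIMACS CNF text (comments and header skipped)."""
    clauses = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith(("c", "p")):
            continue
        lits = [int(t) for t in line.split()]
        if lits and lits[-1] == 0:
            lits = lits[:-1]
        if lits:
            clauses.append(lits)
    return clauses
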