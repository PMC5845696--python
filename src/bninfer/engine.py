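"""The inference loop: enumerate candidates, verify, learn, repeat.

Statically encoding the *absence* of unwanted attractors is hopeless --
the number of conceivable attractors of an n-variable network grows
astronomically with n -- so the engine encodes only the requirements,
then iterates: pull a model from the CNF solver, decode it into a
candidate network, compute the candidate's attractors explicitly, and on
rejection add learned clauses that exclude each offending fixed point or
cycle from every future candidate.  Accepted networks are emitted and
blocked (negation of their full truth-table assignment) so enumeration
never repeats a solution, and the loop ends with a definitive
unsatisfiability verdict once the clause set closes the space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import networkx as nx

from .core import (
    Attractor,
    BooleanNetwork,
    ConstraintSpec,
    Mutation,
    Problem,
    State,
    format_state,
    mutate,
)
from .dynamics import attractors
from .encoding import (
    Formula,
    VariableMap,
    _active_nodes,
    _row_of,
    decode_model,
    encode_constraints,
    encode_regulations,
)
from .regulation import satisfies
from .sat import Solver

__all__ = [
    "Violation",
    "SolveResult",
    "solve",
    "verify_candidate",
    "blocking_clause_fixed_point",
    "blocking_clause_cycle",
    "solution_blocking_clause",
    "run_log_to_tsv",
]


@dataclass(frozen=True)
class Violation:
    """One reason a candidate was rejected."""

    kind: str  # extra_fixed_point | prohibited_fixed_point |
    #           cyclic_attractor | missing_required | non_injective
    states: tuple = ()
    mutation: Optional[Mutation] = None

    def __str__(self) -> str:
        where = "" if self.mutation is None else " [mutant]"
        return f"{self.kind}({','.join(format_state(s) for s in self.states)})" + where


@dataclass
class SolveResult:
    networks: List[BooleanNetwork]
    status: str  # "complete" | "incomplete"
    iterations: int
    log: List[dict] = field(default_factory=list)

    @property
    def satisfiable(self) -> bool:
        return bool(self.networks)


def blocking_clause_fixed_point(
    varmap: VariableMap, y: State, mutation: Optional[Mutation] = None
) -> List[int]:
    """Clause satisfied exactly when y is NOT stationary: some unclamped
    node's table row selected by y must disagree with y."""
    g = varmap.rgraph
    clause = []
    for j in _active_nodes(g, mutation):
        regs = g.potential_regulators(j)
        row = _row_of(regs, {k: y[k] for k in regs})
        clause.append(varmap.table_literal(j, row, 1 - y[j]))
    return clause


def blocking_clause_cycle(
    varmap: VariableMap, states: Sequence[State],
    mutation: Optional[Mutation] = None,
) -> List[int]:
    """Clause breaking at least one transition of the cycle, so that any
    network realizing every transition (in any rotation) is excluded."""
    g = varmap.rgraph
    clause = []
    for t, x in enumerate(states):
        y = states[(t + 1) % len(states)]
        for j in _active_nodes(g, mutation):
            regs = g.potential_regulators(j)
            row = _row_of(regs, {k: x[k] for k in regs})
            clause.append(varmap.table_literal(j, row, 1 - y[j]))
    return clause


def solution_blocking_clause(varmap: VariableMap, model: Dict[int, bool]
                             ) -> List[int]:
    """Negation of the candidate's full table-variable assignment."""
    return [
        -v if model[v] else v
        for v in sorted(varmap.table_vars.values())
    ]


def _witness_matching(patterns, fps: Set[State], injective: bool):
    """Check every pattern has a stationary witness; with ``injective``,
    distinct patterns need distinct witnesses (maximum bipartite
    matching).  Returns the list of unmatched patterns."""
    if not patterns:
        return [], True
    missing = []
    compat = {}
    for idx, pc in enumerate(patterns):
        wit = [x for x in fps if pc.resolved_pattern().matches(x)]
        if not wit:
            missing.append(pc)
        compat[idx] = wit
    if missing or not injective:
        return missing, not missing
    g = nx.Graph()
    left = [("p", i) for i in compat]
    g.add_nodes_from(left, bipartite=0)
    for i, wit in compat.items():
        for x in wit:
            g.add_edge(("p", i), ("s", x))
    match = nx.bipartite.maximum_matching(g, top_nodes=left)
    matched = sum(1 for k in match if k[0] == "p")
    return [], matched == len(patterns)


def verify_candidate(
    f: BooleanNetwork,
    spec: ConstraintSpec,
    explicit_limit: int = 24,
) -> Tuple[bool, List[Violation]]:
    """Runtime verification of the attractor-level constraints.

    Computes the attractors of f and of every referenced mutant, then
    checks: each required pattern is witnessed by a stationary state of
    its context (injectively when flagged); no stationary state matches a
    prohibition; under the exact-set flag every wild-type stationary state
    matches some required wild-type pattern (likewise per mutant context
    that carries required patterns); under the no-cycles flag the
    wild-type has no cyclic attractor.
    """
    contexts: List[Optional[Mutation]] = [None] + list(spec.mutations())
    attrs: Dict[Optional[Mutation], Set[Attractor]] = {}
    fps: Dict[Optional[Mutation], Set[State]] = {}
    for m in contexts:
        fm = f if m is None else mutate(f, m)
        a = attractors(fm, explicit_limit)
        attrs[m] = a
        fps[m] = {w.states[0] for w in a if w.is_fixed_point}

    violations: List[Violation] = []

    for m in contexts:
        req = [pc for pc in spec.required_fixed_points if pc.mutation == m]
        missing, ok = _witness_matching(req, fps[m], spec.injective_matching)
        for pc in missing:
            violations.append(Violation("missing_required", (), m))
        if not missing and not ok:
            violations.append(Violation("non_injective", (), m))

    for pc in spec.prohibited_fixed_points:
        m = pc.mutation
        if m not in fps:
            fm = mutate(f, m)
            a = attractors(fm, explicit_limit)
            attrs[m] = a
            fps[m] = {w.states[0] for w in a if w.is_fixed_point}
        pat = pc.resolved_pattern()
        for x in fps[m]:
            if pat.matches(x):
                violations.append(
                    Violation("prohibited_fixed_point", (x,), m)
                )

    if spec.exact_fixed_point_set:
        for m in contexts:
            req = [pc for pc in spec.required_fixed_points if pc.mutation == m]
            if m is not None and not req:
                continue  # exactness only binds contexts with requirements
            for x in fps[m]:
                if not any(pc.resolved_pattern().matches(x) for pc in req):
                    violations.append(
                        Violation("extra_fixed_point", (x,), m)
                    )

    if spec.forbid_cyclic_attractors:
        for w in attrs[None]:
            if not w.is_fixed_point:
                violations.append(Violation("cyclic_attractor", w.states))

    for x, y in spec.required_transitions:
        from .core import successor

        if successor(f, x) != y:
            violations.append(Violation("missing_required", (x, y)))

    return (not violations), violations


def _learned_clauses(varmap: VariableMap, violations: Sequence[Violation],
                     model: Dict[int, bool]) -> List[List[int]]:
    clauses = []
    needs_solution_block = False
    for v in violations:
        if v.kind in ("extra_fixed_point", "prohibited_fixed_point"):
            clauses.append(
                blocking_clause_fixed_point(varmap, v.states[0], v.mutation)
            )
        elif v.kind == "cyclic_attractor":
            clauses.append(
                blocking_clause_cycle(varmap, v.states, v.mutation)
            )
        else:
            needs_solution_block = True
    if needs_solution_block or not clauses:
        clauses.append(solution_blocking_clause(varmap, model))
    return clauses


def solve(problem: Problem,
          max_solutions: Optional[int] = None) -> SolveResult:
    """Enumerate networks satisfying the problem (Fig-style loop).

    Stops at ``max_solutions`` (problem option used when the argument is
    None; None throughout means all), at unsatisfiability (status
    ``complete``), or at the iteration budget (status ``incomplete``).
    Every emitted network is re-checked against the generalized graph by
    the independent regulation oracle before emission.
    """
    opts = problem.options
    if max_solutions is None:
        max_solutions = opts.max_solutions
    spec = problem.constraints
    formula = encode_regulations(problem.rgraph)
    encode_constraints(formula, spec, opts.static_prohibition_limit)
    solver = Solver(seed=opts.seed if opts.seed else None)
    for cl in formula.clauses:
        solver.add_clause(cl)
    varmap = formula.varmap
    solver.num_vars = max(solver.num_vars, varmap.num_vars)
    networks: List[BooleanNetwork] = []
    log: List[dict] = []
    blocked_fps: Set[Tuple[Optional[Mutation], State]] = set()
    blocked_cycles: Set[Tuple[Optional[Mutation], frozenset]] = set()
    iteration = 0
    status = "complete"
    while True:
        if opts.max_iterations is not None and iteration >= opts.max_iterations:
            status = "incomplete"
            break
        model = solver.solve()
        if model is None:
            break
        iteration += 1
        f = decode_model(model, varmap)
        if not satisfies(f, problem.rgraph):  # encoding soundness guard
            raise RuntimeError(
                "decoded candidate violates the regulation graph; "
                "encoding and semantics disagree"
            )
        accepted, violations = verify_candidate(
            f, spec, opts.explicit_limit
        )
        log.append({
            "iteration": iteration,
            "verdict": "accepted" if accepted else "rejected",
            "violations": [str(v) for v in violations],
        })
        if accepted:
            networks.append(f)
            solver.add_clause(solution_blocking_clause(varmap, model))
            if max_solutions is not None and len(networks) >= max_solutions:
                status = "complete" if solver.solve() is None else "incomplete"
                break
            continue
        use = violations if opts.learn_all_violations else violations[:1]
        # learned-clause bookkeeping: a blocked attractor must never recur
        for v in use:
            if v.kind in ("extra_fixed_point", "prohibited_fixed_point"):
                key = (v.mutation, v.states[0])
                if key in blocked_fps:
                    raise RuntimeError(
                        f"blocked fixed point recurred: {v}"
                    )
                blocked_fps.add(key)
            elif v.kind == "cyclic_attractor":
                ckey = (v.mutation, frozenset(
                    (v.states[t], v.states[(t + 1) % len(v.states)])
                    for t in range(len(v.states))
                ))
                if ckey in blocked_cycles:
                    raise RuntimeError(f"blocked cycle recurred: {v}")
                blocked_cycles.add(ckey)
        for cl in _learned_clauses(varmap, use, model):
            solver.add_clause(cl)
    return SolveResult(networks, status, iteration, log)


def run_log_to_tsv(log: Sequence[dict]) -> str:
    """Per-iteration trace: candidate index, verdict, violation summary."""
    lines = ["iteration\tverdict\tn_violations\tviolations"]
    for rec in log:
        lines.append(
            f"{rec['iteration']}\t{rec['verdict']}\t"
            f"{len(rec['violations'])}\t{';'.join(rec['violations'])}"
        )
    return "\n".join(lines) + "\n"
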