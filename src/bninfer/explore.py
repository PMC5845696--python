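"""Query splitting and attractor-set exploration.

Radial splitting decomposes a generalized-graph query into ordinary
regulation-graph queries: a *center* fixes a sign for every mandatory
edge, and at radius r every way of adding r of the optional edges (each
with one of its present signs) is a member query.  The union of member
solution sets equals the whole-query solution set, and bounding the
radius bounds the number of simultaneous hypotheses entertained at once.

The attractor-set explorer samples networks whose stationary-state sets
(FPASs) are pairwise distinct, by blocking each recorded FPAS as a
clause; the cosine-similarity diagnostics quantify how diverse the
sampled stationary behaviors are.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterator, List, Optional, Sequence, Tuple

import numpy as np

from .core import (
    BooleanNetwork,
    Problem,
    RGraph,
    RLabel,
    State,
    format_state,
)
from .dynamics import attractors
from .encoding import encode_constraints, encode_regulations
from .engine import (
    SolveResult,
    _learned_clauses,
    solution_blocking_clause,
    solve,
    verify_candidate,
)
from .regulation import satisfies
from .sat import Solver

__all__ = [
    "SplitMember",
    "radial_split",
    "split_members",
    "solve_split",
    "SplitAccounting",
    "fpas_explore",
    "FPASResult",
    "similarity_matrix",
    "accounting_to_tsv",
]


@dataclass(frozen=True)
class SplitMember:
    """One member query of a radial splitting."""

    problem: Problem
    center: tuple  # per-mandatory-edge (u, v, (R+, R-))
    radius: int
    added: tuple  # per-added-optional-edge (u, v, (R+, R-))


def _exact_edges(choices) -> Tuple:
    return tuple(
        (u, RLabel.from_sign_pair(rp, rm), v) for u, v, (rp, rm) in choices
    )


def split_members(problem: Problem, r_min: int = 0,
                  r_max: Optional[int] = None) -> Iterator[SplitMember]:
    """Yield member problems of the radial splitting, radii ascending.

    Every member is an ordinary (exact-label) regulation-graph query
    carrying the original constraints; over all centers and radii the
    members generate exactly the candidate instantiations of the
    generalized graph, without duplicates.
    """
    g = problem.rgraph
    if any(not lab.sat_pairs for _u, lab, _v in g.edges):
        return  # a contradictory edge admits nothing
    mandatory = g.mandatory_edges()
    optional = g.optional_edges()
    h = len(optional)
    if r_max is None:
        r_max = h
    if not 0 <= r_min <= r_max <= h:
        raise ValueError(f"invalid radius bounds [{r_min}, {r_max}] for h={h}")
    center_choices = [
        [(u, v, p) for p in sorted(lab.sat_pairs)] for u, lab, v in mandatory
    ]
    opt_present = {
        (u, v): sorted(lab.present_pairs) for u, lab, v in optional
    }
    opt_keys = [(u, v) for u, _lab, v in optional]
    for center in itertools.product(*center_choices):
        for r in range(r_min, r_max + 1):
            for subset in itertools.combinations(opt_keys, r):
                for signs in itertools.product(
                    *(opt_present[k] for k in subset)
                ):
                    added = tuple(
                        (u, v, p) for (u, v), p in zip(subset, signs)
                    )
                    member_graph = RGraph(
                        g.variables, _exact_edges(center + added)
                    )
                    yield SplitMember(
                        Problem(member_graph, problem.constraints,
                                problem.options),
                        center, r, added,
                    )


def radial_split(problem: Problem, r_min: int = 0,
                 r_max: Optional[int] = None) -> Iterator[Problem]:
    """The member problems only (see :func:`split_members`)."""
    for m in split_members(problem, r_min, r_max):
        yield m.problem


@dataclass
class SplitAccounting:
    """Per-radius accounting of a radial run (Table-style columns)."""

    radius: int
    members: int = 0
    satisfying_members: int = 0
    networks: int = 0
    cumulative_members: int = 0
    cumulative_satisfying_members: int = 0
    cumulative_networks: int = 0


def solve_split(problem: Problem, r_min: int = 0,
                r_max: Optional[int] = None,
                budget: Optional[int] = None) -> Tuple[
                    List[BooleanNetwork], List[SplitAccounting], str]:
    """Solve every member and aggregate solutions and per-radius counts.

    ``budget`` caps the number of member queries examined; exhaustion
    flags the accounting as partial (status "incomplete").  The aggregated
    solution set equals the whole-query solution set up to functional
    reduction of the tables.
    """
    rows: Dict[int, SplitAccounting] = {}
    networks: List[BooleanNetwork] = []
    examined = 0
    status = "complete"
    for member in split_members(problem, r_min, r_max):
        if budget is not None and examined >= budget:
            status = "incomplete"
            break
        examined += 1
        row = rows.setdefault(member.radius, SplitAccounting(member.radius))
        row.members += 1
        res = solve(member.problem)
        if res.status != "complete":
            status = "incomplete"
        if res.networks:
            row.satisfying_members += 1
            row.networks += len(res.networks)
            networks.extend(res.networks)
    cm = cs = cn = 0
    out = []
    for r in sorted(rows):
        row = rows[r]
        cm += row.members
        cs += row.satisfying_members
        cn += row.networks
        row.cumulative_members = cm
        row.cumulative_satisfying_members = cs
        row.cumulative_networks = cn
        out.append(row)
    return networks, out, status


def accounting_to_tsv(rows: Sequence[SplitAccounting]) -> str:
    lines = [
        "radius\tmembers\tcumulative_members\t"
        "cumulative_satisfying_members\tcumulative_networks"
    ]
    for r in rows:
        lines.append(
            f"{r.radius}\t{r.members}\t{r.cumulative_members}\t"
            f"{r.cumulative_satisfying_members}\t{r.cumulative_networks}"
        )
    return "\n".join(lines) + "\n"


@dataclass
class FPASResult:
    witnesses: List[Tuple[BooleanNetwork, FrozenSet[State]]]
    status: str  # complete | incomplete | terminal_empty_fpas


def fpas_explore(problem: Problem,
                 budget: Optional[int] = None) -> FPASResult:
    """Sample networks with pairwise-distinct stationary-state sets.

    After each accepted witness the negation of its FPAS is added as a
    clause (at least one member state must not be stationary), so no
    later witness repeats it.  The sampling is deliberately incomplete:
    the clause also blocks every superset of a recorded FPAS.  An
    accepted witness with no stationary state would yield the empty
    clause; it is recorded and treated as terminal.
    """
    opts = problem.options
    spec = problem.constraints
    formula = encode_regulations(problem.rgraph)
    encode_constraints(formula, spec, opts.static_prohibition_limit)
    solver = Solver(seed=opts.seed if opts.seed else None)
    for cl in formula.clauses:
        solver.add_clause(cl)
    varmap = formula.varmap
    solver.num_vars = max(solver.num_vars, varmap.num_vars)
    witnesses: List[Tuple[BooleanNetwork, FrozenSet[State]]] = []
    status = "complete"
    iterations = 0
    from .encoding import decode_model
    from .engine import blocking_clause_fixed_point

    while True:
        if budget is not None and iterations >= budget:
            status = "incomplete"
            break
        iterations += 1
        model = solver.solve()
        if model is None:
            break
        f = decode_model(model, varmap)
        if not satisfies(f, problem.rgraph):
            raise RuntimeError("decoded candidate violates regulation graph")
        accepted, violations = verify_candidate(f, spec, opts.explicit_limit)
        if not accepted:
            for cl in _learned_clauses(varmap, violations, model):
                solver.add_clause(cl)
            continue
        fpas = frozenset(
            w.states[0]
            for w in attractors(f, opts.explicit_limit)
            if w.is_fixed_point
        )
        witnesses.append((f, fpas))
        if not fpas:
            status = "terminal_empty_fpas"
            break
        clause: List[int] = []
        for y in fpas:
            clause.extend(blocking_clause_fixed_point(varmap, y))
        solver.add_clause(clause)
    return FPASResult(witnesses, status)


def similarity_matrix(fpas_list: Sequence[FrozenSet[State]],
                      bins: int = 30):
    """Pairwise cosine similarity of FPAS incidence vectors.

    The universe is the union of all stationary states across the list,
    ordered lexicographically on their state strings.  Returns the
    symmetric unit-diagonal matrix, a (counts, edges) histogram of its
    entries over ``bins`` equal bins on [0, 1], and the fraction of zero
    entries.  An empty FPAS has similarity 0 against everything and 1
    with itself.
    """
    if not fpas_list:
        raise ValueError("need at least one stationary-state set")
    universe = sorted(
        {s for fp in fpas_list for s in fp}, key=format_state
    )
    index = {s: k for k, s in enumerate(universe)}
    m = len(fpas_list)
    inc = np.zeros((m, max(1, len(universe))))
    for i, fp in enumerate(fpas_list):
        for s in fp:
            inc[i, index[s]] = 1.0
    norms = np.linalg.norm(inc, axis=1)
    safe = np.where(norms == 0.0, 1.0, norms)
    sim = (inc @ inc.T) / np.outer(safe, safe)
    np.fill_diagonal(sim, 1.0)
    counts, edges = np.histogram(sim, bins=bins, range=(0.0, 1.0))
    zero_fraction = float(np.mean(sim == 0.0))
    return sim, (counts, edges), zero_fraction
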