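"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the code paths they check: attractors
come from Tarjan SCCs on an explicitly built digraph, regulation signs
from full state-space scans, and solution sets from exhaustive
enumeration of every candidate truth-table assignment.
"""

from __future__ import annotations

import itertools
import random
from typing import Iterable, Iterator, List, Optional, Set, Tuple

import networkx as nx
import pytest

from bninfer.core import (
    Attractor,
    BooleanNetwork,
    ConstraintSpec,
    Problem,
    RGraph,
    RLabel,
    State,
    mutate,
    successor,
)
from bninfer.regulation import (
    negative_regulation_oracle,
    positive_regulation_oracle,
    satisfies,
)


# ---------------------------------------------------------------- builders

def swap_network() -> BooleanNetwork:
    """f(x1, x2) = (x2, x1)."""
    return BooleanNetwork(("v1", "v2"), ((1,), (0,)), ((0, 1), (0, 1)))


def identity_network(n: int) -> BooleanNetwork:
    return BooleanNetwork(
        tuple(f"v{i + 1}" for i in range(n)),
        tuple((j,) for j in range(n)),
        tuple(((0, 1),) * n),
    )


def constant_network(values: Tuple[int, ...]) -> BooleanNetwork:
    n = len(values)
    return BooleanNetwork(
        tuple(f"v{i + 1}" for i in range(n)),
        tuple(() for _ in range(n)),
        tuple((v,) for v in values),
    )


def negation_network() -> BooleanNetwork:
    return BooleanNetwork(("v1",), ((0,),), ((1, 0),))


def xor_pair() -> BooleanNetwork:
    """Both nodes compute x1 XOR x2."""
    return BooleanNetwork(
        ("v1", "v2"), ((0, 1), (0, 1)), ((0, 1, 1, 0), (0, 1, 1, 0))
    )


def random_network(n: int, rng: random.Random,
                   max_degree: Optional[int] = None) -> BooleanNetwork:
    regs, tabs = [], []
    for _ in range(n):
        d = rng.randint(0, max_degree if max_degree is not None else n)
        r = tuple(sorted(rng.sample(range(n), d)))
        regs.append(r)
        tabs.append(tuple(rng.randrange(2) for _ in range(1 << d)))
    return BooleanNetwork(
        tuple(f"v{i + 1}" for i in range(n)), tuple(regs), tuple(tabs)
    )


@pytest.fixture
def swap() -> BooleanNetwork:
    return swap_network()


# ---------------------------------------------------------------- oracles

def oracle_attractors(f: BooleanNetwork) -> Set[Attractor]:
    """Terminal SCCs of the state graph via networkx Tarjan condensation."""
    g = nx.DiGraph()
    for x in itertools.product((0, 1), repeat=f.n):
        g.add_edge(x, successor(f, x))
    cond = nx.condensation(g)
    out = set()
    for node in cond.nodes:
        if cond.out_degree(node) == 0:
            members = list(cond.nodes[node]["members"])
            # order along the successor cycle
            cycle = [min(members)]
            while len(cycle) < len(members):
                cycle.append(successor(f, cycle[-1]))
            out.add(Attractor.canonical(cycle))
    return out


def oracle_fixed_points(f: BooleanNetwork) -> Set[State]:
    return {
        x for x in itertools.product((0, 1), repeat=f.n)
        if successor(f, x) == x
    }


def all_networks(g: RGraph) -> Iterator[BooleanNetwork]:
    """Every truth-table assignment over the graph's potential regulators."""
    regs = [g.potential_regulators(j) for j in range(g.n)]
    spaces = [
        list(itertools.product((0, 1), repeat=1 << len(r))) for r in regs
    ]
    for tabs in itertools.product(*spaces):
        yield BooleanNetwork(g.variables, tuple(regs), tuple(tabs))


def oracle_satisfies(f: BooleanNetwork, g: RGraph) -> bool:
    """Full-state-space evaluation of every edge label (no table tricks)."""
    labeled = {(u, v): lab for u, lab, v in g.edges}
    for u in range(g.n):
        for v in range(g.n):
            pair = (
                positive_regulation_oracle(f, u + 1, v + 1),
                negative_regulation_oracle(f, u + 1, v + 1),
            )
            lab = labeled.get((u, v), RLabel.NR)
            if pair not in lab.sat_pairs:
                return False
    return True


def oracle_spec_holds(f: BooleanNetwork, spec: ConstraintSpec) -> bool:
    """Explicit evaluation of every dynamic constraint."""
    contexts = [None] + list(spec.mutations())
    fps = {
        m: oracle_fixed_points(f if m is None else mutate(f, m))
        for m in contexts
    }
    for m in contexts:
        req = [pc for pc in spec.required_fixed_points if pc.mutation == m]
        wits = [
            [x for x in fps[m] if pc.resolved_pattern().matches(x)]
            for pc in req
        ]
        if any(not w for w in wits):
            return False
        if spec.injective_matching and req:
            ok = any(
                len(set(choice)) == len(req)
                for choice in itertools.product(*wits)
            )
            if not ok:
                return False
    for pc in spec.prohibited_fixed_points:
        pat = pc.resolved_pattern()
        if any(pat.matches(x) for x in fps[pc.mutation]):
            return False
    if spec.exact_fixed_point_set:
        for m in contexts:
            req = [pc for pc in spec.required_fixed_points if pc.mutation == m]
            if m is not None and not req:
                continue
            for x in fps[m]:
                if not any(pc.resolved_pattern().matches(x) for pc in req):
                    return False
    if spec.forbid_cyclic_attractors:
        if any(not a.is_fixed_point for a in oracle_attractors(f)):
            return False
    for x, y in spec.required_transitions:
        if successor(f, x) != y:
            return False
    return True


def brute_force_solutions(problem: Problem) -> Set[Tuple]:
    """Exhaustive solution set, keyed by (regulators, tables)."""
    out = set()
    for f in all_networks(problem.rgraph):
        if oracle_satisfies(f, problem.rgraph) and oracle_spec_holds(
            f, problem.constraints
        ):
            out.add((f.regulators, f.tables))
    return out


def network_key(f: BooleanNetwork) -> Tuple:
    return (f.regulators, f.tables)
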