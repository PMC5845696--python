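"""Functional regulation semantics.

A regulation i -> j is *positive* when some molecular context exists in
which switching variable i on switches f_j on (equivalently, there is a
state x with f_j(x) != f_j(x with i flipped) and x_i = f_j(x)); it is
*negative* when switching i on switches f_j off.  Both may hold at once
(an ambiguous regulation), and neither holds when f_j never responds to
variable i.  These two bits per ordered pair connect network structure
(regulation graphs, generalized or not) with network dynamics.
"""

from __future__ import annotations

import itertools
from typing import Iterable

from .core import (
    BooleanNetwork,
    RegulationGraph,
    RGraph,
    RLabel,
    flip,
    successor,
)

__all__ = [
    "positive_regulation",
    "negative_regulation",
    "positive_regulation_oracle",
    "negative_regulation_oracle",
    "sign_pair",
    "regulation_graph_of",
    "lift",
    "satisfies",
    "instantiations",
    "count_instantiations",
]


def positive_regulation_oracle(f: BooleanNetwork, i: int, j: int) -> int:
    """Full-state-space evaluation of positive regulation (1-based i, j)."""
    for x in itertools.product((0, 1), repeat=f.n):
        fx = f.component(j - 1, x)
        if fx != f.component(j - 1, flip(x, i)) and x[i - 1] == fx:
            return 1
    return 0


def negative_regulation_oracle(f: BooleanNetwork, i: int, j: int) -> int:
    for x in itertools.product((0, 1), repeat=f.n):
        fx = f.component(j - 1, x)
        if fx != f.component(j - 1, flip(x, i)) and x[i - 1] != fx:
            return 1
    return 0


def _table_pairs(f: BooleanNetwork, i0: int, j0: int):
    """Yield (f_j with i=0, f_j with i=1) over contexts of j's other regs."""
    regs = f.regulators[j0]
    k = regs.index(i0)
    d = len(regs)
    tab = f.tables[j0]
    for ctx in itertools.product((0, 1), repeat=d - 1):
        bits = list(ctx[:k]) + [0] + list(ctx[k:])
        r0 = 0
        for b in bits:
            r0 = (r0 << 1) | b
        r1 = r0 | (1 << (d - 1 - k))
        yield tab[r0], tab[r1]


def positive_regulation(f: BooleanNetwork, i: int, j: int) -> int:
    """1 iff i -> j is a positive functional regulation (1-based indices).

    Scans only the 2^(d_j - 1) truth-table row pairs of node j that differ
    in regulator i; returns 0 immediately when i is not a declared
    regulator of j (a non-regulator can never flip the output).
    """
    if i - 1 not in f.regulators[j - 1]:
        return 0
    for a, b in _table_pairs(f, i - 1, j - 1):
        if (a, b) == (0, 1):
            return 1
    return 0


def negative_regulation(f: BooleanNetwork, i: int, j: int) -> int:
    """1 iff i -> j is a negative functional regulation (1-based indices)."""
    if i - 1 not in f.regulators[j - 1]:
        return 0
    for a, b in _table_pairs(f, i - 1, j - 1):
        if (a, b) == (1, 0):
            return 1
    return 0


def sign_pair(f: BooleanNetwork, i: int, j: int) -> tuple:
    """(R+, R-) for the ordered pair i -> j (1-based)."""
    return (positive_regulation(f, i, j), negative_regulation(f, i, j))


def regulation_graph_of(f: BooleanNetwork) -> RegulationGraph:
    """The regulation graph induced by f: exactly the functional edges."""
    iplus, iminus = set(), set()
    for j in range(1, f.n + 1):
        for i0 in f.regulators[j - 1]:
            i = i0 + 1
            rp, rm = sign_pair(f, i, j)
            if rp:
                iplus.add((i - 1, j - 1))
            if rm:
                iminus.add((i - 1, j - 1))
    return RegulationGraph(f.variables, frozenset(iplus), frozenset(iminus))


def lift(g: RegulationGraph) -> RGraph:
    """Exact-label view of an ordinary regulation graph (MPU/MNU/MA edges)."""
    edges = []
    for (u, v) in sorted(g.iplus | g.iminus):
        edges.append((u, RLabel.from_sign_pair(*g.sign_pair(u, v)), v))
    return RGraph(g.variables, tuple(edges))


def satisfies(f: BooleanNetwork, g: RGraph) -> bool:
    """Whether f's regulation signs are admitted by every edge label of g.

    Absent ordered pairs carry the implicit NR label; a pair is only
    checked against NR when f could regulate it at all, i.e. when the
    source is a declared regulator of the target.
    """
    if f.variables != g.variables:
        raise ValueError("network and graph variables differ")
    labeled = {(u, v): lab for u, lab, v in g.edges}
    for (u, v), lab in labeled.items():
        if not lab.admits(*sign_pair(f, u + 1, v + 1)):
            return False
    # implicit-NR pairs: only declared regulators can violate them
    for j0 in range(f.n):
        for i0 in f.regulators[j0]:
            if (i0, j0) not in labeled:
                if sign_pair(f, i0 + 1, j0 + 1) != (0, 0):
                    return False
    return True


def instantiations(g: RGraph, check_realizability: bool = False):
    """All ordinary regulation graphs consistent with the R-graph.

    Candidates are the Cartesian product of per-edge admitted sign pairs
    (count = prod |sat_pairs|).  With ``check_realizability`` only
    candidates admitting at least one satisfying network are kept, decided
    by the inference engine with empty constraints (this realizes the
    stricter existential reading of an instantiation but is expensive, so
    it is off by default).
    """
    pairs = [e[1].sat_pairs for e in g.edges]
    if any(not p for p in pairs):
        return []
    out = []
    for choice in itertools.product(*(sorted(p) for p in pairs)):
        iplus, iminus = set(), set()
        for (u, _lab, v), (rp, rm) in zip(g.edges, choice):
            if rp:
                iplus.add((u, v))
            if rm:
                iminus.add((u, v))
        cand = RegulationGraph(g.variables, frozenset(iplus), frozenset(iminus))
        out.append(cand)
    if check_realizability:
        from .engine import solve
        from .core import Problem, SolverOptions

        kept = []
        for cand in out:
            prob = Problem(lift(cand), options=SolverOptions(max_solutions=1))
            res = solve(prob)
            if res.networks:
                kept.append(cand)
        out = kept
    return out


def functional_reduction(f: BooleanNetwork) -> BooleanNetwork:
    """Drop non-functional regulators and project the tables accordingly.

    Two table representations of the same global map f: B^n -> B^n (they
    can differ when a declared regulator never affects the output) reduce
    to the identical network, so reduced networks compare as functions.
    """
    regulators = []
    tables = []
    for j0 in range(f.n):
        regs = f.regulators[j0]
        keep = [
            k for k in regs
            if sign_pair(f, k + 1, j0 + 1) != (0, 0)
        ]
        d = len(keep)
        tab = []
        for row in range(1 << d):
            bits = {k: (row >> (d - 1 - t)) & 1 for t, k in enumerate(keep)}
            full = 0
            for k in regs:
                full = (full << 1) | bits.get(k, 0)
            tab.append(f.tables[j0][full])
        regulators.append(tuple(keep))
        tables.append(tuple(tab))
    return BooleanNetwork(f.variables, tuple(regulators), tuple(tables))


def count_instantiations(g: RGraph) -> int:
    """Candidate instantiation count: product of per-edge sat-pair counts."""
    total = 1
    for _u, lab, _v in g.edges:
        total *= len(lab.sat_pairs)
    return total
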