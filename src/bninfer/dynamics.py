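"""State-graph dynamics: attractors, fixed points, basins of attraction.

The state graph of a synchronous network is functional (one out-edge per
state), so its attractors -- the terminal strongly connected components --
are exactly the cycles reached by successor-following, and every state
belongs to the basin of exactly one attractor.
"""

from __future__ import annotations

import itertools
from typing import Dict, FrozenSet, Iterable, List, Optional, Set, Tuple

import networkx as nx

from .core import Attractor, BooleanNetwork, State, format_state, successor

__all__ = [
    "state_graph",
    "attractors",
    "fixed_points",
    "basin",
    "basins",
    "attractors_to_tsv",
]

DEFAULT_EXPLICIT_LIMIT = 24


def _check_limit(f: BooleanNetwork, explicit_limit: int) -> None:
    if f.n > explicit_limit:
        raise ValueError(
            f"explicit state-space traversal disabled for n={f.n} > "
            f"{explicit_limit}; raise explicit_limit to override"
        )


def _state_to_int(x: State) -> int:
    r = 0
    for b in x:
        r = (r << 1) | b
    return r


def _int_to_state(v: int, n: int) -> State:
    return tuple((v >> (n - 1 - k)) & 1 for k in range(n))


def _successor_ints(f: BooleanNetwork) -> List[int]:
    """Successor of every state, indexed by the state read as a binary int."""
    n = f.n
    succ = [0] * (1 << n)
    for v in range(1 << n):
        x = _int_to_state(v, n)
        succ[v] = _state_to_int(successor(f, x))
    return succ


def state_graph(f: BooleanNetwork,
                explicit_limit: int = DEFAULT_EXPLICIT_LIMIT) -> nx.DiGraph:
    """The full state graph as a networkx digraph over state tuples."""
    _check_limit(f, explicit_limit)
    g = nx.DiGraph()
    n = f.n
    succ = _successor_ints(f)
    for v in range(1 << n):
        g.add_edge(_int_to_state(v, n), _int_to_state(succ[v], n))
    return g


def attractors(f: BooleanNetwork,
               explicit_limit: int = DEFAULT_EXPLICIT_LIMIT) -> Set[Attractor]:
    """All attractors of f, each in canonical rotation.

    Successor-following with trajectory coloring: each state carries the id
    of the walk that first visited it, so every state is traversed O(1)
    times.  A walk closing on itself exposes a new cycle; a walk hitting an
    earlier color drains into a known attractor.
    """
    _check_limit(f, explicit_limit)
    n = f.n
    succ = _successor_ints(f)
    color = [-1] * (1 << n)  # walk id that first visited the state
    found: Set[Attractor] = set()
    for start in range(1 << n):
        if color[start] != -1:
            continue
        walk: List[int] = []
        pos: Dict[int, int] = {}
        v = start
        while color[v] == -1 and v not in pos:
            pos[v] = len(walk)
            walk.append(v)
            color[v] = start
            v = succ[v]
        if color[v] == start and v in pos:
            cyc = walk[pos[v]:]
            found.add(
                Attractor.canonical([_int_to_state(u, n) for u in cyc])
            )
    return found


def _fixed_points_scan(f: BooleanNetwork) -> Set[State]:
    out = set()
    for x in itertools.product((0, 1), repeat=f.n):
        if successor(f, x) == x:
            out.add(x)
    return out


def _fixed_points_symbolic(f: BooleanNetwork) -> Set[State]:
    """Fixed points by per-node constraint intersection, without scanning.

    A state x is stationary iff for every node j the truth-table row
    selected by x outputs x_j.  Encoding one clause per table row over n
    state variables and enumerating models avoids touching all 2^n states
    when the stationary set is sparse.
    """
    from .sat import Solver

    s = Solver()
    n = f.n
    # state variable i is solver variable i+1
    for j in range(n):
        regs = f.regulators[j]
        d = len(regs)
        for row in range(1 << d):
            bits = [(row >> (d - 1 - k)) & 1 for k in range(d)]
            ante = [-(r + 1) if b else (r + 1) for r, b in zip(regs, bits)]
            out = f.tables[j][row]
            lit = (j + 1) if out else -(j + 1)
            s.add_clause(ante + [lit])
    out_states: Set[State] = set()
    while True:
        model = s.solve()
        if model is None:
            return out_states
        x = tuple(int(model[i + 1]) for i in range(n))
        out_states.add(x)
        s.add_clause([-(i + 1) if x[i] else (i + 1) for i in range(n)])


def fixed_points(f: BooleanNetwork, method: str = "auto") -> Set[State]:
    """The stationary states of f.

    ``method``: "scan" enumerates {0,1}^n; "symbolic" intersects per-node
    stationarity constraints via the CNF solver; "auto" scans for small n
    and goes symbolic beyond 16 variables.
    """
    if method == "auto":
        method = "scan" if f.n <= 16 else "symbolic"
    if method == "scan":
        return _fixed_points_scan(f)
    if method == "symbolic":
        return _fixed_points_symbolic(f)
    raise ValueError(f"unknown fixed-point method {method!r}")


def basin(f: BooleanNetwork, omega: Attractor,
          explicit_limit: int = DEFAULT_EXPLICIT_LIMIT) -> Set[State]:
    """The basin of attraction of omega: backward BFS over the state graph."""
    _check_limit(f, explicit_limit)
    if omega not in attractors(f, explicit_limit):
        raise ValueError(f"{omega} is not an attractor of the network")
    return basins(f, explicit_limit)[omega]


def basins(f: BooleanNetwork,
           explicit_limit: int = DEFAULT_EXPLICIT_LIMIT
           ) -> Dict[Attractor, Set[State]]:
    """Basins of every attractor at once (one backward traversal each).

    Basins partition the state space: disjoint, sizes summing to 2^n.
    """
    _check_limit(f, explicit_limit)
    n = f.n
    succ = _successor_ints(f)
    preds: List[List[int]] = [[] for _ in range(1 << n)]
    for v, w in enumerate(succ):
        preds[w].append(v)
    out: Dict[Attractor, Set[State]] = {}
    for omega in attractors(f, explicit_limit):
        seed = [_state_to_int(x) for x in omega.states]
        seen = set(seed)
        frontier = list(seed)
        while frontier:
            nxt = []
            for v in frontier:
                for u in preds[v]:
                    if u not in seen:
                        seen.add(u)
                        nxt.append(u)
            frontier = nxt
        out[omega] = {_int_to_state(v, n) for v in seen}
    return out


def attractors_to_tsv(attrs: Iterable[Attractor]) -> str:
    """One row per attractor: size, comma-joined state strings."""
    lines = ["size\tstates"]
    for a in sorted(attrs, key=lambda a: (a.size, a.states)):
        lines.append(f"{a.size}\t{a}")
    return "\n".join(lines) + "\n"
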