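"""Domain types for synchronous Boolean networks and regulation graphs.

A *state* of an ``n``-variable network is a point of {0,1}^n, held as a
tuple of ints.  User-facing I/O renders states as strings over ``01`` and
subspaces (partially specified states) as strings over ``01*``, with ``*``
marking a free component.  Variables and state components are 1-based in
the public helpers that take an index, 0-based in internal containers.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Optional, Sequence

State = tuple  # tuple of 0/1 ints

__all__ = [
    "State",
    "Subspace",
    "BooleanNetwork",
    "Mutation",
    "RegulationGraph",
    "RLabel",
    "RGraph",
    "Attractor",
    "ConstraintSpec",
    "PatternConstraint",
    "SolverOptions",
    "Problem",
    "parse_state",
    "format_state",
    "flip",
    "substitute",
    "successor",
    "iterate",
    "mutate",
]


def parse_state(text: str) -> State:
    """Parse a string over ``01`` into a state tuple."""
    if not text or any(c not in "01" for c in text):
        raise ValueError(f"not a state string: {text!r}")
    return tuple(int(c) for c in text)


def format_state(x: Sequence[int]) -> str:
    return "".join(str(int(b)) for b in x)


def flip(x: State, i: int) -> State:
    """Complement component ``i`` (1-based) of ``x``."""
    if not 1 <= i <= len(x):
        raise IndexError(f"component {i} out of range for n={len(x)}")
    return x[: i - 1] + (1 - x[i - 1],) + x[i:]


def substitute(x: State, v: Sequence[int], p: Sequence[int]) -> State:
    """Replace the components of ``x`` at 1-based positions ``p`` by ``v``."""
    if len(v) != len(p):
        raise ValueError("value/position length mismatch")
    if len(set(p)) != len(p):
        raise ValueError("repeated positions in substitution")
    y = list(x)
    for val, pos in zip(v, p):
        if not 1 <= pos <= len(x):
            raise IndexError(f"position {pos} out of range for n={len(x)}")
        y[pos - 1] = int(val)
    return tuple(y)


@dataclass(frozen=True)
class Subspace:
    """A subspace of {0,1}^n written as a wildcard pattern over ``01*``."""

    pattern: str

    def __post_init__(self) -> None:
        if not self.pattern or any(c not in "01*" for c in self.pattern):
            raise ValueError(f"not a subspace pattern: {self.pattern!r}")

    @property
    def n(self) -> int:
        return len(self.pattern)

    @property
    def n_free(self) -> int:
        return self.pattern.count("*")

    def matches(self, x: Sequence[int]) -> bool:
        if len(x) != self.n:
            raise ValueError("state/pattern length mismatch")
        return all(c == "*" or int(c) == b for c, b in zip(self.pattern, x))

    def states(self) -> Iterator[State]:
        """Enumerate the 2^(#free) states of the subspace."""
        free = [i for i, c in enumerate(self.pattern) if c == "*"]
        base = [0 if c == "*" else int(c) for c in self.pattern]
        for bits in itertools.product((0, 1), repeat=len(free)):
            y = list(base)
            for pos, b in zip(free, bits):
                y[pos] = b
            yield tuple(y)

    def size(self) -> int:
        return 1 << self.n_free

    def __str__(self) -> str:
        return self.pattern


@dataclass(frozen=True)
class Mutation:
    """Clamp the variables at 1-based ``positions`` to constant ``values``.

    Models genetic loss- and gain-of-function lines: a mutated node's
    update function becomes the constant given by the mutation, all other
    nodes keep their wild-type function.
    """

    positions: tuple
    values: tuple

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.values):
            raise ValueError("mutation position/value length mismatch")
        if len(set(self.positions)) != len(self.positions):
            raise ValueError("duplicate mutation positions")
        if any(v not in (0, 1) for v in self.values):
            raise ValueError("mutation values must be 0/1")

    @property
    def is_empty(self) -> bool:
        return not self.positions

    def as_dict(self) -> dict:
        """0-based position -> clamped value."""
        return {p - 1: v for p, v in zip(self.positions, self.values)}


@dataclass(frozen=True)
class BooleanNetwork:
    """A synchronous Boolean network: per-node regulator lists and tables.

    ``regulators[j]`` is the ordered list of 0-based node indices feeding
    node ``j``; ``tables[j]`` has ``2**d_j`` entries indexed by reading the
    regulator values as a binary number, first regulator most significant.
    The induced global map sends every state to a unique successor.
    """

    variables: tuple
    regulators: tuple  # tuple of tuples of int
    tables: tuple  # tuple of tuples of 0/1

    def __post_init__(self) -> None:
        n = len(self.variables)
        if len(self.regulators) != n or len(self.tables) != n:
            raise ValueError("regulators/tables must cover every node")
        for j, (regs, tab) in enumerate(zip(self.regulators, self.tables)):
            if len(set(regs)) != len(regs):
                raise ValueError(f"duplicate regulator for node {j}")
            if any(not 0 <= r < n for r in regs):
                raise ValueError(f"regulator index out of range for node {j}")
            if len(tab) != 1 << len(regs):
                raise ValueError(
                    f"node {j}: table length {len(tab)} != 2^{len(regs)}"
                )
            if any(b not in (0, 1) for b in tab):
                raise ValueError(f"node {j}: table entries must be 0/1")

    @property
    def n(self) -> int:
        return len(self.variables)

    def row_index(self, j: int, x: Sequence[int]) -> int:
        """Truth-table row of node ``j`` selected by state ``x``."""
        r = 0
        for k in self.regulators[j]:
            r = (r << 1) | x[k]
        return r

    def component(self, j: int, x: Sequence[int]) -> int:
        return self.tables[j][self.row_index(j, x)]


def successor(f: BooleanNetwork, x: State) -> State:
    """The unique synchronous successor of ``x`` under ``f``."""
    if len(x) != f.n:
        raise ValueError("state length does not match network")
    return tuple(f.tables[j][f.row_index(j, x)] for j in range(f.n))


def iterate(f: BooleanNetwork, x: State, k: int) -> State:
    """Apply ``f`` to ``x`` ``k`` times (k >= 1)."""
    if k < 1:
        raise ValueError("iteration count must be >= 1")
    for _ in range(k):
        x = successor(f, x)
    return x


def mutate(f: BooleanNetwork, m: Mutation) -> BooleanNetwork:
    """The mutant network: clamped nodes become constants, others unchanged."""
    clamp = m.as_dict()
    regs = list(f.regulators)
    tabs = list(f.tables)
    for j, v in clamp.items():
        if not 0 <= j < f.n:
            raise IndexError(f"mutation position {j + 1} out of range")
        regs[j] = ()
        tabs[j] = (v,)
    return BooleanNetwork(f.variables, tuple(regs), tuple(tabs))


@dataclass(frozen=True)
class RegulationGraph:
    """Ordinary regulation graph: signed edge sets I+ and I- (0-based pairs).

    A pair present in both sets is an ambiguous regulation.
    """

    variables: tuple
    iplus: frozenset
    iminus: frozenset

    def __post_init__(self) -> None:
        n = len(self.variables)
        for u, v in self.iplus | self.iminus:
            if not (0 <= u < n and 0 <= v < n):
                raise ValueError(f"edge ({u},{v}) references unknown variable")

    def sign_pair(self, u: int, v: int) -> tuple:
        return (int((u, v) in self.iplus), int((u, v) in self.iminus))


class RLabel(Enum):
    """The 16 generalized regulation labels.

    Each label is a Boolean function h(R+, R-) of the positive/negative
    functional-regulation bits of an ordered variable pair; ``sat_pairs``
    is the set of (R+, R-) values the label admits.  A label is *optional*
    if it admits (0,0) (the regulation may be absent), *mandatory* if it is
    satisfiable but excludes (0,0).
    """

    MPU = frozenset({(1, 0)})
    MNU = frozenset({(0, 1)})
    MA = frozenset({(1, 1)})
    NR = frozenset({(0, 0)})
    MPPA = frozenset({(1, 0), (1, 1)})
    MNPA = frozenset({(0, 1), (1, 1)})
    MUSU = frozenset({(1, 0), (0, 1)})
    MUSPA = frozenset({(1, 0), (0, 1), (1, 1)})
    OPU = frozenset({(0, 0), (1, 0)})
    ONU = frozenset({(0, 0), (0, 1)})
    OA = frozenset({(0, 0), (1, 1)})
    OPPA = frozenset({(0, 0), (1, 0), (1, 1)})
    ONPA = frozenset({(0, 0), (0, 1), (1, 1)})
    OUSU = frozenset({(0, 0), (1, 0), (0, 1)})
    FALSE = frozenset()
    TRUE = frozenset({(0, 0), (0, 1), (1, 0), (1, 1)})

    @property
    def sat_pairs(self) -> frozenset:
        return self.value

    @property
    def is_optional(self) -> bool:
        return (0, 0) in self.value

    @property
    def is_mandatory(self) -> bool:
        return bool(self.value) and (0, 0) not in self.value

    def admits(self, rp: int, rm: int) -> bool:
        return (rp, rm) in self.value

    @property
    def present_pairs(self) -> frozenset:
        """The admitted sign pairs with the regulation present."""
        return frozenset(p for p in self.value if p != (0, 0))

    @classmethod
    def from_acronym(cls, text: str) -> "RLabel":
        key = text.strip().upper()
        if key in ("FALSE", "TRUE"):
            return cls[key]
        try:
            return cls[key]
        except KeyError:
            raise ValueError(f"unknown regulation label {text!r}") from None

    @classmethod
    def from_sign_pair(cls, rp: int, rm: int) -> "RLabel":
        """The exact label admitting only the sign pair (rp, rm)."""
        return {(1, 0): cls.MPU, (0, 1): cls.MNU,
                (1, 1): cls.MA, (0, 0): cls.NR}[(rp, rm)]


@dataclass(frozen=True)
class RGraph:
    """Generalized regulation graph: at most one labeled edge per pair.

    An absent ordered pair carries the implicit label NR, so a node's
    potential regulators are exactly the sources of its non-NR in-edges.
    """

    variables: tuple
    edges: tuple  # tuple of (source, RLabel, target), 0-based endpoints

    def __post_init__(self) -> None:
        n = len(self.variables)
        seen = set()
        for u, lab, v in self.edges:
            if not (0 <= u < n and 0 <= v < n):
                raise ValueError(f"edge ({u},{v}) references unknown variable")
            if not isinstance(lab, RLabel):
                raise TypeError("edge label must be an RLabel")
            if (u, v) in seen:
                raise ValueError(
                    f"duplicate edge for ordered pair ({u},{v})"
                )
            seen.add((u, v))

    @property
    def n(self) -> int:
        return len(self.variables)

    def label(self, u: int, v: int) -> RLabel:
        for s, lab, t in self.edges:
            if (s, t) == (u, v):
                return lab
        return RLabel.NR

    def potential_regulators(self, j: int) -> tuple:
        """Sources of node j's non-NR in-edges, in declaration order."""
        return tuple(
            u for u, lab, v in self.edges if v == j and lab is not RLabel.NR
        )

    def in_degrees(self) -> tuple:
        return tuple(len(self.potential_regulators(j)) for j in range(self.n))

    def mandatory_edges(self) -> tuple:
        return tuple(e for e in self.edges if e[1].is_mandatory)

    def optional_edges(self) -> tuple:
        """Edges that may be absent, excluding pure-NR edges."""
        return tuple(
            e for e in self.edges
            if e[1].is_optional and e[1].present_pairs
        )


@dataclass(frozen=True)
class Attractor:
    """A terminal SCC of the state graph, as an ordered successor cycle.

    Canonical form starts at the lexicographically smallest state, so
    attractors compare and hash as values.  Length-1 cycles are fixed
    points.
    """

    states: tuple  # tuple of State

    def __post_init__(self) -> None:
        if not self.states:
            raise ValueError("attractor cannot be empty")
        if len(set(self.states)) != len(self.states):
            raise ValueError("attractor states must be distinct")

    @staticmethod
    def canonical(cycle: Sequence[State]) -> "Attractor":
        k = min(range(len(cycle)), key=lambda i: cycle[i])
        return Attractor(tuple(cycle[k:]) + tuple(cycle[:k]))

    @property
    def size(self) -> int:
        return len(self.states)

    @property
    def is_fixed_point(self) -> bool:
        return len(self.states) == 1

    def __str__(self) -> str:
        return ",".join(format_state(s) for s in self.states)


@dataclass(frozen=True)
class PatternConstraint:
    """A wildcard pattern, optionally scoped to a mutant background."""

    pattern: Subspace
    mutation: Optional[Mutation] = None

    def __post_init__(self) -> None:
        if self.mutation is not None:
            for p, v in zip(self.mutation.positions, self.mutation.values):
                c = self.pattern.pattern[p - 1]
                if c != "*" and int(c) != v:
                    raise ValueError(
                        f"pattern {self.pattern} contradicts mutation "
                        f"value {v} at position {p}"
                    )

    def resolved_pattern(self) -> Subspace:
        """Pattern with mutation values substituted at clamped positions."""
        if self.mutation is None:
            return self.pattern
        chars = list(self.pattern.pattern)
        for p, v in zip(self.mutation.positions, self.mutation.values):
            chars[p - 1] = str(v)
        return Subspace("".join(chars))


@dataclass(frozen=True)
class ConstraintSpec:
    """Constraints on the dynamics of acceptable networks."""

    required_fixed_points: tuple = ()  # PatternConstraint
    prohibited_fixed_points: tuple = ()  # PatternConstraint
    required_transitions: tuple = ()  # (State, State)
    exact_fixed_point_set: bool = False
    forbid_cyclic_attractors: bool = False
    injective_matching: bool = False

    def validate(self, n: int) -> None:
        for pc in self.required_fixed_points + self.prohibited_fixed_points:
            if pc.pattern.n != n:
                raise ValueError(
                    f"pattern {pc.pattern} has length {pc.pattern.n}, "
                    f"expected {n}"
                )
        for x, y in self.required_transitions:
            if len(x) != n or len(y) != n:
                raise ValueError("transition state length mismatch")

    def mutations(self) -> tuple:
        """Distinct mutation contexts referenced by the constraints."""
        seen = []
        for pc in self.required_fixed_points + self.prohibited_fixed_points:
            if pc.mutation is not None and pc.mutation not in seen:
                seen.append(pc.mutation)
        return tuple(seen)


@dataclass(frozen=True)
class SolverOptions:
    max_solutions: Optional[int] = None  # None = all
    seed: int = 0
    strategy: str = "whole"  # whole | radial
    radius_min: int = 0
    radius_max: Optional[int] = None
    explicit_limit: int = 24
    static_prohibition_limit: int = 8
    learn_all_violations: bool = True
    max_iterations: Optional[int] = None


@dataclass(frozen=True)
class Problem:
    """A network-constraint problem: R-graph + constraints + options."""

    rgraph: RGraph
    constraints: ConstraintSpec = field(default_factory=ConstraintSpec)
    options: SolverOptions = field(default_factory=SolverOptions)

    def __post_init__(self) -> None:
        self.constraints.validate(self.rgraph.n)
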