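"""A small deterministic CNF satisfiability solver.

Implements exactly the contract the inference engine needs: incremental
clause addition, model retrieval, and an unsatisfiability verdict.  It is
an iterative DPLL search with unit propagation over two watched literals
and chronological backtracking; clause learning happens one level up, in
the engine, where whole attractors are blocked.

Literals follow DIMACS conventions: variable v > 0, literals +v / -v.
"""

from __future__ import annotations

import random
from typing import Dict, Iterable, List, Optional

__all__ = ["Solver"]


class Solver:
    """Incremental DPLL solver over integer literals.

    Branching order is ascending variable index with a fixed polarity,
    optionally randomized per-variable by ``seed`` (any given seed yields
    a reproducible run).
    """

    def __init__(self, seed: Optional[int] = None) -> None:
        self.num_vars = 0
        self.clauses: List[List[int]] = []
        self._unsat_flag = False  # empty clause added
        if seed is None:
            self._polarity = None
        else:
            self._polarity = random.Random(seed)
        self._pol_cache: Dict[int, bool] = {}

    # ------------------------------------------------------------------
    def new_var(self) -> int:
        self.num_vars += 1
        return self.num_vars

    def add_clause(self, lits: Iterable[int]) -> None:
        clause = []
        seen = set()
        for lit in lits:
            if lit == 0:
                raise ValueError("0 is not a literal")
            if -lit in seen:  # tautology
                return
            if lit in seen:
                continue
            seen.add(lit)
            clause.append(lit)
            self.num_vars = max(self.num_vars, abs(lit))
        if not clause:
            self._unsat_flag = True
            return
        self.clauses.append(clause)

    # ------------------------------------------------------------------
    def _preferred(self, var: int) -> bool:
        if self._polarity is None:
            return False
        if var not in self._pol_cache:
            self._pol_cache[var] = self._polarity.random() < 0.5
        return self._pol_cache[var]

    def solve(self) -> Optional[Dict[int, bool]]:
        """Return a satisfying assignment {var: bool} or None if unsat."""
        if self._unsat_flag:
            return None
        nv = self.num_vars
        value: List[int] = [-1] * (nv + 1)  # -1 unassigned, 0/1 assigned
        # watch lists keyed by literal index: lit -> idx = lit + nv
        watches: List[List[int]] = [[] for _ in range(2 * nv + 1)]
        watched: List[List[int]] = []  # the two watched literals per clause
        trail: List[int] = []
        units: List[int] = []

        def lit_idx(lit: int) -> int:
            return lit + nv

        def lit_val(lit: int) -> int:
            v = value[abs(lit)]
            if v == -1:
                return -1
            return v if lit > 0 else 1 - v

        for ci, cl in enumerate(self.clauses):
            if len(cl) == 1:
                units.append(cl[0])
                watched.append([cl[0], cl[0]])
            else:
                watched.append([cl[0], cl[1]])
                watches[lit_idx(-cl[0])].append(ci)
                watches[lit_idx(-cl[1])].append(ci)

        def assign(lit: int) -> bool:
            """Assign lit true and propagate; False on conflict."""
            queue = [lit]
            while queue:
                l = queue.pop()
                v = lit_val(l)
                if v == 1:
                    continue
                if v == 0:
                    return False
                value[abs(l)] = 1 if l > 0 else 0
                trail.append(l)
                idx = lit_idx(l)  # clauses watching -l, i.e. keyed by l
                pending = watches[idx]
                watches[idx] = []
                for ci in pending:
                    w = watched[ci]
                    other = w[1] if w[0] == -l else w[0]
                    if lit_val(other) == 1:
                        watches[idx].append(ci)
                        continue
                    # search replacement watch
                    moved = False
                    for cand in self.clauses[ci]:
                        if cand == other or cand == -l:
                            continue
                        if lit_val(cand) != 0:
                            if w[0] == -l:
                                w[0] = cand
                            else:
                                w[1] = cand
                            watches[lit_idx(-cand)].append(ci)
                            moved = True
                            break
                    if moved:
                        continue
                    watches[idx].append(ci)
                    if lit_val(other) == 0:
                        # restore remaining watchers before failing
                        watches[idx].extend(
                            c for c in pending[pending.index(ci) + 1:]
                        )
                        return False
                    queue.append(other)
            return True

        def backtrack(mark: int) -> None:
            while len(trail) > mark:
                l = trail.pop()
                value[abs(l)] = -1

        for l in units:
            if not assign(l):
                return None

        # decision stack: (trail mark, decided literal, tried_other)
        stack: List[List[int]] = []
        var = 1
        while True:
            while var <= nv and value[var] != -1:
                var += 1
            if var > nv:
                return {v: bool(value[v]) for v in range(1, nv + 1)}
            first = var if self._preferred(var) else -var
            mark = len(trail)
            if assign(first):
                stack.append([mark, first, 0, var])
                var += 1
                continue
            backtrack(mark)
            lit = -first
            while True:
                mark = len(trail)
                if assign(lit):
                    stack.append([mark, lit, 1, abs(lit)])
                    var = abs(lit) + 1
                    break
                backtrack(mark)
                # flip an earlier decision
                while stack and stack[-1][2] == 1:
                    backtrack(stack.pop()[0])
                if not stack:
                    return None
                mark0, dec, _t, dvar = stack.pop()
                backtrack(mark0)
                lit = -dec
                stack_mark_var = dvar  # noqa: F841  (kept for clarity)

    def is_satisfiable(self) -> bool:
        return self.solve() is not None

    def enumerate_models(self, project: Optional[List[int]] = None,
                         limit: Optional[int] = None):
        """Yield models, blocking each on ``project`` vars (default: all).

        Mutates the solver by adding blocking clauses.
        """
        count = 0
        proj = project
        while limit is None or count < limit:
            model = self.solve()
            if model is None:
                return
            yield model
            vars_ = proj if proj is not None else sorted(model)
            self.add_clause(
                [-v if model[v] else v for v in vars_]
            )
            count += 1
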