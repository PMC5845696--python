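# Methods

This note records what `bninfer` computes, the choices behind the
implementation, and its known limitations.

## Model

A synchronous Boolean network on `n` components is stored as, per node,
an ordered tuple of declared regulators and a truth table of length
`2^d` (`d` = number of regulators). Rows are indexed by the regulator
values read as a binary number with the *first listed regulator most
significant*. States are `n`-tuples over `{0,1}`; user-facing indices
are 1-based, internal indices 0-based. The dynamics is deterministic:
every state has exactly one successor, so attractors are the terminal
strongly connected components of the state graph — either fixed points
or simple cycles.

A mutation clamps selected components to constants; clamped nodes lose
their regulators, and constraints scoped to a mutant are evaluated in
the clamped dynamics with the clamp values substituted into the
pattern.

## Regulation semantics

Regulator `i` regulates node `j` positively (negatively) iff some state
exists where flipping `x_i` moves `f_j` in the same (opposite)
direction. Operationally this is decided by scanning the `2^(d-1)`
row pairs of `j`'s table that differ only in `i`'s position — a
component not declared as a regulator trivially realizes `(0, 0)`. The
test suite cross-checks this table scan against a direct scan of the
full state space.

An R-graph edge label *is* a set of admitted `(R+, R-)` pairs (e.g.
`MPU = {(1,0)}`, `OPU = {(0,0),(1,0)}`, `TRUE` = all four, `FALSE` =
none). A label is optional iff it admits `(0,0)`. Absent edges are
implicit `NR`. The *potential regulators* of a node are the sources of
its non-`NR` in-edges in declaration order; candidate tables range over
exactly those inputs, so a solution's table may declare a regulator
that turns out non-functional. `functional_reduction` projects such
tables down to their functional inputs; solution sets produced by
different strategies are compared after this reduction.

## CNF encoding

One propositional variable per truth-table entry (`sum_j 2^{d_j}` in
total), plus two regulation variables `(R+, R-)` per edge, each defined
by biconditionals against the relevant table-row pairs through one
auxiliary variable per regulator context. A label contributes one
clause per excluded sign pair. Required fixed-point patterns introduce
fresh choice variables only for their wildcard positions; prohibited
patterns expand to one clause per matching state and are therefore
expanded statically only up to `static_prohibition_limit = 8` wildcards
(default), beyond which they are enforced at runtime like the other
attractor constraints. Transitions are unit literals. Formulas can be
exported to and re-read from DIMACS CNF.

## Search: lazy clause learning

Constraints whose eager encoding is super-polynomial — exactness of
the stationary-state set and the ban on cyclic attractors — are
enforced by a generate-and-refine loop:

1. solve the current CNF with the bundled solver;
2. decode the model into a network and re-check it against the R-graph
   with the independent semantic oracle (a safety guard; a mismatch
   would indicate an encoding bug and raises);
3. compute the attractors of the wild type and of every referenced
   mutant exactly, by successor traversal over the full state space
   (guarded by `explicit_limit = 24` variables);
4. accept, or learn blocking clauses: an unwanted fixed point `y`
   yields the clause "some table row selected by `y` disagrees with
   `y`"; an unwanted cycle yields the analogous clause over all of its
   transitions; violation kinds with no such local witness (e.g. a
   missing required pattern discovered only semantically) fall back to
   blocking the full table assignment;
5. emitted solutions are blocked on their table variables, so
   enumeration is duplicate-free.

The loop asserts that a learned-blocked attractor never recurs; the
iteration count, verdicts and violations are kept in a run log.
Required patterns are matched against the computed fixed points by
maximum bipartite matching when injective witnesses are requested.

The bundled SAT solver is an iterative DPLL with two watched literals,
unit propagation, chronological backtracking and deterministic
ascending-variable branching (optionally seed-randomized polarity). It
supports incremental clause addition and projected model enumeration.
It is adequate for the problem sizes exercised here (hundreds of
variables); swapping in an external CDCL solver would be a drop-in
optimization, not a semantic change.

## Query splitting (radial strategy)

A query over an R-graph with `m` mandatory and `h` optional edges
splits into members indexed by a *center* (one admitted sign choice per
mandatory edge) and a *radius* `r` (an `r`-subset of optional edges,
each with a present-sign choice). Members are ordinary sign-exact
queries carrying the original constraints; over all centers and radii
they cover the instantiation space exactly once (`C(h, r)` subsets at
radius `r`, `2^h` total for single-sign hypotheses). Splitting is
useful when informative solutions are expected near the mandatory core:
radii can be solved in ascending order under a member budget, with
per-radius accounting. Aggregated split answers equal the whole-query
answer up to functional reduction.

## Stationary-state-set exploration (FPAS)

To survey the *diversity* of admissible stationary behaviour, the
explorer repeatedly solves, records the witness's fixed-point attractor
set (FPAS), and adds the clause "at least one recorded stationary state
is not stationary". This is deliberately incomplete: the clause also
blocks strict supersets of a recorded FPAS, and a witness with an empty
FPAS terminates the exploration (its blocking clause would be empty).
The similarity of recorded FPASs is summarized by the cosine-similarity
matrix of their incidence vectors over the union of observed stationary
states (lexicographic order), a 30-bin histogram of its entries, and
the fraction of zero entries.

## Combinatorics

All scale figures are exact big-integer closed forms:

* search space `prod_i 2^(2^{d_i})`;
* exclusionary clause count `sum_{k=1..2^n} (2^n)!/(k (2^n-k)!)` —
  the number of directed cycles of every length over the `2^n` states,
  i.e. the clauses an eager exact-attractor encoding would need; an
  incremental falling factorial keeps evaluation `O(2^n)` big-int
  operations (n = 13, ~28,500 digits, runs in well under a second);
* a `log10` variant via `math.lgamma` with compensated summation for
  sizes where even the digit count is unwieldy (agrees with the exact
  logarithm to < 1e-6 where both are computable);
* the radial schedule `C(h, r)` with cumulative sums.

**Presentation convention:** mantissas of large values are *truncated*,
not rounded, to two significant figures (`2^68 = 2.95...e20` prints as
`2.9e+20`). Truncation is applied consistently by
`counting.mantissa_exponent` / `counting.sci_string`, and exponents are
derived from the bit length with exact integer adjustment, so values
with millions of digits are handled without float overflow or huge
string conversions.

## Default parameters

| parameter | default | rationale |
|---|---|---|
| `explicit_limit` | 24 | full-state-space traversal caps at 2^24 states; above this, explicit attractor checks are refused rather than silently slow |
| `static_prohibition_limit` | 8 | a prohibited pattern expands statically to <= 2^8 clauses; wider patterns are enforced at runtime |
| `learn_all_violations` | true | learn a clause for every violation of a rejected candidate, not just the first — fewer solver round trips |
| `max_iterations` / budgets | none | enumeration is exhaustive unless capped; any cap is reported as status `incomplete` (CLI exit code 3) |
| `seed` | 0 | deterministic branching; a nonzero seed randomizes only branching polarity, never the answer set |
| similarity `bins` | 30 | histogram resolution of the FPAS similarity summary |

Problem sizes used in the test suite (<= 3 nodes for brute-force
equivalence, <= 10–13 nodes for dynamics oracles) are chosen so that
the *entire* candidate space or state space can be enumerated
independently; they are study conditions for the oracles, not tuning.

## File formats

* Query text: `variables:` / `topology:` / `constraints:` / `options:`
  sections; parsing collects *all* errors with line numbers before
  failing; `write_query` round-trips losslessly.
* Networks: JSON (variables, 1-based regulator lists, table
  bit-strings — bit-exact round trip), TSV truth tables (bit-exact),
  and BoolNet-style `.bnet` rules. `.bnet` output is an unminimized
  sum of minterms; it preserves the dynamics exactly but loses declared
  non-functional regulators, so only JSON/TSV are faithful archival
  formats.

## Limitations

* Synchronous (deterministic) update only; no asynchronous semantics.
* Explicit attractor computation bounds verified constraints to
  `explicit_limit` variables; the SAT phase itself has no such bound,
  but acceptance of a candidate requires the explicit check.
* FPAS exploration is intentionally not exhaustive over FPASs (superset
  blocking, empty-FPAS termination), and which witness represents each
  FPAS depends on enumeration order.
* The bookkeeping figure "two regulation variables per edge" counts the
  raw `(R+, R-)` pairs before any constant-propagation a preprocessor
  could apply; fully-determined labels could be eliminated, which is
  why coarser variable counts can be reported elsewhere for the same
  topology.
* The bundled DPLL has no conflict-driven learning or restarts; very
  large R-graphs (tens of nodes with high in-degree) are outside its
  comfortable range.
* No SBML-qual import/export.
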