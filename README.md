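# bninfer

Symbolic inference of synchronous Boolean molecular networks from
partial regulatory knowledge.

## The scientific problem

A synchronous Boolean network models a molecular regulatory system as a
map `f : {0,1}^n -> {0,1}^n`: every gene/protein is ON or OFF, and all
components update simultaneously. Its long-run behaviours — the
attractors of the state-transition graph — are commonly identified with
stable cell types or expression programs.

In practice neither the network nor even its wiring is fully known.
What experiments provide is:

* **partial topology** — "A activates B", "C probably represses A",
  "B's sign of action on C is unknown", and
* **partial dynamics** — observed stationary expression patterns
  (possibly with wildcards), patterns that must *not* be stationary,
  observed transitions, and mutant phenotypes (knock-outs /
  over-expressions).

`bninfer` answers the inverse question: *which Boolean networks are
consistent with all of that evidence?* It encodes the question as a
propositional satisfiability problem over the entries of every node's
truth table and enumerates all solutions, so an empty answer is a proof
of inconsistency and a large answer quantifies the remaining
uncertainty.

## The model in brief

**Regulation semantics.** An edge `i -> j` is a *positive* (resp.
*negative*) regulation of `f` when there exists a state in which
flipping component `i` changes `f_j` in the same (resp. opposite)
direction; both at once means the regulation is *ambiguous*. This is a
property of the function, not of the drawn wiring — a declared input a
table happens to ignore is not a regulation.

**Generalized regulation graphs (R-graphs).** Each edge carries one of
16 labels; a label is exactly a set of admitted `(R+, R-)` outcomes for
that ordered pair. The workhorses:

| acronym | meaning |
|---|---|
| `MPU` / `MNU` | mandatory, positive / negative, unambiguous |
| `MA`  | mandatory and ambiguous (both signs present) |
| `OPU` / `ONU` | optional, positive / negative, unambiguous |
| `MUSU` | mandatory, unknown sign, unambiguous |
| `OA`, `OPPA`, `ONPA`, `OUSU`, `MPPA`, `MNPA`, `MUSPA` | the remaining optional / possibly-ambiguous refinements |
| `NR` | no regulation |
| `TRUE` / `FALSE` | no constraint at all / contradiction |

A network *satisfies* an R-graph when every edge's realized `(R+, R-)`
pair is admitted by its label and every non-edge realizes `(0, 0)`.

**Dynamical constraints.** Required fixed-point patterns over
`{0,1,*}`, prohibited patterns, required transitions, mutant-scoped
patterns (`mutant a=0`), exactness of the stationary-state set,
injective witness matching, and a global ban on cyclic attractors.

**Inference.** Truth-table entries become propositional variables;
regulation labels and constraints become CNF clauses. Constraints that
would need astronomically many clauses up front (exclusion of every
unwanted attractor) are instead *learned lazily*: each SAT model is
decoded, its attractors are computed exactly, and any violation is
turned into a small blocking clause before re-solving. A bundled
watched-literal DPLL solver performs the search, so the package has no
external solver dependency.

## Worked example

Two genes: `a` is known to activate `b`; `b` may activate `a`. The
fully-ON state `11` was observed to be stable, `01` must not be stable,
and no oscillation is tolerated. Query file `mutual.query`:

```
variables: a b
topology:
    a -> b : MPU
    b -> a : OPU
constraints:
    fixed_point 11
    prohibit_fixed_point 01
options:
    forbid_cyclic_attractors = true
```

Running the solver:

```
$ bninfer solve --query mutual.query
# solution 1
targets, factors
a, (!b) | (b)
b, (a)
1 satisfying network(s); status complete
```

Exactly one network survives: `b` copies `a`, and `a` is constantly ON
(rules are printed as unminimized sums of minterms, so `(!b) | (b)` is
the constant 1 — the optional edge `b -> a` is *not* realized). The
only other candidate, `a` copying `b`, is rejected because it has the
cyclic attractor `01 <-> 10`; the run log records that rejection and
the learned clause that excludes it.

The same problem through the library:

```python
from bninfer import RGraph, RLabel, Problem, ConstraintSpec, \
    PatternConstraint, Subspace, solve

g = RGraph(("a", "b"), ((0, RLabel.MPU, 1), (1, RLabel.OPU, 0)))
spec = ConstraintSpec(
    required_fixed_points=(PatternConstraint(Subspace("11")),),
    prohibited_fixed_points=(PatternConstraint(Subspace("01")),),
    forbid_cyclic_attractors=True,
)
result = solve(Problem(g, spec))
print(result.status, [f.tables for f in result.networks])
# complete [((1, 1), (0, 1))]
```

## Command-line interface

| command | purpose |
|---|---|
| `bninfer solve`   | enumerate all satisfying networks of a query |
| `bninfer split`   | same answer via radial query splitting, with per-radius accounting |
| `bninfer fpas`    | sample networks with pairwise-distinct stationary-state sets |
| `bninfer attractors` / `basins` | analyse a concrete network file |
| `bninfer count`   | closed-form problem-scale report for a topology |
| `bninfer validate`| syntax-check a query file |

Exit codes: 0 solutions found, 1 unsatisfiable, 2 usage error, 3 budget
exhausted. Network files are read/written as JSON, tab-separated truth
tables, or BoolNet-style `.bnet` rules.

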