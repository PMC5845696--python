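"""CNF encoding: variable accounting, model soundness, completeness."""

import itertools

import pytest

from bninfer.core import (
    ConstraintSpec,
    Mutation,
    PatternConstraint,
    RGraph,
    RLabel,
    Subspace,
    parse_state,
)
from bninfer.dynamics import fixed_points
from bninfer.encoding import (
    Formula,
    VariableMap,
    decode_model,
    encode_fixed_point,
    encode_prohibited_fixed_point,
    encode_regulations,
    encode_transition,
    export_dimacs,
    parse_dimacs,
)
from bninfer.regulation import satisfies
from bninfer.sat import Solver

from conftest import all_networks, network_key, oracle_satisfies


def enumerate_networks(g, extra_clauses=()):
    """All decoded models of the regulation encoding, projected to tables."""
    formula = encode_regulations(g)
    s = Solver()
    for cl in formula.clauses:
        s.add_clause(cl)
    for cl in extra_clauses:
        s.add_clause(cl)
    s.num_vars = max(s.num_vars, formula.varmap.num_vars)
    tvars = sorted(formula.varmap.table_vars.values())
    out = []
    for model in s.enumerate_models(project=tvars):
        out.append(decode_model(model, formula.varmap))
    return out, formula


def test_table_variable_accounting_matches_degree_sum():
    # in-degrees (1, 2, 3) -> 2 + 4 + 8 table rows
    edges = (
        (0, RLabel.MPU, 0),
        (0, RLabel.OPU, 1), (1, RLabel.ONU, 1),
        (0, RLabel.MPPA, 2), (1, RLabel.OA, 2), (2, RLabel.MUSU, 2),
    )
    g = RGraph(("a", "b", "c"), edges)
    formula = encode_regulations(g)
    vm = formula.varmap
    assert vm.table_var_count == 2 + 4 + 8
    assert vm.reg_var_count == 2 * len(edges)


def test_mpu_self_loop_forces_the_identity_function():
    g = RGraph(("v1",), ((0, RLabel.MPU, 0),))
    nets, _ = enumerate_networks(g)
    assert len(nets) == 1
    assert nets[0].tables == ((0, 1),)  # f(x) = x


def test_mandatory_ambiguous_single_regulator_is_unsatisfiable():
    g = RGraph(("u", "v"), ((0, RLabel.MA, 1),))
    nets, _ = enumerate_networks(g)
    assert nets == []


def test_two_node_mpu_cycle_admits_only_the_swap_network():
    g = RGraph(("v1", "v2"), ((0, RLabel.MPU, 1), (1, RLabel.MPU, 0)))
    nets, _ = enumerate_networks(g)
    assert len(nets) == 1
    assert nets[0].tables == ((0, 1), (0, 1))


@pytest.mark.parametrize("label", list(RLabel))
def test_single_edge_model_count_matches_brute_force(label):
    """Enumeration completeness for each of the 16 labels on 2 nodes."""
    g = RGraph(("u", "v"), ((0, label, 1),))
    nets, _ = enumerate_networks(g)
    brute = [f for f in all_networks(g) if oracle_satisfies(f, g)]
    assert {network_key(f) for f in nets} == {network_key(f) for f in brute}


def test_decoded_models_satisfy_the_graph():
    g = RGraph(
        ("a", "b"),
        ((0, RLabel.OPPA, 1), (1, RLabel.ONU, 0), (0, RLabel.OUSU, 0)),
    )
    nets, _ = enumerate_networks(g)
    assert nets
    for f in nets:
        assert satisfies(f, g)
        assert oracle_satisfies(f, g)


def test_contradictory_label_gives_unsat_formula():
    g = RGraph(("u", "v"), ((0, RLabel.FALSE, 1),))
    nets, _ = enumerate_networks(g)
    assert nets == []


def test_fixed_point_units_pin_table_rows():
    g = RGraph(("v1", "v2"), ((0, RLabel.MPU, 1), (1, RLabel.MPU, 0)))
    formula = encode_regulations(g)
    encode_fixed_point(formula, PatternConstraint(Subspace("11")))
    units = [cl for cl in formula.clauses if len(cl) == 1]
    vm = formula.varmap
    # node 1 row (x2=1) must output 1; node 2 row (x1=1) must output 1
    assert [vm.table_vars[(0, 1)]] in units
    assert [vm.table_vars[(1, 1)]] in units


def test_wildcard_fixed_point_requires_matching_stationary_state():
    g = RGraph(("v1", "v2"), ((0, RLabel.OPU, 1), (1, RLabel.OPU, 0)))
    spec = PatternConstraint(Subspace("1*"))
    formula = encode_regulations(g)
    encode_fixed_point(formula, spec)
    extra = formula.clauses
    nets, formula2 = enumerate_networks(g)
    # re-encode jointly for a fair enumeration
    f2 = encode_regulations(g)
    encode_fixed_point(f2, spec)
    s = Solver()
    for cl in f2.clauses:
        s.add_clause(cl)
    s.num_vars = max(s.num_vars, f2.varmap.num_vars)
    tvars = sorted(f2.varmap.table_vars.values())
    got = {
        network_key(decode_model(m, f2.varmap))
        for m in s.enumerate_models(project=tvars)
    }
    brute = {
        network_key(f) for f in all_networks(g)
        if oracle_satisfies(f, g)
        and any(x[0] == 1 for x in fixed_points(f))
    }
    assert got == brute


def test_all_wildcards_pattern_means_some_fixed_point():
    g = RGraph(("v1", "v2"), ((0, RLabel.OPU, 1), (1, RLabel.OPU, 0)))
    f2 = encode_regulations(g)
    encode_fixed_point(f2, PatternConstraint(Subspace("**")))
    s = Solver()
    for cl in f2.clauses:
        s.add_clause(cl)
    s.num_vars = max(s.num_vars, f2.varmap.num_vars)
    model = s.solve()
    assert model is not None
    f = decode_model(model, f2.varmap)
    assert fixed_points(f)


def test_prohibiting_everything_while_requiring_a_fixed_point_is_unsat():
    g = RGraph(("v1",), ((0, RLabel.OPU, 0),))
    f2 = encode_regulations(g)
    encode_fixed_point(f2, PatternConstraint(Subspace("*")))
    encode_prohibited_fixed_point(f2, PatternConstraint(Subspace("*")))
    s = Solver()
    for cl in f2.clauses:
        s.add_clause(cl)
    s.num_vars = max(s.num_vars, f2.varmap.num_vars)
    assert s.solve() is None


def test_prohibition_on_forced_fixed_point_is_unsat():
    g = RGraph(("v1",), ((0, RLabel.MPU, 0),))  # identity forced
    f2 = encode_regulations(g)
    encode_prohibited_fixed_point(f2, PatternConstraint(Subspace("0")))
    s = Solver()
    for cl in f2.clauses:
        s.add_clause(cl)
    s.num_vars = max(s.num_vars, f2.varmap.num_vars)
    assert s.solve() is None


def test_wide_prohibition_defers_to_runtime():
    g = RGraph(
        tuple(f"v{i}" for i in range(10)),
        tuple((i, RLabel.OPU, (i + 1) % 10) for i in range(10)),
    )
    f2 = encode_regulations(g)
    done = encode_prohibited_fixed_point(
        f2, PatternConstraint(Subspace("*" * 10)), static_limit=8
    )
    assert done is False


def test_mutant_fixed_point_constrains_only_unclamped_nodes():
    g = RGraph(("v1", "v2"), ((0, RLabel.MPU, 1), (1, RLabel.MPU, 0)))
    f2 = encode_regulations(g)
    n_before = len(f2.clauses)
    encode_fixed_point(
        f2,
        PatternConstraint(Subspace("10"), Mutation((1,), (1,))),
    )
    added = f2.clauses[n_before:]
    vm = f2.varmap
    # only node 2 (unclamped) is constrained: its row for x1=1 outputs 0
    assert added == [[-vm.table_vars[(1, 1)]]]


def test_transition_encoding_and_contradiction():
    g = RGraph(("v1", "v2"), ((0, RLabel.TRUE, 1), (1, RLabel.TRUE, 0)))
    f2 = encode_regulations(g)
    encode_transition(f2, parse_state("01"), parse_state("10"))
    encode_transition(f2, parse_state("01"), parse_state("01"))
    s = Solver()
    for cl in f2.clauses:
        s.add_clause(cl)
    assert s.solve() is None


def test_transitions_compose_into_a_required_cycle():
    g = RGraph(("v1", "v2"), ((0, RLabel.TRUE, 1), (1, RLabel.TRUE, 0)))
    f2 = encode_regulations(g)
    encode_transition(f2, parse_state("01"), parse_state("10"))
    encode_transition(f2, parse_state("10"), parse_state("01"))
    s = Solver()
    for cl in f2.clauses:
        s.add_clause(cl)
    s.num_vars = max(s.num_vars, f2.varmap.num_vars)
    model = s.solve()
    f = decode_model(model, f2.varmap)
    from bninfer.core import successor

    assert successor(f, (0, 1)) == (1, 0)
    assert successor(f, (1, 0)) == (0, 1)


def test_adding_clauses_never_enlarges_the_model_set():
    g = RGraph(("v1", "v2"), ((0, RLabel.OPU, 1), (1, RLabel.ONU, 0)))
    base, _ = enumerate_networks(g)
    f2 = encode_regulations(g)
    encode_fixed_point(f2, PatternConstraint(Subspace("0*")))
    s = Solver()
    for cl in f2.clauses:
        s.add_clause(cl)
    s.num_vars = max(s.num_vars, f2.varmap.num_vars)
    tvars = sorted(f2.varmap.table_vars.values())
    narrowed = {
        network_key(decode_model(m, f2.varmap))
        for m in s.enumerate_models(project=tvars)
    }
    assert narrowed <= {network_key(f) for f in base}


def test_dimacs_export_and_roundtrip():
    g = RGraph(("v1",), ((0, RLabel.MPU, 0),))
    formula = encode_regulations(g)
    text = export_dimacs(formula)
    header = [l for l in text.splitlines() if l.startswith("p ")]
    assert header == [
        f"p cnf {formula.varmap.num_vars} {len(formula.clauses)}"
    ]
    back = parse_dimacs(text)
    assert sorted(map(sorted, back)) == sorted(map(sorted, formula.clauses))


def test_empty_formula_dimacs():
    g = RGraph(("v1",), ())
    formula = encode_regulations(g)
    text = export_dimacs(formula)
    assert f"p cnf {formula.varmap.num_vars} 0" in text
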