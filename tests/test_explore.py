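"""Radial splitting and stationary-state-set exploration."""

import itertools
import random

import numpy as np
import pytest

from bninfer.core import (
    ConstraintSpec,
    PatternConstraint,
    Problem,
    RGraph,
    RLabel,
    Subspace,
)
from bninfer.dynamics import fixed_points
from bninfer.engine import solve
from bninfer.explore import (
    accounting_to_tsv,
    fpas_explore,
    radial_split,
    similarity_matrix,
    solve_split,
    split_members,
)
from bninfer.regulation import (
    count_instantiations,
    functional_reduction,
    instantiations,
    satisfies,
)

from conftest import network_key


def reduced_keys(networks):
    return {network_key(functional_reduction(f)) for f in networks}


def test_members_enumerate_every_instantiation_exactly_once():
    g = RGraph(
        ("a", "b", "c"),
        ((0, RLabel.MUSU, 1), (1, RLabel.OPU, 2), (2, RLabel.OA, 0),
         (0, RLabel.OUSU, 0)),
    )
    problem = Problem(g)
    members = list(split_members(problem))
    assert len(members) == count_instantiations(g)
    graphs = {m.problem.rgraph.edges for m in members}
    assert len(graphs) == len(members)  # no duplicates
    # each member is sign-exact: only MPU/MNU/MA labels appear
    exact = {RLabel.MPU, RLabel.MNU, RLabel.MA}
    for m in members:
        assert all(lab in exact for _u, lab, _v in m.problem.rgraph.edges)
    # radii ascend within each center and count added optional edges
    mandatory = len(g.mandatory_edges())
    for m in members:
        assert len(m.center) == mandatory
        assert len(m.added) == m.radius


def test_member_signatures_match_instantiation_signatures():
    g = RGraph(
        ("u", "v"),
        ((0, RLabel.OPPA, 1), (1, RLabel.MUSPA, 0)),
    )
    problem = Problem(g)
    member_sigs = set()
    for m in split_members(problem):
        mg = m.problem.rgraph
        ip = frozenset(
            (u, v) for u, lab, v in mg.edges
            if lab in (RLabel.MPU, RLabel.MA)
        )
        im = frozenset(
            (u, v) for u, lab, v in mg.edges
            if lab in (RLabel.MNU, RLabel.MA)
        )
        member_sigs.add((ip, im))
    inst_sigs = {(c.iplus, c.iminus) for c in instantiations(g)}
    assert member_sigs == inst_sigs


def test_radius_bounds_validated_and_contradiction_empty():
    g = RGraph(("u", "v"), ((0, RLabel.OPU, 1),))
    with pytest.raises(ValueError):
        list(split_members(Problem(g), r_min=2, r_max=2))
    bad = RGraph(("u", "v"), ((0, RLabel.FALSE, 1),))
    assert list(split_members(Problem(bad))) == []


def test_radius_window_restricts_members():
    g = RGraph(
        ("a", "b"),
        ((0, RLabel.OPU, 1), (1, RLabel.ONU, 0), (0, RLabel.OPU, 0)),
    )
    all_m = list(split_members(Problem(g)))
    r1 = list(split_members(Problem(g), r_min=1, r_max=1))
    assert {m.radius for m in r1} == {1}
    assert len(r1) == sum(1 for m in all_m if m.radius == 1) == 3


@pytest.mark.parametrize("label", [
    lab for lab in RLabel if lab is not RLabel.FALSE
])
def test_split_equals_whole_query_for_each_single_edge_label(label):
    g = RGraph(("u", "v"), ((0, label, 1),))
    problem = Problem(g)
    whole = solve(problem)
    split_nets, rows, status = solve_split(problem)
    assert status == "complete"
    assert reduced_keys(split_nets) == reduced_keys(whole.networks)


@pytest.mark.parametrize("seed", range(8))
def test_split_equals_whole_query_on_random_constrained_graphs(seed):
    rng = random.Random(seed)
    n = rng.randint(2, 3)
    variables = tuple(f"v{i + 1}" for i in range(n))
    labels = [l for l in RLabel if l is not RLabel.FALSE]
    edges = []
    for j in range(n):
        for i in rng.sample(range(n), rng.randint(0, min(2, n))):
            edges.append((i, rng.choice(labels), j))
    g = RGraph(variables, tuple(edges))
    spec = ConstraintSpec(
        required_fixed_points=(
            PatternConstraint(Subspace(
                "".join(rng.choice("01*") for _ in range(n))
            )),
        ),
    )
    problem = Problem(g, spec)
    whole = solve(problem)
    split_nets, _rows, status = solve_split(problem)
    assert status == "complete"
    assert reduced_keys(split_nets) == reduced_keys(whole.networks)


def test_small_radius_can_miss_solutions_larger_radius_recovers():
    # realizing the 01 <-> 10 exchange needs both cross-regulations, so
    # no member of radius <= 1 is satisfiable while radius 2 is
    from bninfer.core import parse_state

    g = RGraph(("v1", "v2"), ((0, RLabel.OPU, 1), (1, RLabel.OPU, 0)))
    spec = ConstraintSpec(
        required_transitions=(
            (parse_state("01"), parse_state("10")),
            (parse_state("10"), parse_state("01")),
        ),
    )
    problem = Problem(g, spec)
    small, rows_small, _ = solve_split(problem, r_min=0, r_max=1)
    assert small == []
    full, rows_full, _ = solve_split(problem)
    assert full
    by_radius = {r.radius: r for r in rows_full}
    assert by_radius[2].networks == len(full)
    assert by_radius[2].cumulative_networks == len(full)


def test_accounting_rows_and_tsv():
    g = RGraph(
        ("a", "b"),
        ((0, RLabel.OPU, 1), (1, RLabel.ONU, 0)),
    )
    nets, rows, status = solve_split(Problem(g))
    assert status == "complete"
    assert [r.radius for r in rows] == sorted(r.radius for r in rows)
    assert rows[-1].cumulative_members == sum(r.members for r in rows)
    assert rows[-1].cumulative_networks == len(nets)
    # 2 optional edges: C(2,0)+C(2,1)+C(2,2) = 1+2+1 members
    assert [r.members for r in rows] == [1, 2, 1]
    tsv = accounting_to_tsv(rows)
    lines = tsv.strip().splitlines()
    assert lines[0].startswith("radius\tmembers")
    assert len(lines) == len(rows) + 1


def test_budget_exhaustion_is_flagged():
    g = RGraph(("v1", "v2"), ((0, RLabel.OPU, 1), (1, RLabel.OPU, 0)))
    _nets, _rows, status = solve_split(Problem(g), budget=1)
    assert status == "incomplete"


def test_radial_split_yields_problems():
    g = RGraph(("u", "v"), ((0, RLabel.OPU, 1),))
    probs = list(radial_split(Problem(g)))
    assert all(isinstance(p, Problem) for p in probs)
    assert len(probs) == 2


def test_fpas_witnesses_have_distinct_stationary_sets():
    g = RGraph(("v1", "v2"), ((0, RLabel.OPU, 1), (1, RLabel.OPU, 0)))
    result = fpas_explore(Problem(g))
    sets = [fp for _f, fp in result.witnesses]
    assert len(sets) == len(set(sets))  # pairwise distinct
    for f, fp in result.witnesses:
        assert satisfies(f, g)
        assert fixed_points(f) == set(fp)


def test_fpas_blocking_also_blocks_supersets():
    # one optional self-loop: possible FPASs are {}, {0}, {1}, {0,1};
    # once a singleton is recorded, the superset {0,1} is unreachable
    g = RGraph(("v1",), ((0, RLabel.OPU, 0),))
    result = fpas_explore(Problem(g))
    sets = {fp for _f, fp in result.witnesses}
    assert frozenset({(0,), (1,)}) not in sets
    assert len(sets) >= 2


def test_fpas_empty_set_is_terminal():
    # negation forced: the only network has no stationary state
    g = RGraph(("v1",), ((0, RLabel.MNU, 0),))
    result = fpas_explore(Problem(g))
    assert result.status == "terminal_empty_fpas"
    assert len(result.witnesses) == 1
    assert result.witnesses[0][1] == frozenset()


def test_fpas_budget():
    g = RGraph(("v1", "v2"), ((0, RLabel.OPU, 1), (1, RLabel.OPU, 0)))
    result = fpas_explore(Problem(g), budget=1)
    assert result.status == "incomplete"
    assert len(result.witnesses) <= 1


def test_fpas_respects_constraints():
    g = RGraph(("v1",), ((0, RLabel.OPU, 0),))
    spec = ConstraintSpec(
        prohibited_fixed_points=(PatternConstraint(Subspace("1")),),
    )
    result = fpas_explore(Problem(g, spec))
    for _f, fp in result.witnesses:
        assert (1,) not in fp


def test_similarity_matrix_properties():
    sets = [
        frozenset({(0, 0), (1, 1)}),
        frozenset({(1, 1)}),
        frozenset({(0, 1)}),
        frozenset(),
    ]
    sim, (counts, edges), zero_fraction = similarity_matrix(sets, bins=30)
    assert sim.shape == (4, 4)
    assert np.allclose(sim, sim.T)
    assert np.allclose(np.diag(sim), 1.0)
    assert np.all((sim >= 0.0) & (sim <= 1.0))
    assert sim[0, 1] == pytest.approx(1 / np.sqrt(2))
    assert sim[1, 2] == 0.0
    assert sim[3, 0] == 0.0  # empty set vs anything
    assert counts.sum() == sim.size and len(counts) == 30
    assert zero_fraction == pytest.approx(np.mean(sim == 0.0))


def test_similarity_matrix_identical_sets_are_fully_similar():
    s = frozenset({(0, 1, 0)})
    sim, _h, zf = similarity_matrix([s, s])
    assert np.allclose(sim, 1.0)
    assert zf == 0.0


def test_similarity_matrix_rejects_empty_input():
    with pytest.raises(ValueError):
        similarity_matrix([])
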