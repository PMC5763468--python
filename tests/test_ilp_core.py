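import itertools

import numpy as np
import pandas as pd
import pytest

import tilp
from tilp._model import MilpModel
from tilp.ilp_core import linearize_product
from tilp.validation import brute_force_solve

from conftest import random_small_instance


def profile_from(values, proteins, conditions):
    return tilp.TernaryProfile(
        pd.DataFrame(
            np.asarray(values, dtype=float), index=proteins, columns=conditions
        )
    )


def test_variable_accounting_on_fixture(mcf7_map, mcf7_profile):
    problem = tilp.build_training_problem(mcf7_map, mcf7_profile)
    acct = tilp.variable_accounting(problem)
    assert acct["integer"] == 350  # one node state per (node, condition)
    assert acct["integer"] == len(mcf7_map.nodes) * len(mcf7_profile.conditions)
    assert acct["binary"] == acct["total"] - acct["integer"]
    fam = acct["families"]
    assert fam["y"] == 39
    assert fam["z"] == 39 * 10
    assert fam["a"] == 15 * 10


def test_variable_accounting_small_cases(toy_chain):
    prof = profile_from([[1], [1]], ["A", "B"], ["k"])
    acct = tilp.variable_accounting(tilp.build_training_problem(toy_chain, prof))
    assert acct["integer"] == 2  # 2 nodes x 1 condition

    net = tilp.build_network([("A", 1, "B"), ("B", -1, "C")], observed=["A"])
    prof2 = profile_from([[1, 0]], ["A"], ["k1", "k2"])
    acct2 = tilp.variable_accounting(tilp.build_training_problem(net, prof2))
    assert acct2["integer"] == 6  # 3 nodes x 2 conditions


def test_gamma_bounds_enforced(toy_chain):
    prof = profile_from([[1], [1]], ["A", "B"], ["k"])
    with pytest.raises(ValueError, match="gamma"):
        tilp.build_training_problem(toy_chain, prof, gamma=0.0)
    with pytest.raises(ValueError, match="gamma"):
        tilp.build_training_problem(toy_chain, prof, gamma=-2.0)


def test_prior_on_output_node_rejected(mcf7_map, mcf7_profile):
    prior = tilp.PriorKnowledge([tilp.PriorRecord("c0", "CellGrowth", 1)])
    with pytest.raises(ValueError, match="output node"):
        tilp.build_training_problem(mcf7_map, mcf7_profile, prior)


def test_unknown_prior_node_rejected(toy_chain):
    prof = profile_from([[1], [1]], ["A", "B"], ["k"])
    prior = tilp.PriorKnowledge([tilp.PriorRecord("k", "Ghost", 1)])
    with pytest.raises(ValueError, match="not in network"):
        tilp.build_training_problem(toy_chain, prof, prior)


def test_toy_chain_matching_data_fits_perfectly(toy_chain):
    # brute-force enumeration over all assignments confirms objective 0
    prof = profile_from([[1], [1]], ["A", "B"], ["k"])
    gamma = tilp.default_gamma(toy_chain)
    oracle = brute_force_solve(toy_chain, prof, gamma=gamma)
    assert oracle.objective == 0  # edge forced to occur, no removal, no mismatch
    sol = tilp.solve(tilp.build_training_problem(toy_chain, prof, gamma=gamma))
    assert sol.status == "optimal"
    assert sol.objective == pytest.approx(0)
    assert sol.fit_term == 0 and sol.simplicity_term == 0


def test_empty_data_removes_the_edge(toy_chain):
    prof = profile_from([[np.nan], [np.nan]], ["A", "B"], ["k"])
    problem = tilp.build_training_problem(toy_chain, prof)
    sol = tilp.solve(problem)
    assert sol.status == "optimal"
    # all-zero states are feasible; gamma rewards removing the idle edge
    assert sol.fit_term == 0
    assert sol.objective == pytest.approx(problem.gamma)


def test_product_linearization_exact_on_all_nine_combinations():
    for xu, xd in itertools.product((-1, 0, 1), repeat=2):
        model = MilpModel()
        up, um = model.add_binary("up"), model.add_binary("um")
        dp, dm = model.add_binary("dp"), model.add_binary("dm")
        p, _ = linearize_product(model, up, um, dp, dm)
        # pin the sign-split binaries to encode (xu, xd)
        for var, val in ((up, xu == 1), (um, xu == -1), (dp, xd == 1), (dm, xd == -1)):
            model.lb[var] = model.ub[var] = int(val)
        model.set_objective(dict(p))
        for sense in (1, -1):
            model.objective = {i: sense * c for i, c in p.items()}
            status, values, obj = model.solve()
            assert status == "optimal"
            assert sense * obj == pytest.approx(xu * xd)  # min == max == product


def test_infeasible_when_prior_needs_unavailable_support():
    # with support enforced on the prior target, +1 downstream of a
    # -1-pinned activating parent has no delivering reaction
    net = tilp.build_network([("A", 1, "B")], observed=[])
    prof = profile_from([[np.nan], [np.nan]], ["A", "B"], ["k"])
    prior = tilp.PriorKnowledge(
        [tilp.PriorRecord("k", "A", -1), tilp.PriorRecord("k", "B", 1)]
    )
    problem = tilp.build_training_problem(
        net, prof, prior, exempt_prior_targets=False
    )
    sol = tilp.solve(problem)
    assert sol.status == "infeasible"


def test_no_prior_training_is_always_feasible():
    for seed in range(10):
        net, prof = random_small_instance(seed)
        sol = tilp.solve(tilp.build_training_problem(net, prof))
        assert sol.status == "optimal"


def test_removal_occurrence_coupling_on_solutions():
    # y=1 forces z=1 everywhere; y=0 needs an occurrence somewhere
    for seed in (3, 7, 11):
        net, prof = random_small_instance(seed)
        problem = tilp.build_training_problem(net, prof)
        sol = tilp.solve(problem)
        reg = problem.registry
        for eid, yi in reg.y.items():
            zs = [sol.value(reg.z[(eid, k)]) for k in problem.conditions]
            if sol.value(yi) == 1:
                assert all(z == 1 for z in zs)
            else:
                assert any(z == 0 for z in zs)


def test_mismatch_indicator_tracks_disagreement():
    net = tilp.build_network([("A", 1, "B")], observed=["A", "B"])
    prof = profile_from([[1], [-1]], ["A", "B"], ["k"])
    problem = tilp.build_training_problem(net, prof)
    sol = tilp.solve(problem)
    reg = problem.registry
    for (j, k), ai in reg.a.items():
        m = prof.state(j, k)
        x = sol.value(reg.x[(j, k)])
        assert sol.value(ai) == (0 if x == m else 1)


def test_prediction_mode_has_no_removal_variables(toy_chain):
    prof = profile_from([[1], [1]], ["A", "B"], ["k"])
    problem = tilp.build_prediction_problem(toy_chain, prof)
    assert problem.registry.y == {}
    assert problem.gamma == 0
    sol = tilp.solve(problem)
    assert sol.status == "optimal" and sol.objective == 0


def test_solve_unknown_backend(toy_chain):
    prof = profile_from([[1], [1]], ["A", "B"], ["k"])
    problem = tilp.build_training_problem(toy_chain, prof)
    with pytest.raises(RuntimeError, match="no MILP backend"):
        tilp.solve(problem, backend="gurobi")


def test_lp_export_lists_all_variables(tmp_path, toy_chain):
    prof = profile_from([[1], [1]], ["A", "B"], ["k"])
    problem = tilp.build_training_problem(toy_chain, prof)
    path = tmp_path / "model.lp"
    problem.export_lp(path)
    text = path.read_text()
    assert "Minimize" in text and "Subject To" in text
    assert text.count("\n ") >= problem.model.n_vars  # bounds section covers all
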