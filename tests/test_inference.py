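import numpy as np
import pandas as pd
import pytest

import tilp
from tilp.inference import label_edges
from tilp.synthetic import GeneratorParams, generate_network, simulate_profiles
from tilp.validation import brute_force_solve


def profile_from(values, proteins, conditions):
    return tilp.TernaryProfile(
        pd.DataFrame(np.asarray(values, float), index=proteins, columns=conditions)
    )


@pytest.fixture(scope="module")
def small_synthetic():
    params = GeneratorParams(
        n_nodes=14, n_edges=18, n_tf=3, n_outputs=2, n_conditions=5, seed=5
    )
    net, true_removed = generate_network(params)
    profile, truth, prior = simulate_profiles(net, true_removed, params)
    return net, true_removed, profile, prior


def test_noise_free_synthetic_fits_exactly(small_synthetic):
    net, _, profile, prior = small_synthetic
    result = tilp.infer_cell_specific_network(net, profile, prior)
    assert result.fit_term == 0
    assert result.fitting_precision == 1.0


def test_removed_and_kept_partition_removable_set(small_synthetic):
    net, _, profile, prior = small_synthetic
    result = tilp.infer_cell_specific_network(net, profile, prior)
    kept = {e.id for e in result.cell_specific_network.edges if e.removable}
    removed = set(result.removed_edges)
    assert kept | removed == {e.id for e in net.removable_edges}
    assert kept & removed == set()
    # removed edges never occur (they have no occurrence row marked True)
    for eid in removed:
        assert not result.occurrences.loc[eid].any()


def test_all_zero_profile_prunes_everything(mcf7_map):
    observed = [n.id for n in mcf7_map.observed_nodes]
    profile = profile_from(
        np.zeros((len(observed), 2)), observed, ["k1", "k2"]
    )
    result = tilp.infer_cell_specific_network(mcf7_map, profile)
    assert result.fit_term == 0
    assert len(result.removed_edges) == len(mcf7_map.removable_edges)


def test_never_coactive_edge_is_pruned():
    # oracle-checked 4-node instance: D->C can never deliver C's state
    net = tilp.build_network(
        [("A", 1, "B"), ("B", 1, "C"), ("D", 1, "C")],
        observed=["A", "B", "C", "D"],
    )
    profile = profile_from(
        [[1, -1], [1, -1], [1, -1], [0, 0]], ["A", "B", "C", "D"], ["k1", "k2"]
    )
    oracle = brute_force_solve(net, profile)
    assert "D->C" in oracle.removed_edges
    result = tilp.infer_cell_specific_network(net, profile)
    assert result.removed_edges == ["D->C"]
    assert result.fit_term == oracle.min_fit == 0


def test_determinism(small_synthetic):
    net, _, profile, prior = small_synthetic
    r1 = tilp.infer_cell_specific_network(net, profile, prior, seed=1)
    r2 = tilp.infer_cell_specific_network(net, profile, prior, seed=1)
    assert r1.removed_edges == r2.removed_edges
    assert r1.states.equals(r2.states)
    assert r1.objective == r2.objective


def test_prediction_preserves_topology_and_recovers_training_state(small_synthetic):
    net, _, profile, prior = small_synthetic
    result = tilp.infer_cell_specific_network(net, profile, prior)
    cond = profile.conditions[0]
    sub = tilp.TernaryProfile(profile.values[[cond]])
    response = tilp.predict_compound_response(result.cell_specific_network, sub)
    assert response.fitting_precision == 1.0
    assert {e.id for e in response.network.edges} == {
        e.id for e in result.cell_specific_network.edges
    }
    assert set(response.edge_labels) == {e.id for e in response.network.edges}


def test_prediction_all_zero_profile(mcf7_map):
    observed = [n.id for n in mcf7_map.observed_nodes]
    train = profile_from(np.zeros((len(observed), 1)), observed, ["k"])
    pruned = tilp.infer_cell_specific_network(mcf7_map, train).cell_specific_network
    response = tilp.predict_compound_response(pruned, train)
    assert all(v == 0 for v in response.node_states.values())
    assert response.outcome.as_list() == [0, 0, 0, 0]
    assert set(response.edge_labels.values()) <= {"no-change", "not-occurring"}


def test_prediction_unknown_condition(small_synthetic):
    net, _, profile, prior = small_synthetic
    result = tilp.infer_cell_specific_network(net, profile, prior)
    with pytest.raises(ValueError, match="not in profile"):
        tilp.predict_compound_response(
            result.cell_specific_network, profile, condition="nope"
        )


def test_edge_label_rule():
    net = tilp.build_network([("A", 1, "B"), ("C", -1, "D"), ("E", 1, "F")])
    states = {"A": 1, "B": 1, "C": 1, "D": -1, "E": 0, "F": 0}
    labels = label_edges(
        net, states, {"A->B": True, "C-|D": True, "E->F": False}
    )
    assert labels == {"A->B": "up", "C-|D": "down", "E->F": "no-change"}
    labels2 = label_edges(net, {**states, "F": 1}, {"A->B": True, "C-|D": True, "E->F": False})
    assert labels2["E->F"] == "not-occurring"


def test_decode_tolerates_near_integral_values(small_synthetic, monkeypatch):
    net, _, profile, prior = small_synthetic
    problem = tilp.build_training_problem(net, profile, prior)
    sol = tilp.solve(problem)
    sol.values = sol.values + 9.9e-7  # integrality tolerance
    states, occurrences, removed = tilp.decode_solution(problem, sol)
    assert states.dtypes.apply(lambda d: d.kind == "i").all()


def test_fitting_precision_matches_observed_share(small_synthetic):
    net, _, profile, prior = small_synthetic
    # corrupt one observed entry so exactly one pair mismatches
    vals = profile.values.copy()
    j, k = vals.index[0], vals.columns[0]
    vals.at[j, k] = -vals.at[j, k] if vals.at[j, k] != 0 else 1
    corrupted = tilp.TernaryProfile(vals)
    result = tilp.infer_cell_specific_network(net, corrupted, prior)
    n_pairs = len(corrupted.observed_pairs())
    assert result.fitting_precision == pytest.approx(
        1 - result.fit_term / n_pairs
    )
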