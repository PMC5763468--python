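"""Training and prediction orchestration over the TILP program.

Training fits the generic map to all conditions at once and prunes the
edges whose reactions never occur; prediction re-optimizes node states on
the fixed pruned topology for a new compound and derives its qualitative
(edge labels) and quantitative (outcome vector) treatment effects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import ilp_core
from .datio import PriorKnowledge, TernaryProfile
from .effects import OutcomeVector, compute_output_vector, fitting_precision
from .netio import SignalingNetwork, write_sif

EDGE_LABELS = ("up", "down", "no-change", "not-occurring")


class SolverFailure(RuntimeError):
    def __init__(self, status: str, mode: str):
        super().__init__(f"{mode} problem ended with solver status {status!r}")
        self.status = status


@dataclass
class InferenceResult:
    """Decoded training output: the cell-specific subnetwork and states."""

    cell_specific_network: SignalingNetwork
    removed_edges: list[str]
    states: pd.DataFrame  # node x condition, integer states
    occurrences: pd.DataFrame  # edge x condition, True = reaction takes place
    objective: float
    fit_term: float
    simplicity_term: float
    fitting_precision: float
    gamma: float = 0.0

    def to_report(self) -> dict:
        return {
            "removed_edges": self.removed_edges,
            "kept_edges": [e.id for e in self.cell_specific_network.edges],
            "objective": self.objective,
            "fit_term": self.fit_term,
            "simplicity_term": self.simplicity_term,
            "fitting_precision": self.fitting_precision,
            "gamma": self.gamma,
            "states": {
                k: self.states[k].astype(int).to_dict() for k in self.states.columns
            },
        }

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_sif(
            self.cell_specific_network,
            out / "cell_specific_network.sif",
            out / "cell_specific_nodes.tsv",
        )
        self.states.astype(int).to_csv(out / "states.tsv", sep="\t")
        with open(out / "inference_report.json", "w") as fh:
            json.dump(self.to_report(), fh, indent=2)


@dataclass
class ResponseNetwork:
    """Per-compound response: states, edge labels and outcome readout."""

    condition: str
    network: SignalingNetwork
    node_states: dict[str, int]
    edge_labels: dict[str, str]
    outcome: OutcomeVector | None
    fitting_precision: float
    output_states: dict[str, int] = field(default_factory=dict)

    def to_report(self) -> dict:
        return {
            "condition": self.condition,
            "node_states": self.node_states,
            "edge_labels": self.edge_labels,
            "output_states": self.output_states,
            "outcome_vector": self.outcome.as_list() if self.outcome else None,
            "fitting_precision": self.fitting_precision,
        }


def decode_solution(
    problem: ilp_core.TilpProblem, solution: ilp_core.TilpSolution
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Round solver values back to domain quantities and re-assert the
    removal/occurrence coupling."""
    if solution.status != "optimal":
        raise SolverFailure(solution.status, problem.mode)
    reg = problem.registry
    conditions = problem.conditions
    nodes = [n.id for n in problem.network.nodes]
    states = pd.DataFrame(
        {
            k: [solution.value(reg.x[(nid, k)]) for nid in nodes]
            for k in conditions
        },
        index=nodes,
    )
    edge_ids = sorted({eid for (eid, _) in reg.z})
    occurrences = pd.DataFrame(
        {
            k: [solution.value(reg.z[(eid, k)]) == 0 for eid in edge_ids]
            for k in conditions
        },
        index=edge_ids,
    )
    removed = [eid for eid, yi in reg.y.items() if solution.value(yi) == 1]
    # consistency of removal vs occurrence (kept edges occur somewhere)
    for eid, yi in reg.y.items():
        occ = [solution.value(reg.z[(eid, k)]) == 0 for k in conditions]
        if solution.value(yi) == 1 and any(occ):
            raise RuntimeError(f"removed edge {eid} marked as occurring")
        if solution.value(yi) == 0 and not any(occ):
            raise RuntimeError(f"kept edge {eid} never occurs")
    return states, occurrences, removed


def _precision(
    states: pd.DataFrame, profile: TernaryProfile, network: SignalingNetwork
) -> float:
    observed = {n.id for n in network.observed_nodes}
    pred = {
        (j, k): int(states.at[j, k])
        for j in states.index
        if j in observed
        for k in states.columns
    }
    return fitting_precision(pred, profile)


def infer_cell_specific_network(
    network: SignalingNetwork,
    profile: TernaryProfile,
    prior: PriorKnowledge | None = None,
    gamma: float | None = None,
    backend: str = "highs",
    seed: int = 0,
    time_limit: float | None = None,
) -> InferenceResult:
    """Fit the generic map to the training profile and prune unused edges."""
    problem = ilp_core.build_training_problem(network, profile, prior, gamma)
    solution = ilp_core.solve(problem, backend=backend, seed=seed, time_limit=time_limit)
    states, occurrences, removed = decode_solution(problem, solution)
    pruned = network.without_edges(removed)
    return InferenceResult(
        cell_specific_network=pruned,
        removed_edges=removed,
        states=states,
        occurrences=occurrences,
        objective=solution.objective,
        fit_term=solution.fit_term,
        simplicity_term=solution.simplicity_term,
        fitting_precision=_precision(states, profile, network),
        gamma=problem.gamma,
    )


def _delivered_signal(network: SignalingNetwork, edge_id: str, states) -> int:
    e = network.edge_by_id(edge_id)
    return e.sign * int(states[e.source])


def label_edges(
    network: SignalingNetwork,
    states: dict[str, int],
    occurring: dict[str, bool],
) -> dict[str, str]:
    """Four-way edge coloring of a response network.

    Occurring reactions are labelled by the sign of the delivered signal
    (up/down); non-occurring reactions between two unchanged endpoints are
    "no-change", any other non-occurring reaction is "not-occurring".
    Fixed TF->output links are labelled by their delivered signal alone.
    """
    labels: dict[str, str] = {}
    for e in network.edges:
        if e.id in occurring:
            if occurring[e.id]:
                delivered = e.sign * states[e.source]
                labels[e.id] = "up" if delivered > 0 else "down"
            elif states[e.source] == 0 and states[e.target] == 0:
                labels[e.id] = "no-change"
            else:
                labels[e.id] = "not-occurring"
        else:  # fixed output-definition link
            delivered = e.sign * states[e.source]
            labels[e.id] = (
                "up" if delivered > 0 else "down" if delivered < 0 else "no-change"
            )
    return labels


def predict_compound_response(
    network: SignalingNetwork,
    profile: TernaryProfile,
    condition: str | None = None,
    prior: PriorKnowledge | None = None,
    backend: str = "highs",
    seed: int = 0,
    time_limit: float | None = None,
) -> ResponseNetwork:
    """Re-optimize node states on the fixed cell-specific topology for one
    test condition and decode its treatment effect."""
    conditions = profile.conditions
    if condition is None:
        if len(conditions) != 1:
            raise ValueError("profile has several conditions; name one")
        condition = conditions[0]
    if condition not in conditions:
        raise ValueError(f"condition {condition!r} not in profile")
    sub = TernaryProfile(profile.values[[condition]])
    problem = ilp_core.build_prediction_problem(network, sub, prior)
    solution = ilp_core.solve(problem, backend=backend, seed=seed, time_limit=time_limit)
    states, occurrences, _ = decode_solution(problem, solution)
    node_states = {nid: int(states.at[nid, condition]) for nid in states.index}
    occurring = {
        eid: bool(occurrences.at[eid, condition]) for eid in occurrences.index
    }
    labels = label_edges(network, node_states, occurring)
    output_states = {o.id: node_states[o.id] for o in network.output_nodes}
    outcome = None
    defs = network.output_definitions()
    try:
        tf_states = {
            tf: node_states[tf] for d in defs.values() for tf in d
        }
        outcome = compute_output_vector(tf_states, defs)
    except (ValueError, KeyError):
        outcome = None  # non-canonical output layout; raw states still reported
    return ResponseNetwork(
        condition=condition,
        network=network,
        node_states=node_states,
        edge_labels=labels,
        outcome=outcome,
        fitting_precision=_precision(states, sub, network),
        output_states=output_states,
    )
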