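"""Ground-truth generators: layered signed networks and ternary profiles.

The generator emulates the shape of a curated signaling map — a layered
acyclic signed digraph whose terminal transcription factors feed a small
set of cell-function readouts — together with perturbation-response
profiles produced by sign propagation over a hidden "true" subnetwork.
A fraction of candidate edges is marked truly absent; inference should
recover that removal set from the profiles.

Propagation per condition: perturbed root nodes take a state in {-1, +1};
every other node takes the sign of the sum of delivered signals
(edge sign x parent state) over non-removed incoming edges, with 0 on a
tie or when no active parent exists.  Observed entries are then flipped to
a random different ternary value with probability ``flip_noise_rate``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import networkx as nx
import numpy as np
import pandas as pd

from .datio import PriorKnowledge, PriorRecord, TernaryProfile
from .netio import Edge, Node, SignalingNetwork

_CANONICAL_OUTPUTS = ("CellCycle", "DNARepair", "CellSurvival", "CellGrowth")


@dataclass(frozen=True)
class GeneratorParams:
    """Defaults mirror the packaged breast-cancer map's shape: 35 nodes,
    50 edges (11 of them fixed TF->output links), ~30% inhibitions, about
    a quarter of the candidate edges truly absent, half of the signaling
    nodes observed."""

    n_nodes: int = 35
    n_edges: int = 50
    inhibition_fraction: float = 0.3
    n_outputs: int = 4
    n_tf: int = 11
    n_conditions: int = 10
    perturbations_per_condition: int = 2
    removed_edge_fraction: float = 0.25
    observation_coverage: float = 0.5
    flip_noise_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "inhibition_fraction",
            "removed_edge_fraction",
            "observation_coverage",
            "flip_noise_rate",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        n_sig = self.n_nodes - self.n_outputs
        if n_sig < self.n_tf or n_sig < 1:
            raise ValueError("n_nodes must cover TFs and outputs")
        if self.n_edges < self.n_tf and self.n_outputs:
            raise ValueError("n_edges must at least wire each TF to an output")
        # acyclicity bound on the signaling layer (DAG over n_sig nodes)
        max_sig_edges = n_sig * (n_sig - 1) // 2
        if self.n_edges - (self.n_tf if self.n_outputs else 0) > max_sig_edges:
            raise ValueError("n_edges exceeds the acyclic capacity of the node set")


def generate_network(
    params: GeneratorParams,
) -> tuple[SignalingNetwork, set[str]]:
    """Build a random layered map; returns (network, truly-removed edge ids)."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    n_sig = params.n_nodes - params.n_outputs
    proteins = [f"P{i:02d}" for i in range(n_sig - params.n_tf)]
    tfs = [f"TF{i:02d}" for i in range(params.n_tf)]
    if params.n_outputs == 4:
        outputs = list(_CANONICAL_OUTPUTS)
    else:
        outputs = [f"OUT{i}" for i in range(params.n_outputs)]
    order = proteins + tfs  # topological order: proteins upstream of TFs

    edges: list[Edge] = []
    seen: set[tuple[str, str]] = set()

    def add_edge(src: str, tgt: str, sign: int, removable: bool = True) -> None:
        arrow = "->" if sign > 0 else "-|"
        edges.append(Edge(f"{src}{arrow}{tgt}", src, tgt, sign, removable=removable))
        seen.add((src, tgt))

    # fixed TF->output wiring: each TF feeds exactly one output
    n_fixed = 0
    if params.n_outputs:
        assignment = rng.integers(0, params.n_outputs, size=params.n_tf)
        # make sure every output has at least one TF when possible
        for o in range(min(params.n_outputs, params.n_tf)):
            assignment[o] = o
        for t, o in enumerate(assignment):
            sign = -1 if rng.random() < params.inhibition_fraction else 1
            add_edge(tfs[t], outputs[o], sign, removable=False)
            n_fixed += 1

    n_free = params.n_edges - n_fixed
    # candidate forward pairs (respecting the topological order, TFs sink-side)
    pairs = [
        (order[i], order[j])
        for i in range(len(order))
        for j in range(i + 1, len(order))
    ]
    rng.shuffle(pairs)
    for src, tgt in pairs:
        if n_free <= 0:
            break
        if (src, tgt) in seen:
            continue
        sign = -1 if rng.random() < params.inhibition_fraction else 1
        add_edge(src, tgt, sign)
        n_free -= 1

    removable_ids = [e.id for e in edges if e.removable]
    n_removed = int(round(params.removed_edge_fraction * len(removable_ids)))
    true_removed = set(
        rng.choice(removable_ids, size=n_removed, replace=False).tolist()
    )

    nodes = []
    for nid in order:
        role = "transcription_factor" if nid in tfs else "protein"
        observed = bool(rng.random() < params.observation_coverage)
        nodes.append(Node(nid, role=role, observed=observed))
    nodes += [Node(o, role="output") for o in outputs]
    return SignalingNetwork(nodes=nodes, edges=edges), true_removed


def _toposort(network: SignalingNetwork) -> list[str]:
    g = nx.DiGraph()
    g.add_nodes_from(n.id for n in network.nodes)
    g.add_edges_from((e.source, e.target) for e in network.edges)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("propagation requires an acyclic network")
    return list(nx.topological_sort(g))


def simulate_profiles(
    network: SignalingNetwork,
    true_removed: set[str],
    params: GeneratorParams,
) -> tuple[TernaryProfile, pd.DataFrame, PriorKnowledge]:
    """Propagate perturbations over the true subnetwork.

    Returns (observed noisy profile, full ground-truth state table, prior
    records naming each condition's perturbation target and direction).
    """
    rng = np.random.default_rng(params.seed + 1)
    kept = [e for e in network.edges if e.id not in true_removed]
    order = _toposort(network)
    in_kept: dict[str, list] = {}
    for e in kept:
        in_kept.setdefault(e.target, []).append(e)
    # perturb only full-map roots: their states are unconstrained entry points
    # in the inference program, so noise-free profiles stay exactly feasible
    in_full = {e.target for e in network.edges}
    roots = [
        n.id for n in network.nodes if n.role != "output" and n.id not in in_full
    ]
    if not roots:
        raise ValueError("network has no root nodes to perturb")

    conditions = [f"cond{c:02d}" for c in range(params.n_conditions)]
    truth = pd.DataFrame(0, index=[n.id for n in network.nodes], columns=conditions)
    prior_records: list[PriorRecord] = []
    for k in conditions:
        n_pert = min(params.perturbations_per_condition, len(roots))
        targets = rng.choice(roots, size=n_pert, replace=False)
        states: dict[str, int] = {}
        pert = {t: int(rng.choice([-1, 1])) for t in targets}
        node_roles = {n.id: n.role for n in network.nodes}
        for nid in order:
            if nid in pert:
                states[nid] = pert[nid]
                continue
            delivered = sum(
                e.sign * states.get(e.source, 0) for e in in_kept.get(nid, [])
            )
            # outputs carry the signed sum of their TFs; signaling nodes
            # take the sign of the delivered total (0 on tie)
            if node_roles[nid] == "output":
                states[nid] = int(delivered)
            else:
                states[nid] = int(np.sign(delivered))
        for nid in truth.index:
            truth.at[nid, k] = states.get(nid, 0)
        if pert:
            t0 = sorted(pert)[0]
            prior_records.append(PriorRecord(k, t0, pert[t0]))

    observed_ids = [n.id for n in network.observed_nodes]
    obs = truth.loc[observed_ids].astype(float).copy()
    if params.flip_noise_rate > 0:
        flat = obs.to_numpy()
        flip = rng.random(flat.shape) < params.flip_noise_rate
        # flip to one of the two other ternary values, uniformly
        offsets = rng.integers(1, 3, size=flat.shape)
        flat = np.where(flip, ((flat + 1 + offsets) % 3) - 1, flat)
        obs = pd.DataFrame(flat, index=obs.index, columns=obs.columns)
    return TernaryProfile(obs), truth, PriorKnowledge(prior_records)


def preset_mcf7_like(
    seed: int = 20170, n_conditions: int = 10
) -> tuple[SignalingNetwork, TernaryProfile, PriorKnowledge, set[str], pd.DataFrame]:
    """Deterministic size-matched analog of the packaged breast-cancer map:
    35 nodes, 50 edges, 10 single-target perturbation conditions with one
    literature-style prior per condition."""
    params = GeneratorParams(seed=seed, n_conditions=n_conditions)
    network, true_removed = generate_network(params)
    profile, truth, prior = simulate_profiles(network, true_removed, params)
    return network, profile, prior, true_removed, truth
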