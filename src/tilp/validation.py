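"""Independent brute-force oracle, cross-validation and recovery studies.

The oracle enumerates every ternary state assignment per condition and
derives the optimal occurrence/removal pattern analytically, giving the
exact optimum of the training objective on small instances.  It shares no
code with the MILP path and is used to certify it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ilp_core
from .datio import PriorKnowledge, TernaryProfile
from .effects import topology_similarity
from .inference import SolverFailure, infer_cell_specific_network, predict_compound_response
from .netio import SignalingNetwork
from .synthetic import GeneratorParams, generate_network, simulate_profiles

DEFAULT_LIMITS = (8, 8, 2)  # max signaling nodes, removable edges, conditions


@dataclass
class OracleResult:
    feasible: bool
    objective: float
    min_fit: float
    states: pd.DataFrame | None  # one optimal assignment (signaling nodes)
    removed_edges: list[str]
    n_optima: int


@dataclass
class CrossValReport:
    folds: list[dict] = field(default_factory=list)
    mean_precision: float = float("nan")
    mean_similarity: float = float("nan")
    reference_edge_count: int = 0


def _condition_tables(
    network: SignalingNetwork,
    profile: TernaryProfile,
    prior: PriorKnowledge,
    condition: str,
    exempt_prior_targets: bool,
):
    """Enumerate feasible assignments for one condition.

    Returns (masks, min-mismatch per mask, optimum count per mask,
    representative assignment per mask) where a mask's bit b is set iff
    removable edge b is forced to occur (co-changing endpoints).
    """
    sig = [n.id for n in network.signaling_nodes]
    idx = {nid: i for i, nid in enumerate(sig)}
    n = len(sig)
    assignments = np.array(
        list(itertools.product((-1, 0, 1), repeat=n)), dtype=np.int8
    )
    feasible = np.ones(len(assignments), dtype=bool)

    pk = prior.for_condition(condition)
    for node, direction in pk.items():
        if node in idx:
            feasible &= assignments[:, idx[node]] == direction

    removable = network.removable_edges
    u = np.array([idx[e.source] for e in removable], dtype=int)
    d = np.array([idx[e.target] for e in removable], dtype=int)
    s = np.array([e.sign for e in removable], dtype=np.int8)
    if removable:
        forced = (s[None, :] * assignments[:, u] * assignments[:, d]) == 1
    else:
        forced = np.zeros((len(assignments), 0), dtype=bool)

    # linking-pattern support: a +/-1 child needs a delivering parent
    in_removable: dict[str, list[int]] = {}
    for b, e in enumerate(removable):
        in_removable.setdefault(e.target, []).append(b)
    for nid, b_list in in_removable.items():
        if exempt_prior_targets and nid in pk:
            continue
        deliver = s[b_list][None, :] * assignments[:, u[b_list]]
        has_pos = (deliver == 1).any(axis=1)
        has_neg = (deliver == -1).any(axis=1)
        col = assignments[:, idx[nid]]
        feasible &= ~((col == 1) & ~has_pos)
        feasible &= ~((col == -1) & ~has_neg)

    observed_ids = {n.id for n in network.observed_nodes}
    mismatch = np.zeros(len(assignments), dtype=np.int64)
    for j in profile.proteins:
        if j not in observed_ids or j not in idx:
            continue
        m = profile.state(j, condition)
        if m is None:
            continue
        mismatch += assignments[:, idx[j]] != m

    rows = np.flatnonzero(feasible)
    if len(rows) == 0:
        return None
    masks = forced[rows] @ (1 << np.arange(len(removable), dtype=np.int64))
    mism = mismatch[rows]
    uniq, inverse = np.unique(masks, return_inverse=True)
    mins = np.full(len(uniq), np.iinfo(np.int64).max, dtype=np.int64)
    np.minimum.at(mins, inverse, mism)
    at_min = mism == mins[inverse]
    counts = np.bincount(inverse[at_min], minlength=len(uniq))
    reps = np.zeros(len(uniq), dtype=np.int64)
    # last feasible row attaining the group minimum is as good as any
    reps[inverse[at_min]] = rows[at_min]
    return uniq, mins, counts, reps, assignments, sig


def brute_force_solve(
    network: SignalingNetwork,
    profile: TernaryProfile,
    prior: PriorKnowledge | None = None,
    gamma: float | None = None,
    limits: tuple[int, int, int] = DEFAULT_LIMITS,
    exempt_prior_targets: bool = True,
) -> OracleResult:
    """Exact optimum of ``sum a + gamma * sum y`` by full enumeration.

    For each condition all ternary assignments over the signaling nodes are
    enumerated and filtered by priors and support; occurrences and removals
    follow analytically (an edge can be removed iff it is forced to occur
    in no condition, and removal is always rewarded since gamma < 0).
    """
    prior = prior or PriorKnowledge.empty()
    if gamma is None:
        gamma = ilp_core.default_gamma(network)
    conditions = list(profile.conditions)
    n_sig = len(network.signaling_nodes)
    removable = network.removable_edges
    max_nodes, max_edges, max_conds = limits
    if n_sig > max_nodes or len(removable) > max_edges or len(conditions) > max_conds:
        raise ValueError(
            f"instance exceeds enumeration limits {limits}: "
            f"{n_sig} nodes, {len(removable)} removable edges, {len(conditions)} conditions"
        )

    tables = []
    for k in conditions:
        t = _condition_tables(network, profile, prior, k, exempt_prior_targets)
        if t is None:
            return OracleResult(False, float("nan"), float("nan"), None, [], 0)
        tables.append(t)

    n_rm = len(removable)
    full_mask = (1 << n_rm) - 1
    popcount = np.array([bin(i).count("1") for i in range(1 << n_rm)], dtype=np.int64)

    if len(conditions) == 1:
        uniq, mins, counts, reps, assignments, sig = tables[0]
        n_removed = n_rm - popcount[uniq]
        obj = mins + gamma * n_removed
        best = obj.min()
        winners = np.flatnonzero(np.abs(obj - best) < 1e-9)
        n_optima = int(counts[winners].sum())
        gi = winners[0]
        chosen = [(uniq[gi], reps[gi])]
        min_fit = float(mins.min())
    else:
        u1, m1, c1, r1, asg1, sig = tables[0]
        u2, m2, c2, r2, asg2, _ = tables[1]
        union = u1[:, None] | u2[None, :]
        obj = m1[:, None] + m2[None, :] + gamma * (n_rm - popcount[union])
        best = obj.min()
        winners = np.argwhere(np.abs(obj - best) < 1e-9)
        n_optima = int(sum(c1[i] * c2[j] for i, j in winners))
        i, j = winners[0]
        chosen = [(u1[i], r1[i]), (u2[j], r2[j])]
        min_fit = float(m1.min() + m2.min())
        assignments = None

    # decode one optimal assignment
    states = {}
    union_mask = 0
    for (mask, rep), k, table in zip(chosen, conditions, tables):
        union_mask |= int(mask)
        asg = table[4]
        states[k] = asg[rep].astype(int)
    states_df = pd.DataFrame(states, index=tables[0][5])
    removed = [e.id for b, e in enumerate(removable) if not (union_mask >> b) & 1]
    return OracleResult(
        feasible=True,
        objective=float(best),
        min_fit=min_fit,
        states=states_df,
        removed_edges=removed,
        n_optima=n_optima,
    )


def loo_crossval(
    network: SignalingNetwork,
    profile: TernaryProfile,
    prior: PriorKnowledge | None = None,
    gamma: float | None = None,
    backend: str = "highs",
    seed: int = 0,
    prior_in_prediction: bool = False,
) -> CrossValReport:
    """Leave-one-condition-out cross-validation.

    Each fold trains on the remaining conditions, predicts the held-out one
    on the fold's pruned network, and scores fold-network similarity
    against the all-conditions reference network.
    """
    conditions = list(profile.conditions)
    if len(conditions) < 2:
        raise ValueError("cross-validation needs at least 2 conditions")
    reference = infer_cell_specific_network(
        network, profile, prior, gamma, backend=backend, seed=seed
    ).cell_specific_network
    report = CrossValReport(reference_edge_count=len(reference.edges))
    for held_out in conditions:
        rest = [k for k in conditions if k != held_out]
        train_profile = TernaryProfile(profile.values[rest])
        try:
            fold = infer_cell_specific_network(
                network, train_profile, prior, gamma, backend=backend, seed=seed
            )
            response = predict_compound_response(
                fold.cell_specific_network,
                TernaryProfile(profile.values[[held_out]]),
                prior=prior if prior_in_prediction else None,
                backend=backend,
                seed=seed,
            )
        except SolverFailure as exc:
            report.folds.append(
                {"condition": held_out, "error": str(exc), "skipped": True}
            )
            continue
        report.folds.append(
            {
                "condition": held_out,
                "precision": response.fitting_precision,
                "similarity": topology_similarity(
                    fold.cell_specific_network, reference
                ),
                "skipped": False,
            }
        )
    scored = [f for f in report.folds if not f.get("skipped")]
    if scored:
        report.mean_precision = float(np.mean([f["precision"] for f in scored]))
        report.mean_similarity = float(np.mean([f["similarity"] for f in scored]))
    return report


def recovery_experiment(
    params: GeneratorParams,
    noise_rates: list[float] = (0.0, 0.1, 0.2),
    replicates: int = 3,
    seed: int = 0,
    backend: str = "highs",
) -> pd.DataFrame:
    """Edge-removal recovery under increasing observation noise.

    For each (noise rate, replicate): generate a map with a hidden removed
    edge set, simulate profiles, run inference, and score the inferred
    removals against the truth (precision/recall) plus the fit term.
    """
    rows = []
    for noise in noise_rates:
        for rep in range(replicates):
            p = GeneratorParams(
                **{
                    **params.__dict__,
                    "flip_noise_rate": noise,
                    "seed": (seed + 1000 * rep + int(noise * 1e6)) % (2**31 - 1),
                }
            )
            net, true_removed = generate_network(p)
            profile, _, prior = simulate_profiles(net, true_removed, p)
            result = infer_cell_specific_network(
                net, profile, prior, backend=backend, seed=seed
            )
            inferred = set(result.removed_edges)
            tp = len(inferred & true_removed)
            rows.append(
                {
                    "noise": noise,
                    "replicate": rep,
                    "fit_term": result.fit_term,
                    "n_true_removed": len(true_removed),
                    "n_inferred_removed": len(inferred),
                    "precision": tp / len(inferred) if inferred else float("nan"),
                    "recall": tp / len(true_removed) if true_removed else float("nan"),
                }
            )
    return pd.DataFrame(rows)
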