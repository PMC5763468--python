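"""Ternary-state integer linear program (TILP) construction and solving.

The program couples three decision layers over a signed signaling map and a
set of perturbation conditions:

* ``x[j,k]`` in {-1, 0, +1}: state of protein/TF node j under condition k
  (output-node states are the signed sums of their TFs and get wider
  integer bounds).  Each ternary x is split into sign binaries
  ``x = x+ - x-`` with ``x+ + x- <= 1``.
* ``z[i,k]`` binary: reaction i does NOT take place under condition k
  (0 means it occurs — the convention is kept as in the field literature).
* ``y[i]`` binary (training only): reaction i is removed from the map.

Constraint families
-------------------
C1  ternary domain and sign split.
C2  mismatch indicators: ``m - x <= 2a`` and ``x - m <= 2a`` for every
    observed, non-missing (j, k); binary ``a`` replaces the squared error.
C3  edge-presence coupling: ``z[i,k] >= y[i]`` and
    ``1 - y[i] <= sum_k (1 - z[i,k])`` (a kept edge occurs somewhere).
C4  linking-pattern support: an up (down) node state needs at least one
    occurring incoming reaction delivering a positive (negative) signal,
    unless the node is a root or a direct compound target in that condition.
C5  no missing edges: with p = x_u * x_d (linearized through AND binaries),
    activations satisfy ``-1 <= p + z <= 1`` and inhibitions
    ``-1 <= p - z <= 1`` — consistently co-changing endpoints force the
    reaction to occur, so it cannot be pruned.
C6  a reaction cannot occur from an unchanged parent: ``1 - z <= |x_u|``.
C7  prior knowledge pins ``x[j,k]`` to the literature direction.
C8  output nodes equal the signed sum of their upstream TF states.

Objective: minimize ``sum a + gamma * sum y`` with gamma in
(-1/|removable edges|, 0), so one unit of data fit is never traded for any
number of edge removals, while among equally fitting solutions the sparsest
subnetwork wins.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from ._model import MilpModel
from .datio import PriorKnowledge, TernaryProfile
from .netio import SignalingNetwork

logger = logging.getLogger(__name__)

INTEGRALITY_TOL = 1e-6


def default_gamma(network: SignalingNetwork) -> float:
    """Midpoint of the admissible interval (-1/|removable|, 0)."""
    n_rm = len(network.removable_edges)
    if n_rm == 0:
        return 0.0
    return -0.5 / n_rm


@dataclass
class VariableRegistry:
    """Index maps from domain entities to model variable columns."""

    model: MilpModel
    x: dict = field(default_factory=dict)  # (node, cond) -> idx, integer domain
    xp: dict = field(default_factory=dict)  # (node, cond) -> idx
    xm: dict = field(default_factory=dict)
    y: dict = field(default_factory=dict)  # edge_id -> idx
    z: dict = field(default_factory=dict)  # (edge_id, cond) -> idx
    a: dict = field(default_factory=dict)  # (node, cond) -> idx
    w: dict = field(default_factory=dict)  # (edge_id, cond) -> {pp,mm,pm,mp: idx}
    pos: dict = field(default_factory=dict)  # (edge_id, cond) -> idx
    neg: dict = field(default_factory=dict)

    def families(self) -> dict[str, int]:
        return {
            "x": len(self.x),
            "y": len(self.y),
            "z": len(self.z),
            "a": len(self.a),
            "sign_split": len(self.xp) + len(self.xm),
            "product": 4 * len(self.w),
            "support": len(self.pos) + len(self.neg),
        }


@dataclass
class TilpProblem:
    model: MilpModel
    registry: VariableRegistry
    network: SignalingNetwork
    conditions: list[str]
    gamma: float
    mode: str  # "training" | "prediction"
    observed_pairs: list[tuple[str, str, int]] = field(default_factory=list)

    def export_lp(self, path) -> None:
        self.model.to_lp(path)


@dataclass
class TilpSolution:
    status: str  # optimal | infeasible | error
    values: np.ndarray | None
    objective: float
    fit_term: float
    simplicity_term: float

    def value(self, idx: int) -> int:
        v = self.values[idx]
        r = round(v)
        if abs(v - r) > 1e-4:
            raise ValueError(f"non-integral variable value {v}")
        return int(r)


def linearize_product(
    model: MilpModel,
    u_plus: int,
    u_minus: int,
    d_plus: int,
    d_minus: int,
    tag: str = "p",
) -> tuple[dict[int, float], dict[str, int]]:
    """Linearize p = x_u * x_d from the endpoint sign-split binaries.

    Returns the coefficient map of p (an affine expression over four fresh
    AND binaries) and the binaries themselves.  Each w = b1 AND b2 via
    ``w <= b1``, ``w <= b2``, ``w >= b1 + b2 - 1``.
    """
    w: dict[str, int] = {}
    pairs = {
        "pp": (u_plus, d_plus),
        "mm": (u_minus, d_minus),
        "pm": (u_plus, d_minus),
        "mp": (u_minus, d_plus),
    }
    for key, (b1, b2) in pairs.items():
        wi = model.add_binary(f"w_{key}[{tag}]")
        model.add_constraint({wi: 1, b1: -1}, upper=0)
        model.add_constraint({wi: 1, b2: -1}, upper=0)
        model.add_constraint({wi: 1, b1: -1, b2: -1}, lower=-1)
        w[key] = wi
    p = {w["pp"]: 1.0, w["mm"]: 1.0, w["pm"]: -1.0, w["mp"]: -1.0}
    return p, w


def _build(
    network: SignalingNetwork,
    profile: TernaryProfile,
    prior: PriorKnowledge | None,
    gamma: float | None,
    mode: str,
    exempt_prior_targets: bool = True,
) -> TilpProblem:
    prior = prior or PriorKnowledge.empty()
    conditions = list(profile.conditions)
    if not conditions:
        raise ValueError("profile has no conditions")
    node_map = network.node_map
    removable = network.removable_edges
    if mode == "training":
        if gamma is None:
            gamma = default_gamma(network)
        if removable and not (-1.0 / len(removable) < gamma < 0):
            raise ValueError(
                f"gamma must lie in (-1/{len(removable)}, 0), got {gamma}"
            )
    else:
        gamma = 0.0

    # resolve and validate priors
    prior_by_cond: dict[str, dict[str, int]] = {k: {} for k in conditions}
    for rec in prior.records:
        if rec.condition not in prior_by_cond:
            continue  # prior table may cover conditions outside this profile
        if rec.node not in node_map:
            raise ValueError(f"prior target {rec.node!r} not in network")
        if node_map[rec.node].role == "output":
            raise ValueError(f"prior on output node {rec.node!r} is not allowed")
        prior_by_cond[rec.condition][rec.node] = rec.direction

    model = MilpModel(name=f"tilp_{mode}")
    reg = VariableRegistry(model)
    sig_nodes = network.signaling_nodes
    outputs = network.output_nodes

    # C1: node states with sign split; C8: output equalities; C7: priors
    for k in conditions:
        pk = prior_by_cond[k]
        for n in sig_nodes:
            xi = model.add_var(f"x[{n.id},{k}]", -1, 1)
            xpi = model.add_binary(f"xp[{n.id},{k}]")
            xmi = model.add_binary(f"xm[{n.id},{k}]")
            reg.x[(n.id, k)] = xi
            reg.xp[(n.id, k)] = xpi
            reg.xm[(n.id, k)] = xmi
            model.add_constraint({xi: 1, xpi: -1, xmi: 1}, lower=0, upper=0)
            model.add_constraint({xpi: 1, xmi: 1}, upper=1)
            if n.id in pk:
                d = pk[n.id]
                model.lb[xi], model.ub[xi] = d, d
        for o in outputs:
            in_e = network.in_edges(o.id)
            bound = len(in_e)
            xi = model.add_var(f"x[{o.id},{k}]", -bound, bound)
            reg.x[(o.id, k)] = xi
            coeffs = {xi: 1.0}
            for e in in_e:
                coeffs[reg.x[(e.source, k)]] = coeffs.get(reg.x[(e.source, k)], 0) - e.sign
            model.add_constraint(coeffs, lower=0, upper=0)

    # C2: mismatch indicators for observed, non-missing entries
    observed_pairs: list[tuple[str, str, int]] = []
    observed_ids = {n.id for n in network.observed_nodes}
    for j in profile.proteins:
        if j not in observed_ids:
            continue
        for k in conditions:
            m = profile.state(j, k)
            if m is None:
                continue
            observed_pairs.append((j, k, m))
            ai = model.add_binary(f"a[{j},{k}]")
            reg.a[(j, k)] = ai
            xi = reg.x[(j, k)]
            model.add_constraint({xi: 1, ai: 2}, lower=m)  # m - x <= 2a
            model.add_constraint({xi: 1, ai: -2}, upper=m)  # x - m <= 2a
            d = prior_by_cond[k].get(j)
            if d is not None and d != m:
                logger.warning(
                    "prior %+d on %s under %s conflicts with observation %+d; "
                    "prior wins",
                    d,
                    j,
                    k,
                    m,
                )

    # training-only edge-removal variables
    if mode == "training":
        for e in removable:
            reg.y[e.id] = model.add_binary(f"y[{e.id}]")

    # per-edge, per-condition machinery: z, product, support, C5/C6
    for e in removable:
        for k in conditions:
            zi = model.add_binary(f"z[{e.id},{k}]")
            reg.z[(e.id, k)] = zi
            up, um = reg.xp[(e.source, k)], reg.xm[(e.source, k)]
            dp, dm = reg.xp[(e.target, k)], reg.xm[(e.target, k)]
            p, w = linearize_product(model, up, um, dp, dm, tag=f"{e.id},{k}")
            reg.w[(e.id, k)] = w
            # C5: missing-edge constraints (Boolean product vs occurrence)
            coeffs = dict(p)
            coeffs[zi] = 1.0 if e.sign > 0 else -1.0
            model.add_constraint(coeffs, lower=-1, upper=1)
            # C6: occurring reaction needs a changed parent: 1 - z <= xp_u + xm_u
            model.add_constraint({up: 1, um: 1, zi: 1}, lower=1)
            # support indicators: edge delivers +/- signal and occurs
            deliver_pos = up if e.sign > 0 else um
            deliver_neg = um if e.sign > 0 else up
            pi = model.add_binary(f"pos[{e.id},{k}]")
            ni = model.add_binary(f"neg[{e.id},{k}]")
            reg.pos[(e.id, k)] = pi
            reg.neg[(e.id, k)] = ni
            model.add_constraint({pi: 1, deliver_pos: -1}, upper=0)
            model.add_constraint({pi: 1, zi: 1}, upper=1)
            model.add_constraint({ni: 1, deliver_neg: -1}, upper=0)
            model.add_constraint({ni: 1, zi: 1}, upper=1)
            if mode == "training":
                model.add_constraint({zi: 1, reg.y[e.id]: -1}, lower=0)  # Eq. z>=y
        if mode == "training":
            # kept edge must occur in some condition: sum_k z <= L - 1 + y
            coeffs = {reg.z[(e.id, k)]: 1.0 for k in conditions}
            coeffs[reg.y[e.id]] = -1.0
            model.add_constraint(coeffs, upper=len(conditions) - 1)

    # C4: linking-pattern support per child node
    in_removable: dict[str, list] = {}
    for e in removable:
        in_removable.setdefault(e.target, []).append(e)
    for k in conditions:
        pk = prior_by_cond[k]
        for n in sig_nodes:
            edges_in = in_removable.get(n.id)
            if not edges_in:
                continue  # root (or output-fed only): state free
            if exempt_prior_targets and n.id in pk:
                continue  # direct compound target: state set by the compound
            pos_coeffs = {reg.xp[(n.id, k)]: 1.0}
            neg_coeffs = {reg.xm[(n.id, k)]: 1.0}
            for e in edges_in:
                pos_coeffs[reg.pos[(e.id, k)]] = -1.0
                neg_coeffs[reg.neg[(e.id, k)]] = -1.0
            model.add_constraint(pos_coeffs, upper=0)
            model.add_constraint(neg_coeffs, upper=0)

    objective = {ai: 1.0 for ai in reg.a.values()}
    if mode == "training":
        for yi in reg.y.values():
            objective[yi] = objective.get(yi, 0.0) + gamma
    model.set_objective(objective)
    return TilpProblem(
        model=model,
        registry=reg,
        network=network,
        conditions=conditions,
        gamma=gamma,
        mode=mode,
        observed_pairs=observed_pairs,
    )


def build_training_problem(
    network: SignalingNetwork,
    profile: TernaryProfile,
    prior: PriorKnowledge | None = None,
    gamma: float | None = None,
    exempt_prior_targets: bool = True,
) -> TilpProblem:
    """Training program: infer node states, reaction occurrences and edge
    removals jointly over all conditions of ``profile``."""
    return _build(network, profile, prior, gamma, "training", exempt_prior_targets)


def build_prediction_problem(
    network: SignalingNetwork,
    profile: TernaryProfile,
    prior: PriorKnowledge | None = None,
    exempt_prior_targets: bool = True,
) -> TilpProblem:
    """Prediction program on a fixed (already pruned) topology: no removal
    variables, objective is the pure data-fit term."""
    return _build(network, profile, prior, None, "prediction", exempt_prior_targets)


def variable_accounting(problem: TilpProblem) -> dict:
    """Counts by domain and by variable family.

    Integer-domain variables are exactly the node states (one per node and
    condition); everything else is binary.
    """
    reg = problem.registry
    fam = reg.families()
    n_integer = fam["x"]
    n_binary = problem.model.n_vars - n_integer
    return {
        "integer": n_integer,
        "binary": n_binary,
        "total": problem.model.n_vars,
        "constraints": problem.model.n_constraints,
        "families": fam,
    }


def solve(
    problem: TilpProblem,
    backend: str = "highs",
    seed: int = 0,
    time_limit: float | None = None,
) -> TilpSolution:
    """Solve to proven optimality with the HiGHS branch-and-bound backend.

    HiGHS is deterministic for a fixed model; ``seed`` is recorded in run
    manifests for provenance but does not perturb the search.
    """
    if backend != "highs":
        raise RuntimeError(f"no MILP backend named {backend!r} is available")
    status, values, obj = problem.model.solve(time_limit=time_limit)
    if status != "optimal":
        return TilpSolution(status, values, math.nan, math.nan, math.nan)
    frac = np.abs(values - np.round(values))
    if frac.max(initial=0.0) > 1e-4:
        return TilpSolution("error", values, math.nan, math.nan, math.nan)
    values = np.round(values)
    reg = problem.registry
    fit = float(sum(values[i] for i in reg.a.values()))
    simplicity = float(sum(values[i] for i in reg.y.values()))
    objective = fit + problem.gamma * simplicity  # exact, from rounded values
    return TilpSolution("optimal", values, objective, fit, simplicity)
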