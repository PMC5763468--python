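"""Signed signaling-network data model and SIF/TSV input-output.

A network is a signed directed graph whose nodes carry a biological role:
ordinary signaling ``protein``, ``transcription_factor`` (TF) feeding a
cell-function readout, or ``output`` (the readout itself, e.g. "cell
growth").  Edges are activations (+1) or inhibitions (-1).  Edges into
output nodes encode the fixed arithmetic definition of the readout and are
never candidates for removal during inference; all other edges are.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable

ROLES = ("protein", "transcription_factor", "output")

_RELATION_TOKENS = {
    "1": 1,
    "+1": 1,
    "activates": 1,
    "-1": -1,
    "−1": -1,  # unicode minus
    "inhibits": -1,
}


class NetworkFormatError(ValueError):
    """Raised on malformed SIF/annotation input."""


@dataclass(frozen=True)
class Node:
    id: str
    role: str = "protein"
    observed: bool = False
    display_name: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for node {self.id!r}")


@dataclass(frozen=True)
class Edge:
    id: str
    source: str
    target: str
    sign: int
    removable: bool = True

    def __post_init__(self) -> None:
        if self.sign not in (-1, 1):
            raise ValueError(f"edge {self.id!r}: sign must be +1 or -1")

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.source, self.target, self.sign)


def _edge_id(source: str, target: str, sign: int) -> str:
    arrow = "->" if sign > 0 else "-|"
    return f"{source}{arrow}{target}"


@dataclass
class SignalingNetwork:
    """A signed directed graph with node roles.

    ``nodes`` and ``edges`` are kept in insertion order; helper accessors
    are recomputed on demand so that the object stays a plain container.
    """

    nodes: list[Node] = field(default_factory=list)
    edges: list[Edge] = field(default_factory=list)

    # -- accessors -------------------------------------------------------
    @property
    def node_map(self) -> dict[str, Node]:
        return {n.id: n for n in self.nodes}

    @property
    def output_nodes(self) -> list[Node]:
        return [n for n in self.nodes if n.role == "output"]

    @property
    def signaling_nodes(self) -> list[Node]:
        """Protein and TF nodes: the ones with free ternary states."""
        return [n for n in self.nodes if n.role != "output"]

    @property
    def observed_nodes(self) -> list[Node]:
        return [n for n in self.nodes if n.observed]

    @property
    def removable_edges(self) -> list[Edge]:
        return [e for e in self.edges if e.removable]

    def in_edges(self, node_id: str) -> list[Edge]:
        return [e for e in self.edges if e.target == node_id]

    def out_edges(self, node_id: str) -> list[Edge]:
        return [e for e in self.edges if e.source == node_id]

    def edge_by_id(self, edge_id: str) -> Edge:
        for e in self.edges:
            if e.id == edge_id:
                return e
        raise KeyError(edge_id)

    def root_nodes(self) -> list[Node]:
        targets = {e.target for e in self.edges}
        return [n for n in self.nodes if n.id not in targets]

    def output_definitions(self) -> dict[str, dict[str, int]]:
        """Signed TF coefficients per output node, from the TF->output edges."""
        defs: dict[str, dict[str, int]] = {}
        for out in self.output_nodes:
            defs[out.id] = {e.source: e.sign for e in self.in_edges(out.id)}
        return defs

    def without_edges(self, edge_ids: Iterable[str]) -> "SignalingNetwork":
        drop = set(edge_ids)
        return SignalingNetwork(
            nodes=list(self.nodes),
            edges=[e for e in self.edges if e.id not in drop],
        )


def _normalize_removable(nodes: list[Node], edges: list[Edge]) -> list[Edge]:
    """Force removable=False on edges into output nodes (fixed definitions)."""
    outputs = {n.id for n in nodes if n.role == "output"}
    return [
        replace(e, removable=False) if e.target in outputs else e for e in edges
    ]


def validate_network(network: SignalingNetwork) -> list[str]:
    """Check the structural invariants; violations are returned, not raised."""
    violations: list[str] = []
    seen_ids: set[str] = set()
    for n in network.nodes:
        if n.id in seen_ids:
            violations.append(f"node {n.id!r}: duplicate id")
        seen_ids.add(n.id)
    node_map = network.node_map
    outputs = {n.id for n in network.nodes if n.role == "output"}
    for n in network.nodes:
        if n.role == "output" and n.observed:
            violations.append(f"node {n.id!r}: output nodes must not be observed")
    seen_edge_ids: set[str] = set()
    seen_keys: set[tuple[str, str, int]] = set()
    for e in network.edges:
        if e.id in seen_edge_ids:
            violations.append(f"edge {e.id!r}: duplicate edge id")
        seen_edge_ids.add(e.id)
        if e.key in seen_keys:
            violations.append(f"edge {e.id!r}: duplicate (source, target, sign)")
        seen_keys.add(e.key)
        if e.source not in node_map:
            violations.append(f"edge {e.id!r}: missing source node {e.source!r}")
        if e.target not in node_map:
            violations.append(f"edge {e.id!r}: missing target node {e.target!r}")
        if e.source == e.target:
            violations.append(f"edge {e.id!r}: self-loop")
        if e.source in outputs:
            violations.append(f"edge {e.id!r}: output node has outgoing edge")
        if e.target in outputs and e.removable:
            violations.append(
                f"edge {e.id!r}: edges into output nodes must be non-removable"
            )
    # each TF feeding an output appears in exactly one output definition
    tf_uses: dict[str, int] = {}
    for e in network.edges:
        if e.target in outputs:
            tf_uses[e.source] = tf_uses.get(e.source, 0) + 1
            src = node_map.get(e.source)
            if src is not None and src.role == "output":
                continue
    for tf, count in tf_uses.items():
        if count > 1:
            violations.append(
                f"node {tf!r}: feeds {count} output definitions (must be exactly 1)"
            )
    return violations


def network_stats(network: SignalingNetwork) -> dict:
    """Aggregate counts used in reporting and fixture checks."""
    return {
        "n_nodes": len(network.nodes),
        "n_edges": len(network.edges),
        "n_observed": sum(1 for n in network.nodes if n.observed),
        "n_removable": sum(1 for e in network.edges if e.removable),
        "n_outputs": len(network.output_nodes),
        "n_activation": sum(1 for e in network.edges if e.sign > 0),
        "n_inhibition": sum(1 for e in network.edges if e.sign < 0),
        "root_nodes": sorted(n.id for n in network.root_nodes()),
    }


_TRUTHY = {"1", "true", "yes", "y"}
_FALSY = {"0", "false", "no", "n", ""}


def _parse_bool(token: str, where: str) -> bool:
    t = token.strip().lower()
    if t in _TRUTHY:
        return True
    if t in _FALSY:
        return False
    raise NetworkFormatError(f"{where}: cannot parse boolean {token!r}")


def _read_annotations(path: str | Path) -> dict[str, dict]:
    rows: dict[str, dict] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = {name: i for i, name in enumerate(header)}
        for required in ("id", "role", "observed"):
            if required not in cols:
                raise NetworkFormatError(
                    f"{path}: annotation header missing column {required!r}"
                )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            node_id = parts[cols["id"]].strip()
            role = parts[cols["role"]].strip() or "protein"
            if role == "tf":
                role = "transcription_factor"
            if role not in ROLES:
                raise NetworkFormatError(
                    f"{path}:{lineno}: unknown role {role!r}"
                )
            observed = _parse_bool(parts[cols["observed"]], f"{path}:{lineno}")
            isolated = False
            if "isolated" in cols and len(parts) > cols["isolated"]:
                isolated = _parse_bool(parts[cols["isolated"]], f"{path}:{lineno}")
            if node_id in rows:
                raise NetworkFormatError(f"{path}:{lineno}: duplicate id {node_id!r}")
            rows[node_id] = {"role": role, "observed": observed, "isolated": isolated}
    return rows


def read_sif(
    path: str | Path, annotations_path: str | Path | None = None
) -> SignalingNetwork:
    """Read a SIF edge list plus an optional node-annotation TSV.

    SIF lines are ``source <TAB> relation <TAB> target`` with relation one
    of ``1``, ``-1``, ``activates``, ``inhibits``.  Nodes appearing only in
    the SIF default to role ``protein``, unobserved.
    """
    node_order: list[str] = []
    seen_nodes: set[str] = set()
    edges: list[Edge] = []
    seen_keys: set[tuple[str, str, int]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise NetworkFormatError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, got {len(parts)}"
                )
            source, relation, target = (p.strip() for p in parts)
            if relation not in _RELATION_TOKENS:
                raise NetworkFormatError(
                    f"{path}:{lineno}: unknown relation token {relation!r}"
                )
            sign = _RELATION_TOKENS[relation]
            key = (source, target, sign)
            if key in seen_keys:
                raise NetworkFormatError(
                    f"{path}:{lineno}: duplicate edge {source}->{target} ({sign:+d})"
                )
            seen_keys.add(key)
            for nid in (source, target):
                if nid not in seen_nodes:
                    seen_nodes.add(nid)
                    node_order.append(nid)
            edges.append(Edge(_edge_id(source, target, sign), source, target, sign))

    annotations = _read_annotations(annotations_path) if annotations_path else {}
    for nid, ann in annotations.items():
        if nid not in seen_nodes:
            if not ann["isolated"]:
                raise NetworkFormatError(
                    f"annotation id {nid!r} absent from SIF and not declared isolated"
                )
            seen_nodes.add(nid)
            node_order.append(nid)

    nodes = [
        Node(
            nid,
            role=annotations.get(nid, {}).get("role", "protein"),
            observed=annotations.get(nid, {}).get("observed", False),
        )
        for nid in node_order
    ]
    edges = _normalize_removable(nodes, edges)
    network = SignalingNetwork(nodes=nodes, edges=edges)
    violations = validate_network(network)
    if violations:
        raise NetworkFormatError("; ".join(violations))
    return network


def write_sif(
    network: SignalingNetwork,
    path: str | Path,
    annotations_path: str | Path | None = None,
) -> None:
    """Write the edge list as SIF and, optionally, node annotations as TSV."""
    with open(path, "w") as fh:
        for e in network.edges:
            fh.write(f"{e.source}\t{e.sign}\t{e.target}\n")
    if annotations_path is not None:
        node_with_edges = {e.source for e in network.edges} | {
            e.target for e in network.edges
        }
        with open(annotations_path, "w") as fh:
            fh.write("id\trole\tobserved\tisolated\n")
            for n in network.nodes:
                isolated = int(n.id not in node_with_edges)
                fh.write(f"{n.id}\t{n.role}\t{int(n.observed)}\t{isolated}\n")


def build_network(
    edges: Iterable[tuple[str, int, str]],
    tf_nodes: Iterable[str] = (),
    output_nodes: Iterable[str] = (),
    observed: Iterable[str] = (),
) -> SignalingNetwork:
    """Convenience constructor from (source, sign, target) triples."""
    tf_set, out_set, obs_set = set(tf_nodes), set(output_nodes), set(observed)
    node_order: list[str] = []
    seen: set[str] = set()
    edge_objs: list[Edge] = []
    for source, sign, target in edges:
        for nid in (source, target):
            if nid not in seen:
                seen.add(nid)
                node_order.append(nid)
        edge_objs.append(Edge(_edge_id(source, target, sign), source, target, sign))
    for nid in itertools.chain(tf_set, out_set, obs_set):
        if nid not in seen:
            seen.add(nid)
            node_order.append(nid)
    nodes = []
    for nid in node_order:
        role = "output" if nid in out_set else (
            "transcription_factor" if nid in tf_set else "protein"
        )
        nodes.append(Node(nid, role=role, observed=nid in obs_set))
    edge_objs = _normalize_removable(nodes, edge_objs)
    return SignalingNetwork(nodes=nodes, edges=edge_objs)


def load_mcf7_map() -> SignalingNetwork:
    """Load the packaged breast-cancer (MCF7) generic pathway map fixture.

    The map covers the ER/SHC, EGFR, HER2, INSR, HDAC, MAPK, PI3K/AKT,
    HSP90 and AMPK pathways feeding four cell-function readouts; 15 of its
    signaling nodes are flagged as observed in the phosphoproteomic assay.
    """
    data = resources.files("tilp.data")
    with resources.as_file(data / "mcf7_map.sif") as sif_path, resources.as_file(
        data / "mcf7_nodes.tsv"
    ) as ann_path:
        return read_sif(sif_path, ann_path)
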