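"""Disease-focused mechanism subnetworks around a prioritized candidate.

Given an entity's diffusion profile, the subnetwork collects the entity's
protein targets, the top-k most heavily visited proteins and functions, and
the disease proteins among them; induces all multiscale-layer edges on that
node set plus the entity→target links; and then iteratively prunes entity
targets that have no edge to a disease-associated protein or to a retained
function, until the prune step is a fixed point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .diffusion import DiffusionProfile, TransitionSystem
from .network_model import DiseaseGeneSet, MultiscaleNetwork

logger = logging.getLogger(__name__)

ROLE_COMPOUND = "compound"
ROLE_TARGET = "target"
ROLE_DISEASE_PROTEIN = "disease_protein"
ROLE_FUNCTION = "function"
ROLE_DISEASE = "disease"


@dataclass
class SubnetworkConfig:
    """k_top: how many most-visited proteins/functions to pull in (jointly ranked)."""

    k_top: int = 20
    per_kind_quota: bool = False  # True: k_top proteins AND k_top functions

    def __post_init__(self) -> None:
        if self.k_top < 0:
            raise ValueError("k_top must be non-negative")


@dataclass
class Subnetwork:
    """Extracted mechanism subnetwork with role-labeled nodes."""

    focus: str
    nodes: dict[str, str] = field(default_factory=dict)  # node id -> role
    edges: set[tuple[str, str, str]] = field(default_factory=set)  # (a, b, layer)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for node, role in self.nodes.items():
            g.add_node(node, role=role)
        for a, b, layer in self.edges:
            g.add_edge(a, b, layer=layer)
        return g


def top_visited(
    profile: DiffusionProfile,
    ts: TransitionSystem,
    k_top: int,
    kinds: frozenset[str] | set[str] = frozenset({"protein", "function"}),
) -> list[str]:
    """The k most heavily visited nodes of the requested kinds.

    Sorted by visit probability descending with lexicographic ties.
    """
    candidates = [
        (float(-profile.r[i]), ts.node_index[i])
        for i in range(ts.n)
        if ts.node_kinds[i] in kinds
    ]
    candidates.sort()
    return [node for _, node in candidates[:k_top]]


def build_disease_subnetwork(
    entity_id: str,
    entity_kind: str,
    disease: DiseaseGeneSet,
    network: MultiscaleNetwork,
    entity_profile: DiffusionProfile,
    ts: TransitionSystem,
    config: SubnetworkConfig | None = None,
) -> Subnetwork:
    """Extract the mechanism subnetwork for one candidate entity.

    The top-k pool is ranked on the entity's own profile; disease proteins
    are overlaid afterwards.  Pruning removes entity targets whose only
    context is other targets — a retained target must touch a
    disease-associated protein or a retained function directly.
    """
    config = config or SubnetworkConfig()
    if entity_kind == "herb":
        targets = set(network.herb_targets.get(entity_id, []))
    elif entity_kind == "compound":
        targets = set(network.compound_targets.get(entity_id, set()))
    else:
        raise ValueError(f"unsupported focus kind {entity_kind!r}")

    if config.per_kind_quota:
        top = set(top_visited(entity_profile, ts, config.k_top, {"protein"}))
        top |= set(top_visited(entity_profile, ts, config.k_top, {"function"}))
    else:
        top = set(top_visited(entity_profile, ts, config.k_top))

    disease_proteins = set(disease.proteins)
    node_set = targets | top
    kind_of = {n: network.nodes[n].kind for n in node_set if n in network.nodes}

    # all multiscale-layer edges induced on the node set
    layer_edges: set[tuple[str, str, str]] = set()
    for layer_name in ("ppi", "protein_function", "function_hierarchy"):
        layer = network.layers.get(layer_name)
        if layer is None:
            continue
        for a, b in layer.pairs:
            if a in node_set and b in node_set:
                layer_edges.add((a, b, layer_name))

    functions_retained = {n for n, k in kind_of.items() if k == "function"}

    def disease_connected(target: str) -> bool:
        for a, b, _ in layer_edges:
            other = b if a == target else a if b == target else None
            if other is None:
                continue
            if other in disease_proteins or other in functions_retained:
                return True
        return False

    # iterative prune to fixed point (edges never change, so one pass suffices,
    # but the loop guards against future edge-dependent rules)
    current = set(targets)
    while True:
        drop = {
            t for t in current
            if t not in disease_proteins and not disease_connected(t)
        }
        if not drop:
            break
        current -= drop

    pruned = targets - current
    if pruned:
        logger.info("%s: pruned %d disconnected targets", entity_id, len(pruned))

    final_nodes = (node_set - pruned) | {entity_id, disease.disease_id}
    sub = Subnetwork(focus=entity_id)
    for node in final_nodes:
        if node == entity_id:
            role = ROLE_COMPOUND if entity_kind == "compound" else entity_kind
        elif node == disease.disease_id:
            role = ROLE_DISEASE
        elif node in disease_proteins:
            role = ROLE_DISEASE_PROTEIN
        elif kind_of.get(node) == "function":
            role = ROLE_FUNCTION
        else:
            role = ROLE_TARGET
        sub.nodes[node] = role
    for a, b, layer in layer_edges:
        if a in sub.nodes and b in sub.nodes:
            sub.edges.add((a, b, layer))
    for t in sorted(current):
        sub.edges.add((entity_id, t, "entity_target"))
    if not current and not top:
        logger.warning("%s: subnetwork empty after pruning", entity_id)
    return sub


def export_graphml(sub: Subnetwork, path: str | Path) -> None:
    nx.write_graphml(sub.to_graph(), str(path))


def export_tsv(sub: Subnetwork, nodes_path: str | Path, edges_path: str | Path) -> None:
    """Two-file TSV export: (node, role) and (source, target, layer)."""
    with Path(nodes_path).open("w", encoding="utf-8") as handle:
        handle.write("node\trole\n")
        for node in sorted(sub.nodes):
            handle.write(f"{node}\t{sub.nodes[node]}\n")
    with Path(edges_path).open("w", encoding="utf-8") as handle:
        handle.write("source\ttarget\tlayer\n")
        for a, b, layer in sorted(sub.edges):
            handle.write(f"{a}\t{b}\t{layer}\n")
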