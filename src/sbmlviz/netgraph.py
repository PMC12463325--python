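"""Reaction hypergraph construction.

Each reaction becomes a hyper-edge anchored at a dedicated *centroid* node;
species are ordinary nodes; every (species, reaction, role) participation is
one role-labeled edge between a species-like node and the centroid.  Hub
species that touch many reactions are split into alias nodes, and reactions
missing reactants or products gain emancipated "empty set" source/sink nodes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from .errors import ParameterError
from .types import Document, Role

__all__ = [
    "NodeKind",
    "NetworkNode",
    "NetworkEdge",
    "NetworkGraph",
    "build_graph",
    "add_emptyset_nodes",
    "create_aliases",
    "DEFAULT_ALIAS_THRESHOLD",
]

#: Edge count above which a species is split into aliases. Typical hub
#: metabolites (ATP, NADH, water) exceed this; pathway intermediates do not.
DEFAULT_ALIAS_THRESHOLD = 10

#: SBO terms marking modifier subtypes.
SBO_INHIBITOR = "SBO:0000020"
SBO_ACTIVATOR = "SBO:0000459"


@dataclass
class NetworkNode:
    node_id: str
    kind: str  # "species" | "centroid" | "emptyset"
    model_id: Optional[str] = None
    alias_index: int = 0
    width: float = 60.0
    height: float = 36.0


@dataclass
class NetworkEdge:
    edge_id: str
    species_node: str
    centroid_node: str
    role: Role
    stoichiometry: float = 1.0


@dataclass
class NetworkGraph:
    nodes: dict[str, NetworkNode] = field(default_factory=dict)
    edges: list[NetworkEdge] = field(default_factory=list)
    compartment_of: dict[str, str] = field(default_factory=dict)

    def add_node(self, node: NetworkNode, compartment: Optional[str] = None) -> None:
        self.nodes[node.node_id] = node
        if compartment is not None:
            self.compartment_of[node.node_id] = compartment

    def species_degree(self, node_id: str) -> int:
        return sum(1 for e in self.edges if e.species_node == node_id)

    def edges_of_centroid(self, centroid_id: str) -> list[NetworkEdge]:
        return [e for e in self.edges if e.centroid_node == centroid_id]

    def centroid_nodes(self) -> list[NetworkNode]:
        return [n for n in self.nodes.values() if n.kind == "centroid"]


#: Default node footprints (pt): species boxes vs small reaction centroids.
SPECIES_SIZE = (60.0, 36.0)
CENTROID_SIZE = (10.0, 10.0)


def _modifier_role(ref) -> Role:
    """Classify a modifier participation from its SBO term / annotation."""
    if ref.sbo_term == SBO_INHIBITOR or (ref.annotation_keyword or "").lower() == "inhibitor":
        return Role.INHIBITOR
    if ref.sbo_term == SBO_ACTIVATOR or (ref.annotation_keyword or "").lower() == "activator":
        return Role.ACTIVATOR
    return Role.MODIFIER


def build_graph(doc: Document) -> NetworkGraph:
    """Build the hypergraph: one node per species, one centroid per reaction,
    one role-labeled edge per listed participation, in model document order."""
    model = doc.model
    graph = NetworkGraph()
    for sp in model.species:
        graph.add_node(
            NetworkNode(
                node_id=sp.species_id,
                kind="species",
                model_id=sp.species_id,
                width=SPECIES_SIZE[0],
                height=SPECIES_SIZE[1],
            ),
            compartment=sp.compartment_id or None,
        )
    edge_counter = 0
    for rxn in model.reactions:
        centroid_id = f"centroid_{rxn.reaction_id}"
        comp = None
        for ref in rxn.reactants + rxn.products:
            sp = model.find_species(ref.species_id)
            if sp is not None and sp.compartment_id:
                comp = sp.compartment_id
                break
        graph.add_node(
            NetworkNode(
                node_id=centroid_id,
                kind="centroid",
                model_id=rxn.reaction_id,
                width=CENTROID_SIZE[0],
                height=CENTROID_SIZE[1],
            ),
            compartment=comp,
        )
        for ref in rxn.reactants:
            graph.edges.append(
                NetworkEdge(
                    edge_id=f"e{edge_counter}",
                    species_node=ref.species_id,
                    centroid_node=centroid_id,
                    role=Role.SUBSTRATE,
                    stoichiometry=ref.stoichiometry,
                )
            )
            edge_counter += 1
        for ref in rxn.products:
            graph.edges.append(
                NetworkEdge(
                    edge_id=f"e{edge_counter}",
                    species_node=ref.species_id,
                    centroid_node=centroid_id,
                    role=Role.PRODUCT,
                    stoichiometry=ref.stoichiometry,
                )
            )
            edge_counter += 1
        for ref in rxn.modifiers:
            graph.edges.append(
                NetworkEdge(
                    edge_id=f"e{edge_counter}",
                    species_node=ref.species_id,
                    centroid_node=centroid_id,
                    role=_modifier_role(ref),
                    stoichiometry=1.0,
                )
            )
            edge_counter += 1
    return graph


def add_emptyset_nodes(graph: NetworkGraph) -> NetworkGraph:
    """Give every reactant-less centroid a fresh ∅ source node (substrate edge)
    and every product-less centroid a fresh ∅ sink node; one node per deficit,
    never shared between reactions."""
    counter = 0
    for nid in list(graph.nodes):
        node = graph.nodes[nid]
        if node.kind != "centroid":
            continue
        incident = graph.edges_of_centroid(nid)
        has_sub = any(e.role.is_substrate_like for e in incident)
        has_prod = any(e.role.is_product_like for e in incident)
        for missing_role, present in ((Role.SUBSTRATE, has_sub), (Role.PRODUCT, has_prod)):
            if present:
                continue
            es_id = f"emptyset_{counter}"
            counter += 1
            graph.add_node(
                NetworkNode(node_id=es_id, kind="emptyset", width=28.0, height=28.0),
                compartment=graph.compartment_of.get(nid),
            )
            graph.edges.append(
                NetworkEdge(
                    edge_id=f"e_empty_{es_id}",
                    species_node=es_id,
                    centroid_node=nid,
                    role=missing_role,
                )
            )
    return graph


def balanced_partition_sizes(k: int, threshold: int) -> list[int]:
    """Sizes of the most even partition of k edges into ceil(k/threshold) parts."""
    m = math.ceil(k / threshold)
    base = k // m
    extra = k % m
    return [base + (1 if i < extra else 0) for i in range(m)]


def create_aliases(graph: NetworkGraph, degree_threshold: int = DEFAULT_ALIAS_THRESHOLD) -> NetworkGraph:
    """Split every species node with more than `degree_threshold` incident
    edges into ceil(k/threshold) alias nodes, partitioning its edges as evenly
    as possible (load difference ≤ 1) in input order.

    Empty-set nodes are excluded (each already serves a single reaction).
    Idempotent: a second pass at the same threshold changes nothing.
    """
    if degree_threshold < 1:
        raise ParameterError(f"degree_threshold must be ≥ 1, got {degree_threshold}")
    new_nodes: dict[str, NetworkNode] = {}
    for nid, node in graph.nodes.items():
        if node.kind != "species":
            new_nodes[nid] = node
            continue
        incident = [e for e in graph.edges if e.species_node == nid]
        k = len(incident)
        if k <= degree_threshold:
            new_nodes[nid] = node
            continue
        sizes = balanced_partition_sizes(k, degree_threshold)
        pos = 0
        for idx, size in enumerate(sizes):
            alias_id = nid if idx == 0 else f"{nid}_alias{idx}"
            alias = NetworkNode(
                node_id=alias_id,
                kind="species",
                model_id=node.model_id,
                alias_index=idx,
                width=node.width,
                height=node.height,
            )
            new_nodes[alias_id] = alias
            if nid in graph.compartment_of:
                graph.compartment_of[alias_id] = graph.compartment_of[nid]
            for e in incident[pos: pos + size]:
                e.species_node = alias_id
            pos += size
    graph.nodes = new_nodes
    return graph
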