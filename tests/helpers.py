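"""Shared test utilities: small model builders and independent oracles."""

from __future__ import annotations

import math

from sbmlviz.netgraph import NetworkEdge, NetworkGraph, NetworkNode
from sbmlviz.types import (
    Compartment,
    Document,
    Model,
    Reaction,
    Species,
    SpeciesReference,
    Role,
)


def build_doc(reactions, compartments=("cell",), species_compartment=None, modifier_sbo=None):
    """Build a Document from a compact reaction description.

    `reactions` is a list of (rid, reactant_ids, product_ids, modifier_ids).
    Species are collected automatically into the first compartment unless
    `species_compartment` maps them elsewhere.
    """
    species_compartment = species_compartment or {}
    modifier_sbo = modifier_sbo or {}
    model = Model(model_id="test")
    for cid in compartments:
        model.compartments.append(Compartment(compartment_id=cid))
    seen = []
    for _, reactants, products, modifiers in reactions:
        for sid in list(reactants) + list(products) + list(modifiers):
            if sid not in seen:
                seen.append(sid)
    for sid in seen:
        model.species.append(
            Species(species_id=sid,
                    compartment_id=species_compartment.get(sid, compartments[0]))
        )
    for rid, reactants, products, modifiers in reactions:
        model.reactions.append(
            Reaction(
                reaction_id=rid,
                reactants=[SpeciesReference(s) for s in reactants],
                products=[SpeciesReference(s) for s in products],
                modifiers=[SpeciesReference(s, sbo_term=modifier_sbo.get(s))
                           for s in modifiers],
            )
        )
    return Document(model=model)


def two_node_graph():
    """Minimal single-edge hypergraph: one species, one centroid."""
    g = NetworkGraph()
    g.add_node(NetworkNode("A", "species"))
    g.add_node(NetworkNode("c", "centroid", model_id="R"))
    g.edges.append(NetworkEdge("e0", "A", "c", Role.SUBSTRATE))
    return g


def fr_step_reference(graph, pos, temperature, params):
    """Brute-force reference of the documented force model, plain Python loops.

    Pair repulsion k²/d, edge attraction d²/k, compartment pull at the
    configured weight, displacement capped at the temperature, positions
    clamped to the padded canvas.  Independent of the vectorized engine.
    """
    from sbmlviz.autolayout import ideal_edge_length

    nodes = list(graph.nodes)
    n = len(nodes)
    w, h = params.canvas_for(n)
    pad = params.padding
    k = ideal_edge_length(params, n)
    disp = {nid: [0.0, 0.0] for nid in nodes}
    for a in nodes:
        for b in nodes:
            if a == b:
                continue
            dx = pos[a].x - pos[b].x
            dy = pos[a].y - pos[b].y
            d2 = dx * dx + dy * dy
            disp[a][0] += dx * (k * k) / d2
            disp[a][1] += dy * (k * k) / d2
    for e in graph.edges:
        u, v = e.species_node, e.centroid_node
        ex = pos[v].x - pos[u].x
        ey = pos[v].y - pos[u].y
        d = math.hypot(ex, ey)
        disp[u][0] += ex * d / k
        disp[u][1] += ey * d / k
        disp[v][0] -= ex * d / k
        disp[v][1] -= ey * d / k
    groups = {}
    for nid, comp in graph.compartment_of.items():
        if nid in graph.nodes:
            groups.setdefault(comp, []).append(nid)
    for members in groups.values():
        if len(members) < 2:
            continue
        cx = sum(pos[m].x for m in members) / len(members)
        cy = sum(pos[m].y for m in members) / len(members)
        for m in members:
            gx = cx - pos[m].x
            gy = cy - pos[m].y
            gd = math.hypot(gx, gy)
            disp[m][0] += params.compartment_weight * gx * gd / k
            disp[m][1] += params.compartment_weight * gy * gd / k
    out = {}
    for nid in nodes:
        dx, dy = disp[nid]
        length = math.hypot(dx, dy)
        f = min(1.0, temperature / length) if length > 0 else 0.0
        out[nid] = (
            min(max(pos[nid].x + dx * f, pad), max(w - pad, pad)),
            min(max(pos[nid].y + dy * f, pad), max(h - pad, pad)),
        )
    return out


def balanced_partition_reference(k, threshold):
    """Independent balanced ceiling-division partition: greedy round-robin
    assignment of k items to ceil(k/threshold) bins."""
    m = -(-k // threshold)
    bins = [0] * m
    for i in range(k):
        bins[i % m] += 1
    return sorted(bins, reverse=True)
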