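"""Force-directed auto-layout with biochemistry-aware heuristics.

The placement stage adapts the classical Fruchterman–Reingold simulation:
pairwise repulsion k²/d, attraction d²/k along hypergraph edges, per-node
displacement capped by a linearly cooling temperature, with the ideal edge
length k = k_scale·sqrt(canvas_area / node_count).  Reaction centroids take
part as ordinary (small) nodes.  A weak pull (0.1 × edge attraction) toward
each node's compartment centroid keeps multi-compartment models separable.

On top of the raw positions come the reaction-aware finishing passes:

* UniUni reactions (one reactant, one product) are straightened — the
  centroid snaps to the reactant–product midpoint and the curves degenerate
  to exact straight segments.
* Role-aware Bézier curves: substrate arcs enter the centroid from the
  half-plane facing the substrate mass-center, product arcs from the opposite
  half-plane, modifiers perpendicular to the substrate→product axis; within a
  role class the tangents are fanned evenly by edge count.
* Attachment points on a species boundary are redistributed until pairwise
  angular separation reaches a congestion threshold.

Everything is deterministic given the seed: node iteration follows model
document order and all randomness flows from one seeded generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ParameterError, ValidationError
from .io import fit_dimensions
from .netgraph import (
    DEFAULT_ALIAS_THRESHOLD,
    NetworkGraph,
    add_emptyset_nodes,
    build_graph,
    create_aliases,
)
from .types import (
    BoundingBox,
    CompartmentGlyph,
    CurveSegment,
    Document,
    Layout,
    Point,
    ReactionGlyph,
    Role,
    SpeciesGlyph,
    SpeciesReferenceGlyph,
    TextGlyph,
)

__all__ = [
    "LayoutParams",
    "PositionMap",
    "place_initial",
    "fr_step",
    "run_force_layout",
    "straighten_uniuni",
    "generate_curves",
    "build_layout",
    "rebuild_reaction_curves",
]

PositionMap = dict[str, Point]


@dataclass
class LayoutParams:
    """Tunable parameters of the layout pipeline.

    `canvas_width`/`canvas_height` of None auto-size the canvas to the node
    count; `initial_temperature` of None defaults to canvas_width / 10.
    """

    iterations: int = 50
    seed: int = 0
    canvas_width: Optional[float] = None
    canvas_height: Optional[float] = None
    k_scale: float = 1.0
    initial_temperature: Optional[float] = None
    padding: float = 20.0
    alias_threshold: int = DEFAULT_ALIAS_THRESHOLD
    species_size: tuple[float, float] = (60.0, 36.0)
    centroid_size: tuple[float, float] = (10.0, 10.0)
    congestion_min_angle_deg: float = 15.0
    compartment_weight: float = 0.1
    regenerate: bool = True

    def validate(self) -> None:
        if self.iterations < 0:
            raise ParameterError("iterations must be ≥ 0")
        if self.k_scale <= 0:
            raise ParameterError("k_scale must be > 0")
        if self.canvas_width is not None and self.canvas_width <= 0:
            raise ParameterError("canvas width must be positive")
        if self.canvas_height is not None and self.canvas_height <= 0:
            raise ParameterError("canvas height must be positive")
        if self.alias_threshold < 1:
            raise ParameterError("alias_threshold must be ≥ 1")

    def canvas_for(self, n_nodes: int) -> tuple[float, float]:
        if self.canvas_width is not None and self.canvas_height is not None:
            return (self.canvas_width, self.canvas_height)
        side = max(500.0, math.ceil(math.sqrt(max(n_nodes, 1)) * 90.0))
        return (self.canvas_width or side, self.canvas_height or side)

    def temperature_for(self, canvas_width: float) -> float:
        if self.initial_temperature is not None:
            return self.initial_temperature
        return canvas_width / 10.0


def ideal_edge_length(params: LayoutParams, n_nodes: int) -> float:
    """k = k_scale · sqrt(canvas_area / node_count)."""
    w, h = params.canvas_for(n_nodes)
    return params.k_scale * math.sqrt(w * h / max(n_nodes, 1))


# ---------------------------------------------------------------------------
# Force simulation
# ---------------------------------------------------------------------------

def place_initial(graph: NetworkGraph, params: LayoutParams) -> PositionMap:
    """Seeded uniform positions over the padded canvas.

    Alias nodes of a split species are then pulled to the mean initial
    position of their partner centroids so each alias starts near the
    reactions it serves (this is what makes aliasing reduce crossings).
    """
    params.validate()
    nodes = list(graph.nodes.values())
    n = len(nodes)
    width, height = params.canvas_for(n)
    pad = params.padding
    rng = np.random.default_rng(params.seed)
    xs = pad + rng.random(n) * max(width - 2 * pad, 1.0)
    ys = pad + rng.random(n) * max(height - 2 * pad, 1.0)
    pos: PositionMap = {
        node.node_id: Point(float(x), float(y)) for node, x, y in zip(nodes, xs, ys)
    }

    # aliases start at the mean position of their partitioned centroids
    by_model: dict[str, list] = {}
    for node in nodes:
        if node.kind == "species" and node.model_id is not None:
            by_model.setdefault(node.model_id, []).append(node)
    for group in by_model.values():
        if len(group) < 2:
            continue
        for node in group:
            partners = [e.centroid_node for e in graph.edges if e.species_node == node.node_id]
            if partners:
                mx = sum(pos[c].x for c in partners) / len(partners)
                my = sum(pos[c].y for c in partners) / len(partners)
                pos[node.node_id] = Point(mx, my)
    return pos


def _force_arrays(graph: NetworkGraph, pos: PositionMap):
    nodes = list(graph.nodes)
    index = {nid: i for i, nid in enumerate(nodes)}
    xy = np.array([[pos[nid].x, pos[nid].y] for nid in nodes], dtype=np.float64)
    return nodes, index, xy


def fr_step(
    graph: NetworkGraph,
    pos: PositionMap,
    temperature: float,
    params: LayoutParams,
) -> PositionMap:
    """One synchronous Fruchterman–Reingold iteration.

    Coincident nodes are separated by a deterministic ε-jitter (1e-4 pt,
    directions from the seeded generator) before forces are evaluated.
    """
    if temperature < 0:
        raise ParameterError("temperature must be ≥ 0")
    nodes, index, xy = _force_arrays(graph, pos)
    n = len(nodes)
    if n == 0:
        return {}
    width, height = params.canvas_for(n)
    pad = params.padding
    k = ideal_edge_length(params, n)

    work = xy
    if n > 1:
        dx = work[:, 0][:, None] - work[:, 0][None, :]
        dy = work[:, 1][:, None] - work[:, 1][None, :]
        dist2 = dx * dx + dy * dy
        off_diag = ~np.eye(n, dtype=bool)
        if np.any(dist2[off_diag] < 1e-24):
            rng = np.random.default_rng(params.seed + 9173)
            jitter = rng.standard_normal((n, 2)) * 1e-4
            work = xy + jitter
            dx = work[:, 0][:, None] - work[:, 0][None, :]
            dy = work[:, 1][:, None] - work[:, 1][None, :]
            dist2 = dx * dx + dy * dy
        np.fill_diagonal(dist2, 1.0)  # excluded from forces anyway
        inv = (k * k) / dist2
        np.fill_diagonal(inv, 0.0)
        disp_x = np.sum(dx * inv, axis=1)
        disp_y = np.sum(dy * inv, axis=1)
    else:
        disp_x = np.zeros(1)
        disp_y = np.zeros(1)

    # attraction along hypergraph edges: |f| = d²/k
    if graph.edges:
        ui = np.array([index[e.species_node] for e in graph.edges])
        vi = np.array([index[e.centroid_node] for e in graph.edges])
        ex = work[vi, 0] - work[ui, 0]
        ey = work[vi, 1] - work[ui, 1]
        d = np.sqrt(ex * ex + ey * ey)
        scale = d / k  # (d²/k) / d, applied to the delta vector
        np.add.at(disp_x, ui, ex * scale)
        np.add.at(disp_y, ui, ey * scale)
        np.add.at(disp_x, vi, -ex * scale)
        np.add.at(disp_y, vi, -ey * scale)

    # weak pull toward the compartment's running centroid
    if params.compartment_weight > 0 and graph.compartment_of:
        groups: dict[str, list[int]] = {}
        for nid, comp in graph.compartment_of.items():
            if nid in index:
                groups.setdefault(comp, []).append(index[nid])
        for members in groups.values():
            if len(members) < 2:
                continue
            idxs = np.array(members)
            cx = float(np.mean(work[idxs, 0]))
            cy = float(np.mean(work[idxs, 1]))
            gx = cx - work[idxs, 0]
            gy = cy - work[idxs, 1]
            gd = np.sqrt(gx * gx + gy * gy)
            gscale = params.compartment_weight * gd / k
            disp_x[idxs] += gx * gscale
            disp_y[idxs] += gy * gscale

    # cap displacement at the temperature, then clamp to the canvas
    length = np.sqrt(disp_x * disp_x + disp_y * disp_y)
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = np.where(length > 0, np.minimum(1.0, temperature / np.where(length > 0, length, 1.0)), 0.0)
    new_x = np.clip(xy[:, 0] + disp_x * factor, pad, max(width - pad, pad))
    new_y = np.clip(xy[:, 1] + disp_y * factor, pad, max(height - pad, pad))
    return {nid: Point(float(new_x[i]), float(new_y[i])) for i, nid in enumerate(nodes)}


def run_force_layout(graph: NetworkGraph, params: LayoutParams) -> PositionMap:
    """place_initial followed by `iterations` cooling fr_steps."""
    params.validate()
    pos = place_initial(graph, params)
    if params.iterations == 0:
        return pos
    width, _ = params.canvas_for(len(graph.nodes))
    t0 = params.temperature_for(width)
    for i in range(params.iterations):
        t = t0 * (params.iterations - i) / params.iterations
        pos = fr_step(graph, pos, t, params)
    return pos


# ---------------------------------------------------------------------------
# Reaction-aware finishing
# ---------------------------------------------------------------------------

def _uniuni_centroids(graph: NetworkGraph) -> dict[str, tuple[str, str]]:
    """Centroid id → (substrate species node, product species node) for every
    one-substrate/one-product reaction (modifier edges permitted)."""
    out = {}
    for node in graph.centroid_nodes():
        subs = [e for e in graph.edges if e.centroid_node == node.node_id
                and e.role.is_substrate_like]
        prods = [e for e in graph.edges if e.centroid_node == node.node_id
                 and e.role.is_product_like]
        if len(subs) == 1 and len(prods) == 1:
            out[node.node_id] = (subs[0].species_node, prods[0].species_node)
    return out


def straighten_uniuni(graph: NetworkGraph, pos: PositionMap) -> PositionMap:
    """Snap every UniUni centroid onto its reactant–product midpoint."""
    new_pos = dict(pos)
    for centroid, (s_node, p_node) in _uniuni_centroids(graph).items():
        sp = pos[s_node]
        pp = pos[p_node]
        new_pos[centroid] = Point((sp.x + pp.x) / 2.0, (sp.y + pp.y) / 2.0)
    return new_pos


def _rotate(vx: float, vy: float, deg: float) -> tuple[float, float]:
    rad = math.radians(deg)
    c, s = math.cos(rad), math.sin(rad)
    return (vx * c - vy * s, vx * s + vy * c)


def _ellipse_boundary(center: Point, w: float, h: float, angle: float) -> Point:
    """Boundary point of the inscribed ellipse in direction `angle` (radians)."""
    ca, sa = math.cos(angle), math.sin(angle)
    a = max(w / 2.0, 1e-9)
    b = max(h / 2.0, 1e-9)
    r = 1.0 / math.sqrt((ca / a) ** 2 + (sa / b) ** 2)
    return Point(center.x + r * ca, center.y + r * sa)


def _spread_angles(angles: list[float], min_sep_deg: float) -> list[float]:
    """Minimally rotate angles apart until pairwise separation ≥ min_sep.

    Angles in degrees; circular.  If the demand exceeds the circle the points
    are spaced evenly instead.  Returns angles in input order.
    """
    n = len(angles)
    if n <= 1:
        return list(angles)
    if min_sep_deg * n > 360.0:
        min_sep_deg = 360.0 / n
    order = sorted(range(n), key=lambda i: (angles[i] % 360.0, i))
    vals = [angles[i] % 360.0 for i in order]
    for _ in range(200):
        moved = False
        for j in range(n):
            a = vals[j]
            b = vals[(j + 1) % n] + (360.0 if j + 1 == n else 0.0)
            gap = b - a
            if gap < min_sep_deg - 1e-9:
                push = (min_sep_deg - gap) / 2.0
                vals[j] -= push
                if j + 1 == n:
                    vals[0] += push
                else:
                    vals[j + 1] += push
                moved = True
        if not moved:
            break
    out = [0.0] * n
    for rank, i in enumerate(order):
        out[i] = vals[rank] % 360.0
    return out


def _centroid_tangents(graph: NetworkGraph, pos: PositionMap) -> dict[str, tuple[float, float]]:
    """Assign each edge a unit tangent direction at its centroid.

    Substrate arcs share the half-plane facing the substrate mass-center,
    product arcs the opposite half-plane, modifiers enter perpendicular to the
    substrate→product axis; within a role class the slots are fanned evenly.
    Returns edge_id → (ux, uy), pointing from the centroid toward the arc.
    """
    tangents: dict[str, tuple[float, float]] = {}
    for node in graph.centroid_nodes():
        cid = node.node_id
        incident = [e for e in graph.edges if e.centroid_node == cid]
        subs = [e for e in incident if e.role.is_substrate_like]
        prods = [e for e in incident if e.role.is_product_like]
        mods = [e for e in incident if e.role.is_modifier_like]
        c = pos[cid]

        def mass_center(edges):
            if not edges:
                return None
            mx = sum(pos[e.species_node].x for e in edges) / len(edges)
            my = sum(pos[e.species_node].y for e in edges) / len(edges)
            return (mx, my)

        sbar = mass_center(subs)
        pbar = mass_center(prods)
        if sbar is not None and pbar is not None:
            ux, uy = pbar[0] - sbar[0], pbar[1] - sbar[1]
        elif pbar is not None:
            ux, uy = pbar[0] - c.x, pbar[1] - c.y
        elif sbar is not None:
            ux, uy = c.x - sbar[0], c.y - sbar[1]
        else:
            ux, uy = 1.0, 0.0
        norm = math.hypot(ux, uy)
        if norm < 1e-12:
            ux, uy = 1.0, 0.0
        else:
            ux, uy = ux / norm, uy / norm
        px, py = -uy, ux  # perpendicular

        def fan(edges, base, max_step=30.0, span=80.0):
            m = len(edges)
            if m == 0:
                return
            step = min(max_step, span / m)
            for i, e in enumerate(edges):
                offset = (i - (m - 1) / 2.0) * step
                tangents[e.edge_id] = _rotate(base[0], base[1], offset)

        fan(subs, (-ux, -uy))
        fan(prods, (ux, uy))
        # modifiers alternate sides of the axis, fanned within each side
        left = [e for i, e in enumerate(mods) if i % 2 == 0]
        right = [e for i, e in enumerate(mods) if i % 2 == 1]
        fan(left, (px, py), max_step=25.0, span=50.0)
        fan(right, (-px, -py), max_step=25.0, span=50.0)
    return tangents


def generate_curves(
    graph: NetworkGraph,
    pos: PositionMap,
    params: LayoutParams,
) -> dict[str, list[CurveSegment]]:
    """One cubic Bézier per edge, species boundary → centroid center.

    UniUni substrate/product arcs degenerate to exact straight segments
    (their control points coincide with the endpoints).
    """
    tangents = _centroid_tangents(graph, pos)
    uniuni = _uniuni_centroids(graph)

    # species-side attachment angles with congestion redistribution
    by_species: dict[str, list] = {}
    for e in graph.edges:
        by_species.setdefault(e.species_node, []).append(e)
    attach_angle: dict[str, float] = {}
    for nid, edges in by_species.items():
        sp = pos[nid]
        raw = []
        for e in edges:
            cp = pos[e.centroid_node]
            raw.append(math.degrees(math.atan2(cp.y - sp.y, cp.x - sp.x)))
        spread = _spread_angles(raw, params.congestion_min_angle_deg)
        for e, ang in zip(edges, spread):
            attach_angle[e.edge_id] = ang

    curves: dict[str, list[CurveSegment]] = {}
    for e in graph.edges:
        s_node = graph.nodes[e.species_node]
        sp = pos[e.species_node]
        cp = pos[e.centroid_node]
        ang = math.radians(attach_angle[e.edge_id])
        start = _ellipse_boundary(sp, s_node.width, s_node.height, ang)
        end = Point(cp.x, cp.y)
        is_straight = (
            e.centroid_node in uniuni
            and (e.role.is_substrate_like or e.role.is_product_like)
        )
        if is_straight:
            seg = CurveSegment(
                start=start,
                end=end,
                base_point_1=Point(start.x, start.y),
                base_point_2=Point(end.x, end.y),
            )
        else:
            chord = math.hypot(end.x - start.x, end.y - start.y)
            third = chord / 3.0
            out_dir = (math.cos(ang), math.sin(ang))
            tang = tangents.get(e.edge_id, (-out_dir[0], -out_dir[1]))
            seg = CurveSegment(
                start=start,
                end=end,
                base_point_1=Point(start.x + out_dir[0] * third, start.y + out_dir[1] * third),
                base_point_2=Point(end.x + tang[0] * third, end.y + tang[1] * third),
            )
        curves[e.edge_id] = [seg]
    return curves


# ---------------------------------------------------------------------------
# Glyph emission
# ---------------------------------------------------------------------------

def species_glyph_id(node_id: str) -> str:
    return node_id if node_id.startswith("emptyset_") else f"sg_{node_id}"


def build_layout(doc: Document, params: Optional[LayoutParams] = None) -> Document:
    """Full pipeline: hypergraph → empty-set nodes → aliases → force layout →
    UniUni straightening → curves → glyph emission.

    Every species (including aliases) receives a SpeciesGlyph and a TextGlyph,
    every reaction a ReactionGlyph with its reference-glyph curves, every
    compartment a CompartmentGlyph sized to the padded extent of its members.
    An existing layout is replaced only when ``params.regenerate`` is set.
    """
    if doc.model is None:
        raise ValidationError("document has no model")
    params = params or LayoutParams()
    params.validate()
    if doc.layout is not None and not params.regenerate:
        return doc

    graph = build_graph(doc)
    graph = add_emptyset_nodes(graph)
    graph = create_aliases(graph, params.alias_threshold)
    pos = run_force_layout(graph, params)
    pos = straighten_uniuni(graph, pos)
    curves = generate_curves(graph, pos, params)

    layout = Layout(layout_id="sbmlviz_layout", width=0.0, height=0.0)

    for node in graph.nodes.values():
        if node.kind == "centroid":
            continue
        gid = species_glyph_id(node.node_id)
        bbox = BoundingBox.centered(pos[node.node_id], node.width, node.height)
        layout.species_glyphs.append(
            SpeciesGlyph(
                glyph_id=gid,
                species_id=node.model_id,
                bbox=bbox,
                alias_index=node.alias_index,
            )
        )
        if node.kind == "species":
            sp = doc.model.find_species(node.model_id)
            label = (sp.name if sp is not None and sp.name else node.model_id)
            layout.text_glyphs.append(
                TextGlyph(
                    glyph_id=f"tg_{gid}",
                    target_glyph_id=gid,
                    text=label,
                    bbox=BoundingBox(bbox.x, bbox.y, bbox.width, bbox.height),
                )
            )

    edges_by_centroid: dict[str, list] = {}
    for e in graph.edges:
        edges_by_centroid.setdefault(e.centroid_node, []).append(e)
    for node in graph.centroid_nodes():
        rxn_id = node.model_id
        rg = ReactionGlyph(
            glyph_id=f"rg_{rxn_id}",
            reaction_id=rxn_id,
            center_bbox=BoundingBox.centered(pos[node.node_id], node.width, node.height),
        )
        for i, e in enumerate(edges_by_centroid.get(node.node_id, [])):
            segs = curves[e.edge_id]
            if e.role.is_product_like:
                segs = [s.reversed() for s in segs]
            rg.reference_glyphs.append(
                SpeciesReferenceGlyph(
                    glyph_id=f"srg_{rxn_id}_{i}",
                    species_glyph_id=species_glyph_id(e.species_node),
                    role=e.role,
                    curve=segs,
                )
            )
        layout.reaction_glyphs.append(rg)

    _emit_compartment_glyphs(doc, graph, layout, params)
    _shift_nonnegative(layout, params.padding)
    fit_dimensions(layout, params.padding)

    doc.layout = layout
    return doc


def _emit_compartment_glyphs(doc, graph, layout, params) -> None:
    pad = params.padding
    members: dict[str, list[BoundingBox]] = {c.compartment_id: [] for c in doc.model.compartments}
    glyph_boxes = {g.glyph_id: g.bbox for g in layout.species_glyphs}
    for node in graph.nodes.values():
        comp = graph.compartment_of.get(node.node_id)
        if comp is None or comp not in members:
            continue
        if node.kind == "centroid":
            rg = layout.find_reaction_glyph_by_reaction(node.model_id)
            if rg is not None:
                members[comp].append(rg.center_bbox)
        else:
            bbox = glyph_boxes.get(species_glyph_id(node.node_id))
            if bbox is not None:
                members[comp].append(bbox)
    for comp in doc.model.compartments:
        boxes = members.get(comp.compartment_id, [])
        if boxes:
            min_x = min(b.x for b in boxes) - pad
            min_y = min(b.y for b in boxes) - pad
            max_x = max(b.x + b.width for b in boxes) + pad
            max_y = max(b.y + b.height for b in boxes) + pad
            bbox = BoundingBox(min_x, min_y, max_x - min_x, max_y - min_y)
        else:
            bbox = BoundingBox(pad, pad, 100.0, 100.0)
        layout.compartment_glyphs.append(
            CompartmentGlyph(
                glyph_id=f"cg_{comp.compartment_id}",
                compartment_id=comp.compartment_id,
                bbox=bbox,
            )
        )


def _shift_nonnegative(layout: Layout, padding: float) -> None:
    """Translate everything so the minimum coordinate sits at `padding`."""
    min_x = math.inf
    min_y = math.inf
    for g in layout.all_glyphs():
        bbox = g.center_bbox if isinstance(g, ReactionGlyph) else g.bbox
        min_x = min(min_x, bbox.x)
        min_y = min(min_y, bbox.y)
    if not math.isfinite(min_x):
        return
    dx = padding - min_x
    dy = padding - min_y
    if dx == 0.0 and dy == 0.0:
        return
    translate_layout(layout, dx, dy)


def translate_layout(layout: Layout, dx: float, dy: float) -> None:
    for g in layout.all_glyphs():
        bbox = g.center_bbox if isinstance(g, ReactionGlyph) else g.bbox
        bbox.x += dx
        bbox.y += dy
    for rg in layout.reaction_glyphs:
        for srg in rg.reference_glyphs:
            for seg in srg.curve:
                for pt in (seg.start, seg.end, seg.base_point_1, seg.base_point_2):
                    if pt is not None:
                        pt.x += dx
                        pt.y += dy


# ---------------------------------------------------------------------------
# Local (per-reaction) curve regeneration used by arrangement edits
# ---------------------------------------------------------------------------

def rebuild_reaction_curves(doc: Document, reaction_glyph: ReactionGlyph,
                            params: Optional[LayoutParams] = None) -> None:
    """Regenerate the reference-glyph curves of one reaction from the current
    glyph positions, using the same role-aware tangent rules as the global
    pass (attachment redistribution is local to this reaction)."""
    params = params or LayoutParams()
    layout = doc.layout
    center = reaction_glyph.center_bbox.center

    parts = []
    for srg in reaction_glyph.reference_glyphs:
        sg = layout.find_species_glyph(srg.species_glyph_id)
        if sg is None:
            continue
        parts.append((srg, sg))

    subs = [(srg, sg) for srg, sg in parts if srg.role.is_substrate_like]
    prods = [(srg, sg) for srg, sg in parts if srg.role.is_product_like]
    mods = [(srg, sg) for srg, sg in parts if srg.role.is_modifier_like]
    is_uniuni = len(subs) == 1 and len(prods) == 1

    def mass_center(group):
        if not group:
            return None
        return (
            sum(sg.bbox.center.x for _, sg in group) / len(group),
            sum(sg.bbox.center.y for _, sg in group) / len(group),
        )

    sbar, pbar = mass_center(subs), mass_center(prods)
    if sbar is not None and pbar is not None:
        ux, uy = pbar[0] - sbar[0], pbar[1] - sbar[1]
    elif pbar is not None:
        ux, uy = pbar[0] - center.x, pbar[1] - center.y
    elif sbar is not None:
        ux, uy = center.x - sbar[0], center.y - sbar[1]
    else:
        ux, uy = 1.0, 0.0
    norm = math.hypot(ux, uy)
    ux, uy = (1.0, 0.0) if norm < 1e-12 else (ux / norm, uy / norm)
    px, py = -uy, ux

    tangent: dict[int, tuple[float, float]] = {}

    def fan(group, base, max_step=30.0, span=80.0):
        m = len(group)
        if m == 0:
            return
        step = min(max_step, span / m)
        for i, (srg, _) in enumerate(group):
            tangent[id(srg)] = _rotate(base[0], base[1], (i - (m - 1) / 2.0) * step)

    fan(subs, (-ux, -uy))
    fan(prods, (ux, uy))
    fan([m for i, m in enumerate(mods) if i % 2 == 0], (px, py), 25.0, 50.0)
    fan([m for i, m in enumerate(mods) if i % 2 == 1], (-px, -py), 25.0, 50.0)

    for srg, sg in parts:
        sc = sg.bbox.center
        ang = math.atan2(center.y - sc.y, center.x - sc.x)
        start = _ellipse_boundary(sc, sg.bbox.width, sg.bbox.height, ang)
        end = Point(center.x, center.y)
        straight = is_uniuni and (srg.role.is_substrate_like or srg.role.is_product_like)
        if straight:
            seg = CurveSegment(start, end, Point(start.x, start.y), Point(end.x, end.y))
        else:
            chord = math.hypot(end.x - start.x, end.y - start.y)
            third = chord / 3.0
            out_dir = (math.cos(ang), math.sin(ang))
            tang = tangent.get(id(srg), (-out_dir[0], -out_dir[1]))
            seg = CurveSegment(
                start,
                end,
                Point(start.x + out_dir[0] * third, start.y + out_dir[1] * third),
                Point(end.x + tang[0] * third, end.y + tang[1] * third),
            )
        if srg.role.is_product_like:
            seg = seg.reversed()
        srg.curve = [seg]
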