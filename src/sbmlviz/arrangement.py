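"""Post-layout geometric editing.

Angle convention for arcs: 0° points up (12 o'clock), positive angles run
clockwise, all in the y-down screen coordinates of the layout — the way
pathway maps such as the TCA cycle are conventionally read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .autolayout import rebuild_reaction_curves
from .errors import ParameterError, UnknownElementError
from .io import fit_dimensions
from .types import BoundingBox, Document, Point, ReactionGlyph, SpeciesReferenceGlyph

__all__ = [
    "ArcSpec",
    "align_reaction",
    "arrange_reactions_circle",
    "move_species_glyph",
]


@dataclass
class ArcSpec:
    center: Point
    radius: float
    start_angle: float = 0.0  # degrees, 0 = up
    direction: str = "clockwise"  # "clockwise" | "counterclockwise"
    span: float = 360.0  # degrees in (0, 360]

    def validate(self) -> None:
        if self.radius <= 0:
            raise ParameterError("arc radius must be > 0")
        if not (0.0 < self.span <= 360.0):
            raise ParameterError("arc span must be in (0, 360]")
        if self.direction not in ("clockwise", "counterclockwise"):
            raise ParameterError(f"unknown direction {self.direction!r}")

    def point_at(self, angle_deg: float) -> Point:
        """Position on the arc at `angle_deg` (0 = up, clockwise positive)."""
        rad = math.radians(angle_deg)
        return Point(
            self.center.x + self.radius * math.sin(rad),
            self.center.y - self.radius * math.cos(rad),
        )


def _require_layout(doc: Document) -> None:
    if doc.layout is None:
        raise ParameterError("document has no layout; run build_layout first")


def _find_reaction_glyph(doc: Document, reaction_id: str) -> ReactionGlyph:
    rg = doc.layout.find_reaction_glyph_by_reaction(reaction_id)
    if rg is None:
        available = ", ".join(g.reaction_id for g in doc.layout.reaction_glyphs)
        raise UnknownElementError(
            f"unknown reaction {reaction_id!r}; available reactions: {available}")
    return rg


def _main_refs(rg: ReactionGlyph) -> tuple[SpeciesReferenceGlyph, SpeciesReferenceGlyph]:
    """First-listed substrate and product reference glyphs."""
    sub = next((s for s in rg.reference_glyphs if s.role.is_substrate_like), None)
    prod = next((s for s in rg.reference_glyphs if s.role.is_product_like), None)
    if sub is None or prod is None:
        raise ParameterError(
            f"reaction glyph {rg.glyph_id!r} lacks a substrate or product to align")
    return sub, prod


def _recenter_species(doc: Document, glyph_id: str, new_center: Point) -> None:
    sg = doc.layout.find_species_glyph(glyph_id)
    if sg is None:
        raise UnknownElementError(f"unknown species glyph {glyph_id!r}")
    sg.bbox = BoundingBox.centered(new_center, sg.bbox.width, sg.bbox.height)
    text = doc.layout.find_text_glyph_for(glyph_id)
    if text is not None:
        text.bbox = BoundingBox(sg.bbox.x, sg.bbox.y, sg.bbox.width, sg.bbox.height)


def align_reaction(doc: Document, reaction_id: str, orientation: str) -> Document:
    """Make the main substrate, centroid and main product collinear on a
    horizontal or vertical line through the centroid, preserving the current
    substrate–product chord length.  Curves of this reaction are regenerated;
    nothing else moves."""
    _require_layout(doc)
    if orientation not in ("horizontal", "vertical"):
        raise ParameterError(f"orientation must be horizontal or vertical, got {orientation!r}")
    rg = _find_reaction_glyph(doc, reaction_id)
    sub, prod = _main_refs(rg)
    sub_glyph = doc.layout.find_species_glyph(sub.species_glyph_id)
    prod_glyph = doc.layout.find_species_glyph(prod.species_glyph_id)
    c = rg.center_bbox.center
    s_c = sub_glyph.bbox.center
    p_c = prod_glyph.bbox.center
    half = math.hypot(p_c.x - s_c.x, p_c.y - s_c.y) / 2.0
    if half == 0.0:
        half = 50.0
    if orientation == "horizontal":
        # keep the substrate on the side it already occupies (ties: left)
        sign = -1.0 if s_c.x <= p_c.x else 1.0
        new_s = Point(c.x + sign * half, c.y)
        new_p = Point(c.x - sign * half, c.y)
    else:
        sign = -1.0 if s_c.y <= p_c.y else 1.0
        new_s = Point(c.x, c.y + sign * half)
        new_p = Point(c.x, c.y - sign * half)
    _recenter_species(doc, sub_glyph.glyph_id, new_s)
    _recenter_species(doc, prod_glyph.glyph_id, new_p)
    rebuild_reaction_curves(doc, rg)
    fit_dimensions(doc.layout)
    return doc


def arrange_reactions_circle(doc: Document, reaction_ids: list[str], arc: ArcSpec) -> Document:
    """Place reaction centroids on a circular arc at equal angular spacing,
    chaining consecutive reactions through their shared main species.

    Main substrates/products sit on the arc a half-step before/after their
    centroid; when reaction i's main product species equals reaction i+1's
    main substrate species the two reference glyphs share a single merged
    species glyph at the boundary angle.
    """
    _require_layout(doc)
    if not reaction_ids:
        raise ParameterError("reaction id list is empty")
    if len(set(reaction_ids)) != len(reaction_ids):
        dupes = sorted({r for r in reaction_ids if reaction_ids.count(r) > 1})
        raise ParameterError(f"duplicate reaction ids: {', '.join(dupes)}")
    arc.validate()
    glyphs = [_find_reaction_glyph(doc, rid) for rid in reaction_ids]
    n = len(glyphs)
    full_circle = arc.span >= 360.0
    if n == 1:
        step = 0.0
    elif full_circle:
        step = arc.span / n
    else:
        step = arc.span / (n - 1)
    sign = 1.0 if arc.direction == "clockwise" else -1.0
    half = step / 2.0 if n > 1 else 45.0

    merged: dict[str, str] = {}  # replaced glyph id -> surviving glyph id
    placements: list[tuple[ReactionGlyph, float]] = []
    for i, rg in enumerate(glyphs):
        angle = arc.start_angle + sign * step * i
        c = arc.point_at(angle)
        rg.center_bbox = BoundingBox.centered(c, rg.center_bbox.width, rg.center_bbox.height)
        placements.append((rg, angle))

    layout = doc.layout
    for i, (rg, angle) in enumerate(placements):
        sub, prod = _main_refs(rg)
        sub_gid = merged.get(sub.species_glyph_id, sub.species_glyph_id)
        sub.species_glyph_id = sub_gid
        _recenter_species(doc, sub_gid, arc.point_at(angle - sign * half))
        _recenter_species(doc, prod.species_glyph_id, arc.point_at(angle + sign * half))

        # merge with the next reaction's main substrate if species match
        if i + 1 < len(placements) or (full_circle and n > 1):
            nxt_rg, _ = placements[(i + 1) % n]
            if nxt_rg is rg:
                continue
            nxt_sub, _ = _main_refs(nxt_rg)
            prod_glyph = layout.find_species_glyph(prod.species_glyph_id)
            nxt_gid = merged.get(nxt_sub.species_glyph_id, nxt_sub.species_glyph_id)
            nxt_glyph = layout.find_species_glyph(nxt_gid)
            if (
                prod_glyph is not None
                and nxt_glyph is not None
                and prod_glyph.glyph_id != nxt_glyph.glyph_id
                and prod_glyph.species_id is not None
                and prod_glyph.species_id == nxt_glyph.species_id
            ):
                _merge_species_glyphs(doc, keep=prod_glyph.glyph_id, drop=nxt_glyph.glyph_id)
                merged[nxt_glyph.glyph_id] = prod_glyph.glyph_id

    for rg, _ in placements:
        rebuild_reaction_curves(doc, rg)
    fit_dimensions(layout)
    return doc


def _merge_species_glyphs(doc: Document, keep: str, drop: str) -> None:
    """Retarget every reference from `drop` to `keep`, then delete `drop`
    and its text glyph.  Never leaves dangling references."""
    layout = doc.layout
    for rg in layout.reaction_glyphs:
        for srg in rg.reference_glyphs:
            if srg.species_glyph_id == drop:
                srg.species_glyph_id = keep
    layout.text_glyphs = [t for t in layout.text_glyphs if t.target_glyph_id != drop]
    layout.species_glyphs = [g for g in layout.species_glyphs if g.glyph_id != drop]


def move_species_glyph(doc: Document, glyph_id: str, new_center: Point) -> Document:
    """Recenter one species glyph; its text glyph follows and curves of the
    incident reactions re-attach.  Nothing else moves."""
    _require_layout(doc)
    sg = doc.layout.find_species_glyph(glyph_id)
    if sg is None:
        raise UnknownElementError(f"unknown species glyph {glyph_id!r}")
    _recenter_species(doc, glyph_id, new_center)
    for rg in doc.layout.reaction_glyphs:
        if any(srg.species_glyph_id == glyph_id for srg in rg.reference_glyphs):
            rebuild_reaction_curves(doc, rg)
    fit_dimensions(doc.layout)
    return doc
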