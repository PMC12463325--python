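"""In-memory data model mirroring SBML core plus the Layout and Render packages.

Coordinate convention: origin at the top-left, y grows downward, units are
layout points (pt) — the convention shared by the SBML Layout package and SVG.
Bounding boxes are (origin, width, height).

Render primitive coordinates (rectangle/ellipse/polygon/curve anchors) are
stored on the 0..100 "percent of bounding box" scale used by the Render
package's relative coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Union

__all__ = [
    "Point",
    "BoundingBox",
    "CurveSegment",
    "Role",
    "SpeciesGlyph",
    "SpeciesReferenceGlyph",
    "ReactionGlyph",
    "CompartmentGlyph",
    "TextGlyph",
    "GraphicalObject",
    "Layout",
    "ColorDefinition",
    "GradientStop",
    "LinearGradient",
    "RectanglePrimitive",
    "EllipsePrimitive",
    "PolygonPrimitive",
    "RenderCurvePrimitive",
    "RenderGroup",
    "LineEnding",
    "Style",
    "RenderInfo",
    "Compartment",
    "Species",
    "SpeciesReference",
    "Reaction",
    "Model",
    "Document",
    "EMPTYSET_PREFIX",
]

#: Reserved id/metaid prefix for emancipated (model-free) source/sink glyphs.
EMPTYSET_PREFIX = "emptyset_"


@dataclass
class Point:
    x: float
    y: float

    def is_finite(self) -> bool:
        return math.isfinite(self.x) and math.isfinite(self.y)

    def __iter__(self):
        yield self.x
        yield self.y


@dataclass
class BoundingBox:
    x: float
    y: float
    width: float
    height: float

    @property
    def center(self) -> Point:
        return Point(self.x + self.width / 2.0, self.y + self.height / 2.0)

    def contains(self, other: "BoundingBox", tol: float = 1e-9) -> bool:
        return (
            other.x >= self.x - tol
            and other.y >= self.y - tol
            and other.x + other.width <= self.x + self.width + tol
            and other.y + other.height <= self.y + self.height + tol
        )

    @staticmethod
    def centered(center: Point, width: float, height: float) -> "BoundingBox":
        return BoundingBox(center.x - width / 2.0, center.y - height / 2.0, width, height)


@dataclass
class CurveSegment:
    """A line segment (no base points) or cubic Bézier (both base points)."""

    start: Point
    end: Point
    base_point_1: Optional[Point] = None
    base_point_2: Optional[Point] = None

    @property
    def is_cubic(self) -> bool:
        return self.base_point_1 is not None and self.base_point_2 is not None

    def reversed(self) -> "CurveSegment":
        return CurveSegment(
            start=self.end,
            end=self.start,
            base_point_1=self.base_point_2,
            base_point_2=self.base_point_1,
        )


class Role(str, Enum):
    """Biochemical role of a species-reference arc."""

    SUBSTRATE = "substrate"
    PRODUCT = "product"
    SIDE_SUBSTRATE = "sidesubstrate"
    SIDE_PRODUCT = "sideproduct"
    MODIFIER = "modifier"
    ACTIVATOR = "activator"
    INHIBITOR = "inhibitor"
    UNDEFINED = "undefined"

    @property
    def is_substrate_like(self) -> bool:
        return self in (Role.SUBSTRATE, Role.SIDE_SUBSTRATE)

    @property
    def is_product_like(self) -> bool:
        return self in (Role.PRODUCT, Role.SIDE_PRODUCT)

    @property
    def is_modifier_like(self) -> bool:
        return self in (Role.MODIFIER, Role.ACTIVATOR, Role.INHIBITOR, Role.UNDEFINED)


@dataclass
class SpeciesGlyph:
    glyph_id: str
    species_id: Optional[str]  # None for emancipated (empty-set) glyphs
    bbox: BoundingBox
    alias_index: int = 0


@dataclass
class SpeciesReferenceGlyph:
    glyph_id: str
    species_glyph_id: str
    role: Role
    curve: list[CurveSegment] = field(default_factory=list)


@dataclass
class ReactionGlyph:
    glyph_id: str
    reaction_id: str
    center_bbox: BoundingBox
    reference_glyphs: list[SpeciesReferenceGlyph] = field(default_factory=list)


@dataclass
class CompartmentGlyph:
    glyph_id: str
    compartment_id: str
    bbox: BoundingBox


@dataclass
class TextGlyph:
    glyph_id: str
    target_glyph_id: str
    text: str
    bbox: BoundingBox


@dataclass
class GraphicalObject:
    """A layout element with no model counterpart (color bar, decorations)."""

    glyph_id: str
    bbox: BoundingBox
    metaid: Optional[str] = None


@dataclass
class Layout:
    layout_id: str
    width: float
    height: float
    compartment_glyphs: list[CompartmentGlyph] = field(default_factory=list)
    species_glyphs: list[SpeciesGlyph] = field(default_factory=list)
    reaction_glyphs: list[ReactionGlyph] = field(default_factory=list)
    text_glyphs: list[TextGlyph] = field(default_factory=list)
    additional_objects: list[GraphicalObject] = field(default_factory=list)

    # -- lookup helpers -------------------------------------------------
    def all_glyphs(self):
        yield from self.compartment_glyphs
        yield from self.species_glyphs
        yield from self.reaction_glyphs
        yield from self.text_glyphs
        yield from self.additional_objects

    def all_glyph_ids(self) -> list[str]:
        ids = [g.glyph_id for g in self.all_glyphs()]
        for rg in self.reaction_glyphs:
            ids.extend(srg.glyph_id for srg in rg.reference_glyphs)
        return ids

    def find_species_glyph(self, glyph_id: str) -> Optional[SpeciesGlyph]:
        for g in self.species_glyphs:
            if g.glyph_id == glyph_id:
                return g
        return None

    def species_glyphs_of(self, species_id: str) -> list[SpeciesGlyph]:
        return [g for g in self.species_glyphs if g.species_id == species_id]

    def find_reaction_glyph_by_reaction(self, reaction_id: str) -> Optional[ReactionGlyph]:
        for g in self.reaction_glyphs:
            if g.reaction_id == reaction_id:
                return g
        return None

    def find_text_glyph_for(self, target_glyph_id: str) -> Optional[TextGlyph]:
        for t in self.text_glyphs:
            if t.target_glyph_id == target_glyph_id:
                return t
        return None


# ---------------------------------------------------------------------------
# Render package types
# ---------------------------------------------------------------------------

@dataclass
class ColorDefinition:
    color_id: str
    value: str  # "#RRGGBB" or "#RRGGBBAA", uppercase canonical


@dataclass
class GradientStop:
    offset: float  # fraction in [0, 1]
    color: str  # hex value or color-definition id


@dataclass
class LinearGradient:
    gradient_id: str
    stops: list[GradientStop]
    # endpoints as percent of the filled box; default left-to-right
    x1: float = 0.0
    y1: float = 0.0
    x2: float = 100.0
    y2: float = 0.0


@dataclass
class RectanglePrimitive:
    # percent-of-bbox coordinates
    x: float = 0.0
    y: float = 0.0
    width: float = 100.0
    height: float = 100.0
    rx: float = 0.0  # corner radii, absolute pt
    ry: float = 0.0


@dataclass
class EllipsePrimitive:
    cx: float = 50.0
    cy: float = 50.0
    rx: float = 50.0
    ry: float = 50.0


@dataclass
class PolygonPrimitive:
    points: list[tuple[float, float]] = field(default_factory=list)


@dataclass
class RenderCurvePrimitive:
    """Open polyline/curve inside the bbox frame (percent coordinates)."""

    points: list[tuple[float, float]] = field(default_factory=list)


Primitive = Union[RectanglePrimitive, EllipsePrimitive, PolygonPrimitive, RenderCurvePrimitive]


@dataclass
class RenderGroup:
    stroke: Optional[str] = None  # hex, color id, or gradient id
    stroke_width: float = 1.0
    stroke_dasharray: Optional[list[float]] = None
    fill: Optional[str] = None
    font_family: str = "sans-serif"
    font_size: float = 11.0
    font_weight: str = "normal"
    text_anchor: str = "middle"
    start_head: Optional[str] = None  # LineEnding ids
    end_head: Optional[str] = None
    primitives: list[Primitive] = field(default_factory=list)

    def copy(self) -> "RenderGroup":
        g = replace(self)
        g.primitives = [replace(p) for p in self.primitives]
        for p in g.primitives:
            if isinstance(p, (PolygonPrimitive, RenderCurvePrimitive)):
                p.points = list(p.points)
        if self.stroke_dasharray is not None:
            g.stroke_dasharray = list(self.stroke_dasharray)
        return g


@dataclass
class LineEnding:
    ending_id: str
    bbox: BoundingBox  # frame relative to the anchored curve end
    group: RenderGroup
    rotational_mapping: bool = True


#: Render-spec element type names usable in Style.type_list.
GLYPH_TYPE_NAMES = (
    "COMPARTMENTGLYPH",
    "SPECIESGLYPH",
    "REACTIONGLYPH",
    "SPECIESREFERENCEGLYPH",
    "TEXTGLYPH",
    "GRAPHICALOBJECT",
    "ANY",
)


@dataclass
class Style:
    style_id: str
    group: RenderGroup
    role_list: list[str] = field(default_factory=list)
    type_list: list[str] = field(default_factory=list)
    id_list: list[str] = field(default_factory=list)

    @property
    def is_default(self) -> bool:
        return not (self.role_list or self.type_list or self.id_list)


@dataclass
class RenderInfo:
    render_id: str = "renderInfo"
    background_color: str = "#FFFFFF"
    colors: list[ColorDefinition] = field(default_factory=list)
    gradients: list[LinearGradient] = field(default_factory=list)
    line_endings: list[LineEnding] = field(default_factory=list)
    styles: list[Style] = field(default_factory=list)

    def find_color(self, color_id: str) -> Optional[ColorDefinition]:
        for c in self.colors:
            if c.color_id == color_id:
                return c
        return None

    def find_gradient(self, gradient_id: str) -> Optional[LinearGradient]:
        for g in self.gradients:
            if g.gradient_id == gradient_id:
                return g
        return None

    def find_line_ending(self, ending_id: str) -> Optional[LineEnding]:
        for e in self.line_endings:
            if e.ending_id == ending_id:
                return e
        return None


# ---------------------------------------------------------------------------
# SBML core model (the subset layout generation needs)
# ---------------------------------------------------------------------------

@dataclass
class Compartment:
    compartment_id: str
    name: Optional[str] = None


@dataclass
class Species:
    species_id: str
    compartment_id: str
    name: Optional[str] = None
    sbo_term: Optional[str] = None
    sbgn_class: Optional[str] = None  # explicit SBGN PD class annotation


@dataclass
class SpeciesReference:
    species_id: str
    stoichiometry: float = 1.0
    sbo_term: Optional[str] = None  # carries activator/inhibitor for modifiers
    annotation_keyword: Optional[str] = None


@dataclass
class Reaction:
    reaction_id: str
    reactants: list[SpeciesReference] = field(default_factory=list)
    products: list[SpeciesReference] = field(default_factory=list)
    modifiers: list[SpeciesReference] = field(default_factory=list)
    reversible: bool = False
    name: Optional[str] = None
    sbo_term: Optional[str] = None
    sbgn_class: Optional[str] = None


@dataclass
class Model:
    model_id: str
    compartments: list[Compartment] = field(default_factory=list)
    species: list[Species] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)

    def find_species(self, species_id: str) -> Optional[Species]:
        for s in self.species:
            if s.species_id == species_id:
                return s
        return None

    def find_reaction(self, reaction_id: str) -> Optional[Reaction]:
        for r in self.reactions:
            if r.reaction_id == reaction_id:
                return r
        return None

    def find_compartment(self, compartment_id: str) -> Optional[Compartment]:
        for c in self.compartments:
            if c.compartment_id == compartment_id:
                return c
        return None


@dataclass
class Document:
    """An SBML model with optional Layout and Render sections.

    The single unit every sbmlviz operation consumes and produces.
    """

    model: Model
    layout: Optional[Layout] = None
    render: Optional[RenderInfo] = None
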