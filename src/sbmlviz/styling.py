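"""Style generation and editing.

Covers the named-HTML-color table, automatic default styles, the predefined
templates (default / SBGN Process Description / Escher-like), effective-style
resolution with a documented cascade, and group/batch editing.

Cascade precedence (total order, highest wins):
    id-selector  >  role-selector  >  type-selector  >  default style
Among styles at the same tier, the one added latest wins.  This makes
overlays and batch edits pure overrides: removing the id-selector styles
restores the previous rendering exactly.
"""

from __future__ import annotations

import difflib
import json
from dataclasses import dataclass, field
from typing import Optional, Union

from matplotlib.colors import CSS4_COLORS

from .autolayout import rebuild_reaction_curves
from .errors import CapabilityError, ParameterError, UnknownColorError, UnknownElementError
from .io import HEX_COLOR_RE
from .types import (
    BoundingBox,
    ColorDefinition,
    Document,
    EllipsePrimitive,
    LineEnding,
    PolygonPrimitive,
    RectanglePrimitive,
    RenderCurvePrimitive,
    RenderGroup,
    RenderInfo,
    Role,
    Style,
)

__all__ = [
    "HTML_COLORS",
    "resolve_color",
    "default_render",
    "apply_template",
    "sbgn_style_for_class",
    "StyleRecipe",
    "StyleTemplate",
    "load_template",
    "register_template",
    "select_elements",
    "batch_set",
    "effective_group",
    "element_kind",
    "SBGN_CLASSES",
]

#: The 148 standard HTML/CSS color names with their hex codes (uppercase).
HTML_COLORS: dict[str, str] = {name: value.upper() for name, value in CSS4_COLORS.items()}


def resolve_color(name: str) -> str:
    """Resolve an HTML color name or hex string to canonical uppercase hex.

    Lookup is case-insensitive over the 148 standard names; unknown names
    raise :class:`UnknownColorError` listing the nearest matches.
    """
    if name.startswith("#"):
        canonical = name.upper()
        if not HEX_COLOR_RE.match(canonical):
            raise UnknownColorError(name, [])
        return canonical
    key = name.strip().lower()
    if key in HTML_COLORS:
        return HTML_COLORS[key]
    suggestions = difflib.get_close_matches(key, HTML_COLORS.keys(), n=3)
    raise UnknownColorError(name, suggestions)


# ---------------------------------------------------------------------------
# Element classification (for style selectors)
# ---------------------------------------------------------------------------

def element_kind(doc: Document) -> dict[str, tuple[str, Optional[str]]]:
    """Map every layout element id to (render type name, role-or-None).

    Emancipated species glyphs (no model reference) classify as
    GRAPHICALOBJECT, matching how they are serialized.
    """
    out: dict[str, tuple[str, Optional[str]]] = {}
    layout = doc.layout
    if layout is None:
        return out
    for g in layout.compartment_glyphs:
        out[g.glyph_id] = ("COMPARTMENTGLYPH", None)
    for g in layout.species_glyphs:
        kind = "SPECIESGLYPH" if g.species_id is not None else "GRAPHICALOBJECT"
        out[g.glyph_id] = (kind, None)
    for rg in layout.reaction_glyphs:
        out[rg.glyph_id] = ("REACTIONGLYPH", None)
        for srg in rg.reference_glyphs:
            out[srg.glyph_id] = ("SPECIESREFERENCEGLYPH", srg.role.value)
    for t in layout.text_glyphs:
        out[t.glyph_id] = ("TEXTGLYPH", None)
    for g in layout.additional_objects:
        out[g.glyph_id] = ("GRAPHICALOBJECT", None)
    return out


def _style_tier(style: Style, element_id: str, type_name: str, role: Optional[str]) -> int:
    """-1 if the style does not match, else its cascade tier."""
    if element_id in style.id_list:
        return 3
    if role is not None and role in style.role_list:
        return 2
    if type_name in style.type_list or "ANY" in style.type_list:
        return 1
    if style.is_default:
        return 0
    return -1


def _matching_style_with_kinds(doc: Document, kinds, element_id: str) -> Optional[Style]:
    if element_id not in kinds or doc.render is None:
        return None
    type_name, role = kinds[element_id]
    best: Optional[Style] = None
    best_key = (-1, -1)
    for idx, style in enumerate(doc.render.styles):
        tier = _style_tier(style, element_id, type_name, role)
        if tier >= 0 and (tier, idx) > best_key:
            best, best_key = style, (tier, idx)
    return best


def matching_style(doc: Document, element_id: str) -> Optional[Style]:
    """Highest-precedence style matching the element (None if uncovered)."""
    return _matching_style_with_kinds(doc, element_kind(doc), element_id)


def effective_group(doc: Document, element_id: str) -> Optional[RenderGroup]:
    style = matching_style(doc, element_id)
    return style.group if style is not None else None


def make_style_resolver(doc: Document):
    """Effective-group lookup with the element index computed once.

    The returned callable is only valid while layout topology and the style
    list are unchanged apart from appends.
    """
    kinds = element_kind(doc)

    def resolve(element_id: str) -> Optional[RenderGroup]:
        style = _matching_style_with_kinds(doc, kinds, element_id)
        return style.group if style is not None else None

    return resolve


# ---------------------------------------------------------------------------
# Line endings (arrowheads)
# ---------------------------------------------------------------------------

def _ending(ending_id: str, group: RenderGroup) -> LineEnding:
    return LineEnding(
        ending_id=ending_id,
        bbox=BoundingBox(-12.0, -6.0, 12.0, 12.0),
        group=group,
        rotational_mapping=True,
    )


def standard_line_endings() -> dict[str, LineEnding]:
    """Arrowhead vocabulary: filled/open triangles, bar, circle, diamond."""
    return {
        "arrow_filled": _ending(
            "arrow_filled",
            RenderGroup(stroke="#000000", fill="#000000",
                        primitives=[PolygonPrimitive([(0.0, 0.0), (100.0, 50.0), (0.0, 100.0)])]),
        ),
        "arrow_open": _ending(
            "arrow_open",
            RenderGroup(stroke="#000000", fill="#FFFFFF",
                        primitives=[PolygonPrimitive([(0.0, 0.0), (100.0, 50.0), (0.0, 100.0)])]),
        ),
        "inhibit_bar": _ending(
            "inhibit_bar",
            RenderGroup(stroke="#000000", fill="#000000",
                        primitives=[RectanglePrimitive(x=80.0, y=0.0, width=20.0, height=100.0)]),
        ),
        "open_circle": _ending(
            "open_circle",
            RenderGroup(stroke="#000000", fill="#FFFFFF",
                        primitives=[EllipsePrimitive(cx=50.0, cy=50.0, rx=45.0, ry=45.0)]),
        ),
        "open_diamond": _ending(
            "open_diamond",
            RenderGroup(stroke="#000000", fill="#FFFFFF",
                        primitives=[PolygonPrimitive(
                            [(0.0, 50.0), (50.0, 0.0), (100.0, 50.0), (50.0, 100.0)])]),
        ),
    }


# ---------------------------------------------------------------------------
# Default render information
# ---------------------------------------------------------------------------

def default_render(doc: Document) -> Document:
    """Attach the automatic RenderInfo: role-based arc styles (product arcs
    end in a filled triangle, inhibitors in a bar, activators in an open
    circle) plus type-based node styles.  Replaces any previous render block.
    """
    if doc.layout is None:
        raise ParameterError("document has no layout; run build_layout first")
    render = RenderInfo(render_id="defaultRender", background_color="#FFFFFF")
    render.colors = [
        ColorDefinition("black", "#000000"),
        ColorDefinition("white", "#FFFFFF"),
    ]
    render.line_endings = list(standard_line_endings().values())
    render.styles = [
        Style("default", RenderGroup(stroke="#000000", stroke_width=1.0, fill="none")),
        Style(
            "species_default",
            RenderGroup(stroke="#D6B656", stroke_width=2.0, fill="#FFF2CC",
                        primitives=[RectanglePrimitive(rx=6.0, ry=6.0)]),
            type_list=["SPECIESGLYPH"],
        ),
        Style(
            "reaction_default",
            RenderGroup(stroke="#000000", stroke_width=1.0, fill="#FFFFFF",
                        primitives=[EllipsePrimitive()]),
            type_list=["REACTIONGLYPH"],
        ),
        Style(
            "compartment_default",
            RenderGroup(stroke="#C8C8C8", stroke_width=2.0, fill="none",
                        primitives=[RectanglePrimitive(rx=12.0, ry=12.0)]),
            type_list=["COMPARTMENTGLYPH"],
        ),
        Style(
            "text_default",
            RenderGroup(stroke="#000000", stroke_width=1.0, font_family="sans-serif",
                        font_size=11.0, text_anchor="middle"),
            type_list=["TEXTGLYPH"],
        ),
        Style(
            "emptyset_default",
            RenderGroup(stroke="#000000", stroke_width=1.5, fill="none",
                        primitives=[EllipsePrimitive(cx=50.0, cy=50.0, rx=40.0, ry=40.0),
                                    RenderCurvePrimitive([(15.0, 85.0), (85.0, 15.0)])]),
            type_list=["GRAPHICALOBJECT"],
        ),
        Style(
            "substrate_arc",
            RenderGroup(stroke="#000000", stroke_width=1.5, fill="none"),
            role_list=[Role.SUBSTRATE.value, Role.SIDE_SUBSTRATE.value],
        ),
        Style(
            "product_arc",
            RenderGroup(stroke="#000000", stroke_width=1.5, fill="none",
                        end_head="arrow_filled"),
            role_list=[Role.PRODUCT.value, Role.SIDE_PRODUCT.value],
        ),
        Style(
            "modifier_arc",
            RenderGroup(stroke="#000000", stroke_width=1.2, fill="none",
                        stroke_dasharray=[4.0, 3.0]),
            role_list=[Role.MODIFIER.value, Role.UNDEFINED.value],
        ),
        Style(
            "activator_arc",
            RenderGroup(stroke="#000000", stroke_width=1.2, fill="none",
                        end_head="open_circle"),
            role_list=[Role.ACTIVATOR.value],
        ),
        Style(
            "inhibitor_arc",
            RenderGroup(stroke="#000000", stroke_width=1.2, fill="none",
                        end_head="inhibit_bar"),
            role_list=[Role.INHIBITOR.value],
        ),
    ]
    doc.render = render
    return doc


# ---------------------------------------------------------------------------
# SBGN Process Description
# ---------------------------------------------------------------------------

SBGN_CLASSES = (
    "macromolecule",
    "simple-chemical",
    "nucleic-acid-feature",
    "complex",
    "source-and-sink",
    "process",
    "association",
    "dissociation",
    "compartment",
    "consumption",
    "production",
    "catalysis",
    "inhibition",
    "stimulation",
    "modulation",
)

#: SBO term → SBGN PD class (the standard carriers of SBGN semantics in SBML).
SBGN_SBO_MAP = {
    "SBO:0000245": "macromolecule",
    "SBO:0000247": "simple-chemical",
    "SBO:0000253": "complex",
    "SBO:0000354": "nucleic-acid-feature",
    "SBO:0000291": "source-and-sink",
    "SBO:0000375": "process",
    "SBO:0000177": "association",
    "SBO:0000180": "dissociation",
}

_ROLE_TO_SBGN_ARC = {
    Role.SUBSTRATE: "consumption",
    Role.SIDE_SUBSTRATE: "consumption",
    Role.PRODUCT: "production",
    Role.SIDE_PRODUCT: "production",
    Role.MODIFIER: "modulation",
    Role.ACTIVATOR: "stimulation",
    Role.INHIBITOR: "inhibition",
    Role.UNDEFINED: "modulation",
}


@dataclass
class StyleRecipe:
    """A class-level style: render attributes plus an optional node size."""

    group: RenderGroup
    node_size: Optional[tuple[float, float]] = None
    is_arc: bool = False
    required_endings: list[str] = field(default_factory=list)


def sbgn_style_for_class(cls: str) -> StyleRecipe:
    """The predefined recipe for one SBGN PD class (node shape or arc head)."""
    white, black = "#FFFFFF", "#000000"
    if cls == "macromolecule":
        return StyleRecipe(RenderGroup(stroke=black, stroke_width=2.0, fill="#E0F0E0",
                                       primitives=[RectanglePrimitive(rx=10.0, ry=10.0)]))
    if cls == "simple-chemical":
        return StyleRecipe(RenderGroup(stroke=black, stroke_width=2.0, fill="#F0F0E0",
                                       primitives=[EllipsePrimitive()]))
    if cls == "nucleic-acid-feature":
        return StyleRecipe(RenderGroup(
            stroke=black, stroke_width=2.0, fill="#E0E0F0",
            primitives=[PolygonPrimitive([(0.0, 0.0), (100.0, 0.0), (100.0, 75.0),
                                          (85.0, 100.0), (15.0, 100.0), (0.0, 75.0)])]))
    if cls == "complex":
        cut = 20.0
        return StyleRecipe(RenderGroup(
            stroke=black, stroke_width=2.0, fill="#E8E8E8",
            primitives=[PolygonPrimitive([
                (cut, 0.0), (100.0 - cut, 0.0), (100.0, cut), (100.0, 100.0 - cut),
                (100.0 - cut, 100.0), (cut, 100.0), (0.0, 100.0 - cut), (0.0, cut)])]))
    if cls == "source-and-sink":
        return StyleRecipe(RenderGroup(
            stroke=black, stroke_width=2.0, fill="none",
            primitives=[EllipsePrimitive(cx=50.0, cy=50.0, rx=40.0, ry=40.0),
                        RenderCurvePrimitive([(15.0, 85.0), (85.0, 15.0)])]))
    if cls == "process":
        return StyleRecipe(
            RenderGroup(stroke=black, stroke_width=2.0, fill=white,
                        primitives=[RectanglePrimitive()]),
            node_size=(14.0, 14.0),
        )
    if cls == "association":
        return StyleRecipe(
            RenderGroup(stroke=black, stroke_width=2.0, fill=black,
                        primitives=[EllipsePrimitive()]),
            node_size=(14.0, 14.0),
        )
    if cls == "dissociation":
        return StyleRecipe(
            RenderGroup(stroke=black, stroke_width=2.0, fill="none",
                        primitives=[EllipsePrimitive(),
                                    EllipsePrimitive(cx=50.0, cy=50.0, rx=30.0, ry=30.0)]),
            node_size=(14.0, 14.0),
        )
    if cls == "compartment":
        return StyleRecipe(RenderGroup(stroke="#B0A080", stroke_width=4.0, fill="none",
                                       primitives=[RectanglePrimitive(rx=20.0, ry=20.0)]))
    if cls == "consumption":
        return StyleRecipe(RenderGroup(stroke=black, stroke_width=1.5, fill="none"),
                           is_arc=True)
    if cls == "production":
        return StyleRecipe(RenderGroup(stroke=black, stroke_width=1.5, fill="none",
                                       end_head="arrow_filled"),
                           is_arc=True, required_endings=["arrow_filled"])
    if cls == "catalysis":
        return StyleRecipe(RenderGroup(stroke=black, stroke_width=1.5, fill="none",
                                       end_head="open_circle"),
                           is_arc=True, required_endings=["open_circle"])
    if cls == "inhibition":
        return StyleRecipe(RenderGroup(stroke=black, stroke_width=1.5, fill="none",
                                       end_head="inhibit_bar"),
                           is_arc=True, required_endings=["inhibit_bar"])
    if cls == "stimulation":
        return StyleRecipe(RenderGroup(stroke=black, stroke_width=1.5, fill="none",
                                       end_head="arrow_open"),
                           is_arc=True, required_endings=["arrow_open"])
    if cls == "modulation":
        return StyleRecipe(RenderGroup(stroke=black, stroke_width=1.5, fill="none",
                                       end_head="open_diamond"),
                           is_arc=True, required_endings=["open_diamond"])
    raise CapabilityError(
        f"SBGN class {cls!r} is not in the supported Process-Description subset: "
        f"{', '.join(SBGN_CLASSES)}"
    )


def resolve_sbgn_class(doc: Document, element_id: str) -> Optional[str]:
    """Class resolution order: explicit annotation → SBO term → glyph-type
    fallback (species→macromolecule, reaction→process, ∅→source-and-sink)."""
    layout = doc.layout
    for g in layout.species_glyphs:
        if g.glyph_id == element_id:
            if g.species_id is None:
                return "source-and-sink"
            sp = doc.model.find_species(g.species_id)
            if sp is not None:
                if sp.sbgn_class:
                    return sp.sbgn_class
                if sp.sbo_term in SBGN_SBO_MAP:
                    return SBGN_SBO_MAP[sp.sbo_term]
            return "macromolecule"
    for rg in layout.reaction_glyphs:
        if rg.glyph_id == element_id:
            rxn = doc.model.find_reaction(rg.reaction_id)
            if rxn is not None:
                if rxn.sbgn_class:
                    return rxn.sbgn_class
                if rxn.sbo_term in SBGN_SBO_MAP:
                    return SBGN_SBO_MAP[rxn.sbo_term]
            return "process"
        for srg in rg.reference_glyphs:
            if srg.glyph_id == element_id:
                return _ROLE_TO_SBGN_ARC[srg.role]
    for g in layout.compartment_glyphs:
        if g.glyph_id == element_id:
            return "compartment"
    return None


def _apply_sbgn_template(doc: Document) -> Document:
    render = RenderInfo(render_id="sbgnRender", background_color="#FFFFFF")
    render.line_endings = list(standard_line_endings().values())
    render.styles.append(
        Style("default", RenderGroup(stroke="#000000", stroke_width=1.5, fill="none"))
    )
    render.styles.append(
        Style("sbgn_text",
              RenderGroup(stroke="#000000", font_family="sans-serif", font_size=11.0,
                          text_anchor="middle"),
              type_list=["TEXTGLYPH"]),
    )
    # arcs by role
    for role, cls in _ROLE_TO_SBGN_ARC.items():
        recipe = sbgn_style_for_class(cls)
        style_id = f"sbgn_arc_{role.value}"
        render.styles.append(Style(style_id, recipe.group, role_list=[role.value]))
    # nodes by resolved class, one style per class
    doc.render = render  # needed before resizing below
    layout = doc.layout
    by_class: dict[str, list[str]] = {}
    for g in layout.species_glyphs:
        by_class.setdefault(resolve_sbgn_class(doc, g.glyph_id), []).append(g.glyph_id)
    for rg in layout.reaction_glyphs:
        by_class.setdefault(resolve_sbgn_class(doc, rg.glyph_id), []).append(rg.glyph_id)
    for g in layout.compartment_glyphs:
        by_class.setdefault("compartment", []).append(g.glyph_id)
    for cls in sorted(by_class):
        if cls is None:
            continue
        recipe = sbgn_style_for_class(cls)
        render.styles.append(Style(f"sbgn_{cls}", recipe.group, id_list=list(by_class[cls])))
        if recipe.node_size is not None:
            for gid in by_class[cls]:
                for rg in layout.reaction_glyphs:
                    if rg.glyph_id == gid:
                        c = rg.center_bbox.center
                        rg.center_bbox = BoundingBox.centered(c, *recipe.node_size)
    return doc


# ---------------------------------------------------------------------------
# Escher-like template
# ---------------------------------------------------------------------------

#: Concrete Escher-look values (house choice; fully overridable).
ESCHER_REACTION_STROKE = "#334E75"
ESCHER_REACTION_WIDTH = 9.0
ESCHER_SPECIES_DIAMETER = 25.0
ESCHER_FONT_SIZE = 20.0


def _apply_escher_template(doc: Document) -> Document:
    layout = doc.layout
    # species as fixed-diameter circles; re-attach curves afterwards
    for g in layout.species_glyphs:
        if g.species_id is not None:
            c = g.bbox.center
            g.bbox = BoundingBox.centered(c, ESCHER_SPECIES_DIAMETER, ESCHER_SPECIES_DIAMETER)
            t = layout.find_text_glyph_for(g.glyph_id)
            if t is not None:
                t.bbox = BoundingBox(g.bbox.x, g.bbox.y, g.bbox.width, g.bbox.height)
    for rg in layout.reaction_glyphs:
        rebuild_reaction_curves(doc, rg)

    render = RenderInfo(render_id="escherRender", background_color="#FFFFFF")
    render.line_endings = list(standard_line_endings().values())
    # scale the arrowhead with the thick curves
    for le in render.line_endings:
        le.bbox = BoundingBox(-18.0, -9.0, 18.0, 18.0)
    render.styles = [
        Style("default", RenderGroup(stroke=ESCHER_REACTION_STROKE, stroke_width=2.0,
                                     fill="none")),
        Style("escher_species",
              RenderGroup(stroke=ESCHER_REACTION_STROKE, stroke_width=2.0, fill="#B8CCE4",
                          primitives=[EllipsePrimitive()]),
              type_list=["SPECIESGLYPH"]),
        Style("escher_reaction",
              RenderGroup(stroke=ESCHER_REACTION_STROKE, stroke_width=2.0, fill="#334E75",
                          primitives=[EllipsePrimitive()]),
              type_list=["REACTIONGLYPH"]),
        Style("escher_compartment",
              RenderGroup(stroke="#DDDDDD", stroke_width=1.0, fill="none",
                          primitives=[RectanglePrimitive()]),
              type_list=["COMPARTMENTGLYPH"]),
        Style("escher_emptyset",
              RenderGroup(stroke=ESCHER_REACTION_STROKE, stroke_width=2.0, fill="none",
                          primitives=[EllipsePrimitive(cx=50.0, cy=50.0, rx=40.0, ry=40.0),
                                      RenderCurvePrimitive([(15.0, 85.0), (85.0, 15.0)])]),
              type_list=["GRAPHICALOBJECT"]),
        Style("escher_text",
              RenderGroup(stroke="#000000", font_family="sans-serif",
                          font_size=ESCHER_FONT_SIZE, font_weight="bold",
                          text_anchor="middle"),
              type_list=["TEXTGLYPH"]),
        Style("escher_substrate",
              RenderGroup(stroke=ESCHER_REACTION_STROKE,
                          stroke_width=ESCHER_REACTION_WIDTH, fill="none"),
              role_list=[Role.SUBSTRATE.value, Role.SIDE_SUBSTRATE.value]),
        Style("escher_product",
              RenderGroup(stroke=ESCHER_REACTION_STROKE,
                          stroke_width=ESCHER_REACTION_WIDTH, fill="none",
                          end_head="arrow_filled"),
              role_list=[Role.PRODUCT.value, Role.SIDE_PRODUCT.value]),
        Style("escher_modifier",
              RenderGroup(stroke="#8896AB", stroke_width=3.0, fill="none",
                          stroke_dasharray=[6.0, 4.0], end_head="open_circle"),
              role_list=[Role.MODIFIER.value, Role.ACTIVATOR.value,
                         Role.INHIBITOR.value, Role.UNDEFINED.value]),
    ]
    doc.render = render
    return doc


# ---------------------------------------------------------------------------
# Template registry, JSON templates
# ---------------------------------------------------------------------------

@dataclass
class StyleTemplate:
    """Declarative template: element-class → attribute recipe."""

    name: str
    class_styles: dict[str, dict] = field(default_factory=dict)
    defaults: dict = field(default_factory=dict)


_CLASS_TO_SELECTOR = {
    "species": ("type", "SPECIESGLYPH"),
    "reaction": ("type", "REACTIONGLYPH"),
    "compartment": ("type", "COMPARTMENTGLYPH"),
    "text": ("type", "TEXTGLYPH"),
    "emptyset": ("type", "GRAPHICALOBJECT"),
    **{role.value: ("role", role.value) for role in Role},
}

_CUSTOM_TEMPLATES: dict[str, StyleTemplate] = {}

BUILTIN_TEMPLATES = ("default", "sbgn-pd", "escher")


def register_template(template: StyleTemplate) -> None:
    _CUSTOM_TEMPLATES[template.name] = template


def load_template(path: str) -> StyleTemplate:
    """Load and register a template from a JSON file:
    {"name": ..., "class_styles": {class: {attr: value}}, "defaults": {...}}"""
    with open(path) as fh:
        data = json.load(fh)
    template = StyleTemplate(
        name=data["name"],
        class_styles=data.get("class_styles", {}),
        defaults=data.get("defaults", {}),
    )
    register_template(template)
    return template


def _group_from_recipe(attrs: dict, base: Optional[RenderGroup] = None) -> RenderGroup:
    group = base.copy() if base is not None else RenderGroup()
    for key, value in attrs.items():
        if key == "shape":
            shape = {
                "rectangle": RectanglePrimitive(),
                "rounded-rectangle": RectanglePrimitive(rx=8.0, ry=8.0),
                "ellipse": EllipsePrimitive(),
            }.get(value)
            if shape is None:
                raise ParameterError(f"unknown shape {value!r} in template recipe")
            group.primitives = [shape]
        else:
            _set_group_attribute(group, key, value)
    return group


def _apply_custom_template(doc: Document, template: StyleTemplate) -> Document:
    render = RenderInfo(render_id=f"{template.name}Render",
                        background_color=resolve_color(
                            template.defaults.get("background_color", "#FFFFFF")))
    render.line_endings = list(standard_line_endings().values())
    default_attrs = {k: v for k, v in template.defaults.items() if k != "background_color"}
    render.styles.append(Style("default", _group_from_recipe(default_attrs)))
    for cls, attrs in template.class_styles.items():
        if cls not in _CLASS_TO_SELECTOR:
            raise ParameterError(
                f"unknown element class {cls!r}; known: {sorted(_CLASS_TO_SELECTOR)}")
        sel_kind, sel_value = _CLASS_TO_SELECTOR[cls]
        style = Style(
            f"{template.name}_{cls}",
            _group_from_recipe(attrs),
            role_list=[sel_value] if sel_kind == "role" else [],
            type_list=[sel_value] if sel_kind == "type" else [],
        )
        render.styles.append(style)
    doc.render = render
    return doc


def apply_template(doc: Document, name: Union[str, StyleTemplate]) -> Document:
    """Replace the document's render information with a template's styles."""
    if doc.layout is None:
        raise ParameterError("document has no layout; run build_layout first")
    if isinstance(name, StyleTemplate):
        return _apply_custom_template(doc, name)
    if name == "default":
        return default_render(doc)
    if name == "sbgn-pd":
        return _apply_sbgn_template(doc)
    if name == "escher":
        return _apply_escher_template(doc)
    if name in _CUSTOM_TEMPLATES:
        return _apply_custom_template(doc, _CUSTOM_TEMPLATES[name])
    raise ParameterError(
        f"unknown template {name!r}; available: default, sbgn-pd, escher"
    )


# ---------------------------------------------------------------------------
# Selection and batch editing
# ---------------------------------------------------------------------------

_ATTRIBUTE_FIELDS = {
    "stroke": "stroke",
    "stroke-width": "stroke_width",
    "stroke_width": "stroke_width",
    "fill": "fill",
    "font-family": "font_family",
    "font_family": "font_family",
    "font-size": "font_size",
    "font_size": "font_size",
    "font-weight": "font_weight",
    "font_weight": "font_weight",
    "text-anchor": "text_anchor",
    "text_anchor": "text_anchor",
    "start-head": "start_head",
    "start_head": "start_head",
    "end-head": "end_head",
    "end_head": "end_head",
}


def _set_group_attribute(group: RenderGroup, attribute: str, value) -> None:
    if attribute not in _ATTRIBUTE_FIELDS:
        raise ParameterError(
            f"unknown style attribute {attribute!r}; known: "
            f"{sorted(set(_ATTRIBUTE_FIELDS.values()))}")
    field_name = _ATTRIBUTE_FIELDS[attribute]
    if field_name in ("stroke", "fill") and value is not None and value != "none":
        value = resolve_color(str(value))
    if field_name in ("stroke_width", "font_size"):
        value = float(value)
        if value < 0:
            raise ParameterError(f"{attribute} must be ≥ 0, got {value}")
    setattr(group, field_name, value)


def _get_group_attribute(group: RenderGroup, attribute: str):
    if attribute not in _ATTRIBUTE_FIELDS:
        raise ParameterError(f"unknown style attribute {attribute!r}")
    return getattr(group, _ATTRIBUTE_FIELDS[attribute])


def select_elements(doc: Document, attribute: str, value) -> list[str]:
    """Ids of layout elements whose effective style attribute equals value."""
    if doc.render is None:
        raise ParameterError("document has no render information")
    if attribute not in _ATTRIBUTE_FIELDS:
        raise ParameterError(f"unknown style attribute {attribute!r}")
    if _ATTRIBUTE_FIELDS[attribute] in ("stroke", "fill") and isinstance(value, str) \
            and value not in (None, "none"):
        value = resolve_color(value)
    resolve = make_style_resolver(doc)
    out = []
    for element_id in element_kind(doc):
        group = resolve(element_id)
        if group is not None and _get_group_attribute(group, attribute) == value:
            out.append(element_id)
    return out


def batch_set(doc: Document, element_ids: list[str], attribute: str, value) -> Document:
    """Set one style attribute on each element via id-selector override styles.

    Other attributes inherit from the element's previous effective style (the
    override starts as a copy of it).
    """
    if doc.render is None:
        raise ParameterError("document has no render information")
    kinds = element_kind(doc)
    for element_id in element_ids:
        if element_id not in kinds:
            raise UnknownElementError(f"unknown element id {element_id!r}")
    singleton_styles = {s.id_list[0]: s for s in doc.render.styles if len(s.id_list) == 1}
    for element_id in element_ids:
        existing = singleton_styles.get(element_id)
        if existing is not None:
            _set_group_attribute(existing.group, attribute, value)
            # promote to highest precedence among id styles
            doc.render.styles.remove(existing)
            doc.render.styles.append(existing)
        else:
            base_style = _matching_style_with_kinds(doc, kinds, element_id)
            base = base_style.group if base_style is not None else None
            group = base.copy() if base is not None else RenderGroup()
            _set_group_attribute(group, attribute, value)
            style_id = f"idstyle_{element_id}"
            existing_ids = {s.style_id for s in doc.render.styles}
            suffix = 0
            while style_id in existing_ids:
                suffix += 1
                style_id = f"idstyle_{element_id}_{suffix}"
            new_style = Style(style_id, group, id_list=[element_id])
            doc.render.styles.append(new_style)
            singleton_styles[element_id] = new_style
    return doc
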