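"""Reading, writing and validation of SBML Level 3 documents with Layout/Render.

Implements the subset of SBML L3V1 core plus the Layout (v1) and Render (v1)
packages that the visualization pipeline produces and consumes. Documents at
other Level-3 versions are read permissively (the package namespace is matched
by its "/layout/" or "/render/" path component, not the exact version).

Emancipated source/sink glyphs (no model counterpart) are serialized as
generic graphical objects whose id/metaid carries the reserved prefix
``emptyset_`` so they survive round-trips losslessly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Union

from lxml import etree

from .errors import ParseError, ValidationError
from .types import (
    EMPTYSET_PREFIX,
    BoundingBox,
    ColorDefinition,
    Compartment,
    CompartmentGlyph,
    CurveSegment,
    Document,
    EllipsePrimitive,
    GradientStop,
    GraphicalObject,
    Layout,
    LinearGradient,
    LineEnding,
    Model,
    Point,
    PolygonPrimitive,
    Reaction,
    ReactionGlyph,
    RectanglePrimitive,
    RenderCurvePrimitive,
    RenderGroup,
    RenderInfo,
    Role,
    Species,
    SpeciesGlyph,
    SpeciesReference,
    SpeciesReferenceGlyph,
    Style,
    TextGlyph,
)

NS_CORE = "http://www.sbml.org/sbml/level3/version1/core"
NS_LAYOUT = "http://www.sbml.org/sbml/level3/version1/layout/version1"
NS_RENDER = "http://www.sbml.org/sbml/level3/version1/render/version1"
NS_XSI = "http://www.w3.org/2001/XMLSchema-instance"
NS_VIZ = "http://sbmlviz.org/annotations"

HEX_COLOR_RE = re.compile(r"^#[0-9A-F]{6}([0-9A-F]{2})?$")

_ROLE_VALUES = {r.value for r in Role}


def _fmt(v: float) -> str:
    """Serialize a float losslessly; integers without a trailing '.0'."""
    v = float(v)
    if v.is_integer() and abs(v) < 1e15:
        return str(int(v))
    return repr(v)


def _pct(v: float) -> str:
    return _fmt(v) + "%"


def _parse_pct(s: str) -> float:
    s = s.strip()
    if s.endswith("%"):
        s = s[:-1]
    return float(s)


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

class _W:
    """Tag helpers bound to fixed namespaces for the writer."""

    @staticmethod
    def core(tag: str) -> str:
        return f"{{{NS_CORE}}}{tag}"

    @staticmethod
    def lo(tag: str) -> str:
        return f"{{{NS_LAYOUT}}}{tag}"

    @staticmethod
    def rn(tag: str) -> str:
        return f"{{{NS_RENDER}}}{tag}"


def write_document(doc: Document) -> str:
    """Serialize a Document to SBML Level 3 XML text.

    The layout/render package namespaces are declared iff the corresponding
    sections are present.  Raises :class:`ValidationError` before emitting any
    output when a structural invariant of the document is violated.
    """
    issues = [i for i in validate_layout(doc) if i.severity == "error"]
    if issues:
        raise ValidationError(
            "document invalid: " + "; ".join(f"{i.element_id}: {i.message}" for i in issues[:5])
        )

    nsmap = {None: NS_CORE}
    if doc.layout is not None:
        nsmap["layout"] = NS_LAYOUT
    if doc.render is not None:
        nsmap["render"] = NS_RENDER
    nsmap["xsi"] = NS_XSI
    nsmap["sbmlviz"] = NS_VIZ

    root = etree.Element(_W.core("sbml"), nsmap=nsmap)
    root.set("level", "3")
    root.set("version", "1")
    if doc.layout is not None:
        root.set(_W.lo("required"), "false")
    if doc.render is not None:
        root.set(_W.rn("required"), "false")

    model_el = etree.SubElement(root, _W.core("model"))
    model_el.set("id", doc.model.model_id)
    _write_model(model_el, doc.model)
    if doc.layout is not None:
        lol = etree.SubElement(model_el, _W.lo("listOfLayouts"))
        _write_layout(lol, doc.layout, doc.render)

    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    ).decode("utf-8")


def _write_model(model_el, model: Model) -> None:
    if model.compartments:
        loc = etree.SubElement(model_el, _W.core("listOfCompartments"))
        for c in model.compartments:
            el = etree.SubElement(loc, _W.core("compartment"))
            el.set("id", c.compartment_id)
            if c.name:
                el.set("name", c.name)
            el.set("constant", "true")
    if model.species:
        los = etree.SubElement(model_el, _W.core("listOfSpecies"))
        for s in model.species:
            el = etree.SubElement(los, _W.core("species"))
            el.set("id", s.species_id)
            if s.name:
                el.set("name", s.name)
            el.set("compartment", s.compartment_id)
            if s.sbo_term:
                el.set("sboTerm", s.sbo_term)
            el.set("hasOnlySubstanceUnits", "false")
            el.set("boundaryCondition", "false")
            el.set("constant", "false")
            if s.sbgn_class:
                el.set(f"{{{NS_VIZ}}}sbgnClass", s.sbgn_class)
    if model.reactions:
        lor = etree.SubElement(model_el, _W.core("listOfReactions"))
        for r in model.reactions:
            el = etree.SubElement(lor, _W.core("reaction"))
            el.set("id", r.reaction_id)
            if r.name:
                el.set("name", r.name)
            el.set("reversible", "true" if r.reversible else "false")
            el.set("fast", "false")
            if r.sbo_term:
                el.set("sboTerm", r.sbo_term)
            if r.sbgn_class:
                el.set(f"{{{NS_VIZ}}}sbgnClass", r.sbgn_class)
            for list_tag, ref_tag, refs in (
                ("listOfReactants", "speciesReference", r.reactants),
                ("listOfProducts", "speciesReference", r.products),
                ("listOfModifiers", "modifierSpeciesReference", r.modifiers),
            ):
                if not refs:
                    continue
                lst = etree.SubElement(el, _W.core(list_tag))
                for ref in refs:
                    rel = etree.SubElement(lst, _W.core(ref_tag))
                    rel.set("species", ref.species_id)
                    if ref_tag == "speciesReference":
                        rel.set("stoichiometry", _fmt(ref.stoichiometry))
                        rel.set("constant", "true")
                    if ref.sbo_term:
                        rel.set("sboTerm", ref.sbo_term)
                    if ref.annotation_keyword:
                        rel.set(f"{{{NS_VIZ}}}keyword", ref.annotation_keyword)


def _write_bbox(parent, bbox: BoundingBox, tag: str = "boundingBox") -> None:
    bb = etree.SubElement(parent, _W.lo(tag))
    pos = etree.SubElement(bb, _W.lo("position"))
    pos.set(_W.lo("x"), _fmt(bbox.x))
    pos.set(_W.lo("y"), _fmt(bbox.y))
    dim = etree.SubElement(bb, _W.lo("dimensions"))
    dim.set(_W.lo("width"), _fmt(bbox.width))
    dim.set(_W.lo("height"), _fmt(bbox.height))


def _write_curve(parent, segments: list[CurveSegment]) -> None:
    curve = etree.SubElement(parent, _W.lo("curve"))
    locs = etree.SubElement(curve, _W.lo("listOfCurveSegments"))
    for seg in segments:
        el = etree.SubElement(locs, _W.lo("curveSegment"))
        el.set(f"{{{NS_XSI}}}type", "CubicBezier" if seg.is_cubic else "LineSegment")
        for tag, pt in (("start", seg.start), ("end", seg.end)):
            p = etree.SubElement(el, _W.lo(tag))
            p.set(_W.lo("x"), _fmt(pt.x))
            p.set(_W.lo("y"), _fmt(pt.y))
        if seg.is_cubic:
            for tag, pt in (("basePoint1", seg.base_point_1), ("basePoint2", seg.base_point_2)):
                p = etree.SubElement(el, _W.lo(tag))
                p.set(_W.lo("x"), _fmt(pt.x))
                p.set(_W.lo("y"), _fmt(pt.y))


def _write_layout(lol, layout: Layout, render: Optional[RenderInfo]) -> None:
    lay = etree.SubElement(lol, _W.lo("layout"))
    lay.set(_W.lo("id"), layout.layout_id)
    dim = etree.SubElement(lay, _W.lo("dimensions"))
    dim.set(_W.lo("width"), _fmt(layout.width))
    dim.set(_W.lo("height"), _fmt(layout.height))

    if layout.compartment_glyphs:
        lst = etree.SubElement(lay, _W.lo("listOfCompartmentGlyphs"))
        for g in layout.compartment_glyphs:
            el = etree.SubElement(lst, _W.lo("compartmentGlyph"))
            el.set(_W.lo("id"), g.glyph_id)
            el.set(_W.lo("compartment"), g.compartment_id)
            _write_bbox(el, g.bbox)

    referenced = [g for g in layout.species_glyphs if g.species_id is not None]
    emancipated = [g for g in layout.species_glyphs if g.species_id is None]
    if referenced:
        lst = etree.SubElement(lay, _W.lo("listOfSpeciesGlyphs"))
        for g in referenced:
            el = etree.SubElement(lst, _W.lo("speciesGlyph"))
            el.set(_W.lo("id"), g.glyph_id)
            el.set(_W.lo("species"), g.species_id)
            if g.alias_index:
                el.set(f"{{{NS_VIZ}}}alias", str(g.alias_index))
            _write_bbox(el, g.bbox)

    if layout.reaction_glyphs:
        lst = etree.SubElement(lay, _W.lo("listOfReactionGlyphs"))
        for rg in layout.reaction_glyphs:
            el = etree.SubElement(lst, _W.lo("reactionGlyph"))
            el.set(_W.lo("id"), rg.glyph_id)
            el.set(_W.lo("reaction"), rg.reaction_id)
            _write_bbox(el, rg.center_bbox)
            if rg.reference_glyphs:
                losrg = etree.SubElement(el, _W.lo("listOfSpeciesReferenceGlyphs"))
                for srg in rg.reference_glyphs:
                    sel = etree.SubElement(losrg, _W.lo("speciesReferenceGlyph"))
                    sel.set(_W.lo("id"), srg.glyph_id)
                    sel.set(_W.lo("speciesGlyph"), srg.species_glyph_id)
                    sel.set(_W.lo("role"), srg.role.value)
                    if srg.curve:
                        _write_curve(sel, srg.curve)

    if layout.text_glyphs:
        lst = etree.SubElement(lay, _W.lo("listOfTextGlyphs"))
        for t in layout.text_glyphs:
            el = etree.SubElement(lst, _W.lo("textGlyph"))
            el.set(_W.lo("id"), t.glyph_id)
            el.set(_W.lo("graphicalObject"), t.target_glyph_id)
            el.set(_W.lo("text"), t.text)
            _write_bbox(el, t.bbox)

    if emancipated or layout.additional_objects:
        lst = etree.SubElement(lay, _W.lo("listOfAdditionalGraphicalObjects"))
        for g in emancipated:
            el = etree.SubElement(lst, _W.lo("graphicalObject"))
            el.set(_W.lo("id"), g.glyph_id)
            el.set("metaid", g.glyph_id if g.glyph_id.startswith(EMPTYSET_PREFIX)
                   else EMPTYSET_PREFIX + g.glyph_id)
            if g.alias_index:
                el.set(f"{{{NS_VIZ}}}alias", str(g.alias_index))
            _write_bbox(el, g.bbox)
        for g in layout.additional_objects:
            el = etree.SubElement(lst, _W.lo("graphicalObject"))
            el.set(_W.lo("id"), g.glyph_id)
            if g.metaid:
                el.set("metaid", g.metaid)
            _write_bbox(el, g.bbox)

    if render is not None:
        lori = etree.SubElement(lay, _W.rn("listOfRenderInformation"))
        _write_render(lori, render)


def _write_group(parent, group: RenderGroup) -> None:
    g = etree.SubElement(parent, _W.rn("g"))
    if group.stroke is not None:
        g.set(_W.rn("stroke"), group.stroke)
    g.set(_W.rn("stroke-width"), _fmt(group.stroke_width))
    if group.stroke_dasharray is not None:
        g.set(_W.rn("stroke-dasharray"), ",".join(_fmt(v) for v in group.stroke_dasharray))
    if group.fill is not None:
        g.set(_W.rn("fill"), group.fill)
    g.set(_W.rn("font-family"), group.font_family)
    g.set(_W.rn("font-size"), _fmt(group.font_size))
    if group.font_weight != "normal":
        g.set(_W.rn("font-weight"), group.font_weight)
    g.set(_W.rn("text-anchor"), group.text_anchor)
    if group.start_head is not None:
        g.set(_W.rn("startHead"), group.start_head)
    if group.end_head is not None:
        g.set(_W.rn("endHead"), group.end_head)
    for prim in group.primitives:
        if isinstance(prim, RectanglePrimitive):
            el = etree.SubElement(g, _W.rn("rectangle"))
            el.set(_W.rn("x"), _pct(prim.x))
            el.set(_W.rn("y"), _pct(prim.y))
            el.set(_W.rn("width"), _pct(prim.width))
            el.set(_W.rn("height"), _pct(prim.height))
            if prim.rx:
                el.set(_W.rn("rx"), _fmt(prim.rx))
            if prim.ry:
                el.set(_W.rn("ry"), _fmt(prim.ry))
        elif isinstance(prim, EllipsePrimitive):
            el = etree.SubElement(g, _W.rn("ellipse"))
            el.set(_W.rn("cx"), _pct(prim.cx))
            el.set(_W.rn("cy"), _pct(prim.cy))
            el.set(_W.rn("rx"), _pct(prim.rx))
            el.set(_W.rn("ry"), _pct(prim.ry))
        elif isinstance(prim, (PolygonPrimitive, RenderCurvePrimitive)):
            tag = "polygon" if isinstance(prim, PolygonPrimitive) else "curve"
            el = etree.SubElement(g, _W.rn(tag))
            loe = etree.SubElement(el, _W.rn("listOfElements"))
            for (px, py) in prim.points:
                pel = etree.SubElement(loe, _W.rn("element"))
                pel.set(f"{{{NS_XSI}}}type", "RenderPoint")
                pel.set(_W.rn("x"), _pct(px))
                pel.set(_W.rn("y"), _pct(py))
        else:  # pragma: no cover - guarded by type construction
            raise ValidationError(f"unknown render primitive {prim!r}")


def _write_render(lori, render: RenderInfo) -> None:
    ri = etree.SubElement(lori, _W.rn("renderInformation"))
    ri.set(_W.rn("id"), render.render_id)
    ri.set(_W.rn("backgroundColor"), render.background_color)
    if render.colors:
        lst = etree.SubElement(ri, _W.rn("listOfColorDefinitions"))
        for c in render.colors:
            el = etree.SubElement(lst, _W.rn("colorDefinition"))
            el.set(_W.rn("id"), c.color_id)
            el.set(_W.rn("value"), c.value)
    if render.gradients:
        lst = etree.SubElement(ri, _W.rn("listOfGradientDefinitions"))
        for grad in render.gradients:
            el = etree.SubElement(lst, _W.rn("linearGradient"))
            el.set(_W.rn("id"), grad.gradient_id)
            el.set(_W.rn("x1"), _pct(grad.x1))
            el.set(_W.rn("y1"), _pct(grad.y1))
            el.set(_W.rn("x2"), _pct(grad.x2))
            el.set(_W.rn("y2"), _pct(grad.y2))
            for stop in grad.stops:
                sel = etree.SubElement(el, _W.rn("stop"))
                sel.set(_W.rn("offset"), _pct(stop.offset * 100.0))
                sel.set(_W.rn("stop-color"), stop.color)
    if render.line_endings:
        lst = etree.SubElement(ri, _W.rn("listOfLineEndings"))
        for le in render.line_endings:
            el = etree.SubElement(lst, _W.rn("lineEnding"))
            el.set(_W.rn("id"), le.ending_id)
            el.set(_W.rn("enableRotationalMapping"),
                   "true" if le.rotational_mapping else "false")
            _write_bbox(el, le.bbox)
            _write_group(el, le.group)
    if render.styles:
        lst = etree.SubElement(ri, _W.rn("listOfStyles"))
        for st in render.styles:
            el = etree.SubElement(lst, _W.rn("style"))
            el.set(_W.rn("id"), st.style_id)
            if st.role_list:
                el.set(_W.rn("roleList"), " ".join(st.role_list))
            if st.type_list:
                el.set(_W.rn("typeList"), " ".join(st.type_list))
            if st.id_list:
                el.set(_W.rn("idList"), " ".join(st.id_list))
            _write_group(el, st.group)


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def read_document(source: Union[str, bytes]) -> Document:
    """Parse SBML XML text/bytes into a :class:`Document`.

    Layout/Render sections are populated when their package namespaces are
    declared; absent packages yield absent fields.  Unresolvable internal
    references raise :class:`ValidationError` naming the offending id.
    """
    if isinstance(source, str):
        source = source.encode("utf-8")
    try:
        root = etree.fromstring(source)
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"malformed XML: {exc}") from exc

    ns_layout = _find_pkg_ns(root, "/layout/")
    ns_render = _find_pkg_ns(root, "/render/")
    ns_core = etree.QName(root).namespace or NS_CORE

    model_el = root.find(f"{{{ns_core}}}model")
    if model_el is None:
        raise ParseError("no <model> element found")
    model = _read_model(model_el, ns_core)

    layout = None
    render = None
    if ns_layout:
        lol = model_el.find(f"{{{ns_layout}}}listOfLayouts")
        if lol is not None:
            lay_el = lol.find(f"{{{ns_layout}}}layout")
            if lay_el is not None:
                layout = _read_layout(lay_el, ns_layout)
                if ns_render:
                    lori = lay_el.find(f"{{{ns_render}}}listOfRenderInformation")
                    if lori is not None:
                        ri = lori.find(f"{{{ns_render}}}renderInformation")
                        if ri is not None:
                            render = _read_render(ri, ns_render, ns_layout)

    doc = Document(model=model, layout=layout, render=render)
    _check_references_on_read(doc)
    return doc


def _find_pkg_ns(root, path_fragment: str) -> Optional[str]:
    for uri in root.nsmap.values():
        if uri and uri.startswith("http://www.sbml.org/sbml/level3") and path_fragment in uri:
            return uri
    return None


def _attr(el, ns: str, name: str) -> Optional[str]:
    v = el.get(f"{{{ns}}}{name}")
    if v is None:
        v = el.get(name)
    return v


def _read_model(model_el, ns: str) -> Model:
    model = Model(model_id=model_el.get("id") or "model")
    loc = model_el.find(f"{{{ns}}}listOfCompartments")
    if loc is not None:
        for el in loc.findall(f"{{{ns}}}compartment"):
            model.compartments.append(
                Compartment(compartment_id=el.get("id"), name=el.get("name"))
            )
    los = model_el.find(f"{{{ns}}}listOfSpecies")
    if los is not None:
        for el in los.findall(f"{{{ns}}}species"):
            model.species.append(
                Species(
                    species_id=el.get("id"),
                    compartment_id=el.get("compartment") or "",
                    name=el.get("name"),
                    sbo_term=el.get("sboTerm"),
                    sbgn_class=el.get(f"{{{NS_VIZ}}}sbgnClass"),
                )
            )
    lor = model_el.find(f"{{{ns}}}listOfReactions")
    if lor is not None:
        for el in lor.findall(f"{{{ns}}}reaction"):
            rxn = Reaction(
                reaction_id=el.get("id"),
                reversible=(el.get("reversible") == "true"),
                name=el.get("name"),
                sbo_term=el.get("sboTerm"),
                sbgn_class=el.get(f"{{{NS_VIZ}}}sbgnClass"),
            )
            for list_tag, ref_tag, target in (
                ("listOfReactants", "speciesReference", rxn.reactants),
                ("listOfProducts", "speciesReference", rxn.products),
                ("listOfModifiers", "modifierSpeciesReference", rxn.modifiers),
            ):
                lst = el.find(f"{{{ns}}}{list_tag}")
                if lst is None:
                    continue
                for rel in lst.findall(f"{{{ns}}}{ref_tag}"):
                    target.append(
                        SpeciesReference(
                            species_id=rel.get("species"),
                            stoichiometry=float(rel.get("stoichiometry") or 1.0),
                            sbo_term=rel.get("sboTerm"),
                            annotation_keyword=rel.get(f"{{{NS_VIZ}}}keyword"),
                        )
                    )
            model.reactions.append(rxn)
    return model


def _read_bbox(parent, ns: str) -> BoundingBox:
    bb = parent.find(f"{{{ns}}}boundingBox")
    if bb is None:
        return BoundingBox(0.0, 0.0, 0.0, 0.0)
    pos = bb.find(f"{{{ns}}}position")
    dim = bb.find(f"{{{ns}}}dimensions")
    return BoundingBox(
        x=float(_attr(pos, ns, "x")) if pos is not None else 0.0,
        y=float(_attr(pos, ns, "y")) if pos is not None else 0.0,
        width=float(_attr(dim, ns, "width")) if dim is not None else 0.0,
        height=float(_attr(dim, ns, "height")) if dim is not None else 0.0,
    )


def _read_point(el, ns: str) -> Point:
    return Point(float(_attr(el, ns, "x")), float(_attr(el, ns, "y")))


def _read_curve(parent, ns: str) -> list[CurveSegment]:
    curve = parent.find(f"{{{ns}}}curve")
    segments: list[CurveSegment] = []
    if curve is None:
        return segments
    locs = curve.find(f"{{{ns}}}listOfCurveSegments")
    if locs is None:
        return segments
    for el in locs.findall(f"{{{ns}}}curveSegment"):
        start = _read_point(el.find(f"{{{ns}}}start"), ns)
        end = _read_point(el.find(f"{{{ns}}}end"), ns)
        bp1_el = el.find(f"{{{ns}}}basePoint1")
        bp2_el = el.find(f"{{{ns}}}basePoint2")
        bp1 = _read_point(bp1_el, ns) if bp1_el is not None else None
        bp2 = _read_point(bp2_el, ns) if bp2_el is not None else None
        segments.append(CurveSegment(start=start, end=end, base_point_1=bp1, base_point_2=bp2))
    return segments


def _read_layout(lay_el, ns: str) -> Layout:
    dim = lay_el.find(f"{{{ns}}}dimensions")
    layout = Layout(
        layout_id=_attr(lay_el, ns, "id") or "layout",
        width=float(_attr(dim, ns, "width")) if dim is not None else 0.0,
        height=float(_attr(dim, ns, "height")) if dim is not None else 0.0,
    )
    lst = lay_el.find(f"{{{ns}}}listOfCompartmentGlyphs")
    if lst is not None:
        for el in lst.findall(f"{{{ns}}}compartmentGlyph"):
            layout.compartment_glyphs.append(
                CompartmentGlyph(
                    glyph_id=_attr(el, ns, "id"),
                    compartment_id=_attr(el, ns, "compartment"),
                    bbox=_read_bbox(el, ns),
                )
            )
    lst = lay_el.find(f"{{{ns}}}listOfSpeciesGlyphs")
    if lst is not None:
        for el in lst.findall(f"{{{ns}}}speciesGlyph"):
            layout.species_glyphs.append(
                SpeciesGlyph(
                    glyph_id=_attr(el, ns, "id"),
                    species_id=_attr(el, ns, "species"),
                    bbox=_read_bbox(el, ns),
                    alias_index=int(el.get(f"{{{NS_VIZ}}}alias") or 0),
                )
            )
    lst = lay_el.find(f"{{{ns}}}listOfReactionGlyphs")
    if lst is not None:
        for el in lst.findall(f"{{{ns}}}reactionGlyph"):
            rg = ReactionGlyph(
                glyph_id=_attr(el, ns, "id"),
                reaction_id=_attr(el, ns, "reaction"),
                center_bbox=_read_bbox(el, ns),
            )
            losrg = el.find(f"{{{ns}}}listOfSpeciesReferenceGlyphs")
            if losrg is not None:
                for sel in losrg.findall(f"{{{ns}}}speciesReferenceGlyph"):
                    role_raw = (_attr(sel, ns, "role") or "undefined").lower()
                    role = Role(role_raw) if role_raw in _ROLE_VALUES else Role.UNDEFINED
                    rg.reference_glyphs.append(
                        SpeciesReferenceGlyph(
                            glyph_id=_attr(sel, ns, "id"),
                            species_glyph_id=_attr(sel, ns, "speciesGlyph"),
                            role=role,
                            curve=_read_curve(sel, ns),
                        )
                    )
            layout.reaction_glyphs.append(rg)
    lst = lay_el.find(f"{{{ns}}}listOfTextGlyphs")
    if lst is not None:
        for el in lst.findall(f"{{{ns}}}textGlyph"):
            layout.text_glyphs.append(
                TextGlyph(
                    glyph_id=_attr(el, ns, "id"),
                    target_glyph_id=_attr(el, ns, "graphicalObject"),
                    text=_attr(el, ns, "text") or "",
                    bbox=_read_bbox(el, ns),
                )
            )
    lst = lay_el.find(f"{{{ns}}}listOfAdditionalGraphicalObjects")
    if lst is not None:
        for el in lst.findall(f"{{{ns}}}graphicalObject"):
            gid = _attr(el, ns, "id")
            metaid = el.get("metaid")
            if (metaid or gid or "").startswith(EMPTYSET_PREFIX):
                layout.species_glyphs.append(
                    SpeciesGlyph(
                        glyph_id=gid,
                        species_id=None,
                        bbox=_read_bbox(el, ns),
                        alias_index=int(el.get(f"{{{NS_VIZ}}}alias") or 0),
                    )
                )
            else:
                layout.additional_objects.append(
                    GraphicalObject(glyph_id=gid, bbox=_read_bbox(el, ns), metaid=metaid)
                )
    return layout


def _read_group(parent, ns: str, ns_layout: str) -> RenderGroup:
    g_el = parent.find(f"{{{ns}}}g")
    group = RenderGroup()
    if g_el is None:
        return group
    a = lambda name: _attr(g_el, ns, name)  # noqa: E731
    if a("stroke") is not None:
        group.stroke = a("stroke")
    if a("stroke-width") is not None:
        group.stroke_width = float(a("stroke-width"))
    if a("stroke-dasharray") is not None:
        group.stroke_dasharray = [float(v) for v in a("stroke-dasharray").split(",") if v]
    if a("fill") is not None:
        group.fill = a("fill")
    if a("font-family") is not None:
        group.font_family = a("font-family")
    if a("font-size") is not None:
        group.font_size = float(a("font-size"))
    if a("font-weight") is not None:
        group.font_weight = a("font-weight")
    if a("text-anchor") is not None:
        group.text_anchor = a("text-anchor")
    if a("startHead") is not None:
        group.start_head = a("startHead")
    if a("endHead") is not None:
        group.end_head = a("endHead")
    for el in g_el:
        tag = etree.QName(el).localname
        if tag == "rectangle":
            group.primitives.append(
                RectanglePrimitive(
                    x=_parse_pct(_attr(el, ns, "x") or "0"),
                    y=_parse_pct(_attr(el, ns, "y") or "0"),
                    width=_parse_pct(_attr(el, ns, "width") or "100"),
                    height=_parse_pct(_attr(el, ns, "height") or "100"),
                    rx=float(_attr(el, ns, "rx") or 0.0),
                    ry=float(_attr(el, ns, "ry") or 0.0),
                )
            )
        elif tag == "ellipse":
            group.primitives.append(
                EllipsePrimitive(
                    cx=_parse_pct(_attr(el, ns, "cx") or "50"),
                    cy=_parse_pct(_attr(el, ns, "cy") or "50"),
                    rx=_parse_pct(_attr(el, ns, "rx") or "50"),
                    ry=_parse_pct(_attr(el, ns, "ry") or "50"),
                )
            )
        elif tag in ("polygon", "curve"):
            pts = []
            loe = el.find(f"{{{ns}}}listOfElements")
            if loe is not None:
                for pel in loe.findall(f"{{{ns}}}element"):
                    pts.append(
                        (_parse_pct(_attr(pel, ns, "x") or "0"),
                         _parse_pct(_attr(pel, ns, "y") or "0"))
                    )
            cls = PolygonPrimitive if tag == "polygon" else RenderCurvePrimitive
            group.primitives.append(cls(points=pts))
    return group


def _read_render(ri_el, ns: str, ns_layout: str) -> RenderInfo:
    render = RenderInfo(
        render_id=_attr(ri_el, ns, "id") or "renderInfo",
        background_color=_attr(ri_el, ns, "backgroundColor") or "#FFFFFF",
    )
    lst = ri_el.find(f"{{{ns}}}listOfColorDefinitions")
    if lst is not None:
        for el in lst.findall(f"{{{ns}}}colorDefinition"):
            render.colors.append(
                ColorDefinition(color_id=_attr(el, ns, "id"), value=_attr(el, ns, "value"))
            )
    lst = ri_el.find(f"{{{ns}}}listOfGradientDefinitions")
    if lst is not None:
        for el in lst.findall(f"{{{ns}}}linearGradient"):
            grad = LinearGradient(
                gradient_id=_attr(el, ns, "id"),
                stops=[],
                x1=_parse_pct(_attr(el, ns, "x1") or "0"),
                y1=_parse_pct(_attr(el, ns, "y1") or "0"),
                x2=_parse_pct(_attr(el, ns, "x2") or "100"),
                y2=_parse_pct(_attr(el, ns, "y2") or "0"),
            )
            for sel in el.findall(f"{{{ns}}}stop"):
                grad.stops.append(
                    GradientStop(
                        offset=_parse_pct(_attr(sel, ns, "offset") or "0") / 100.0,
                        color=_attr(sel, ns, "stop-color"),
                    )
                )
            render.gradients.append(grad)
    lst = ri_el.find(f"{{{ns}}}listOfLineEndings")
    if lst is not None:
        for el in lst.findall(f"{{{ns}}}lineEnding"):
            render.line_endings.append(
                LineEnding(
                    ending_id=_attr(el, ns, "id"),
                    bbox=_read_bbox(el, ns_layout),
                    group=_read_group(el, ns, ns_layout),
                    rotational_mapping=(_attr(el, ns, "enableRotationalMapping") != "false"),
                )
            )
    lst = ri_el.find(f"{{{ns}}}listOfStyles")
    if lst is not None:
        for el in lst.findall(f"{{{ns}}}style"):
            render.styles.append(
                Style(
                    style_id=_attr(el, ns, "id"),
                    role_list=(_attr(el, ns, "roleList") or "").split(),
                    type_list=(_attr(el, ns, "typeList") or "").split(),
                    id_list=(_attr(el, ns, "idList") or "").split(),
                    group=_read_group(el, ns, ns_layout),
                )
            )
    return render


def _check_references_on_read(doc: Document) -> None:
    if doc.layout is None:
        return
    species_ids = {s.species_id for s in doc.model.species}
    reaction_ids = {r.reaction_id for r in doc.model.reactions}
    compartment_ids = {c.compartment_id for c in doc.model.compartments}
    for g in doc.layout.species_glyphs:
        if g.species_id is not None and g.species_id not in species_ids:
            raise ValidationError(
                f"species glyph {g.glyph_id!r} references unknown species {g.species_id!r}"
            )
    for g in doc.layout.reaction_glyphs:
        if g.reaction_id not in reaction_ids:
            raise ValidationError(
                f"reaction glyph {g.glyph_id!r} references unknown reaction {g.reaction_id!r}"
            )
    for g in doc.layout.compartment_glyphs:
        if g.compartment_id not in compartment_ids:
            raise ValidationError(
                f"compartment glyph {g.glyph_id!r} references unknown compartment "
                f"{g.compartment_id!r}"
            )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass
class Issue:
    severity: str  # "error" | "warning"
    message: str
    element_id: str


def validate_layout(doc: Document) -> list[Issue]:
    """Check all structural invariants; returns issues instead of raising."""
    issues: list[Issue] = []

    def err(element_id, message):
        issues.append(Issue("error", message, element_id))

    if doc.render is not None and doc.layout is None:
        err("document", "render information present without a layout")
    if doc.layout is None:
        return issues
    layout = doc.layout

    species_ids = {s.species_id for s in doc.model.species}
    reaction_ids = {r.reaction_id for r in doc.model.reactions}
    compartment_ids = {c.compartment_id for c in doc.model.compartments}

    seen: set[str] = set()
    for gid in layout.all_glyph_ids():
        if gid in seen:
            err(gid, "duplicate glyph id")
        seen.add(gid)

    def check_bbox(gid, bbox):
        if bbox.width < 0 or bbox.height < 0:
            err(gid, f"negative bounding-box dimensions ({bbox.width}, {bbox.height})")
        for v in (bbox.x, bbox.y, bbox.width, bbox.height):
            if not (v == v and abs(v) != float("inf")):
                err(gid, "non-finite bounding-box value")
                break

    species_glyph_ids = {g.glyph_id for g in layout.species_glyphs}
    for g in layout.species_glyphs:
        check_bbox(g.glyph_id, g.bbox)
        if g.species_id is not None and g.species_id not in species_ids:
            err(g.glyph_id, f"unknown species {g.species_id!r}")
        if g.alias_index < 0:
            err(g.glyph_id, "negative alias index")
    for g in layout.compartment_glyphs:
        check_bbox(g.glyph_id, g.bbox)
        if g.compartment_id not in compartment_ids:
            err(g.glyph_id, f"unknown compartment {g.compartment_id!r}")
    for rg in layout.reaction_glyphs:
        check_bbox(rg.glyph_id, rg.center_bbox)
        if rg.reaction_id not in reaction_ids:
            err(rg.glyph_id, f"unknown reaction {rg.reaction_id!r}")
        for srg in rg.reference_glyphs:
            if srg.species_glyph_id not in species_glyph_ids:
                err(srg.glyph_id, f"unresolved species glyph {srg.species_glyph_id!r}")
            for seg in srg.curve:
                if (seg.base_point_1 is None) != (seg.base_point_2 is None):
                    err(srg.glyph_id, "curve segment with exactly one base point")
                for pt in (seg.start, seg.end, seg.base_point_1, seg.base_point_2):
                    if pt is not None and not pt.is_finite():
                        err(srg.glyph_id, "non-finite curve coordinate")
    targets = seen
    for t in layout.text_glyphs:
        check_bbox(t.glyph_id, t.bbox)
        if t.target_glyph_id not in targets:
            err(t.glyph_id, f"unresolved text target {t.target_glyph_id!r}")
    for g in layout.additional_objects:
        check_bbox(g.glyph_id, g.bbox)

    # dimensions must enclose all boxes
    frame = BoundingBox(0.0, 0.0, layout.width, layout.height)
    for g in layout.all_glyphs():
        bbox = g.center_bbox if isinstance(g, ReactionGlyph) else g.bbox
        if bbox.width < 0 or bbox.height < 0:
            continue  # already reported above
        if not frame.contains(bbox, tol=1e-6):
            err(g.glyph_id, "bounding box outside layout dimensions")

    if doc.render is not None:
        _validate_render(doc, issues)
    return issues


def _validate_render(doc: Document, issues: list[Issue]) -> None:
    render = doc.render
    assert render is not None

    def err(element_id, message):
        issues.append(Issue("error", message, element_id))

    color_ids = {c.color_id for c in render.colors}
    gradient_ids = {g.gradient_id for g in render.gradients}
    ending_ids = {e.ending_id for e in render.line_endings}
    paint_ids = color_ids | gradient_ids | {"none"}

    for c in render.colors:
        if not HEX_COLOR_RE.match(c.value or ""):
            err(c.color_id, f"color value {c.value!r} is not canonical #RRGGBB[AA]")
    for g in render.gradients:
        if len(g.stops) < 2:
            err(g.gradient_id, "gradient needs at least 2 stops")
        else:
            offsets = [s.offset for s in g.stops]
            if offsets != sorted(offsets) or offsets[0] != 0.0 or offsets[-1] != 1.0:
                err(g.gradient_id, "gradient stop offsets must be non-decreasing from 0 to 1")
        for s in g.stops:
            if not (s.color.startswith("#") and HEX_COLOR_RE.match(s.color)) \
                    and s.color not in color_ids:
                err(g.gradient_id, f"gradient stop references undefined color {s.color!r}")

    def check_paint(owner_id, value, what):
        if value is None or value == "none":
            return
        if value.startswith("#"):
            if not HEX_COLOR_RE.match(value):
                err(owner_id, f"{what} {value!r} is not canonical #RRGGBB[AA]")
        elif value not in paint_ids:
            err(owner_id, f"{what} references undefined paint {value!r}")

    def check_group(owner_id, group):
        check_paint(owner_id, group.stroke, "stroke")
        check_paint(owner_id, group.fill, "fill")
        if group.stroke_width < 0:
            err(owner_id, f"negative stroke width {group.stroke_width}")
        for head in (group.start_head, group.end_head):
            if head is not None and head not in ending_ids:
                err(owner_id, f"undefined line ending {head!r}")

    for le in render.line_endings:
        if not le.group.primitives:
            err(le.ending_id, "line ending has no primitives")
        check_group(le.ending_id, le.group)

    seen_styles: set[str] = set()
    layout_ids = set(doc.layout.all_glyph_ids()) if doc.layout else set()
    for st in render.styles:
        if st.style_id in seen_styles:
            err(st.style_id, "duplicate style id")
        seen_styles.add(st.style_id)
        check_group(st.style_id, st.group)
        for gid in st.id_list:
            if gid not in layout_ids:
                err(st.style_id, f"id selector references unknown glyph {gid!r}")
    check_paint("renderInfo", render.background_color, "background color")


def fit_dimensions(layout: Layout, padding: float = 10.0) -> None:
    """Expand (never shrink) layout dimensions to enclose all bounding boxes."""
    max_x = layout.width
    max_y = layout.height
    for g in layout.all_glyphs():
        bbox = g.center_bbox if isinstance(g, ReactionGlyph) else g.bbox
        max_x = max(max_x, bbox.x + bbox.width + padding)
        max_y = max(max_y, bbox.y + bbox.height + padding)
    layout.width = max_x
    layout.height = max_y
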