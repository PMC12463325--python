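"""Figure export: SVG (native mapping of Render primitives) and raster/vector
formats (PNG/JPEG/PDF through matplotlib's Agg/PDF backends).

Z-order, back to front: background, compartments, reaction curves (with
arrowhead markers), species nodes, additional graphical objects (color bar),
text.  The SVG path is the reference renderer — every Render primitive maps
to its SVG counterpart (rectangle→rect, ellipse→ellipse, polygon→polygon,
curve→path, gradients→linearGradient defs, line endings→marker defs).  The
raster path draws the same primitives with matplotlib; gradients there are
approximated by their mean stop color and arrowheads by oriented polygons.
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass
from typing import Optional

from lxml import etree

from .errors import ParameterError
from .styling import default_render, make_style_resolver, resolve_color
from .types import (
    BoundingBox,
    CurveSegment,
    Document,
    EllipsePrimitive,
    LinearGradient,
    PolygonPrimitive,
    RectanglePrimitive,
    RenderCurvePrimitive,
    RenderGroup,
    ReactionGlyph,
    TextGlyph,
)

__all__ = ["ExportOptions", "to_svg", "to_bytes", "SUPPORTED_FORMATS"]

SVG_NS = "http://www.w3.org/2000/svg"
SUPPORTED_FORMATS = ("svg", "png", "jpeg", "pdf")


@dataclass
class ExportOptions:
    format: str = "svg"
    scale: float = 1.0  # pixels per layout pt (raster formats)
    background: Optional[str] = None

    def validate(self) -> None:
        if self.format not in SUPPORTED_FORMATS:
            raise ParameterError(
                f"unsupported format {self.format!r}; supported: "
                + ", ".join(SUPPORTED_FORMATS))
        if self.scale <= 0:
            raise ParameterError("scale must be > 0")


def _fmt(v: float) -> str:
    v = float(v)
    if v.is_integer() and abs(v) < 1e15:
        return str(int(v))
    return repr(v)


class _PaintResolver:
    def __init__(self, doc: Document):
        self.render = doc.render

    def resolve(self, paint: Optional[str]) -> str:
        """Map a paint reference to an SVG paint value."""
        if paint is None or paint == "none":
            return "none"
        if paint.startswith("#"):
            return paint
        if self.render is not None:
            c = self.render.find_color(paint)
            if c is not None:
                return c.value
            g = self.render.find_gradient(paint)
            if g is not None:
                return f"url(#{g.gradient_id})"
        try:
            return resolve_color(paint)
        except Exception:
            return "#000000"

    def flat_color(self, paint: Optional[str]) -> Optional[str]:
        """A single hex color approximating the paint (for raster gradients)."""
        if paint is None or paint == "none":
            return None
        if paint.startswith("#"):
            return paint[:7]
        if self.render is not None:
            c = self.render.find_color(paint)
            if c is not None:
                return c.value[:7]
            g = self.render.find_gradient(paint)
            if g is not None:
                rgbs = [_hex_rgb(resolve_color(s.color)) for s in g.stops]
                r = round(sum(c[0] for c in rgbs) / len(rgbs))
                gg = round(sum(c[1] for c in rgbs) / len(rgbs))
                b = round(sum(c[2] for c in rgbs) / len(rgbs))
                return f"#{r:02X}{gg:02X}{b:02X}"
        try:
            return resolve_color(paint)[:7]
        except Exception:
            return "#000000"


def _hex_rgb(color: str) -> tuple[int, int, int]:
    return (int(color[1:3], 16), int(color[3:5], 16), int(color[5:7], 16))


# ---------------------------------------------------------------------------
# SVG
# ---------------------------------------------------------------------------

def to_svg(doc: Document) -> str:
    """Render the document's Layout+Render data to SVG 1.1 text."""
    if doc.layout is None:
        raise ParameterError("document has no layout; run build_layout first")
    if doc.render is None:
        default_render(doc)
    layout = doc.layout
    paints = _PaintResolver(doc)
    resolve_style = make_style_resolver(doc)

    root = etree.Element(f"{{{SVG_NS}}}svg", nsmap={None: SVG_NS})
    root.set("width", _fmt(layout.width))
    root.set("height", _fmt(layout.height))
    root.set("viewBox", f"0 0 {_fmt(layout.width)} {_fmt(layout.height)}")
    root.set("version", "1.1")

    defs = etree.SubElement(root, f"{{{SVG_NS}}}defs")
    for grad in doc.render.gradients:
        _svg_gradient(defs, grad)
    for le in doc.render.line_endings:
        _svg_marker(defs, le, paints)

    bg = etree.SubElement(root, f"{{{SVG_NS}}}rect")
    bg.set("x", "0")
    bg.set("y", "0")
    bg.set("width", _fmt(layout.width))
    bg.set("height", _fmt(layout.height))
    bg.set("fill", paints.resolve(doc.render.background_color))

    ordered = (
        list(layout.compartment_glyphs)
        + list(layout.reaction_glyphs)
        + list(layout.species_glyphs)
        + list(layout.additional_objects)
        + list(layout.text_glyphs)
    )
    for glyph in ordered:
        g_el = etree.SubElement(root, f"{{{SVG_NS}}}g")
        g_el.set("id", glyph.glyph_id)
        group = resolve_style(glyph.glyph_id)
        if group is None:
            continue
        if isinstance(glyph, TextGlyph):
            _svg_text(g_el, glyph, group, paints)
            continue
        if isinstance(glyph, ReactionGlyph):
            for srg in glyph.reference_glyphs:
                srg_group = resolve_style(srg.glyph_id) or group
                _svg_curve(g_el, srg.glyph_id, srg.curve, srg_group, paints)
            _svg_primitives(g_el, glyph.center_bbox, group, paints)
            continue
        _svg_primitives(g_el, glyph.bbox, group, paints)

    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    ).decode("utf-8")


def _svg_gradient(defs, grad: LinearGradient) -> None:
    el = etree.SubElement(defs, f"{{{SVG_NS}}}linearGradient")
    el.set("id", grad.gradient_id)
    el.set("x1", f"{_fmt(grad.x1)}%")
    el.set("y1", f"{_fmt(grad.y1)}%")
    el.set("x2", f"{_fmt(grad.x2)}%")
    el.set("y2", f"{_fmt(grad.y2)}%")
    for stop in grad.stops:
        s = etree.SubElement(el, f"{{{SVG_NS}}}stop")
        s.set("offset", f"{_fmt(stop.offset * 100.0)}%")
        s.set("stop-color", resolve_color(stop.color))


def _svg_marker(defs, le, paints) -> None:
    w, h = le.bbox.width, le.bbox.height
    marker = etree.SubElement(defs, f"{{{SVG_NS}}}marker")
    marker.set("id", le.ending_id)
    marker.set("markerWidth", _fmt(w))
    marker.set("markerHeight", _fmt(h))
    marker.set("viewBox", f"0 0 {_fmt(w)} {_fmt(h)}")
    marker.set("refX", _fmt(-le.bbox.x))
    marker.set("refY", _fmt(-le.bbox.y))
    marker.set("markerUnits", "userSpaceOnUse")
    marker.set("orient", "auto" if le.rotational_mapping else "0")
    frame = BoundingBox(0.0, 0.0, w, h)
    _svg_primitives(marker, frame, le.group, paints)


def _style_attrs(el, group: RenderGroup, paints, with_fill=True) -> None:
    el.set("stroke", paints.resolve(group.stroke))
    el.set("stroke-width", _fmt(group.stroke_width))
    if group.stroke_dasharray:
        el.set("stroke-dasharray", ",".join(_fmt(v) for v in group.stroke_dasharray))
    if with_fill:
        el.set("fill", paints.resolve(group.fill))


def _svg_primitives(parent, bbox: BoundingBox, group: RenderGroup, paints) -> None:
    def ax(px):  # percent of bbox → absolute
        return bbox.x + px / 100.0 * bbox.width

    def ay(py):
        return bbox.y + py / 100.0 * bbox.height

    for prim in group.primitives:
        if isinstance(prim, RectanglePrimitive):
            el = etree.SubElement(parent, f"{{{SVG_NS}}}rect")
            el.set("x", _fmt(ax(prim.x)))
            el.set("y", _fmt(ay(prim.y)))
            el.set("width", _fmt(prim.width / 100.0 * bbox.width))
            el.set("height", _fmt(prim.height / 100.0 * bbox.height))
            if prim.rx:
                el.set("rx", _fmt(prim.rx))
            if prim.ry:
                el.set("ry", _fmt(prim.ry))
            _style_attrs(el, group, paints)
        elif isinstance(prim, EllipsePrimitive):
            el = etree.SubElement(parent, f"{{{SVG_NS}}}ellipse")
            el.set("cx", _fmt(ax(prim.cx)))
            el.set("cy", _fmt(ay(prim.cy)))
            el.set("rx", _fmt(prim.rx / 100.0 * bbox.width))
            el.set("ry", _fmt(prim.ry / 100.0 * bbox.height))
            _style_attrs(el, group, paints)
        elif isinstance(prim, PolygonPrimitive):
            el = etree.SubElement(parent, f"{{{SVG_NS}}}polygon")
            el.set("points", " ".join(f"{_fmt(ax(px))},{_fmt(ay(py))}"
                                      for px, py in prim.points))
            _style_attrs(el, group, paints)
        elif isinstance(prim, RenderCurvePrimitive):
            el = etree.SubElement(parent, f"{{{SVG_NS}}}polyline")
            el.set("points", " ".join(f"{_fmt(ax(px))},{_fmt(ay(py))}"
                                      for px, py in prim.points))
            _style_attrs(el, group, paints, with_fill=False)
            el.set("fill", "none")


def _curve_path_d(segments: list[CurveSegment]) -> str:
    parts = []
    for i, seg in enumerate(segments):
        if i == 0:
            parts.append(f"M {_fmt(seg.start.x)} {_fmt(seg.start.y)}")
        if seg.is_cubic:
            parts.append(
                "C "
                f"{_fmt(seg.base_point_1.x)} {_fmt(seg.base_point_1.y)}, "
                f"{_fmt(seg.base_point_2.x)} {_fmt(seg.base_point_2.y)}, "
                f"{_fmt(seg.end.x)} {_fmt(seg.end.y)}"
            )
        else:
            parts.append(f"L {_fmt(seg.end.x)} {_fmt(seg.end.y)}")
    return " ".join(parts)


def _svg_curve(parent, glyph_id: str, segments, group: RenderGroup, paints) -> None:
    if not segments:
        return
    el = etree.SubElement(parent, f"{{{SVG_NS}}}path")
    el.set("id", glyph_id)
    el.set("d", _curve_path_d(segments))
    el.set("fill", "none")
    _style_attrs(el, group, paints, with_fill=False)
    if group.end_head:
        el.set("marker-end", f"url(#{group.end_head})")
    if group.start_head:
        el.set("marker-start", f"url(#{group.start_head})")


def _svg_text(parent, glyph: TextGlyph, group: RenderGroup, paints) -> None:
    el = etree.SubElement(parent, f"{{{SVG_NS}}}text")
    c = glyph.bbox.center
    el.set("x", _fmt(c.x))
    el.set("y", _fmt(c.y))
    el.set("text-anchor", group.text_anchor)
    el.set("dominant-baseline", "central")
    el.set("font-family", group.font_family)
    el.set("font-size", _fmt(group.font_size))
    if group.font_weight != "normal":
        el.set("font-weight", group.font_weight)
    el.set("fill", paints.resolve(group.stroke) if group.stroke else "#000000")
    el.text = glyph.text


# ---------------------------------------------------------------------------
# Raster / PDF via matplotlib
# ---------------------------------------------------------------------------

def to_bytes(doc: Document, opts: Optional[ExportOptions] = None) -> bytes:
    """Binary export.  SVG returns the UTF-8 of :func:`to_svg`; PNG/JPEG are
    rasterized at `scale` px per pt (output dims = ceil(layout dims × scale));
    PDF is vector."""
    opts = opts or ExportOptions()
    opts.validate()
    if opts.format == "svg":
        return to_svg(doc).encode("utf-8")
    return _render_matplotlib(doc, opts)


def _render_matplotlib(doc: Document, opts: ExportOptions) -> bytes:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.patches import Ellipse, FancyBboxPatch, PathPatch, Polygon, Rectangle
    from matplotlib.path import Path as MplPath

    if doc.layout is None:
        raise ParameterError("document has no layout; run build_layout first")
    if doc.render is None:
        default_render(doc)
    layout = doc.layout
    paints = _PaintResolver(doc)
    resolve_style = make_style_resolver(doc)

    px_w = math.ceil(layout.width * opts.scale)
    px_h = math.ceil(layout.height * opts.scale)
    dpi = 100.0
    fig = plt.figure(figsize=(px_w / dpi, px_h / dpi), dpi=dpi)
    ax = fig.add_axes([0, 0, 1, 1])
    ax.set_xlim(0, layout.width)
    ax.set_ylim(layout.height, 0)  # y-down
    ax.axis("off")
    bg = opts.background or doc.render.background_color
    fig.patch.set_facecolor(paints.flat_color(bg) or "#FFFFFF")

    def draw_primitives(bbox: BoundingBox, group: RenderGroup, z: float):
        stroke = paints.flat_color(group.stroke)
        fill = paints.flat_color(group.fill)
        lw = group.stroke_width
        common = dict(
            linewidth=lw,
            edgecolor=stroke or "none",
            facecolor=fill or "none",
            zorder=z,
        )
        for prim in group.primitives:
            if isinstance(prim, RectanglePrimitive):
                x = bbox.x + prim.x / 100.0 * bbox.width
                y = bbox.y + prim.y / 100.0 * bbox.height
                w = prim.width / 100.0 * bbox.width
                h = prim.height / 100.0 * bbox.height
                if prim.rx:
                    patch = FancyBboxPatch(
                        (x + prim.rx, y + prim.ry), max(w - 2 * prim.rx, 0.1),
                        max(h - 2 * prim.ry, 0.1),
                        boxstyle=f"round,pad={min(prim.rx, prim.ry)}", **common)
                else:
                    patch = Rectangle((x, y), w, h, **common)
                ax.add_patch(patch)
            elif isinstance(prim, EllipsePrimitive):
                cx = bbox.x + prim.cx / 100.0 * bbox.width
                cy = bbox.y + prim.cy / 100.0 * bbox.height
                ax.add_patch(Ellipse((cx, cy), prim.rx / 50.0 * bbox.width,
                                     prim.ry / 50.0 * bbox.height, **common))
            elif isinstance(prim, (PolygonPrimitive, RenderCurvePrimitive)):
                pts = [(bbox.x + px / 100.0 * bbox.width,
                        bbox.y + py / 100.0 * bbox.height) for px, py in prim.points]
                if len(pts) >= 2:
                    closed = isinstance(prim, PolygonPrimitive)
                    kw = dict(common)
                    if not closed:
                        kw["facecolor"] = "none"
                    ax.add_patch(Polygon(pts, closed=closed, **kw))

    def draw_curve(segments, group: RenderGroup, z: float):
        stroke = paints.flat_color(group.stroke) or "#000000"
        verts, codes = [], []
        for i, seg in enumerate(segments):
            if i == 0:
                verts.append((seg.start.x, seg.start.y))
                codes.append(MplPath.MOVETO)
            if seg.is_cubic:
                verts.extend([
                    (seg.base_point_1.x, seg.base_point_1.y),
                    (seg.base_point_2.x, seg.base_point_2.y),
                    (seg.end.x, seg.end.y),
                ])
                codes.extend([MplPath.CURVE4] * 3)
            else:
                verts.append((seg.end.x, seg.end.y))
                codes.append(MplPath.LINETO)
        if not verts:
            return
        dashes = (0, tuple(group.stroke_dasharray)) if group.stroke_dasharray else None
        patch = PathPatch(MplPath(verts, codes), fill=False, edgecolor=stroke,
                          linewidth=group.stroke_width, zorder=z)
        if dashes:
            patch.set_linestyle((0, tuple(group.stroke_dasharray)))
        ax.add_patch(patch)
        if group.end_head:
            last = segments[-1]
            ref = last.base_point_2 if last.is_cubic else last.start
            dx = last.end.x - ref.x
            dy = last.end.y - ref.y
            norm = math.hypot(dx, dy)
            if norm > 1e-9:
                ux, uy = dx / norm, dy / norm
                size = 10.0
                tip = (last.end.x, last.end.y)
                left = (tip[0] - ux * size - uy * size * 0.5,
                        tip[1] - uy * size + ux * size * 0.5)
                right = (tip[0] - ux * size + uy * size * 0.5,
                         tip[1] - uy * size - ux * size * 0.5)
                ax.add_patch(Polygon([tip, left, right], closed=True,
                                     facecolor=stroke, edgecolor=stroke, zorder=z))

    for g in layout.compartment_glyphs:
        group = resolve_style(g.glyph_id)
        if group:
            draw_primitives(g.bbox, group, 1.0)
    for rg in layout.reaction_glyphs:
        group = resolve_style(rg.glyph_id)
        for srg in rg.reference_glyphs:
            sg_group = resolve_style(srg.glyph_id) or group
            if sg_group:
                draw_curve(srg.curve, sg_group, 2.0)
        if group:
            draw_primitives(rg.center_bbox, group, 2.5)
    for g in layout.species_glyphs:
        group = resolve_style(g.glyph_id)
        if group:
            draw_primitives(g.bbox, group, 3.0)
    for g in layout.additional_objects:
        group = resolve_style(g.glyph_id)
        if group:
            draw_primitives(g.bbox, group, 4.0)
    for t in layout.text_glyphs:
        group = resolve_style(t.glyph_id)
        if group is None:
            continue
        c = t.bbox.center
        ax.text(c.x, c.y, t.text,
                ha={"middle": "center", "start": "left", "end": "right"}.get(
                    group.text_anchor, "center"),
                va="center",
                fontsize=group.font_size,
                fontfamily="sans-serif",
                fontweight=group.font_weight,
                color=paints.flat_color(group.stroke) or "#000000",
                zorder=5.0)

    buf = _io.BytesIO()
    fmt = {"jpeg": "jpg"}.get(opts.format, opts.format)
    save_kw = {"format": fmt, "dpi": dpi}
    if opts.format in ("png", "jpeg"):
        save_kw["facecolor"] = fig.get_facecolor()
    fig.savefig(buf, **save_kw)
    plt.close(fig)
    return buf.getvalue()
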