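"""Quantitative data overlays.

Maps reaction fluxes / species concentrations onto visual channels (gradient
color, curve thickness, node size) and renders a color bar.  All overlay
output is written as id-selector override styles plus ordinary Layout/Render
elements, so the base template survives untouched and everything round-trips
through the SBML file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from .autolayout import LayoutParams, rebuild_reaction_curves
from .errors import ParameterError, UnknownElementError
from .io import fit_dimensions
from .styling import batch_set, default_render, resolve_color
from .types import (
    BoundingBox,
    Document,
    GradientStop,
    GraphicalObject,
    LinearGradient,
    Point,
    RenderGroup,
    Style,
    TextGlyph,
)

__all__ = [
    "ValueMap",
    "OverlaySpec",
    "ColorBarSpec",
    "default_gradient",
    "normalize_values",
    "value_to_color",
    "overlay_reaction_values",
    "overlay_species_values",
    "add_colorbar",
    "read_value_map",
]

ValueMap = dict[str, float]


def default_gradient(gradient_id: str = "flux_gradient") -> LinearGradient:
    """Muted blue → light gray → vivid red: high values read as vivid hues,
    low values as muted tones."""
    return LinearGradient(
        gradient_id=gradient_id,
        stops=[
            GradientStop(0.0, "#5B7DA2"),
            GradientStop(0.5, "#D9D9D9"),
            GradientStop(1.0, "#E8262C"),
        ],
    )


@dataclass
class OverlaySpec:
    """Declarative mapping from numbers to one visual channel.

    `normalization="symmetric"` centers zero at fraction 0.5 with range
    ±max|v| — the documented convention for signed (reversible) fluxes.
    """

    target: str = "reactions"  # "reactions" | "species"
    channel: str = "color"  # "color" | "width" | "size"
    gradient: Optional[LinearGradient] = None
    out_range: tuple[float, float] = (1.0, 10.0)
    value_range: Optional[tuple[float, float]] = None
    missing_policy: str = "error"  # "error" | "skip" | "dim"
    normalization: str = "linear"  # "linear" | "symmetric"

    def validate(self) -> None:
        if self.target not in ("reactions", "species"):
            raise ParameterError(f"target must be 'reactions' or 'species', got {self.target!r}")
        if self.channel not in ("color", "width", "size"):
            raise ParameterError(f"channel must be color/width/size, got {self.channel!r}")
        if self.out_range[0] > self.out_range[1]:
            raise ParameterError("out_range min must be ≤ max")
        if self.missing_policy not in ("error", "skip", "dim"):
            raise ParameterError(f"unknown missing_policy {self.missing_policy!r}")


@dataclass
class ColorBarSpec:
    position: Optional[Point] = None  # default: right edge of the layout
    width: float = 18.0
    height: float = 160.0
    orientation: str = "vertical"  # "vertical" | "horizontal"
    tick_count: int = 5
    label_format: str = "{:g}"

    def validate(self) -> None:
        if self.tick_count < 2:
            raise ParameterError("tick_count must be ≥ 2")
        if self.orientation not in ("vertical", "horizontal"):
            raise ParameterError(f"unknown orientation {self.orientation!r}")


# ---------------------------------------------------------------------------
# Value normalization and color interpolation
# ---------------------------------------------------------------------------

def normalize_values(
    values: ValueMap,
    value_range: Optional[tuple[float, float]] = None,
    normalization: str = "linear",
) -> dict[str, float]:
    """Linear min–max scaling to [0, 1]; out-of-range values are clipped.

    A degenerate range (vmin == vmax, e.g. a single value) maps everything to
    0.5.  `normalization="symmetric"` uses the range ±max|v| so zero lands at
    fraction 0.5.
    """
    if not values:
        raise ParameterError("empty value map")
    for k, v in values.items():
        if not math.isfinite(v):
            raise ParameterError(f"non-finite value for {k!r}")
    if normalization == "symmetric" and value_range is None:
        vmax = max(abs(v) for v in values.values())
        vmin = -vmax
    elif value_range is not None:
        vmin, vmax = value_range
        if vmin > vmax:
            raise ParameterError("value_range min must be ≤ max")
    else:
        vmin = min(values.values())
        vmax = max(values.values())
    if vmin == vmax:
        return {k: 0.5 for k in values}
    span = vmax - vmin
    return {k: min(1.0, max(0.0, (v - vmin) / span)) for k, v in values.items()}


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _hex_to_rgb(color: str) -> tuple[int, int, int]:
    color = resolve_color(color)
    return (int(color[1:3], 16), int(color[3:5], 16), int(color[5:7], 16))


def value_to_color(fraction: float, gradient: LinearGradient) -> str:
    """Interpolate a gradient at `fraction` ∈ [0, 1] to "#RRGGBB".

    Per-channel linear interpolation in 8-bit RGB with round-half-up;
    fractions 0 and 1 return the first/last stop colors exactly.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ParameterError(
            f"fraction {fraction} outside [0, 1]; normalize values first")
    stops = gradient.stops
    if not stops:
        raise ParameterError(f"gradient {gradient.gradient_id!r} has no stops")
    if fraction <= stops[0].offset:
        return resolve_color(stops[0].color)
    if fraction >= stops[-1].offset:
        return resolve_color(stops[-1].color)
    for lo, hi in zip(stops, stops[1:]):
        if lo.offset <= fraction <= hi.offset:
            if hi.offset == lo.offset:
                continue
            t = (fraction - lo.offset) / (hi.offset - lo.offset)
            r1, g1, b1 = _hex_to_rgb(lo.color)
            r2, g2, b2 = _hex_to_rgb(hi.color)
            r = _round_half_up(r1 + t * (r2 - r1))
            g = _round_half_up(g1 + t * (g2 - g1))
            b = _round_half_up(b1 + t * (b2 - b1))
            return f"#{r:02X}{g:02X}{b:02X}"
    return resolve_color(stops[-1].color)  # pragma: no cover


# ---------------------------------------------------------------------------
# Overlays
# ---------------------------------------------------------------------------

def _prepare(doc: Document, spec: OverlaySpec) -> None:
    spec.validate()
    if doc.layout is None:
        raise ParameterError("document has no layout; run build_layout first")
    if doc.render is None:
        default_render(doc)


def _resolve_targets(doc, values, spec, known_ids) -> tuple[ValueMap, list[str]]:
    """Split the value map into (present, missing) per the missing policy."""
    present: ValueMap = {}
    missing: list[str] = []
    for key, v in values.items():
        if key in known_ids:
            present[key] = v
        else:
            missing.append(key)
    if missing and spec.missing_policy == "error":
        raise UnknownElementError(
            f"value map names unknown ids: {', '.join(sorted(missing))}")
    return present, missing


def overlay_reaction_values(doc: Document, values: ValueMap, spec: OverlaySpec) -> Document:
    """Encode reaction values as curve stroke color or thickness."""
    _prepare(doc, spec)
    if spec.target != "reactions":
        raise ParameterError("spec.target must be 'reactions'")
    if spec.channel == "size":
        raise ParameterError("the size channel applies to species, not reactions")
    known = {rg.reaction_id for rg in doc.layout.reaction_glyphs}
    present, _ = _resolve_targets(doc, values, spec, known)
    if not present:
        return doc
    fractions = normalize_values(present, spec.value_range, spec.normalization)
    gradient = spec.gradient or default_gradient()
    for rid, frac in fractions.items():
        rg = doc.layout.find_reaction_glyph_by_reaction(rid)
        ids = [rg.glyph_id] + [srg.glyph_id for srg in rg.reference_glyphs]
        if spec.channel == "color":
            batch_set(doc, ids, "stroke", value_to_color(frac, gradient))
        else:  # width
            lo, hi = spec.out_range
            batch_set(doc, ids, "stroke-width", lo + frac * (hi - lo))
    if spec.missing_policy == "dim":
        for rg in doc.layout.reaction_glyphs:
            if rg.reaction_id not in present:
                ids = [rg.glyph_id] + [srg.glyph_id for srg in rg.reference_glyphs]
                batch_set(doc, ids, "stroke", "#D3D3D3")
    return doc


#: Reference width a size overlay scales against (the default species box).
DEFAULT_SPECIES_SIZE = (60.0, 36.0)


def overlay_species_values(doc: Document, values: ValueMap, spec: OverlaySpec) -> Document:
    """Encode species values as node fill color or node size.

    Color applies identically to every alias glyph of a species; size scales
    each alias bbox about its center to `out_min + f·(out_max − out_min)`
    times the default width (aspect preserved) and re-attaches curves.
    """
    _prepare(doc, spec)
    if spec.target != "species":
        raise ParameterError("spec.target must be 'species'")
    if spec.channel == "width":
        raise ParameterError("the width channel applies to reaction curves, not species")
    known = {g.species_id for g in doc.layout.species_glyphs if g.species_id}
    present, _ = _resolve_targets(doc, values, spec, known)
    if not present:
        return doc
    fractions = normalize_values(present, spec.value_range, spec.normalization)
    gradient = spec.gradient or default_gradient()
    touched_reactions = set()
    for sid, frac in fractions.items():
        glyphs = doc.layout.species_glyphs_of(sid)
        ids = [g.glyph_id for g in glyphs]
        if spec.channel == "color":
            batch_set(doc, ids, "fill", value_to_color(frac, gradient))
        else:  # size
            lo, hi = spec.out_range
            factor = lo + frac * (hi - lo)
            for g in glyphs:
                c = g.bbox.center
                g.bbox = BoundingBox.centered(
                    c, factor * DEFAULT_SPECIES_SIZE[0], factor * DEFAULT_SPECIES_SIZE[1])
                t = doc.layout.find_text_glyph_for(g.glyph_id)
                if t is not None:
                    t.bbox = BoundingBox(g.bbox.x, g.bbox.y, g.bbox.width, g.bbox.height)
                for rg in doc.layout.reaction_glyphs:
                    if any(srg.species_glyph_id == g.glyph_id for srg in rg.reference_glyphs):
                        touched_reactions.add(rg.glyph_id)
    if spec.missing_policy == "dim":
        dim_ids = [g.glyph_id for g in doc.layout.species_glyphs
                   if g.species_id and g.species_id not in present]
        if dim_ids:
            batch_set(doc, dim_ids, "fill", "#D3D3D3")
    for rg in doc.layout.reaction_glyphs:
        if rg.glyph_id in touched_reactions:
            rebuild_reaction_curves(doc, rg, LayoutParams())
    fit_dimensions(doc.layout)
    return doc


# ---------------------------------------------------------------------------
# Color bar
# ---------------------------------------------------------------------------

def add_colorbar(
    doc: Document,
    gradient: LinearGradient,
    value_range: tuple[float, float],
    bar: Optional[ColorBarSpec] = None,
) -> Document:
    """Add a gradient-filled bar plus tick labels, all as ordinary
    Layout+Render elements (so the bar round-trips inside the SBML file)."""
    if doc.layout is None:
        raise ParameterError("document has no layout; run build_layout first")
    vmin, vmax = value_range
    if vmin > vmax:
        raise ParameterError(f"value range min {vmin} exceeds max {vmax}")
    bar = bar or ColorBarSpec()
    bar.validate()
    if doc.render is None:
        default_render(doc)
    layout = doc.layout

    pos = bar.position
    if pos is None:
        pos = Point(layout.width + 20.0, 20.0)
    if bar.orientation == "vertical":
        bbox = BoundingBox(pos.x, pos.y, bar.width, bar.height)
    else:
        bbox = BoundingBox(pos.x, pos.y, bar.height, bar.width)

    existing = {g.glyph_id for g in layout.all_glyphs()}
    bar_id = "colorbar"
    suffix = 0
    while bar_id in existing:
        suffix += 1
        bar_id = f"colorbar_{suffix}"
    layout.additional_objects.append(GraphicalObject(glyph_id=bar_id, bbox=bbox))

    grad = LinearGradient(
        gradient_id=gradient.gradient_id,
        stops=[GradientStop(s.offset, resolve_color(s.color)) for s in gradient.stops],
    )
    if bar.orientation == "vertical":
        # vmin at the bottom, vmax at the top
        grad.x1, grad.y1, grad.x2, grad.y2 = 0.0, 100.0, 0.0, 0.0
    else:
        grad.x1, grad.y1, grad.x2, grad.y2 = 0.0, 0.0, 100.0, 0.0
    doc.render.gradients = [g for g in doc.render.gradients
                            if g.gradient_id != grad.gradient_id]
    doc.render.gradients.append(grad)

    doc.render.styles.append(
        Style(f"style_{bar_id}",
              RenderGroup(stroke="#000000", stroke_width=1.0, fill=grad.gradient_id),
              id_list=[bar_id]))

    n = bar.tick_count
    for i in range(n):
        t = i / (n - 1)
        value = vmin + t * (vmax - vmin)
        label = bar.label_format.format(value)
        if bar.orientation == "vertical":
            ty = bbox.y + bbox.height - t * bbox.height - 7.0
            tb = BoundingBox(bbox.x + bbox.width + 4.0, ty, 40.0, 14.0)
        else:
            tx = bbox.x + t * bbox.width - 20.0
            tb = BoundingBox(tx, bbox.y + bbox.height + 4.0, 40.0, 14.0)
        layout.text_glyphs.append(
            TextGlyph(
                glyph_id=f"{bar_id}_tick_{i}",
                target_glyph_id=bar_id,
                text=label,
                bbox=tb,
            )
        )
    fit_dimensions(layout)
    return doc


# ---------------------------------------------------------------------------
# Value files
# ---------------------------------------------------------------------------

def read_value_map(path: str) -> ValueMap:
    """Read `id,value` delimited text (comma or tab auto-detected; '#'
    comment lines and an optional header row are skipped)."""
    values: ValueMap = {}
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    rows = []
    for ln in lines:
        if not ln or ln.startswith("#"):
            continue
        delim = "\t" if "\t" in ln else ","
        parts = [p.strip() for p in ln.split(delim)]
        if len(parts) < 2:
            raise ParameterError(f"malformed value-map line: {ln!r}")
        rows.append(parts[:2])
    for i, (key, raw) in enumerate(rows):
        try:
            values[key] = float(raw)
        except ValueError:
            if i == 0:  # header row
                continue
            raise ParameterError(f"non-numeric value {raw!r} for id {key!r}") from None
    if not values:
        raise ParameterError("value map file contains no data rows")
    return values
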