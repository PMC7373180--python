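"""Rendering of a layout to SVG (authoritative) and PNG/PDF (derived).

Glyph shapes follow the SBGN Process Description visual vocabulary:
macromolecules are rounded rectangles, simple chemicals ellipses, nucleic
acid features bottom-rounded rectangles, complexes octagonal boxes,
phenotypes hexagons, source/sink an empty-set circle, processes small
squares sitting on the reaction curve, residue states small labelled
circles on the entity border.

All shape logic produces format-agnostic drawing primitives once
(:func:`glyph_shape`); the SVG, PNG and PDF backends only translate
primitives, so the three outputs cannot drift apart.  Z-order is fixed:
compartments back-to-front by area (largest first), then complexes, then
species, then reactions, then labels — nested compartments therefore always
paint over their parents.

Label widths are estimated from a bundled Helvetica metric table rather
than system fonts, keeping output byte-identical across machines.
"""

from __future__ import annotations

import io
import math
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

from lxml import etree

from .model import (
    BoundingBox,
    ColorRGBA,
    CurveSegment,
    Document,
    ElementClass,
    FontSpec,
    Glyph,
    GlyphKind,
    Layout,
    ModelError,
    ModificationState,
    Point,
    Style,
    bbox,
    canvas_bounds,
    style_for_glyph,
)

BLACK = ColorRGBA(0, 0, 0)
WHITE = ColorRGBA(255, 255, 255)
DEFAULT_STYLE = Style(id="default", stroke=BLACK, stroke_width=1.0, fill=WHITE)

# Helvetica advance widths (units per 1000 em) for ASCII 32..126; anything
# outside the range uses the average width.
_HELVETICA_WIDTHS = [
    278, 278, 355, 556, 556, 889, 667, 191, 333, 333, 389, 584, 278, 333,
    278, 278, 556, 556, 556, 556, 556, 556, 556, 556, 556, 556, 278, 278,
    584, 584, 584, 556, 1015, 667, 667, 722, 722, 667, 611, 778, 722, 278,
    500, 667, 556, 833, 722, 778, 667, 778, 722, 667, 611, 722, 667, 944,
    667, 667, 611, 278, 278, 278, 469, 556, 333, 556, 556, 500, 556, 556,
    278, 556, 556, 222, 222, 500, 222, 833, 556, 556, 556, 556, 333, 500,
    278, 556, 500, 722, 500, 500, 500, 334, 260, 334, 584,
]
_AVG_WIDTH = sum(_HELVETICA_WIDTHS) / len(_HELVETICA_WIDTHS)


def text_width(text: str, font_size: float) -> float:
    """Estimated advance width in diagram units."""
    units = sum(
        _HELVETICA_WIDTHS[ord(c) - 32] if 32 <= ord(c) < 127 else _AVG_WIDTH for c in text
    )
    return units * font_size / 1000.0


# ---------------------------------------------------------------------------
# drawing primitives
# ---------------------------------------------------------------------------


@dataclass
class PathPrim:
    segments: list[CurveSegment]
    closed: bool = False
    stroke: ColorRGBA = BLACK
    stroke_width: float = 1.0
    fill: Optional[ColorRGBA] = None


@dataclass
class EllipsePrim:
    cx: float
    cy: float
    rx: float
    ry: float
    stroke: ColorRGBA = BLACK
    stroke_width: float = 1.0
    fill: Optional[ColorRGBA] = None


@dataclass
class TextPrim:
    x: float  # anchor center
    y: float  # baseline center
    text: str
    font: FontSpec = field(default_factory=FontSpec)
    color: ColorRGBA = BLACK


Primitive = object  # PathPrim | EllipsePrim | TextPrim


def _poly(points: Sequence[tuple[float, float]], style: Style, closed: bool = True) -> PathPrim:
    segs = [
        CurveSegment("line", Point(*points[i]), Point(*points[(i + 1) % len(points)]))
        for i in range(len(points) - (0 if closed else 1))
    ]
    return PathPrim(segs, closed=closed, stroke=style.stroke, stroke_width=style.stroke_width,
                    fill=style.fill if closed else None)


def _rounded_rect(b: BoundingBox, r: float, style: Style,
                  round_top: bool = True, round_bottom: bool = True) -> PathPrim:
    """Rectangle with quarter-circle corners approximated by cubic beziers."""
    k = 0.5523  # circle-to-bezier constant
    x0, y0, x1, y1 = b.x, b.y, b.x + b.width, b.y + b.height
    rt = r if round_top else 0.0
    rb = r if round_bottom else 0.0
    segs: list[CurveSegment] = []

    def lineseg(a: tuple, c: tuple) -> None:
        if a != c:
            segs.append(CurveSegment("line", Point(*a), Point(*c)))

    def corner(a: tuple, ctrl: tuple, c: tuple, radius: float) -> None:
        if radius <= 0:
            lineseg(a, c)
            return
        c1 = (a[0] + (ctrl[0] - a[0]) * k, a[1] + (ctrl[1] - a[1]) * k)
        c2 = (c[0] + (ctrl[0] - c[0]) * k, c[1] + (ctrl[1] - c[1]) * k)
        segs.append(CurveSegment("cubic-bezier", Point(*a), Point(*c), Point(*c1), Point(*c2)))

    lineseg((x0 + rt, y0), (x1 - rt, y0))
    corner((x1 - rt, y0), (x1, y0), (x1, y0 + rt), rt)
    lineseg((x1, y0 + rt), (x1, y1 - rb))
    corner((x1, y1 - rb), (x1, y1), (x1 - rb, y1), rb)
    lineseg((x1 - rb, y1), (x0 + rb, y1))
    corner((x0 + rb, y1), (x0, y1), (x0, y1 - rb), rb)
    lineseg((x0, y1 - rb), (x0, y0 + rt))
    corner((x0, y0 + rt), (x0, y0), (x0 + rt, y0), rt)
    return PathPrim(segs, closed=True, stroke=style.stroke, stroke_width=style.stroke_width,
                    fill=style.fill)


def glyph_shape(
    glyph: Glyph,
    element_class: Optional[ElementClass] = None,
    style: Optional[Style] = None,
    modifications: Sequence[ModificationState] = (),
    label: Optional[str] = None,
) -> list[Primitive]:
    """Drawing primitives for one glyph per the PD visual vocabulary."""
    style = style or DEFAULT_STYLE
    prims: list[Primitive] = []

    if glyph.kind == GlyphKind.REACTION:
        if not glyph.curve and not glyph.participant_links:
            raise ModelError("no-geometry", f"reaction glyph {glyph.id!r} has no curve")
        for link in glyph.participant_links:
            if link.curve:
                prims.append(PathPrim(list(link.curve), closed=False, stroke=style.stroke,
                                      stroke_width=style.stroke_width))
        if glyph.curve:
            prims.append(PathPrim(list(glyph.curve), closed=False, stroke=style.stroke,
                                  stroke_width=style.stroke_width))
            mid = _curve_midpoint(glyph.curve)
            s = 8.0
            square = bbox(mid.x - s / 2, mid.y - s / 2, s, s)
            prims.append(_poly(_rect_pts(square), Style(id="", stroke=style.stroke,
                                                        stroke_width=style.stroke_width,
                                                        fill=WHITE)))
        return prims

    if glyph.kind == GlyphKind.TEXT:
        if glyph.bbox is None:
            raise ModelError("no-geometry", f"text glyph {glyph.id!r} has no bbox")
        font = style.font or FontSpec()
        c = glyph.bbox.center
        prims.append(TextPrim(c.x, c.y, glyph.text or "", font=font, color=style.stroke))
        return prims

    b = glyph.bbox
    if b is None:
        raise ModelError("no-geometry", f"entity glyph {glyph.id!r} has no bbox")

    cls = element_class or ElementClass.UNSPECIFIED
    if glyph.kind == GlyphKind.COMPARTMENT:
        prims.append(_rounded_rect(b, min(15.0, b.width / 4, b.height / 4), style))
    elif cls in (ElementClass.MACROMOLECULE, ElementClass.RECEPTOR):
        prims.append(_rounded_rect(b, min(10.0, b.width / 4, b.height / 4), style))
    elif cls in (ElementClass.SIMPLE_CHEMICAL, ElementClass.ION, ElementClass.UNSPECIFIED):
        prims.append(EllipsePrim(b.center.x, b.center.y, b.width / 2, b.height / 2,
                                 stroke=style.stroke, stroke_width=style.stroke_width,
                                 fill=style.fill))
    elif cls in (ElementClass.NUCLEIC_ACID_FEATURE, ElementClass.GENE, ElementClass.RNA):
        prims.append(_rounded_rect(b, min(10.0, b.width / 4, b.height / 4), style,
                                   round_top=False))
    elif cls == ElementClass.COMPLEX:
        c = min(12.0, b.width / 4, b.height / 4)
        x0, y0, x1, y1 = b.x, b.y, b.x + b.width, b.y + b.height
        prims.append(_poly([(x0 + c, y0), (x1 - c, y0), (x1, y0 + c), (x1, y1 - c),
                            (x1 - c, y1), (x0 + c, y1), (x0, y1 - c), (x0, y0 + c)], style))
    elif cls == ElementClass.PHENOTYPE:
        c = min(15.0, b.width / 4)
        x0, y0, x1, y1 = b.x, b.y, b.x + b.width, b.y + b.height
        my = (y0 + y1) / 2
        prims.append(_poly([(x0 + c, y0), (x1 - c, y0), (x1, my), (x1 - c, y1),
                            (x0 + c, y1), (x0, my)], style))
    elif cls == ElementClass.SOURCE_SINK:
        r = min(b.width, b.height) / 2
        cx, cy = b.center.x, b.center.y
        prims.append(EllipsePrim(cx, cy, r, r, stroke=style.stroke,
                                 stroke_width=style.stroke_width, fill=style.fill))
        d = r / math.sqrt(2)
        prims.append(PathPrim([CurveSegment("line", Point(cx - d, cy + d), Point(cx + d, cy - d))],
                              stroke=style.stroke, stroke_width=style.stroke_width))
    else:
        prims.append(_rounded_rect(b, 0.0, style))

    # residue-state decorations along the top border
    sv = 14.0
    for i, m in enumerate(modifications):
        cx = b.x + 12 + i * (sv + 4)
        cy = b.y
        prims.append(EllipsePrim(cx, cy, sv / 2, sv / 2, stroke=style.stroke,
                                 stroke_width=style.stroke_width, fill=WHITE))
        from .sbgnml_io import STATE_ABBREV

        prims.append(TextPrim(cx, cy, STATE_ABBREV.get(m.state, m.state[:2]),
                              font=FontSpec(size=8.0), color=style.stroke))

    if label:
        font = style.font or FontSpec()
        est = text_width(label, font.size)
        if est > b.width * 0.95 and est > 0:
            font = FontSpec(font.family, max(4.0, font.size * b.width * 0.95 / est),
                            font.weight, font.slant)
        c = b.center
        prims.append(TextPrim(c.x, c.y, label, font=font, color=style.stroke))
    return prims


def _rect_pts(b: BoundingBox) -> list[tuple[float, float]]:
    return [(b.x, b.y), (b.x + b.width, b.y), (b.x + b.width, b.y + b.height),
            (b.x, b.y + b.height)]


def _curve_midpoint(segments: list[CurveSegment]) -> Point:
    pts = [segments[0].start] + [s.end for s in segments]
    if len(pts) % 2 == 0:
        a, c = pts[len(pts) // 2 - 1], pts[len(pts) // 2]
        return Point((a.x + c.x) / 2, (a.y + c.y) / 2)
    return pts[len(pts) // 2]


# ---------------------------------------------------------------------------
# z-ordering
# ---------------------------------------------------------------------------


def _z_ordered(doc: Document, layout: Layout) -> list[Glyph]:
    """Compartments largest-first, then complexes, species, reactions, labels."""
    elements = {e.id: e for e in doc.elements}

    def area(g: Glyph) -> float:
        return g.bbox.width * g.bbox.height if g.bbox is not None else 0.0

    compartments = sorted(
        layout.glyphs_of_kind(GlyphKind.COMPARTMENT), key=lambda g: (-area(g), g.id)
    )
    species = layout.glyphs_of_kind(GlyphKind.SPECIES)
    complexes = [
        g
        for g in species
        if g.model_ref in elements
        and elements[g.model_ref].element_class == ElementClass.COMPLEX
    ]
    plain = [g for g in species if g not in complexes]
    reactions = layout.glyphs_of_kind(GlyphKind.REACTION)
    texts = layout.glyphs_of_kind(GlyphKind.TEXT)
    return compartments + complexes + plain + reactions + texts


# ---------------------------------------------------------------------------
# SVG backend
# ---------------------------------------------------------------------------

SVG_NS = "http://www.w3.org/2000/svg"


def _fmt(x: float) -> str:
    s = f"{x:.3f}".rstrip("0").rstrip(".")
    return s if s not in ("-0", "") else "0"


def _svg_path_d(prim: PathPrim) -> str:
    parts: list[str] = []
    cursor: Optional[Point] = None
    for seg in prim.segments:
        if cursor is None or (seg.start.x, seg.start.y) != (cursor.x, cursor.y):
            parts.append(f"M {_fmt(seg.start.x)} {_fmt(seg.start.y)}")
        if seg.kind == "cubic-bezier":
            parts.append(
                f"C {_fmt(seg.control1.x)} {_fmt(seg.control1.y)} "
                f"{_fmt(seg.control2.x)} {_fmt(seg.control2.y)} "
                f"{_fmt(seg.end.x)} {_fmt(seg.end.y)}"
            )
        else:
            parts.append(f"L {_fmt(seg.end.x)} {_fmt(seg.end.y)}")
        cursor = seg.end
    if prim.closed:
        parts.append("Z")
    return " ".join(parts)


def _svg_color(c: Optional[ColorRGBA]) -> str:
    return "none" if c is None else c.to_hex_rgb()


def _emit_svg_prim(parent: etree._Element, prim: Primitive) -> None:
    if isinstance(prim, PathPrim):
        el = etree.SubElement(parent, f"{{{SVG_NS}}}path")
        el.set("d", _svg_path_d(prim))
        el.set("fill", _svg_color(prim.fill))
        el.set("stroke", _svg_color(prim.stroke))
        el.set("stroke-width", _fmt(prim.stroke_width))
        if prim.fill is not None and prim.fill.a < 255:
            el.set("fill-opacity", _fmt(prim.fill.a / 255))
    elif isinstance(prim, EllipsePrim):
        el = etree.SubElement(parent, f"{{{SVG_NS}}}ellipse")
        el.set("cx", _fmt(prim.cx))
        el.set("cy", _fmt(prim.cy))
        el.set("rx", _fmt(prim.rx))
        el.set("ry", _fmt(prim.ry))
        el.set("fill", _svg_color(prim.fill))
        el.set("stroke", _svg_color(prim.stroke))
        el.set("stroke-width", _fmt(prim.stroke_width))
        if prim.fill is not None and prim.fill.a < 255:
            el.set("fill-opacity", _fmt(prim.fill.a / 255))
    elif isinstance(prim, TextPrim):
        el = etree.SubElement(parent, f"{{{SVG_NS}}}text")
        el.set("x", _fmt(prim.x))
        el.set("y", _fmt(prim.y))
        el.set("text-anchor", "middle")
        el.set("dominant-baseline", "central")
        el.set("font-family", prim.font.family)
        el.set("font-size", _fmt(prim.font.size))
        if prim.font.weight != "normal":
            el.set("font-weight", prim.font.weight)
        if prim.font.slant != "normal":
            el.set("font-style", prim.font.slant)
        el.set("fill", prim.color.to_hex_rgb())
        el.text = prim.text


def _layout_for(doc: Document, layout_id: Optional[str]) -> Layout:
    if layout_id is None:
        if not doc.layouts:
            raise ModelError("no-geometry", "document has no layout")
        return doc.layouts[0]
    return doc.layout(layout_id)


def _glyph_primitives(doc: Document, layout: Layout) -> list[tuple[Glyph, list[Primitive]]]:
    elements = {e.id: e for e in doc.elements}
    labelled = {
        g.parent_glyph_ref for g in layout.glyphs_of_kind(GlyphKind.TEXT) if g.parent_glyph_ref
    }
    out = []
    for g in _z_ordered(doc, layout):
        e = elements.get(g.model_ref) if g.model_ref else None
        style = style_for_glyph(doc, g, e.element_class if e else None) or DEFAULT_STYLE
        label = None
        if g.kind in (GlyphKind.SPECIES, GlyphKind.COMPARTMENT) and g.id not in labelled:
            label = e.name if (e is not None and e.name) else None
            if g.kind == GlyphKind.COMPARTMENT and g.model_ref:
                try:
                    label = doc.compartment(g.model_ref).name or None
                except KeyError:
                    label = None
        prims = glyph_shape(
            g,
            e.element_class if e is not None else None,
            style,
            modifications=e.modifications if (e is not None and g.kind == GlyphKind.SPECIES) else (),
            label=label,
        )
        out.append((g, prims))
    return out


def render_svg(
    doc: Document,
    layout_id: Optional[str] = None,
    margin: float = 10.0,
    background: Optional[ColorRGBA] = None,
) -> bytes:
    """Render one layout to standalone SVG 1.1; deterministic byte output."""
    layout = _layout_for(doc, layout_id)
    if not layout.glyphs:
        raise ModelError("no-geometry", f"layout {layout.id!r} is empty")
    bounds = canvas_bounds(layout)
    vx, vy = bounds.x - margin, bounds.y - margin
    vw, vh = bounds.width + 2 * margin, bounds.height + 2 * margin

    svg = etree.Element(f"{{{SVG_NS}}}svg", nsmap={None: SVG_NS})
    svg.set("version", "1.1")
    svg.set("viewBox", f"{_fmt(vx)} {_fmt(vy)} {_fmt(vw)} {_fmt(vh)}")
    svg.set("width", _fmt(vw))
    svg.set("height", _fmt(vh))
    if background is not None:
        rect = etree.SubElement(svg, f"{{{SVG_NS}}}rect")
        rect.set("x", _fmt(vx))
        rect.set("y", _fmt(vy))
        rect.set("width", _fmt(vw))
        rect.set("height", _fmt(vh))
        rect.set("fill", background.to_hex_rgb())

    for g, prims in _glyph_primitives(doc, layout):
        group = etree.SubElement(svg, f"{{{SVG_NS}}}g")
        group.set("id", g.id)
        for prim in prims:
            _emit_svg_prim(group, prim)

    return etree.tostring(svg, xml_declaration=True, encoding="UTF-8", pretty_print=True)


# ---------------------------------------------------------------------------
# raster / PDF backends
# ---------------------------------------------------------------------------


def _flatten_path(prim: PathPrim, samples: int = 12) -> list[tuple[float, float]]:
    pts: list[tuple[float, float]] = []
    for seg in prim.segments:
        if not pts or pts[-1] != (seg.start.x, seg.start.y):
            pts.append((seg.start.x, seg.start.y))
        if seg.kind == "cubic-bezier":
            p0, c1, c2, p1 = seg.start, seg.control1, seg.control2, seg.end
            for i in range(1, samples + 1):
                t = i / samples
                mt = 1 - t
                x = mt**3 * p0.x + 3 * mt**2 * t * c1.x + 3 * mt * t**2 * c2.x + t**3 * p1.x
                y = mt**3 * p0.y + 3 * mt**2 * t * c1.y + 3 * mt * t**2 * c2.y + t**3 * p1.y
                pts.append((x, y))
        else:
            pts.append((seg.end.x, seg.end.y))
    return pts


def render_raster(
    doc: Document,
    format: str = "png",
    scale: float = 1.0,
    layout_id: Optional[str] = None,
    margin: float = 10.0,
    background: Optional[ColorRGBA] = None,
) -> bytes:
    """PNG or single-page PDF derived from the same primitives as the SVG.

    Pixel dimensions of the PNG are ``ceil((canvas + 2*margin) * scale)``.
    """
    if scale <= 0:
        raise ModelError("bad-scale", f"scale must be positive, got {scale}")
    if format not in ("png", "pdf"):
        raise ModelError("bad-format", f"unknown raster format {format!r}")
    layout = _layout_for(doc, layout_id)
    if not layout.glyphs:
        raise ModelError("no-geometry", f"layout {layout.id!r} is empty")
    bounds = canvas_bounds(layout)
    vx, vy = bounds.x - margin, bounds.y - margin
    vw, vh = bounds.width + 2 * margin, bounds.height + 2 * margin
    prims = [p for _, ps in _glyph_primitives(doc, layout) for p in ps]
    if format == "png":
        return _render_png(prims, vx, vy, vw, vh, scale, background)
    return _render_pdf(prims, vx, vy, vw, vh, background)


def _render_png(prims, vx, vy, vw, vh, scale, background) -> bytes:
    from PIL import Image, ImageDraw, ImageFont

    w = max(1, math.ceil(vw * scale))
    h = max(1, math.ceil(vh * scale))
    bg = (background.r, background.g, background.b, background.a) if background else (255, 255, 255, 255)
    img = Image.new("RGBA", (w, h), bg)
    draw = ImageDraw.Draw(img)

    def tx(p: tuple[float, float]) -> tuple[float, float]:
        return ((p[0] - vx) * scale, (p[1] - vy) * scale)

    def rgba(c: Optional[ColorRGBA]):
        return None if c is None else (c.r, c.g, c.b, c.a)

    for prim in prims:
        if isinstance(prim, PathPrim):
            pts = [tx(p) for p in _flatten_path(prim)]
            lw = max(1, round(prim.stroke_width * scale))
            if prim.closed and len(pts) >= 3:
                draw.polygon(pts, fill=rgba(prim.fill), outline=rgba(prim.stroke), width=lw)
            elif len(pts) >= 2:
                draw.line(pts, fill=rgba(prim.stroke), width=lw)
        elif isinstance(prim, EllipsePrim):
            x0, y0 = tx((prim.cx - prim.rx, prim.cy - prim.ry))
            x1, y1 = tx((prim.cx + prim.rx, prim.cy + prim.ry))
            lw = max(1, round(prim.stroke_width * scale))
            draw.ellipse([x0, y0, x1, y1], fill=rgba(prim.fill), outline=rgba(prim.stroke), width=lw)
        elif isinstance(prim, TextPrim):
            size = max(6, round(prim.font.size * scale))
            try:
                font = ImageFont.load_default(size=size)
            except TypeError:  # older Pillow
                font = ImageFont.load_default()
            draw.text(tx((prim.x, prim.y)), prim.text, fill=rgba(prim.color),
                      font=font, anchor="mm")
    out = io.BytesIO()
    img.save(out, format="PNG")
    return out.getvalue()


def _pdf_escape(s: str) -> str:
    return s.replace("\\", r"\\").replace("(", r"\(").replace(")", r"\)")


def _render_pdf(prims, vx, vy, vw, vh, background) -> bytes:
    """Single-page vector PDF; media box matches the canvas plus margin."""

    def tx(x: float, y: float) -> tuple[float, float]:
        # PDF y-axis points up
        return (x - vx, vh - (y - vy))

    def col(c: ColorRGBA) -> str:
        return f"{c.r / 255:.3f} {c.g / 255:.3f} {c.b / 255:.3f}"

    ops: list[str] = []
    if background is not None:
        ops.append(f"{col(background)} rg 0 0 {vw:.2f} {vh:.2f} re f")
    for prim in prims:
        if isinstance(prim, PathPrim):
            ops.append(f"{prim.stroke_width:.2f} w {col(prim.stroke)} RG")
            if prim.fill is not None:
                ops.append(f"{col(prim.fill)} rg")
            sx, sy = tx(prim.segments[0].start.x, prim.segments[0].start.y)
            ops.append(f"{sx:.2f} {sy:.2f} m")
            for seg in prim.segments:
                if seg.kind == "cubic-bezier":
                    c1 = tx(seg.control1.x, seg.control1.y)
                    c2 = tx(seg.control2.x, seg.control2.y)
                    e = tx(seg.end.x, seg.end.y)
                    ops.append(
                        f"{c1[0]:.2f} {c1[1]:.2f} {c2[0]:.2f} {c2[1]:.2f} {e[0]:.2f} {e[1]:.2f} c"
                    )
                else:
                    e = tx(seg.end.x, seg.end.y)
                    ops.append(f"{e[0]:.2f} {e[1]:.2f} l")
            if prim.closed:
                ops.append("h")
                ops.append("B" if prim.fill is not None else "S")
            else:
                ops.append("S")
        elif isinstance(prim, EllipsePrim):
            # ellipse from four bezier arcs
            k = 0.5523
            cx, cy = prim.cx, prim.cy
            rx, ry = prim.rx, prim.ry
            p = [tx(cx + rx, cy), tx(cx, cy + ry), tx(cx - rx, cy), tx(cx, cy - ry)]
            kx, ky = rx * k, ry * k
            ops.append(f"{prim.stroke_width:.2f} w {col(prim.stroke)} RG")
            if prim.fill is not None:
                ops.append(f"{col(prim.fill)} rg")
            ops.append(f"{p[0][0]:.2f} {p[0][1]:.2f} m")
            arcs = [
                (p[0][0], p[0][1] - ky, p[1][0] + kx, p[1][1], p[1]),
                (p[1][0] - kx, p[1][1], p[2][0], p[2][1] - ky, p[2]),
                (p[2][0], p[2][1] + ky, p[3][0] - kx, p[3][1], p[3]),
                (p[3][0] + kx, p[3][1], p[0][0], p[0][1] + ky, p[0]),
            ]
            for c1x, c1y, c2x, c2y, e in arcs:
                ops.append(f"{c1x:.2f} {c1y:.2f} {c2x:.2f} {c2y:.2f} {e[0]:.2f} {e[1]:.2f} c")
            ops.append("h")
            ops.append("B" if prim.fill is not None else "S")
        elif isinstance(prim, TextPrim):
            x, y = tx(prim.x, prim.y)
            x -= text_width(prim.text, prim.font.size) / 2
            y -= prim.font.size * 0.35
            ops.append(
                f"BT /F1 {prim.font.size:.2f} Tf {col(prim.color)} rg "
                f"{x:.2f} {y:.2f} Td ({_pdf_escape(prim.text)}) Tj ET"
            )
    content = ("\n".join(ops)).encode("latin-1", errors="replace")
    compressed = zlib.compress(content)

    objects: list[bytes] = []
    objects.append(b"<< /Type /Catalog /Pages 2 0 R >>")
    objects.append(b"<< /Type /Pages /Kids [3 0 R] /Count 1 >>")
    objects.append(
        f"<< /Type /Page /Parent 2 0 R /MediaBox [0 0 {vw:.2f} {vh:.2f}] "
        f"/Contents 4 0 R /Resources << /Font << /F1 5 0 R >> >> >>".encode()
    )
    objects.append(
        f"<< /Length {len(compressed)} /Filter /FlateDecode >>\nstream\n".encode()
        + compressed
        + b"\nendstream"
    )
    objects.append(b"<< /Type /Font /Subtype /Type1 /BaseFont /Helvetica >>")

    out = io.BytesIO()
    out.write(b"%PDF-1.4\n%\xe2\xe3\xcf\xd3\n")
    offsets = [0]
    for i, obj in enumerate(objects, start=1):
        offsets.append(out.tell())
        out.write(f"{i} 0 obj\n".encode())
        out.write(obj)
        out.write(b"\nendobj\n")
    xref_pos = out.tell()
    out.write(f"xref\n0 {len(objects) + 1}\n".encode())
    out.write(b"0000000000 65535 f \n")
    for off in offsets[1:]:
        out.write(f"{off:010d} 00000 n \n".encode())
    out.write(
        f"trailer\n<< /Size {len(objects) + 1} /Root 1 0 R >>\nstartxref\n{xref_pos}\n%%EOF\n".encode()
    )
    return out.getvalue()
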