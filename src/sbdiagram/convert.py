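"""Format-to-format conversion with geometry normalization and loud loss.

The pipeline is read → :func:`normalize_geometry` → write.  Every conversion
produces a :class:`ConversionReport` alongside the output bytes: whenever
the target notation cannot hold something the source carried (extra layouts,
label positions, duplicate identity, decorative graphics), exactly one
structured warning lands in the report — silent loss is treated as a bug.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

from lxml import etree

from . import celldesigner_io, sbgnml_io, sbml_io
from .model import (
    BoundingBox,
    CurveSegment,
    Document,
    Glyph,
    GlyphKind,
    Layout,
    ModelError,
    Point,
    Severity,
    Violation,
    bbox,
    canvas_bounds,
)

FORMATS = ("sbml", "celldesigner", "sbgnml")
GRAPHIC_FORMATS = ("svg", "png", "pdf")


@dataclass
class ConversionReport:
    """Structured record of what a conversion dropped or synthesized."""

    source: str = ""
    target: str = ""
    warnings: list[Violation] = field(default_factory=list)

    def warn(self, rule_id: str, object_id: str, message: str) -> None:
        self.warnings.append(Violation(rule_id, Severity.WARNING, object_id, message))

    def rules(self) -> list[str]:
        return [w.rule_id for w in self.warnings]

    def to_json_lines(self) -> str:
        return "\n".join(
            json.dumps(
                {
                    "rule_id": w.rule_id,
                    "severity": w.severity.value,
                    "object_id": w.object_id,
                    "message": w.message,
                }
            )
            for w in self.warnings
        )


def detect_format(data: bytes) -> str:
    """Sniff the notation from XML namespaces.

    CellDesigner documents are SBML too, so the CellDesigner namespace is
    checked before plain SBML.
    """
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise ModelError("unknown-format", f"input is not XML: {exc}") from exc
    namespaces = set()
    for el in root.iter():
        qn = etree.QName(el)
        if qn.namespace:
            namespaces.add(qn.namespace)
        for attr in el.attrib:
            if attr.startswith("{"):
                namespaces.add(attr[1:].split("}")[0])
    if any("sbgn.org" in ns for ns in namespaces):
        return "sbgnml"
    if celldesigner_io.CD_NS in namespaces:
        return "celldesigner"
    if any("sbml.org/sbml" in ns for ns in namespaces):
        return "sbml"
    raise ModelError("unknown-format", "no SBML, CellDesigner or SBGN-ML namespace found")


def read_document(data: bytes, source: str = "auto", warn=None) -> Document:
    fmt = detect_format(data) if source == "auto" else source
    if fmt == "sbml":
        # an actual CellDesigner file must be read by its own reader
        if celldesigner_io.CD_NS.encode() in data:
            return celldesigner_io.read_celldesigner(data, warn=warn)
        return sbml_io.read_sbml(data, warn=warn)
    if fmt == "celldesigner":
        return celldesigner_io.read_celldesigner(data, warn=warn)
    if fmt == "sbgnml":
        return sbgnml_io.read_sbgnml(data, warn=warn)
    raise ModelError("unknown-format", f"unknown source format {fmt!r}")


def write_document(
    doc: Document,
    target: str,
    layout_index: int = 0,
    strict: bool = True,
    report: Optional[ConversionReport] = None,
) -> bytes:
    rep = report if report is not None else ConversionReport()

    if target in ("celldesigner", "sbgnml"):
        if len(doc.layouts) > 1:
            dropped = len(doc.layouts) - 1
            rep.warn(
                "layouts-dropped",
                doc.layouts[layout_index].id,
                f"{target} holds a single layout; {dropped} layout(s) dropped "
                f"(kept index {layout_index})",
            )
    if target == "celldesigner":
        if doc.layouts and any(
            g.kind == GlyphKind.TEXT for g in doc.layouts[layout_index].glyphs
        ):
            rep.warn(
                "label-positions-dropped",
                doc.layouts[layout_index].id,
                "CellDesigner cannot place labels; label bounding boxes dropped "
                "(labels will render centered)",
            )
        return celldesigner_io.write_celldesigner(
            doc, layout_index=layout_index, warn=lambda m: rep.warn("writer", "", m)
        )
    if target == "sbgnml":
        if doc.passthrough.get("celldesigner:model"):
            rep.warn(
                "decorative-graphics-dropped",
                "celldesigner:model",
                "CellDesigner decorative graphics have no SBGN-ML representation",
            )
        if doc.layouts:
            from .model import duplicate_groups

            groups = duplicate_groups(doc, doc.layouts[layout_index].id)
            if groups:
                rep.warn(
                    "duplicate-identity-lost",
                    doc.layouts[layout_index].id,
                    f"{sum(len(g) for g in groups)} duplicate glyphs emitted with clone "
                    "markers; which species each clone duplicates is not expressible "
                    "in SBGN-ML",
                )
        return sbgnml_io.write_sbgnml(
            doc,
            layout_index=layout_index,
            strict=strict,
            warn=lambda m: rep.warn("writer", "", m),
        )
    if target == "sbml":
        if doc.passthrough.get("celldesigner:model"):
            rep.warn(
                "decorative-graphics-dropped",
                "celldesigner:model",
                "CellDesigner decorative graphics have no SBML layout representation",
            )
        return sbml_io.write_sbml(doc)
    raise ModelError("unknown-format", f"unknown target format {target!r}")


def convert(
    data: bytes,
    target: str,
    source: str = "auto",
    layout_index: int = 0,
    strict: bool = True,
    normalize: bool = True,
) -> tuple[bytes, ConversionReport]:
    """Convert between notations; returns (output bytes, loss report).

    Converting a format to itself is allowed and canonicalizes the file.
    """
    rep = ConversionReport(source=source, target=target)
    doc = read_document(data, source, warn=lambda m: rep.warn("reader", "", m))
    rep.source = doc.source_format
    if normalize:
        doc = normalize_geometry(doc)
    if not doc.layouts and target in ("celldesigner", "sbgnml"):
        raise ModelError("no-layout", f"document has no layout; cannot write {target}")
    out = write_document(doc, target, layout_index=layout_index, strict=strict, report=rep)
    return out, rep


def normalize_geometry(doc: Document) -> Document:
    """Make under-specified geometry drawable; idempotent.

    * reactions with no curve get a single segment between the centroids of
      their reactant and product glyph bboxes;
    * species/compartment glyphs lacking a label text glyph get one,
      centered on the owner bbox;
    * layouts reaching into negative coordinates are translated uniformly so
      the canvas origin is (0, 0);
    * the canvas is recomputed from the glyphs.
    """
    for layout in doc.layouts:
        _synthesize_reaction_curves(doc, layout)
        _synthesize_labels(doc, layout)
        if layout.glyphs:
            bounds = canvas_bounds(layout)
            if bounds.x < 0 or bounds.y < 0:
                _translate_layout(layout, -min(bounds.x, 0.0), -min(bounds.y, 0.0))
                bounds = canvas_bounds(layout)
            layout.canvas = bbox(0, 0, bounds.x + bounds.width, bounds.y + bounds.height)
    return doc


def _centroid(points: list[Point]) -> Optional[Point]:
    if not points:
        return None
    return Point(sum(p.x for p in points) / len(points), sum(p.y for p in points) / len(points))


def _synthesize_reaction_curves(doc: Document, layout: Layout) -> None:
    glyph_index = {g.id: g for g in layout.glyphs}
    for g in layout.glyphs_of_kind(GlyphKind.REACTION):
        if g.curve:
            continue
        reactant_centers: list[Point] = []
        product_centers: list[Point] = []
        links = g.participant_links
        if not links and g.model_ref:
            # fall back to the model: first glyph of each participating element
            try:
                reaction = doc.reaction(g.model_ref)
            except KeyError:
                continue
            by_model: dict[str, Glyph] = {}
            for sg in layout.glyphs_of_kind(GlyphKind.SPECIES):
                if sg.model_ref:
                    by_model.setdefault(sg.model_ref, sg)
            for p in reaction.reactants:
                sg = by_model.get(p.element_ref)
                if sg is not None and sg.bbox is not None:
                    reactant_centers.append(sg.bbox.center)
            for p in reaction.products:
                sg = by_model.get(p.element_ref)
                if sg is not None and sg.bbox is not None:
                    product_centers.append(sg.bbox.center)
        else:
            for link in links:
                sg = glyph_index.get(link.glyph_ref)
                if sg is None or sg.bbox is None:
                    continue
                if link.role.value in ("substrate", "side-substrate"):
                    reactant_centers.append(sg.bbox.center)
                elif link.role.value in ("product", "side-product"):
                    product_centers.append(sg.bbox.center)
        start = _centroid(reactant_centers)
        end = _centroid(product_centers)
        if start is not None and end is not None:
            g.curve = [CurveSegment("line", start, end)]


def _synthesize_labels(doc: Document, layout: Layout) -> None:
    labelled = {
        g.parent_glyph_ref
        for g in layout.glyphs_of_kind(GlyphKind.TEXT)
        if g.parent_glyph_ref is not None
    }
    container_ids = {
        g.parent_glyph_ref for g in layout.glyphs if g.parent_glyph_ref is not None
    }
    new: list[Glyph] = []
    for g in layout.glyphs:
        if g.kind not in (GlyphKind.SPECIES, GlyphKind.COMPARTMENT):
            continue
        if g.id in labelled or g.bbox is None or g.model_ref is None:
            continue
        try:
            name = (
                doc.element(g.model_ref).name
                if g.kind == GlyphKind.SPECIES
                else doc.compartment(g.model_ref).name
            )
        except KeyError:
            name = ""
        if not name:
            continue
        # keep labels off the contents of containers: compartments are
        # labelled along the top edge, complexes along the bottom edge
        label_box = g.bbox
        strip = min(18.0, g.bbox.height)
        if g.kind == GlyphKind.COMPARTMENT:
            label_box = bbox(g.bbox.x, g.bbox.y, g.bbox.width, strip)
        elif g.id in container_ids:
            label_box = bbox(
                g.bbox.x, g.bbox.y + g.bbox.height - strip, g.bbox.width, strip
            )
        new.append(
            Glyph(
                id=f"{g.id}_label",
                kind=GlyphKind.TEXT,
                model_ref=g.model_ref,
                bbox=label_box,
                text=name,
                parent_glyph_ref=g.id,
            )
        )
    layout.glyphs.extend(new)


def _translate_layout(layout: Layout, dx: float, dy: float) -> None:
    def shift_point(p: Point) -> Point:
        return Point(p.x + dx, p.y + dy)

    def shift_bbox(b: Optional[BoundingBox]) -> Optional[BoundingBox]:
        if b is None:
            return None
        return BoundingBox(shift_point(b.origin), b.width, b.height)

    def shift_curve(curve: list[CurveSegment]) -> list[CurveSegment]:
        out = []
        for seg in curve:
            out.append(
                CurveSegment(
                    seg.kind,
                    shift_point(seg.start),
                    shift_point(seg.end),
                    shift_point(seg.control1) if seg.control1 else None,
                    shift_point(seg.control2) if seg.control2 else None,
                )
            )
        return out

    for g in layout.glyphs:
        g.bbox = shift_bbox(g.bbox)
        g.curve = shift_curve(g.curve)
        for link in g.participant_links:
            link.curve = shift_curve(link.curve)
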