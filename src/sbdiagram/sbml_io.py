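"""SBML Level 3 I/O with the layout package and, optionally, render.

The writer emits SBML L3V1 core + layout v1 + render v1 — the widest
compatibility point among layout-capable consumers.  The reader accepts L2
and L3 cores and any layout/render namespace version (matched by namespace
prefix, since the package URIs only differ in a trailing version).

What goes where:

* network structure -> SBML core (species / compartments / reactions);
* element semantics -> ``sboTerm`` attributes, so consumers can derive
  SBGN shapes even when no render information is present;
* geometry -> layout package glyphs (every layout of the document — SBML is
  the only one of the three notations that can hold more than one);
* colors / fonts / line widths -> render package styles; explicit shape
  primitives only behind ``explicit_shapes=True``;
* residue modification states, complex membership and glyph containment,
  which plain SBML cannot express, -> ``<annotation>`` elements in a
  self-describing auxiliary namespace (SBML's sanctioned extension point),
  so they survive an SBML round trip and third-party validators.

Unrecognized annotations, notes and kinetic laws are preserved verbatim in
``Document.passthrough`` and re-emitted on write.
"""

from __future__ import annotations

from typing import Callable, Optional

from lxml import etree

from . import mapping
from .model import (
    BoundingBox,
    ColorRGBA,
    CurveSegment,
    Document,
    Element,
    ElementClass,
    Compartment,
    FontSpec,
    Glyph,
    GlyphKind,
    Layout,
    ModelError,
    ModificationState,
    Participant,
    ParticipantLink,
    Point,
    Reaction,
    ReactionClass,
    Role,
    Selector,
    Style,
    bbox,
    canvas_bounds,
    validate,
)

SBML_L3_NS = "http://www.sbml.org/sbml/level3/version1/core"
LAYOUT_NS = "http://www.sbml.org/sbml/level3/version1/layout/version1"
RENDER_NS = "http://www.sbml.org/sbml/level3/version1/render/version1"
XSI_NS = "http://www.w3.org/2001/XMLSchema-instance"
#: auxiliary namespace for content plain SBML cannot express
SBD_NS = "https://sbdiagram.dev/ns/sbml-extras"

_NSMAP = {
    None: SBML_L3_NS,
    "layout": LAYOUT_NS,
    "render": RENDER_NS,
    "xsi": XSI_NS,
    "sbd": SBD_NS,
}

WarnFn = Optional[Callable[[str], None]]


def _num(x: float) -> str:
    """Shortest decimal that round-trips; integers without trailing .0."""
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(float(x))


def _q(ns: str, tag: str) -> str:
    return f"{{{ns}}}{tag}"


def _local(el: etree._Element) -> str:
    return etree.QName(el).localname


def _ns_of(el: etree._Element) -> str:
    return etree.QName(el).namespace or ""


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------


def write_sbml(doc: Document, explicit_shapes: bool = False) -> bytes:
    """Serialize a document to SBML L3V1 + layout (+ render when styled)."""
    errors = [v for v in validate(doc) if v.severity.value == "error"]
    if errors:
        raise ModelError("invalid-document", "; ".join(str(v) for v in errors))

    root = etree.Element(_q(SBML_L3_NS, "sbml"), nsmap=_NSMAP)
    root.set("level", "3")
    root.set("version", "1")
    root.set(_q(LAYOUT_NS, "required"), "false")
    if doc.styles:
        root.set(_q(RENDER_NS, "required"), "false")
    model = etree.SubElement(root, _q(SBML_L3_NS, "model"))
    model.set("id", "model")

    if doc.compartments:
        loc = etree.SubElement(model, _q(SBML_L3_NS, "listOfCompartments"))
        for c in doc.compartments:
            el = etree.SubElement(loc, _q(SBML_L3_NS, "compartment"))
            el.set("id", c.id)
            if c.name:
                el.set("name", c.name)
            el.set("constant", "true")
            _write_passthrough(
                doc, c.id, el, extras=[_extras_el(parentCompartment=c.parent_ref)]
            )

    if doc.elements:
        los = etree.SubElement(model, _q(SBML_L3_NS, "listOfSpecies"))
        for e in doc.elements:
            el = etree.SubElement(los, _q(SBML_L3_NS, "species"))
            el.set("id", e.id)
            if e.name:
                el.set("name", e.name)
            compartment = e.compartment_ref or (doc.compartments[0].id if doc.compartments else "default")
            el.set("compartment", compartment)
            el.set("sboTerm", e.sbo_term or mapping.class_to_sbo(e.element_class))
            el.set("hasOnlySubstanceUnits", "false")
            el.set("boundaryCondition", "false")
            el.set("constant", "false")
            _write_passthrough(
                doc,
                e.id,
                el,
                extras=[
                    _modification_annotation(e),
                    _extras_el(
                        parentComplex=e.parent_complex_ref,
                        hypothetical="true" if e.is_hypothetical else None,
                    ),
                ],
            )

    if doc.reactions:
        lor = etree.SubElement(model, _q(SBML_L3_NS, "listOfReactions"))
        for r in doc.reactions:
            el = etree.SubElement(lor, _q(SBML_L3_NS, "reaction"))
            el.set("id", r.id)
            el.set("reversible", "false")
            el.set("fast", "false")
            el.set("sboTerm", mapping.reaction_class_to_sbo(r.reaction_class))
            _write_passthrough(doc, r.id, el)
            for tag, parts in (
                ("listOfReactants", r.reactants),
                ("listOfProducts", r.products),
            ):
                if not parts:
                    continue
                lst = etree.SubElement(el, _q(SBML_L3_NS, tag))
                for p in parts:
                    ref = etree.SubElement(lst, _q(SBML_L3_NS, "speciesReference"))
                    ref.set("species", p.element_ref)
                    ref.set("constant", "true")
                    role_sbo = _ROLE_SBO.get(p.role)
                    if role_sbo:
                        ref.set("sboTerm", role_sbo)
            if r.modifiers:
                lst = etree.SubElement(el, _q(SBML_L3_NS, "listOfModifiers"))
                for p in r.modifiers:
                    ref = etree.SubElement(lst, _q(SBML_L3_NS, "modifierSpeciesReference"))
                    ref.set("species", p.element_ref)
                    sbo = "SBO:0000013" if p.modifier_kind == "catalysis" else _ROLE_SBO.get(p.role)
                    if sbo:
                        ref.set("sboTerm", sbo)

    if doc.layouts:
        lol = etree.SubElement(model, _q(LAYOUT_NS, "listOfLayouts"))
        for layout in doc.layouts:
            _write_layout(lol, doc, layout, explicit_shapes)

    return etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


_ROLE_SBO = {
    Role.SUBSTRATE: "SBO:0000010",
    Role.SIDE_SUBSTRATE: "SBO:0000603",
    Role.PRODUCT: "SBO:0000011",
    Role.SIDE_PRODUCT: "SBO:0000604",
    Role.MODIFIER: "SBO:0000019",
    Role.ACTIVATOR: "SBO:0000459",
    Role.INHIBITOR: "SBO:0000020",
}
_SBO_ROLE = {v: k for k, v in _ROLE_SBO.items()}


def _extras_el(**attrs: Optional[str]) -> Optional[etree._Element]:
    """Auxiliary markers ride inside <annotation> as attributes of one
    <sbd:extras/> element; SBML forbids foreign attributes on core elements."""
    items = {k: v for k, v in attrs.items() if v}
    if not items:
        return None
    el = etree.Element(_q(SBD_NS, "extras"))
    for k, v in items.items():
        el.set(k, v)
    return el


def _set_extras(el: etree._Element, **attrs: Optional[str]) -> None:
    """Attach <annotation><sbd:extras .../></annotation> to a layout/render
    element (which never carries passthrough content of its own)."""
    extras = _extras_el(**attrs)
    if extras is not None:
        ann = etree.SubElement(el, _q(SBML_L3_NS, "annotation"))
        ann.append(extras)


def _get_extras(el: etree._Element) -> dict[str, str]:
    for ann in el:
        if _local(ann) == "annotation":
            for c in ann:
                if _ns_of(c) == SBD_NS and _local(c) == "extras":
                    return dict(c.attrib)
    return {}


def _modification_annotation(e: Element) -> Optional[etree._Element]:
    if not e.modifications:
        return None
    frag = etree.Element(_q(SBD_NS, "modifications"))
    for m in e.modifications:
        ms = etree.SubElement(frag, _q(SBD_NS, "modification"))
        if m.residue_label:
            ms.set("residue", m.residue_label)
        ms.set("state", m.state)
    return frag


def _write_passthrough(
    doc: Document,
    owner_id: str,
    el: etree._Element,
    extras: Optional[list[Optional[etree._Element]]] = None,
) -> None:
    """Re-emit preserved notes / kinetic law / annotation children."""
    annotation_children: list[etree._Element] = [x for x in extras or [] if x is not None]
    for frag in doc.passthrough.get(owner_id, []):
        node = etree.fromstring(frag.encode())
        if _local(node) in ("notes", "kineticLaw"):
            el.append(node)
        else:
            annotation_children.append(node)
    if annotation_children:
        ann = etree.SubElement(el, _q(SBML_L3_NS, "annotation"))
        for child in annotation_children:
            ann.append(child)


def _write_bbox(parent: etree._Element, b: BoundingBox) -> None:
    bb = etree.SubElement(parent, _q(LAYOUT_NS, "boundingBox"))
    pos = etree.SubElement(bb, _q(LAYOUT_NS, "position"))
    pos.set(_q(LAYOUT_NS, "x"), _num(b.x))
    pos.set(_q(LAYOUT_NS, "y"), _num(b.y))
    dim = etree.SubElement(bb, _q(LAYOUT_NS, "dimensions"))
    dim.set(_q(LAYOUT_NS, "width"), _num(b.width))
    dim.set(_q(LAYOUT_NS, "height"), _num(b.height))


def _write_curve(parent: etree._Element, segments: list[CurveSegment]) -> None:
    curve = etree.SubElement(parent, _q(LAYOUT_NS, "curve"))
    locs = etree.SubElement(curve, _q(LAYOUT_NS, "listOfCurveSegments"))
    for seg in segments:
        cs = etree.SubElement(locs, _q(LAYOUT_NS, "curveSegment"))
        cs.set(_q(XSI_NS, "type"), "CubicBezier" if seg.kind == "cubic-bezier" else "LineSegment")
        for tag, pt in (("start", seg.start), ("end", seg.end)):
            p = etree.SubElement(cs, _q(LAYOUT_NS, tag))
            p.set(_q(LAYOUT_NS, "x"), _num(pt.x))
            p.set(_q(LAYOUT_NS, "y"), _num(pt.y))
        if seg.kind == "cubic-bezier":
            for tag, pt in (("basePoint1", seg.control1), ("basePoint2", seg.control2)):
                p = etree.SubElement(cs, _q(LAYOUT_NS, tag))
                p.set(_q(LAYOUT_NS, "x"), _num(pt.x))
                p.set(_q(LAYOUT_NS, "y"), _num(pt.y))


def _write_layout(parent: etree._Element, doc: Document, layout: Layout, explicit_shapes: bool) -> None:
    lay = etree.SubElement(parent, _q(LAYOUT_NS, "layout"))
    lay.set(_q(LAYOUT_NS, "id"), layout.id)
    canvas = layout.canvas
    if canvas.width == 0 and canvas.height == 0 and layout.glyphs:
        canvas = canvas_bounds(layout)
    dim = etree.SubElement(lay, _q(LAYOUT_NS, "dimensions"))
    dim.set(_q(LAYOUT_NS, "width"), _num(canvas.width))
    dim.set(_q(LAYOUT_NS, "height"), _num(canvas.height))

    comp_glyphs = layout.glyphs_of_kind(GlyphKind.COMPARTMENT)
    species_glyphs = layout.glyphs_of_kind(GlyphKind.SPECIES)
    reaction_glyphs = layout.glyphs_of_kind(GlyphKind.REACTION)
    text_glyphs = layout.glyphs_of_kind(GlyphKind.TEXT)

    if comp_glyphs:
        lst = etree.SubElement(lay, _q(LAYOUT_NS, "listOfCompartmentGlyphs"))
        for g in comp_glyphs:
            el = etree.SubElement(lst, _q(LAYOUT_NS, "compartmentGlyph"))
            el.set(_q(LAYOUT_NS, "id"), g.id)
            if g.model_ref:
                el.set(_q(LAYOUT_NS, "compartment"), g.model_ref)
            _set_glyph_extras(el, g)
            _write_bbox(el, g.bbox)
    if species_glyphs:
        lst = etree.SubElement(lay, _q(LAYOUT_NS, "listOfSpeciesGlyphs"))
        for g in species_glyphs:
            el = etree.SubElement(lst, _q(LAYOUT_NS, "speciesGlyph"))
            el.set(_q(LAYOUT_NS, "id"), g.id)
            if g.model_ref:
                el.set(_q(LAYOUT_NS, "species"), g.model_ref)
            _set_glyph_extras(el, g)
            _write_bbox(el, g.bbox)
    if reaction_glyphs:
        lst = etree.SubElement(lay, _q(LAYOUT_NS, "listOfReactionGlyphs"))
        for g in reaction_glyphs:
            el = etree.SubElement(lst, _q(LAYOUT_NS, "reactionGlyph"))
            el.set(_q(LAYOUT_NS, "id"), g.id)
            if g.model_ref:
                el.set(_q(LAYOUT_NS, "reaction"), g.model_ref)
            if g.curve:
                _write_curve(el, g.curve)
            if g.participant_links:
                srgs = etree.SubElement(el, _q(LAYOUT_NS, "listOfSpeciesReferenceGlyphs"))
                for i, link in enumerate(g.participant_links):
                    srg = etree.SubElement(srgs, _q(LAYOUT_NS, "speciesReferenceGlyph"))
                    srg.set(_q(LAYOUT_NS, "id"), f"{g.id}_srg_{i}")
                    srg.set(_q(LAYOUT_NS, "speciesGlyph"), link.glyph_ref)
                    srg.set(_q(LAYOUT_NS, "role"), mapping.SBML_ROLE[link.role])
                    _set_extras(srg, modifierKind=link.modifier_kind)
                    if link.curve:
                        _write_curve(srg, link.curve)
    if text_glyphs:
        lst = etree.SubElement(lay, _q(LAYOUT_NS, "listOfTextGlyphs"))
        for g in text_glyphs:
            el = etree.SubElement(lst, _q(LAYOUT_NS, "textGlyph"))
            el.set(_q(LAYOUT_NS, "id"), g.id)
            if g.text is not None:
                el.set(_q(LAYOUT_NS, "text"), g.text)
            elif g.model_ref:
                el.set(_q(LAYOUT_NS, "originOfText"), g.model_ref)
            if g.parent_glyph_ref:
                el.set(_q(LAYOUT_NS, "graphicalObject"), g.parent_glyph_ref)
            _write_bbox(el, g.bbox)

    if doc.styles:
        _write_render(lay, doc, explicit_shapes)


def _set_glyph_extras(el: etree._Element, g: Glyph) -> None:
    _set_extras(
        el,
        parentGlyph=g.parent_glyph_ref,
        clone="true" if g.cloned else None,
        styleRef=g.style_ref,
    )


_EXPLICIT_SHAPE_TAGS = {
    "rounded-rectangle": "rectangle",
    "rectangle": "rectangle",
    "ellipse": "ellipse",
}


def _write_render(lay: etree._Element, doc: Document, explicit_shapes: bool) -> None:
    lri = etree.SubElement(lay, _q(RENDER_NS, "listOfRenderInformation"))
    lri.set(_q(RENDER_NS, "versionMajor"), "1")
    lri.set(_q(RENDER_NS, "versionMinor"), "0")
    ri = etree.SubElement(lri, _q(RENDER_NS, "renderInformation"))
    ri.set(_q(RENDER_NS, "id"), "render_info")
    ri.set(_q(RENDER_NS, "programName"), "sbdiagram")

    colors: dict[str, str] = {}  # hex -> color definition id

    def color_id(c: ColorRGBA) -> str:
        h = c.to_hex_rgba()
        if h not in colors:
            colors[h] = f"color_{len(colors)}"
        return colors[h]

    styles_el = etree.Element(_q(RENDER_NS, "listOfStyles"))
    for s in doc.styles:
        st = etree.SubElement(styles_el, _q(RENDER_NS, "style"))
        st.set(_q(RENDER_NS, "id"), s.id)
        if s.applies_to.glyph_ids:
            st.set(_q(RENDER_NS, "idList"), " ".join(s.applies_to.glyph_ids))
        if s.applies_to.roles:
            st.set(_q(RENDER_NS, "roleList"), " ".join(mapping.SBML_ROLE[r] for r in s.applies_to.roles))
        _set_extras(
            st,
            classList=" ".join(c.value for c in s.applies_to.element_classes) or None,
            shape=s.explicit_shape,
        )
        g = etree.SubElement(st, _q(RENDER_NS, "g"))
        g.set(_q(RENDER_NS, "stroke"), color_id(s.stroke))
        g.set(_q(RENDER_NS, "stroke-width"), _num(s.stroke_width))
        g.set(_q(RENDER_NS, "fill"), color_id(s.fill))
        if s.font is not None:
            g.set(_q(RENDER_NS, "font-family"), s.font.family)
            g.set(_q(RENDER_NS, "font-size"), _num(s.font.size))
            g.set(_q(RENDER_NS, "font-weight"), s.font.weight)
            g.set(_q(RENDER_NS, "font-style"), s.font.slant)
        if explicit_shapes and s.explicit_shape:
            shape = s.explicit_shape
            if shape in _EXPLICIT_SHAPE_TAGS:
                prim = etree.SubElement(g, _q(RENDER_NS, _EXPLICIT_SHAPE_TAGS[shape]))
                for attr in ("x", "y"):
                    prim.set(_q(RENDER_NS, attr), "0%")
                for attr in ("width", "height"):
                    prim.set(_q(RENDER_NS, attr), "100%")
                if shape == "rounded-rectangle":
                    prim.set(_q(RENDER_NS, "rx"), "10%")

    locd = etree.SubElement(ri, _q(RENDER_NS, "listOfColorDefinitions"))
    for h, cid in colors.items():
        cd = etree.SubElement(locd, _q(RENDER_NS, "colorDefinition"))
        cd.set(_q(RENDER_NS, "id"), cid)
        cd.set(_q(RENDER_NS, "value"), h)
    ri.append(styles_el)


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------


def read_sbml(data: bytes, warn: WarnFn = None) -> Document:
    """Parse SBML (L2 or L3 core; layout/render of any package version)."""
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise ModelError("parse-error", str(exc)) from exc
    if _local(root) != "sbml" or "sbml.org/sbml" not in _ns_of(root):
        raise ModelError("invalid-sbml", "root element is not SBML")
    model = _child(root, "model")
    if model is None:
        raise ModelError("invalid-sbml", "SBML document without a model element")

    doc = Document(source_format="sbml")

    for c in _children(model, "listOfCompartments", "compartment"):
        comp = Compartment(
            id=c.get("id"),
            name=c.get("name", ""),
            parent_ref=_get_extras(c).get("parentCompartment") or c.get("outside"),
        )
        doc.compartments.append(comp)
        _read_passthrough(doc, comp.id, c)

    for s in _children(model, "listOfSpecies", "species"):
        sbo = s.get("sboTerm")
        cls = mapping.sbo_to_class(sbo) if sbo else None
        extras = _get_extras(s)
        e = Element(
            id=s.get("id"),
            name=s.get("name", ""),
            element_class=cls or ElementClass.UNSPECIFIED,
            sbo_term=sbo,
            compartment_ref=s.get("compartment"),
            parent_complex_ref=extras.get("parentComplex"),
            is_hypothetical=extras.get("hypothetical") == "true",
        )
        _read_passthrough(doc, e.id, s, element=e)
        doc.elements.append(e)

    for r in _children(model, "listOfReactions", "reaction"):
        sbo = r.get("sboTerm")
        rc = (mapping.sbo_to_reaction_class(sbo) if sbo else None) or ReactionClass.STATE_TRANSITION
        rx = Reaction(id=r.get("id"), reaction_class=rc)
        for ref in _children(r, "listOfReactants", "speciesReference"):
            role = _SBO_ROLE.get(ref.get("sboTerm", ""), Role.SUBSTRATE)
            rx.reactants.append(Participant(ref.get("species"), role))
        for ref in _children(r, "listOfProducts", "speciesReference"):
            role = _SBO_ROLE.get(ref.get("sboTerm", ""), Role.PRODUCT)
            rx.products.append(Participant(ref.get("species"), role))
        for ref in _children(r, "listOfModifiers", "modifierSpeciesReference"):
            sbo_m = ref.get("sboTerm", "")
            if sbo_m == "SBO:0000013":
                rx.modifiers.append(Participant(ref.get("species"), Role.ACTIVATOR, "catalysis"))
            else:
                rx.modifiers.append(
                    Participant(ref.get("species"), _SBO_ROLE.get(sbo_m, Role.MODIFIER))
                )
        _read_passthrough(doc, rx.id, r)
        doc.reactions.append(rx)

    for lol in model:
        if _local(lol) == "listOfLayouts" and "layout" in _ns_of(lol):
            for lay in lol:
                if _local(lay) == "layout":
                    doc.layouts.append(_read_layout(lay, doc, warn))

    return doc


def _child(el: etree._Element, name: str) -> Optional[etree._Element]:
    for c in el:
        if _local(c) == name:
            return c
    return None


def _children(el: etree._Element, list_name: str, item_name: str) -> list[etree._Element]:
    lst = _child(el, list_name)
    if lst is None:
        return []
    return [c for c in lst if _local(c) == item_name]


def _read_passthrough(
    doc: Document, owner_id: str, el: etree._Element, element: Optional[Element] = None
) -> None:
    for c in el:
        name = _local(c)
        if name == "notes" or name == "kineticLaw":
            doc.add_passthrough(owner_id, etree.tostring(c, encoding="unicode"))
        elif name == "annotation":
            for ann_child in c:
                if _ns_of(ann_child) == SBD_NS:
                    if element is not None and _local(ann_child) == "modifications":
                        for m in ann_child:
                            element.modifications.append(
                                ModificationState(m.get("residue", ""), m.get("state", "unknown"))
                            )
                else:
                    doc.add_passthrough(owner_id, etree.tostring(ann_child, encoding="unicode"))


def _get_num(el: etree._Element, attr: str) -> float:
    # layout attributes are namespaced in L3 but occasionally bare in the wild
    v = el.get(_q(LAYOUT_NS, attr))
    if v is None:
        v = el.get(attr)
    return float(v) if v is not None else 0.0


def _get_attr(el: etree._Element, attr: str) -> Optional[str]:
    v = el.get(_q(LAYOUT_NS, attr))
    if v is None:
        v = el.get(attr)
    return v


def _read_bbox(parent: etree._Element) -> Optional[BoundingBox]:
    bb = _child(parent, "boundingBox")
    if bb is None:
        return None
    pos = _child(bb, "position")
    dim = _child(bb, "dimensions")
    return bbox(
        _get_num(pos, "x") if pos is not None else 0.0,
        _get_num(pos, "y") if pos is not None else 0.0,
        _get_num(dim, "width") if dim is not None else 0.0,
        _get_num(dim, "height") if dim is not None else 0.0,
    )


def _read_curve(parent: etree._Element) -> list[CurveSegment]:
    curve = _child(parent, "curve")
    if curve is None:
        return []
    segments = []
    locs = _child(curve, "listOfCurveSegments")
    for cs in locs if locs is not None else []:
        kind = cs.get(_q(XSI_NS, "type"), "LineSegment")
        start = _child(cs, "start")
        end = _child(cs, "end")
        p0 = Point(_get_num(start, "x"), _get_num(start, "y"))
        p1 = Point(_get_num(end, "x"), _get_num(end, "y"))
        if kind == "CubicBezier":
            b1 = _child(cs, "basePoint1")
            b2 = _child(cs, "basePoint2")
            c1 = Point(_get_num(b1, "x"), _get_num(b1, "y")) if b1 is not None else p0
            c2 = Point(_get_num(b2, "x"), _get_num(b2, "y")) if b2 is not None else p1
            segments.append(CurveSegment("cubic-bezier", p0, p1, c1, c2))
        else:
            segments.append(CurveSegment("line", p0, p1))
    return segments


def _glyph_extras(el: etree._Element, g: Glyph) -> None:
    extras = _get_extras(el)
    g.parent_glyph_ref = extras.get("parentGlyph")
    g.cloned = extras.get("clone") == "true"
    g.style_ref = extras.get("styleRef")


def _read_layout(lay: etree._Element, doc: Document, warn: WarnFn) -> Layout:
    layout = Layout(id=_get_attr(lay, "id") or f"layout_{len(doc.layouts)}")
    dim = _child(lay, "dimensions")
    if dim is not None:
        layout.canvas = bbox(0, 0, _get_num(dim, "width"), _get_num(dim, "height"))

    for g_el in _children(lay, "listOfCompartmentGlyphs", "compartmentGlyph"):
        g = Glyph(
            id=_get_attr(g_el, "id"),
            kind=GlyphKind.COMPARTMENT,
            model_ref=_get_attr(g_el, "compartment"),
            bbox=_read_bbox(g_el),
        )
        _glyph_extras(g_el, g)
        layout.glyphs.append(g)

    for g_el in _children(lay, "listOfSpeciesGlyphs", "speciesGlyph"):
        g = Glyph(
            id=_get_attr(g_el, "id"),
            kind=GlyphKind.SPECIES,
            model_ref=_get_attr(g_el, "species"),
            bbox=_read_bbox(g_el),
        )
        _glyph_extras(g_el, g)
        if g.model_ref is not None and not doc.has_element(g.model_ref) and warn:
            warn(f"species glyph {g.id!r} references unknown species {g.model_ref!r}")
        layout.glyphs.append(g)

    for g_el in _children(lay, "listOfReactionGlyphs", "reactionGlyph"):
        g = Glyph(
            id=_get_attr(g_el, "id"),
            kind=GlyphKind.REACTION,
            model_ref=_get_attr(g_el, "reaction"),
            curve=_read_curve(g_el),
        )
        for srg in _children(g_el, "listOfSpeciesReferenceGlyphs", "speciesReferenceGlyph"):
            role = mapping.SBML_ROLE_INV.get(_get_attr(srg, "role") or "undefined", Role.UNDEFINED)
            g.participant_links.append(
                ParticipantLink(
                    glyph_ref=_get_attr(srg, "speciesGlyph"),
                    role=role,
                    curve=_read_curve(srg),
                    modifier_kind=_get_extras(srg).get("modifierKind"),
                )
            )
        layout.glyphs.append(g)

    for g_el in _children(lay, "listOfTextGlyphs", "textGlyph"):
        g = Glyph(
            id=_get_attr(g_el, "id"),
            kind=GlyphKind.TEXT,
            model_ref=_get_attr(g_el, "originOfText"),
            bbox=_read_bbox(g_el),
            text=_get_attr(g_el, "text"),
            parent_glyph_ref=_get_attr(g_el, "graphicalObject"),
        )
        layout.glyphs.append(g)

    for lri in lay:
        if _local(lri) == "listOfRenderInformation":
            _read_render(lri, doc)

    return layout


def _r_attr(el: etree._Element, attr: str) -> Optional[str]:
    v = el.get(_q(RENDER_NS, attr))
    if v is None:
        v = el.get(attr)
    return v


def _read_render(lri: etree._Element, doc: Document) -> None:
    for ri in lri:
        if _local(ri) != "renderInformation":
            continue
        colors: dict[str, ColorRGBA] = {}
        for cd in _children(ri, "listOfColorDefinitions", "colorDefinition"):
            colors[_r_attr(cd, "id")] = ColorRGBA.from_hex(_r_attr(cd, "value") or "#000000")
        for st in _children(ri, "listOfStyles", "style"):
            sel = Selector()
            id_list = _r_attr(st, "idList")
            if id_list:
                sel.glyph_ids = id_list.split()
            role_list = _r_attr(st, "roleList")
            if role_list:
                sel.roles = [
                    mapping.SBML_ROLE_INV[r] for r in role_list.split() if r in mapping.SBML_ROLE_INV
                ]
            st_extras = _get_extras(st)
            class_list = st_extras.get("classList")
            if class_list:
                sel.element_classes = [ElementClass(c) for c in class_list.split()]
            style = Style(id=_r_attr(st, "id") or f"style_{len(doc.styles)}", applies_to=sel)
            g = _child(st, "g")
            if g is not None:
                stroke = _r_attr(g, "stroke")
                if stroke in colors:
                    style.stroke = colors[stroke]
                fill = _r_attr(g, "fill")
                if fill in colors:
                    style.fill = colors[fill]
                sw = _r_attr(g, "stroke-width")
                if sw:
                    style.stroke_width = float(sw)
                fam = _r_attr(g, "font-family")
                fs = _r_attr(g, "font-size")
                if fam or fs:
                    style.font = FontSpec(
                        family=fam or "sans-serif",
                        size=float(fs) if fs else 11.0,
                        weight=_r_attr(g, "font-weight") or "normal",
                        slant=_r_attr(g, "font-style") or "normal",
                    )
            style.explicit_shape = st_extras.get("shape")
            # every layout repeats the document-level styles; keep one copy
            if all(existing.id != style.id for existing in doc.styles):
                doc.styles.append(style)
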