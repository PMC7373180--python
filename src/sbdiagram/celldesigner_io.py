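"""I/O for SBML documents carrying the CellDesigner extension namespace.

CellDesigner predates the SBML layout package and stores geometry in its own
namespace inside SBML annotations: a *species alias* positions one depiction
of a species (several aliases of one species encode node duplication), a
*complexSpeciesAlias* positions a complex whose subunits are nested aliases,
and a *compartmentAlias* positions a compartment.  Unlike SBML layout, the
alias tags blend rendering attributes (fill color, line width, font size)
with geometry, the species type (protein, ion, gene, ...) lives in a
``speciesIdentity`` extension rather than an SBO term, and reaction geometry
is stored as *edit points* inside the core reaction's annotation — which is
also why the format cannot hold more than one layout.

The writer emits an SBML Level 2 Version 4 core (the dialect CellDesigner
4.4 produces); the reader accepts any Level 2 minor version.

Complex subunits ("included species") are not listed in the SBML core's
``listOfSpecies`` but in a CellDesigner-specific list; :func:`species_counts`
reports top-level and included species separately, since tools disagree on
which convention a "species count" means.

Edit points use a local coordinate frame anchored on the reaction axis:
origin at the base reactant's alias center, x-axis the vector to the base
product's alias center, y-axis its +90° rotation, both scaled by the axis
length.  This convention was inferred empirically (the format is
undocumented) and is exercised by inverse-consistency tests.
"""

from __future__ import annotations

from typing import Callable, Optional

from lxml import etree

from . import mapping
from .model import (
    BoundingBox,
    ColorRGBA,
    Compartment,
    CurveSegment,
    Document,
    Element,
    ElementClass,
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
    Role,
    Selector,
    Style,
    bbox,
    canvas_bounds,
    style_for_glyph,
    validate,
)

SBML_L2_NS = "http://www.sbml.org/sbml/level2/version4"
CD_NS = "http://www.sbml.org/2001/ns/celldesigner"

WarnFn = Optional[Callable[[str], None]]


def _q(ns: str, tag: str) -> str:
    return f"{{{ns}}}{tag}"


def _local(el: etree._Element) -> str:
    return etree.QName(el).localname


def _num(x: float) -> str:
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(float(x))


def _cd(parent: etree._Element, tag: str, **attrs: str) -> etree._Element:
    el = etree.SubElement(parent, _q(CD_NS, tag))
    for k, v in attrs.items():
        el.set(k, v)
    return el


# classes CellDesigner cannot name get the closest type string
_CD_CLASS_FALLBACK = {ElementClass.NUCLEIC_ACID_FEATURE: "GENE"}


def _cd_species_class(element_class: ElementClass, warn: WarnFn) -> str:
    if element_class in _CD_CLASS_FALLBACK:
        if warn:
            warn(
                f"element class {element_class.value!r} has no CellDesigner type; "
                f"writing {_CD_CLASS_FALLBACK[element_class]}"
            )
        return _CD_CLASS_FALLBACK[element_class]
    cd = mapping.class_to_celldesigner(element_class)
    if cd is None:  # pragma: no cover - table is currently total
        raise ModelError("unmappable-class", f"no CellDesigner type for {element_class.value!r}")
    return cd


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------


def write_celldesigner(doc: Document, layout_index: int = 0, warn: WarnFn = None) -> bytes:
    errors = [v for v in validate(doc) if v.severity.value == "error"]
    if errors:
        raise ModelError("invalid-document", "; ".join(str(v) for v in errors))
    if not doc.layouts:
        raise ModelError("no-layout", "CellDesigner requires exactly one layout")
    layout = doc.layouts[layout_index]

    root = etree.Element(
        _q(SBML_L2_NS, "sbml"), nsmap={None: SBML_L2_NS, "celldesigner": CD_NS}
    )
    root.set("level", "2")
    root.set("version", "4")
    model = etree.SubElement(root, _q(SBML_L2_NS, "model"))
    model.set("id", "model")

    elements = {e.id: e for e in doc.elements}
    top_level = [e for e in doc.elements if e.parent_complex_ref is None]
    included = [e for e in doc.elements if e.parent_complex_ref is not None]
    complex_ids = {e.id for e in doc.elements if e.element_class == ElementClass.COMPLEX}

    # model-level CellDesigner extension
    ann = etree.SubElement(model, _q(SBML_L2_NS, "annotation"))
    ext = _cd(ann, "extension")
    mv = _cd(ext, "modelVersion")
    mv.text = "4.0"
    canvas = layout.canvas
    if canvas.width == 0 and canvas.height == 0 and layout.glyphs:
        canvas = canvas_bounds(layout)
    _cd(ext, "modelDisplaySize", width=_num(canvas.width), height=_num(canvas.height))

    if included:
        lis = _cd(ext, "listOfIncludedSpecies")
        for e in included:
            sp = _cd(lis, "species", id=e.id, name=e.name or e.id)
            sann = _cd(sp, "annotation")
            cs = _cd(sann, "complexSpecies")
            cs.text = e.parent_complex_ref
            _write_identity(sann, e, warn)

    glyphs_by_kind: dict[GlyphKind, list[Glyph]] = {k: layout.glyphs_of_kind(k) for k in GlyphKind}
    glyph_of_element: dict[str, str] = {}
    for g in glyphs_by_kind[GlyphKind.SPECIES]:
        glyph_of_element.setdefault(g.model_ref, g.id)
    compartment_alias_of: dict[str, str] = {}
    for g in glyphs_by_kind[GlyphKind.COMPARTMENT]:
        if g.model_ref:
            compartment_alias_of.setdefault(g.model_ref, g.id)

    if glyphs_by_kind[GlyphKind.COMPARTMENT]:
        lca = _cd(ext, "listOfCompartmentAliases")
        for g in glyphs_by_kind[GlyphKind.COMPARTMENT]:
            al = _cd(lca, "compartmentAlias", id=g.id)
            if g.model_ref:
                al.set("compartment", g.model_ref)
            cls = _cd(al, "class")
            cls.text = "SQUARE"
            _write_bounds(al, g.bbox)
            style = style_for_glyph(doc, g)
            _cd(
                al,
                "paint",
                color=(style.fill if style else ColorRGBA(204, 204, 204)).to_argb_hex(),
                scheme="Color",
            )

    complex_glyphs = [
        g
        for g in glyphs_by_kind[GlyphKind.SPECIES]
        if g.model_ref in complex_ids
    ]
    plain_glyphs = [g for g in glyphs_by_kind[GlyphKind.SPECIES] if g.model_ref not in complex_ids]

    if complex_glyphs:
        lcsa = _cd(ext, "listOfComplexSpeciesAliases")
        for g in complex_glyphs:
            _write_alias(lcsa, "complexSpeciesAlias", doc, g, elements, compartment_alias_of)
    lsa = _cd(ext, "listOfSpeciesAliases")
    for g in plain_glyphs:
        _write_alias(lsa, "speciesAlias", doc, g, elements, compartment_alias_of)

    _write_named_refs(ext, doc, warn)

    # decorative graphics and other preserved model-level fragments
    for frag in doc.passthrough.get("celldesigner:model", []):
        ext.append(etree.fromstring(frag.encode()))

    # SBML core
    if doc.compartments:
        loc = etree.SubElement(model, _q(SBML_L2_NS, "listOfCompartments"))
        for c in doc.compartments:
            el = etree.SubElement(loc, _q(SBML_L2_NS, "compartment"))
            el.set("id", c.id)
            if c.name:
                el.set("name", c.name)
            if c.parent_ref:
                el.set("outside", c.parent_ref)

    if top_level:
        los = etree.SubElement(model, _q(SBML_L2_NS, "listOfSpecies"))
        for e in top_level:
            el = etree.SubElement(los, _q(SBML_L2_NS, "species"))
            el.set("id", e.id)
            el.set("name", e.name or e.id)
            el.set(
                "compartment",
                e.compartment_ref or (doc.compartments[0].id if doc.compartments else "default"),
            )
            sann = etree.SubElement(el, _q(SBML_L2_NS, "annotation"))
            sext = _cd(sann, "extension")
            pos = _cd(sext, "positionToCompartment")
            pos.text = "inside"
            _write_identity(sext, e, warn)
            for frag in doc.passthrough.get(e.id, []):
                node = etree.fromstring(frag.encode())
                if _local(node) == "notes":
                    el.append(node)
                else:
                    sann.append(node)

    if doc.reactions:
        lor = etree.SubElement(model, _q(SBML_L2_NS, "listOfReactions"))
        reaction_glyphs = {g.model_ref: g for g in glyphs_by_kind[GlyphKind.REACTION]}
        for r in doc.reactions:
            _write_reaction(lor, doc, r, reaction_glyphs.get(r.id), layout, glyph_of_element, warn)

    return etree.tostring(root, xml_declaration=True, encoding="UTF-8", pretty_print=True)


def _write_bounds(parent: etree._Element, b: Optional[BoundingBox]) -> None:
    if b is None:
        b = bbox(0, 0, 0, 0)
    _cd(parent, "bounds", x=_num(b.x), y=_num(b.y), w=_num(b.width), h=_num(b.height))


def _write_alias(
    parent: etree._Element,
    tag: str,
    doc: Document,
    g: Glyph,
    elements: dict[str, Element],
    compartment_alias_of: dict[str, str],
) -> None:
    al = _cd(parent, tag, id=g.id)
    if g.model_ref:
        al.set("species", g.model_ref)
        e = elements.get(g.model_ref)
        if e is not None and e.compartment_ref in compartment_alias_of:
            al.set("compartmentAlias", compartment_alias_of[e.compartment_ref])
    if g.parent_glyph_ref:
        al.set("complexSpeciesAlias", g.parent_glyph_ref)
    act = _cd(al, "activity")
    act.text = "inactive"
    _write_bounds(al, g.bbox)
    element = elements.get(g.model_ref) if g.model_ref else None
    style = style_for_glyph(doc, g, element.element_class if element else None)
    font = (style.font if style else None) or FontSpec()
    _cd(al, "font", size=_num(font.size))
    view = _cd(al, "usualView")
    _cd(view, "singleLine", width=_num(style.stroke_width if style else 1.0))
    fill = style.fill if style else ColorRGBA(204, 255, 204)
    _cd(view, "paint", color=fill.to_argb_hex(), scheme="Color")


def _write_identity(parent: etree._Element, e: Element, warn: WarnFn) -> None:
    ident = _cd(parent, "speciesIdentity")
    cls = _cd(ident, "class")
    cls.text = _cd_species_class(e.element_class, warn)
    if e.modifications:
        state = _cd(ident, "state")
        lom = _cd(state, "listOfModifications")
        for m in e.modifications:
            _cd(lom, "modification", residue=m.residue_label, state=m.state)
    if e.is_hypothetical:
        hypo = _cd(ident, "hypothetical")
        hypo.text = "true"


def _write_named_refs(ext: etree._Element, doc: Document, warn: WarnFn) -> None:
    """Protein/gene/RNA reference lists with modification residues."""
    proteins = [
        e
        for e in doc.elements
        if e.element_class in (ElementClass.MACROMOLECULE, ElementClass.RECEPTOR)
    ]
    if proteins:
        lop = _cd(ext, "listOfProteins")
        for e in proteins:
            pr = _cd(
                lop,
                "protein",
                id=f"pr_{e.id}",
                name=e.name or e.id,
                type="RECEPTOR" if e.element_class == ElementClass.RECEPTOR else "GENERIC",
            )
            if e.modifications:
                lomr = _cd(pr, "listOfModificationResidues")
                for i, m in enumerate(e.modifications):
                    _cd(lomr, "modificationResidue", angle="0", id=f"rs_{e.id}_{i}", name=m.residue_label)
    genes = [e for e in doc.elements if e.element_class == ElementClass.GENE]
    if genes:
        log = _cd(ext, "listOfGenes")
        for e in genes:
            _cd(log, "gene", id=f"gn_{e.id}", name=e.name or e.id, type="GENE")
    rnas = [e for e in doc.elements if e.element_class == ElementClass.RNA]
    if rnas:
        lor = _cd(ext, "listOfRNAs")
        for e in rnas:
            _cd(lor, "RNA", id=f"rn_{e.id}", name=e.name or e.id, type="RNA")


# --- edit-point frame ------------------------------------------------------


def _axis_frame(r_center: Point, p_center: Point) -> tuple[Point, Point, Point]:
    """(origin, u, v): local frame of the reactant→product axis.

    (Near-)coincident anchors would collapse the frame; fall back to the
    unit x axis whenever the squared axis length underflows to zero, so the
    transform pair stays invertible.
    """
    u = Point(p_center.x - r_center.x, p_center.y - r_center.y)
    if u.x * u.x + u.y * u.y == 0.0:
        u = Point(1.0, 0.0)
    v = Point(-u.y, u.x)
    return r_center, u, v


def to_absolute(local: Point, r_center: Point, p_center: Point) -> Point:
    o, u, v = _axis_frame(r_center, p_center)
    return Point(o.x + local.x * u.x + local.y * v.x, o.y + local.x * u.y + local.y * v.y)


def to_local(absolute: Point, r_center: Point, p_center: Point) -> Point:
    o, u, v = _axis_frame(r_center, p_center)
    d = Point(absolute.x - o.x, absolute.y - o.y)
    uu = u.x * u.x + u.y * u.y
    return Point((d.x * u.x + d.y * u.y) / uu, (d.x * v.x + d.y * v.y) / uu)


def _glyph_center(layout: Layout, glyph_id: Optional[str]) -> Optional[Point]:
    if glyph_id is None:
        return None
    try:
        g = layout.glyph(glyph_id)
    except KeyError:
        return None
    return g.bbox.center if g.bbox is not None else None


def _write_reaction(
    parent: etree._Element,
    doc: Document,
    r: Reaction,
    glyph: Optional[Glyph],
    layout: Layout,
    glyph_of_element: dict[str, str],
    warn: WarnFn,
) -> None:
    el = etree.SubElement(parent, _q(SBML_L2_NS, "reaction"))
    el.set("id", r.id)
    el.set("reversible", "false")
    ann = etree.SubElement(el, _q(SBML_L2_NS, "annotation"))
    ext = _cd(ann, "extension")
    rt = _cd(ext, "reactionType")
    rt.text = mapping.reaction_class_to_celldesigner(r.reaction_class)

    def alias_for(p: Participant, link_role: Optional[Role] = None) -> str:
        # prefer the glyph the reaction glyph explicitly links to
        if glyph is not None:
            for link in glyph.participant_links:
                lg = layout.glyph(link.glyph_ref)
                if lg.model_ref == p.element_ref and (link_role is None or link.role == link_role):
                    return link.glyph_ref
        return glyph_of_element.get(p.element_ref, "")

    main_reactants = [p for p in r.reactants if p.role != Role.SIDE_SUBSTRATE] or r.reactants
    main_products = [p for p in r.products if p.role != Role.SIDE_PRODUCT] or r.products
    side_reactants = [p for p in r.reactants if p not in main_reactants]
    side_products = [p for p in r.products if p not in main_products]

    br = _cd(ext, "baseReactants")
    for p in main_reactants:
        _cd(br, "baseReactant", species=p.element_ref, alias=alias_for(p))
    bp = _cd(ext, "baseProducts")
    for p in main_products:
        _cd(bp, "baseProduct", species=p.element_ref, alias=alias_for(p))
    if side_reactants:
        lrl = _cd(ext, "listOfReactantLinks")
        for p in side_reactants:
            _cd(lrl, "reactantLink", reactant=p.element_ref, alias=alias_for(p))
    if side_products:
        lpl = _cd(ext, "listOfProductLinks")
        for p in side_products:
            _cd(lpl, "productLink", product=p.element_ref, alias=alias_for(p))

    # interior curve anchors -> edit points in the axis frame
    if glyph is not None and glyph.curve:
        pts: list[Point] = [glyph.curve[0].start]
        for seg in glyph.curve:
            pts.append(seg.end)
        interior = pts[1:-1]
        r_center = _glyph_center(layout, alias_for(main_reactants[0]) if main_reactants else None)
        p_center = _glyph_center(layout, alias_for(main_products[0]) if main_products else None)
        if interior and r_center is not None and p_center is not None:
            locals_ = [to_local(pt, r_center, p_center) for pt in interior]
            ep = _cd(ext, "editPoints")
            ep.text = " ".join(f"{_num(p.x)},{_num(p.y)}" for p in locals_)

    if r.modifiers:
        lom = _cd(ext, "listOfModification")
        for p in r.modifiers:
            _cd(
                lom,
                "modification",
                type=mapping.role_to_celldesigner_modification(p.role, p.modifier_kind),
                modifiers=p.element_ref,
                aliases=alias_for(p),
            )
    _cd(ext, "line", width="1", color="ff000000")

    for frag in doc.passthrough.get(r.id, []):
        node = etree.fromstring(frag.encode())
        if _local(node) == "kineticLaw":
            el.append(node)
        else:
            ann.append(node)

    if r.reactants:
        lst = etree.SubElement(el, _q(SBML_L2_NS, "listOfReactants"))
        for p in r.reactants:
            sr = etree.SubElement(lst, _q(SBML_L2_NS, "speciesReference"))
            sr.set("species", p.element_ref)
    if r.products:
        lst = etree.SubElement(el, _q(SBML_L2_NS, "listOfProducts"))
        for p in r.products:
            sr = etree.SubElement(lst, _q(SBML_L2_NS, "speciesReference"))
            sr.set("species", p.element_ref)
    if r.modifiers:
        lst = etree.SubElement(el, _q(SBML_L2_NS, "listOfModifiers"))
        for p in r.modifiers:
            sr = etree.SubElement(lst, _q(SBML_L2_NS, "modifierSpeciesReference"))
            sr.set("species", p.element_ref)


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------


def read_celldesigner(data: bytes, warn: WarnFn = None) -> Document:
    try:
        root = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        raise ModelError("parse-error", str(exc)) from exc
    if CD_NS not in data.decode("utf-8", errors="replace"):
        raise ModelError("not-celldesigner", "CellDesigner namespace not present")
    model = _find_child(root, "model")
    if model is None:
        raise ModelError("invalid-sbml", "SBML document without a model element")

    doc = Document(source_format="celldesigner")
    layout = Layout(id="layout_0")
    doc.layouts.append(layout)

    ext = _model_extension(model)

    for c in _list_children(model, "listOfCompartments", "compartment"):
        doc.compartments.append(
            Compartment(id=c.get("id"), name=c.get("name", ""), parent_ref=c.get("outside"))
        )

    # core species
    for s in _list_children(model, "listOfSpecies", "species"):
        e = Element(id=s.get("id"), name=s.get("name", ""), compartment_ref=s.get("compartment"))
        _read_identity_into(s, e, doc, warn)
        doc.elements.append(e)

    # included species (complex subunits)
    if ext is not None:
        lis = _find_cd(ext, "listOfIncludedSpecies")
        for s in lis if lis is not None else []:
            if _local(s) != "species":
                continue
            e = Element(id=s.get("id"), name=s.get("name", ""))
            sann = _find_cd(s, "annotation")
            if sann is not None:
                cs = _find_cd(sann, "complexSpecies")
                if cs is not None and cs.text:
                    e.parent_complex_ref = cs.text.strip()
                _apply_identity(_find_cd(sann, "speciesIdentity"), e, warn)
            doc.elements.append(e)

    style_cache: dict[tuple, Style] = {}

    def alias_style(fill: ColorRGBA, width: float, font_size: float, glyph_id: str) -> str:
        key = (fill.to_argb_hex(), width, font_size)
        if key not in style_cache:
            style = Style(
                id=f"style_{len(style_cache)}",
                applies_to=Selector(glyph_ids=[]),
                stroke=ColorRGBA(0, 0, 0),
                stroke_width=width,
                fill=fill,
                font=FontSpec(size=font_size),
            )
            style_cache[key] = style
            doc.styles.append(style)
        style_cache[key].applies_to.glyph_ids.append(glyph_id)
        return style_cache[key].id

    known_species = {e.id for e in doc.elements}

    if ext is not None:
        lca = _find_cd(ext, "listOfCompartmentAliases")
        for al in lca if lca is not None else []:
            if _local(al) != "compartmentAlias":
                continue
            g = Glyph(
                id=al.get("id"),
                kind=GlyphKind.COMPARTMENT,
                model_ref=al.get("compartment"),
                bbox=_read_bounds(al),
            )
            paint = _find_cd(al, "paint")
            if paint is not None and paint.get("color"):
                g.style_ref = alias_style(
                    ColorRGBA.from_argb_hex(paint.get("color")), 1.0, 11.0, g.id
                )
            layout.glyphs.append(g)

        for list_name, tag in (
            ("listOfComplexSpeciesAliases", "complexSpeciesAlias"),
            ("listOfSpeciesAliases", "speciesAlias"),
        ):
            lst = _find_cd(ext, list_name)
            for al in lst if lst is not None else []:
                if _local(al) != tag:
                    continue
                species_ref = al.get("species")
                if species_ref and species_ref not in known_species and warn:
                    warn(f"alias {al.get('id')!r} references unknown species {species_ref!r}")
                g = Glyph(
                    id=al.get("id"),
                    kind=GlyphKind.SPECIES,
                    model_ref=species_ref,
                    bbox=_read_bounds(al),
                    parent_glyph_ref=al.get("complexSpeciesAlias"),
                )
                font = _find_cd(al, "font")
                font_size = float(font.get("size", "11")) if font is not None else 11.0
                fill = ColorRGBA(204, 255, 204)
                width = 1.0
                view = _find_cd(al, "usualView")
                if view is not None:
                    line_el = _find_cd(view, "singleLine")
                    if line_el is not None and line_el.get("width"):
                        width = float(line_el.get("width"))
                    paint = _find_cd(view, "paint")
                    if paint is not None and paint.get("color"):
                        fill = ColorRGBA.from_argb_hex(paint.get("color"))
                g.style_ref = alias_style(fill, width, font_size, g.id)
                layout.glyphs.append(g)

        # decorative graphics CellDesigner can carry but the other notations cannot
        for extra in ("listOfGroups", "listOfTexts", "listOfLayers"):
            node = _find_cd(ext, extra)
            if node is not None and len(node):
                doc.add_passthrough("celldesigner:model", etree.tostring(node, encoding="unicode"))

    # reactions (+ glyph geometry from edit points)
    for r_el in _list_children(model, "listOfReactions", "reaction"):
        _read_reaction(r_el, doc, layout, warn)

    if layout.glyphs:
        layout.canvas = canvas_bounds(layout)
    return doc


def _find_child(el: etree._Element, name: str) -> Optional[etree._Element]:
    for c in el:
        if _local(c) == name:
            return c
    return None


def _list_children(el: etree._Element, list_name: str, item_name: str) -> list[etree._Element]:
    lst = _find_child(el, list_name)
    if lst is None:
        return []
    return [c for c in lst if _local(c) == item_name]


def _find_cd(el: etree._Element, name: str) -> Optional[etree._Element]:
    if el is None:
        return None
    for c in el:
        if _ns(c) == CD_NS and _local(c) == name:
            return c
    return None


def _ns(el: etree._Element) -> str:
    return etree.QName(el).namespace or ""


def _model_extension(model: etree._Element) -> Optional[etree._Element]:
    ann = _find_child(model, "annotation")
    return _find_cd(ann, "extension") if ann is not None else None


def _read_bounds(al: etree._Element) -> Optional[BoundingBox]:
    b = _find_cd(al, "bounds")
    if b is None:
        return None
    return bbox(
        float(b.get("x", "0")), float(b.get("y", "0")), float(b.get("w", "0")), float(b.get("h", "0"))
    )


def _apply_identity(ident: Optional[etree._Element], e: Element, warn: WarnFn) -> None:
    if ident is None:
        return
    cls = _find_cd(ident, "class")
    if cls is not None and cls.text:
        e.element_class = mapping.celldesigner_type_to_class(cls.text.strip(), warn)
        e.sbo_term = mapping.class_to_sbo(e.element_class)
    state = _find_cd(ident, "state")
    if state is not None:
        lom = _find_cd(state, "listOfModifications")
        for m in lom if lom is not None else []:
            if _local(m) == "modification":
                e.modifications.append(
                    ModificationState(m.get("residue", ""), m.get("state", "unknown"))
                )
    hypo = _find_cd(ident, "hypothetical")
    if hypo is not None and (hypo.text or "").strip() == "true":
        e.is_hypothetical = True


def _read_identity_into(species_el: etree._Element, e: Element, doc: Document, warn: WarnFn) -> None:
    ann = _find_child(species_el, "annotation")
    if ann is None:
        return
    ext = _find_cd(ann, "extension")
    if ext is not None:
        _apply_identity(_find_cd(ext, "speciesIdentity"), e, warn)
    for child in ann:
        if _ns(child) != CD_NS:
            doc.add_passthrough(e.id, etree.tostring(child, encoding="unicode"))
    notes = _find_child(species_el, "notes")
    if notes is not None:
        doc.add_passthrough(e.id, etree.tostring(notes, encoding="unicode"))


def _read_reaction(r_el: etree._Element, doc: Document, layout: Layout, warn: WarnFn) -> None:
    r = Reaction(id=r_el.get("id"))
    ann = _find_child(r_el, "annotation")
    ext = _find_cd(ann, "extension") if ann is not None else None

    base_reactant_alias: Optional[str] = None
    base_product_alias: Optional[str] = None
    side_reactants: set[str] = set()
    side_products: set[str] = set()
    modifier_info: dict[str, tuple[Role, Optional[str], Optional[str]]] = {}
    edit_points: list[Point] = []

    if ext is not None:
        rt = _find_cd(ext, "reactionType")
        if rt is not None and rt.text:
            r.reaction_class = mapping.celldesigner_reaction_type_to_class(rt.text.strip(), warn)
        br = _find_cd(ext, "baseReactants")
        if br is not None and len(br):
            base_reactant_alias = br[0].get("alias")
        bp = _find_cd(ext, "baseProducts")
        if bp is not None and len(bp):
            base_product_alias = bp[0].get("alias")
        lrl = _find_cd(ext, "listOfReactantLinks")
        for link in lrl if lrl is not None else []:
            side_reactants.add(link.get("reactant"))
        lpl = _find_cd(ext, "listOfProductLinks")
        for link in lpl if lpl is not None else []:
            side_products.add(link.get("product"))
        lom = _find_cd(ext, "listOfModification")
        for m in lom if lom is not None else []:
            role, kind = mapping.CD_MODIFICATION_TYPE.get(
                (m.get("type") or "").upper(), (Role.MODIFIER, None)
            )
            modifier_info[m.get("modifiers")] = (role, kind, m.get("aliases"))
        ep = _find_cd(ext, "editPoints")
        if ep is not None and ep.text:
            for token in ep.text.split():
                x, y = token.split(",")
                edit_points.append(Point(float(x), float(y)))
        for child in ann:
            if _ns(child) != CD_NS:
                doc.add_passthrough(r.id, etree.tostring(child, encoding="unicode"))
    kl = _find_child(r_el, "kineticLaw")
    if kl is not None:
        doc.add_passthrough(r.id, etree.tostring(kl, encoding="unicode"))

    for ref in _list_children(r_el, "listOfReactants", "speciesReference"):
        sid = ref.get("species")
        role = Role.SIDE_SUBSTRATE if sid in side_reactants else Role.SUBSTRATE
        r.reactants.append(Participant(sid, role))
    for ref in _list_children(r_el, "listOfProducts", "speciesReference"):
        sid = ref.get("species")
        role = Role.SIDE_PRODUCT if sid in side_products else Role.PRODUCT
        r.products.append(Participant(sid, role))
    for ref in _list_children(r_el, "listOfModifiers", "modifierSpeciesReference"):
        sid = ref.get("species")
        role, kind, _alias = modifier_info.get(sid, (Role.MODIFIER, None, None))
        r.modifiers.append(Participant(sid, role, kind))

    doc.reactions.append(r)

    # reaction glyph: polyline through the edit points in the axis frame
    g = Glyph(id=f"rg_{r.id}", kind=GlyphKind.REACTION, model_ref=r.id)
    r_center = _glyph_center(layout, base_reactant_alias)
    p_center = _glyph_center(layout, base_product_alias)
    if r_center is not None and p_center is not None:
        pts = [r_center]
        pts += [to_absolute(p, r_center, p_center) for p in edit_points]
        pts.append(p_center)
        g.curve = [
            CurveSegment("line", pts[i], pts[i + 1]) for i in range(len(pts) - 1)
        ]
    glyph_by_model: dict[str, str] = {}
    for sg in layout.glyphs:
        if sg.kind == GlyphKind.SPECIES and sg.model_ref:
            glyph_by_model.setdefault(sg.model_ref, sg.id)
    for p in list(r.reactants) + list(r.products) + list(r.modifiers):
        alias = None
        if p in r.modifiers:
            info = modifier_info.get(p.element_ref)
            alias = info[2] if info else None
        alias = alias or glyph_by_model.get(p.element_ref)
        if alias is not None:
            g.participant_links.append(ParticipantLink(alias, p.role, modifier_kind=p.modifier_kind))
    layout.glyphs.append(g)


# ---------------------------------------------------------------------------
# reporting helpers
# ---------------------------------------------------------------------------


def species_counts(doc: Document) -> dict[str, int]:
    """Top-level vs included (complex-subunit) species counts.

    CellDesigner lists complex subunits outside the SBML core's species
    list, so tools disagree on what a "species count" includes; both
    conventions are reported.
    """
    top = sum(1 for e in doc.elements if e.parent_complex_ref is None)
    included = sum(1 for e in doc.elements if e.parent_complex_ref is not None)
    return {"top_level": top, "included": included, "total": top + included}
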