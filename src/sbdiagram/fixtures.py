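"""Deterministic synthetic diagrams for testing and benchmarking.

The generator emulates the structural features of curated disease-map
exports: duplicated nodes (one species drawn twice), proteins with modified
residues, species grouped into complexes, and nested compartments.  The
structure of a generated document is a pure function of the size arguments;
the seed only jitters glyph positions, so failures reproduce exactly.

:func:`benchmark_like` builds stand-ins for the three published benchmark
networks by element count — an inflammation pathway (37 species /
20 reactions, one compartment), a striatal-neuron network (152 / 132,
multi-compartment) and a full disease-map scale network (~5000 / ~2500).
These are synthetic: they match the originals in size and structural
features, not in biology.
"""

from __future__ import annotations

import math
import random
from typing import Callable, Optional

from .model import (
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
    ReactionClass,
    Role,
    Selector,
    Style,
    bbox,
    canvas_bounds,
)

CELL_W, CELL_H = 150.0, 90.0
GLYPH_W, GLYPH_H = 100.0, 50.0

_CLASS_CYCLE = [
    ElementClass.MACROMOLECULE,
    ElementClass.SIMPLE_CHEMICAL,
    ElementClass.GENE,
    ElementClass.RNA,
    ElementClass.PHENOTYPE,
    ElementClass.ION,
    ElementClass.RECEPTOR,
]

_REACTION_CYCLE = [
    ReactionClass.STATE_TRANSITION,
    ReactionClass.TRANSPORT,
    ReactionClass.STATE_TRANSITION,
    ReactionClass.ASSOCIATION,
    ReactionClass.STATE_TRANSITION,
]


def make_toy_document(
    n_species: int, n_reactions: int, n_compartments: int, seed: int
) -> Document:
    """Synthetic document with the study's structural features built in.

    Guarantees (for ``n_species >= 4``): one duplicated species drawn with
    two glyphs, one complex with two subunits, a phosphorylated
    macromolecule, and (with ``n_reactions >= 1``) one reaction carrying an
    inhibitor; with ``n_compartments >= 2`` the second compartment nests
    inside the first.  Glyphs sit on a collision-free grid;
    ``validate(doc)`` returns no findings.
    """
    if n_species < 1 or n_reactions < 0 or n_compartments < 1:
        raise ModelError("infeasible", "need n_species >= 1, n_reactions >= 0, n_compartments >= 1")
    if n_reactions > 0 and n_species < 2:
        raise ModelError("infeasible", "reactions need at least two species")

    rng = random.Random(seed)
    doc = Document(source_format="synthetic")

    for k in range(n_compartments):
        doc.compartments.append(
            Compartment(
                id=f"c{k}",
                name=f"compartment_{k}",
                parent_ref="c0" if (k == 1 and n_compartments >= 2) else None,
            )
        )

    rich = n_species >= 4
    elements: list[Element] = []
    for i in range(n_species):
        if rich and i == 0:
            cls = ElementClass.COMPLEX
        elif rich and i in (1, 2):
            cls = _CLASS_CYCLE[i % len(_CLASS_CYCLE)]
        else:
            cls = _CLASS_CYCLE[i % len(_CLASS_CYCLE)]
        e = Element(
            id=f"s{i}",
            name=f"SP{i}",
            element_class=cls,
            compartment_ref=f"c{i % n_compartments}",
        )
        if rich and i in (1, 2):
            e.parent_complex_ref = "s0"
            e.element_class = ElementClass.MACROMOLECULE
            e.compartment_ref = doc.compartments[0].id
        elements.append(e)
    if rich:
        elements[0].compartment_ref = doc.compartments[0].id
        # a protein with a modified residue
        for e in elements:
            if e.parent_complex_ref is None and e.element_class == ElementClass.MACROMOLECULE:
                e.modifications.append(ModificationState("S45", "phosphorylated"))
                break
        else:
            elements[3].modifications.append(ModificationState("S45", "phosphorylated"))
    doc.elements = elements

    top_level = [e for e in elements if e.parent_complex_ref is None]
    duplicated = top_level[-1] if rich else None

    for j in range(n_reactions):
        t = len(top_level)
        r = Reaction(
            id=f"r{j}",
            reaction_class=_REACTION_CYCLE[j % len(_REACTION_CYCLE)],
            reactants=[Participant(top_level[j % t].id, Role.SUBSTRATE)],
            products=[Participant(top_level[(j + 1) % t].id, Role.PRODUCT)],
        )
        if rich and j == 0:
            r.modifiers.append(Participant(top_level[(j + 2) % t].id, Role.INHIBITOR))
        doc.reactions.append(r)

    doc.layouts.append(_grid_layout(doc, top_level, duplicated, rng))
    _default_styles(doc)
    return doc


def _grid_layout(
    doc: Document,
    top_level: list[Element],
    duplicated: Optional[Element],
    rng: random.Random,
) -> Layout:
    layout = Layout(id="layout_0")
    slots = len(top_level) + (1 if duplicated is not None else 0)
    ncols = max(1, math.ceil(math.sqrt(slots)))

    def slot_origin(k: int) -> Point:
        col, row = k % ncols, k // ncols
        jx = rng.uniform(-3, 3)
        jy = rng.uniform(-3, 3)
        return Point(60 + col * CELL_W + jx, 60 + row * CELL_H + jy)

    glyph_of: dict[str, Glyph] = {}
    subunits = [e for e in doc.elements if e.parent_complex_ref is not None]
    slot = 0
    for e in top_level:
        o = slot_origin(slot)
        slot += 1
        if e.element_class == ElementClass.COMPLEX and subunits:
            g = Glyph(id=f"g_{e.id}", kind=GlyphKind.SPECIES, model_ref=e.id,
                      bbox=bbox(o.x, o.y, GLYPH_W + 30, GLYPH_H + 34))
            layout.glyphs.append(g)
            glyph_of[e.id] = g
            for si, sub in enumerate(s for s in subunits if s.parent_complex_ref == e.id):
                sg = Glyph(
                    id=f"g_{sub.id}",
                    kind=GlyphKind.SPECIES,
                    model_ref=sub.id,
                    bbox=bbox(o.x + 10, o.y + 12 + si * (GLYPH_H / 2 + 6), GLYPH_W, GLYPH_H / 2),
                    parent_glyph_ref=g.id,
                )
                layout.glyphs.append(sg)
                glyph_of[sub.id] = sg
        else:
            g = Glyph(id=f"g_{e.id}", kind=GlyphKind.SPECIES, model_ref=e.id,
                      bbox=bbox(o.x, o.y, GLYPH_W, GLYPH_H))
            layout.glyphs.append(g)
            glyph_of[e.id] = g
    if duplicated is not None:
        o = slot_origin(slot)
        layout.glyphs.append(
            Glyph(id=f"g_{duplicated.id}_dup", kind=GlyphKind.SPECIES,
                  model_ref=duplicated.id, bbox=bbox(o.x, o.y, GLYPH_W, GLYPH_H))
        )

    # nested compartment boxes around the species grid
    if layout.glyphs:
        grid_bounds = canvas_bounds(layout)
        for k, c in enumerate(doc.compartments):
            inset = 40.0 - 12.0 * min(k, 2)
            layout.glyphs.append(
                Glyph(
                    id=f"g_{c.id}",
                    kind=GlyphKind.COMPARTMENT,
                    model_ref=c.id,
                    bbox=bbox(
                        grid_bounds.x - inset,
                        grid_bounds.y - inset,
                        grid_bounds.width + 2 * inset,
                        grid_bounds.height + 2 * inset,
                    ),
                )
            )

    for r in doc.reactions:
        src = glyph_of[r.reactants[0].element_ref]
        dst = glyph_of[r.products[0].element_ref]
        g = Glyph(
            id=f"g_{r.id}",
            kind=GlyphKind.REACTION,
            model_ref=r.id,
            curve=[CurveSegment("line", src.bbox.center, dst.bbox.center)],
        )
        for p in list(r.reactants) + list(r.products) + list(r.modifiers):
            g.participant_links.append(
                ParticipantLink(glyph_of[p.element_ref].id, p.role, modifier_kind=p.modifier_kind)
            )
        layout.glyphs.append(g)

    layout.canvas = canvas_bounds(layout)
    return layout


def _default_styles(doc: Document) -> None:
    """CellDesigner-flavored palette keyed on element class."""
    palette = [
        ([ElementClass.MACROMOLECULE, ElementClass.RECEPTOR], ColorRGBA(204, 255, 204)),
        ([ElementClass.SIMPLE_CHEMICAL, ElementClass.ION], ColorRGBA(255, 204, 153)),
        ([ElementClass.GENE, ElementClass.RNA, ElementClass.NUCLEIC_ACID_FEATURE],
         ColorRGBA(255, 255, 179)),
        ([ElementClass.COMPLEX], ColorRGBA(230, 230, 250)),
    ]
    present = {e.element_class for e in doc.elements}
    for i, (classes, fill) in enumerate(palette):
        classes = [c for c in classes if c in present]
        if not classes:
            continue
        doc.styles.append(
            Style(
                id=f"cls_style_{i}",
                applies_to=Selector(element_classes=classes),
                stroke=ColorRGBA(0, 0, 0),
                stroke_width=1.0,
                fill=fill,
                font=FontSpec(size=11.0),
            )
        )


def minimal_examples() -> dict[str, Document]:
    """Named single-feature documents, each passing validation cleanly."""
    out: dict[str, Document] = {}

    def doc_with(builder: Callable[[Document, Layout], None], name: str) -> None:
        d = Document(source_format="synthetic")
        d.compartments.append(Compartment(id="c0", name="cell"))
        layout = Layout(id="layout_0")
        d.layouts.append(layout)
        builder(d, layout)
        layout.canvas = canvas_bounds(layout)
        out[name] = d

    def species(d: Document, layout: Layout, sid: str, x: float, y: float,
                cls: ElementClass = ElementClass.MACROMOLECULE, **kw) -> Glyph:
        e = Element(id=sid, name=sid.upper(), element_class=cls, compartment_ref="c0", **kw)
        d.elements.append(e)
        g = Glyph(id=f"g_{sid}", kind=GlyphKind.SPECIES, model_ref=sid,
                  bbox=bbox(x, y, GLYPH_W, GLYPH_H))
        layout.glyphs.append(g)
        return g

    def one_species(d: Document, layout: Layout) -> None:
        species(d, layout, "a", 20, 20)

    def one_reaction(d: Document, layout: Layout) -> None:
        ga = species(d, layout, "a", 20, 20)
        gb = species(d, layout, "b", 220, 20)
        d.reactions.append(
            Reaction(id="r0", reactants=[Participant("a", Role.SUBSTRATE)],
                     products=[Participant("b", Role.PRODUCT)])
        )
        layout.glyphs.append(
            Glyph(id="g_r0", kind=GlyphKind.REACTION, model_ref="r0",
                  curve=[CurveSegment("line", ga.bbox.center, gb.bbox.center)],
                  participant_links=[ParticipantLink(ga.id, Role.SUBSTRATE),
                                     ParticipantLink(gb.id, Role.PRODUCT)])
        )

    def complex_subunits(d: Document, layout: Layout) -> None:
        d.elements.append(Element(id="cx", name="CX", element_class=ElementClass.COMPLEX,
                                  compartment_ref="c0"))
        g = Glyph(id="g_cx", kind=GlyphKind.SPECIES, model_ref="cx",
                  bbox=bbox(20, 20, 140, 110))
        layout.glyphs.append(g)
        for i in range(2):
            d.elements.append(Element(id=f"u{i}", name=f"U{i}",
                                      element_class=ElementClass.MACROMOLECULE,
                                      compartment_ref="c0", parent_complex_ref="cx"))
            layout.glyphs.append(
                Glyph(id=f"g_u{i}", kind=GlyphKind.SPECIES, model_ref=f"u{i}",
                      bbox=bbox(35, 32 + i * 40, 100, 30), parent_glyph_ref="g_cx")
            )

    def duplicate_pair(d: Document, layout: Layout) -> None:
        species(d, layout, "w", 20, 20, cls=ElementClass.SIMPLE_CHEMICAL)
        layout.glyphs.append(
            Glyph(id="g_w_dup", kind=GlyphKind.SPECIES, model_ref="w",
                  bbox=bbox(260, 140, GLYPH_W, GLYPH_H))
        )

    def nested_compartments(d: Document, layout: Layout) -> None:
        d.compartments.append(Compartment(id="c1", name="nucleus", parent_ref="c0"))
        layout.glyphs.append(Glyph(id="g_c0", kind=GlyphKind.COMPARTMENT, model_ref="c0",
                                   bbox=bbox(10, 10, 400, 300)))
        layout.glyphs.append(Glyph(id="g_c1", kind=GlyphKind.COMPARTMENT, model_ref="c1",
                                   bbox=bbox(180, 120, 180, 140)))
        g = species(d, layout, "n", 210, 150, cls=ElementClass.GENE)
        d.elements[-1].compartment_ref = "c1"

    def modified_protein(d: Document, layout: Layout) -> None:
        species(d, layout, "p", 30, 30,
                modifications=[ModificationState("S45", "phosphorylated"),
                               ModificationState("Y204", "phosphorylated")])

    doc_with(one_species, "one-species")
    doc_with(one_reaction, "one-reaction-two-species")
    doc_with(complex_subunits, "complex-with-subunits")
    doc_with(duplicate_pair, "duplicate-pair")
    doc_with(nested_compartments, "nested-compartments")
    doc_with(modified_protein, "modified-protein")
    return out


#: element/reaction counts of the published benchmark networks that the
#: synthetic stand-ins reproduce (size and features, not biology)
BENCHMARK_SIZES = {
    "INP": (37, 20, 1),
    "SN": (152, 132, 4),
    "PDM": (5000, 2500, 8),
}


def benchmark_like(name: str, seed: int = 0) -> Document:
    """Synthetic stand-in for one of the benchmark networks by size."""
    if name not in BENCHMARK_SIZES:
        raise ModelError("unknown-benchmark", f"no benchmark named {name!r}")
    n_species, n_reactions, n_compartments = BENCHMARK_SIZES[name]
    return make_toy_document(n_species, n_reactions, n_compartments, seed=seed)
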