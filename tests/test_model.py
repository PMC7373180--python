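import math

import pytest

from sbdiagram.model import (
    BoundingBox,
    ColorRGBA,
    CurveSegment,
    Document,
    Element,
    ElementClass,
    Glyph,
    GlyphKind,
    Layout,
    ModelError,
    Participant,
    Point,
    Reaction,
    Role,
    Selector,
    Style,
    bbox,
    canvas_bounds,
    duplicate_groups,
    style_for_glyph,
    validate,
)


class TestGeometryPrimitives:
    def test_bbox_accessors(self):
        b = bbox(10, 20, 100, 50)
        assert (b.x, b.y, b.width, b.height) == (10, 20, 100, 50)
        assert b.center == Point(60, 45)

    def test_bbox_contains(self):
        outer = bbox(0, 0, 100, 100)
        assert outer.contains(bbox(10, 10, 50, 50))
        assert outer.contains(outer)
        assert not outer.contains(bbox(60, 60, 50, 50))
        assert not outer.contains(bbox(-1, 0, 10, 10))

    def test_point_rejects_non_finite(self):
        with pytest.raises(ValueError):
            Point(float("nan"), 0.0)
        with pytest.raises(ValueError):
            Point(0.0, float("inf"))

    def test_negative_bbox_dimensions_rejected(self):
        with pytest.raises(ValueError):
            bbox(0, 0, -1, 5)

    def test_cubic_segment_requires_controls(self):
        with pytest.raises(ValueError):
            CurveSegment("cubic-bezier", Point(0, 0), Point(1, 1))
        seg = CurveSegment(
            "cubic-bezier", Point(0, 0), Point(3, 0), Point(1, 1), Point(2, 1)
        )
        assert seg.control1 == Point(1, 1)

    def test_line_segment_has_no_controls(self):
        with pytest.raises(ValueError):
            CurveSegment("line", Point(0, 0), Point(1, 1), Point(0.5, 0.5))


class TestColor:
    def test_hex_rgba_round_trip(self):
        c = ColorRGBA(18, 52, 86, 120)
        assert ColorRGBA.from_hex(c.to_hex_rgba()) == c

    def test_argb_round_trip(self):
        c = ColorRGBA(255, 204, 0)
        assert ColorRGBA.from_argb_hex(c.to_argb_hex()) == c
        assert c.to_argb_hex() == "ffffcc00"

    def test_component_range_checked(self):
        with pytest.raises(ValueError):
            ColorRGBA(256, 0, 0)


def _single_glyph_doc():
    doc = Document()
    doc.elements.append(Element(id="a", name="A"))
    layout = Layout(id="l0")
    layout.glyphs.append(
        Glyph(id="g_a", kind=GlyphKind.SPECIES, model_ref="a", bbox=bbox(5, 10, 40, 20))
    )
    doc.layouts.append(layout)
    return doc


class TestCanvasBounds:
    def test_single_glyph(self):
        doc = _single_glyph_doc()
        b = canvas_bounds(doc.layouts[0])
        assert (b.x, b.y, b.width, b.height) == (5, 10, 40, 20)

    def test_includes_curves(self):
        doc = _single_glyph_doc()
        doc.layouts[0].glyphs.append(
            Glyph(
                id="g_r",
                kind=GlyphKind.REACTION,
                curve=[CurveSegment("line", Point(0, 0), Point(200, 150))],
            )
        )
        b = canvas_bounds(doc.layouts[0])
        assert (b.x, b.y) == (0, 0)
        assert (b.width, b.height) == (200, 150)

    def test_empty_layout_raises(self):
        with pytest.raises(ModelError) as exc:
            canvas_bounds(Layout(id="empty"))
        assert exc.value.code == "no-geometry"


class TestValidate:
    def test_clean_document(self):
        assert validate(_single_glyph_doc()) == []

    def test_duplicate_id(self):
        doc = _single_glyph_doc()
        doc.elements.append(Element(id="a"))
        assert "duplicate-id" in {v.rule_id for v in validate(doc)}

    def test_dangling_reference(self):
        doc = _single_glyph_doc()
        doc.reactions.append(
            Reaction(id="r", reactants=[Participant("ghost", Role.SUBSTRATE)],
                     products=[Participant("a", Role.PRODUCT)])
        )
        assert "dangling-ref" in {v.rule_id for v in validate(doc)}

    def test_complex_cycle(self):
        doc = Document()
        doc.elements.append(Element(id="x", parent_complex_ref="y"))
        doc.elements.append(Element(id="y", parent_complex_ref="x"))
        assert "complex-cycle" in {v.rule_id for v in validate(doc)}

    def test_empty_reaction(self):
        doc = _single_glyph_doc()
        doc.reactions.append(Reaction(id="r"))
        assert "empty-reaction" in {v.rule_id for v in validate(doc)}

    def test_bad_modifier_role(self):
        doc = _single_glyph_doc()
        doc.reactions.append(
            Reaction(
                id="r",
                reactants=[Participant("a", Role.SUBSTRATE)],
                products=[Participant("a", Role.PRODUCT)],
                modifiers=[Participant("a", Role.PRODUCT)],
            )
        )
        assert "bad-modifier-role" in {v.rule_id for v in validate(doc)}

    def test_species_glyph_missing_bbox(self):
        doc = _single_glyph_doc()
        doc.layouts[0].glyphs.append(Glyph(id="g_b", kind=GlyphKind.SPECIES, model_ref="a"))
        assert "missing-bbox" in {v.rule_id for v in validate(doc)}

    def test_containment_warning(self):
        doc = _single_glyph_doc()
        doc.elements.append(Element(id="b"))
        doc.layouts[0].glyphs.append(
            Glyph(id="g_b", kind=GlyphKind.SPECIES, model_ref="b",
                  bbox=bbox(500, 500, 40, 20), parent_glyph_ref="g_a")
        )
        found = [v for v in validate(doc) if v.rule_id == "containment"]
        assert len(found) == 1
        assert found[0].severity.value == "warning"


class TestDuplicateGroups:
    def test_two_glyphs_one_species(self):
        doc = _single_glyph_doc()
        doc.layouts[0].glyphs.append(
            Glyph(id="g_a2", kind=GlyphKind.SPECIES, model_ref="a", bbox=bbox(100, 10, 40, 20))
        )
        groups = duplicate_groups(doc, "l0")
        assert groups == [["g_a", "g_a2"]]

    def test_no_duplicates(self):
        assert duplicate_groups(_single_glyph_doc(), "l0") == []


class TestStyleResolution:
    def test_explicit_ref_wins(self):
        doc = _single_glyph_doc()
        doc.styles.append(Style(id="s1"))
        doc.styles.append(Style(id="s2", applies_to=Selector(glyph_ids=["g_a"])))
        g = doc.layouts[0].glyphs[0]
        g.style_ref = "s1"
        assert style_for_glyph(doc, g).id == "s1"

    def test_id_selector_beats_class_selector(self):
        doc = _single_glyph_doc()
        doc.styles.append(
            Style(id="cls", applies_to=Selector(element_classes=[ElementClass.UNSPECIFIED]))
        )
        doc.styles.append(Style(id="byid", applies_to=Selector(glyph_ids=["g_a"])))
        g = doc.layouts[0].glyphs[0]
        assert style_for_glyph(doc, g, ElementClass.UNSPECIFIED).id == "byid"

    def test_class_selector(self):
        doc = _single_glyph_doc()
        doc.styles.append(
            Style(id="cls", applies_to=Selector(element_classes=[ElementClass.MACROMOLECULE]))
        )
        g = doc.layouts[0].glyphs[0]
        assert style_for_glyph(doc, g, ElementClass.MACROMOLECULE).id == "cls"
        assert style_for_glyph(doc, g, ElementClass.COMPLEX) is None

    def test_no_style(self):
        doc = _single_glyph_doc()
        assert style_for_glyph(doc, doc.layouts[0].glyphs[0]) is None


class TestDocumentLookups:
    def test_lookup_and_keyerror(self):
        doc = _single_glyph_doc()
        assert doc.element("a").name == "A"
        with pytest.raises(KeyError):
            doc.element("zzz")

    def test_sample_points_cover_bbox_and_curve(self):
        g = Glyph(
            id="g",
            kind=GlyphKind.REACTION,
            bbox=bbox(0, 0, 10, 10),
            curve=[CurveSegment("line", Point(50, 50), Point(60, 70))],
        )
        pts = g.sample_points()
        xs = [p.x for p in pts]
        ys = [p.y for p in pts]
        assert min(xs) == 0 and max(xs) == 60
        assert min(ys) == 0 and max(ys) == 70
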