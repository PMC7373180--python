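import math

import pytest
from lxml import etree

from sbdiagram.celldesigner_io import (
    CD_NS,
    _axis_frame,
    read_celldesigner,
    species_counts,
    to_absolute,
    to_local,
    write_celldesigner,
)
from sbdiagram.model import (
    CurveSegment,
    ElementClass,
    GlyphKind,
    ModelError,
    Point,
    Role,
)

GEOM_TOL = 1e-6


def _roundtrip(doc):
    return read_celldesigner(write_celldesigner(doc))


def _species_boxes(layout):
    return sorted(
        (round(g.bbox.x, 6), round(g.bbox.y, 6), round(g.bbox.width, 6),
         round(g.bbox.height, 6))
        for g in layout.glyphs_of_kind(GlyphKind.SPECIES)
    )


class TestEditPointFrame:
    """The local frame used by reaction edit points: its own inverse is the
    oracle — to_local then to_absolute must reproduce any point exactly."""

    def test_inverse_pair(self):
        r, p = Point(100, 200), Point(400, 150)
        for pt in (Point(250, 175), Point(0, 0), Point(-30, 999), Point(123.456, -7.89)):
            local = to_local(pt, r, p)
            back = to_absolute(local, r, p)
            assert math.isclose(back.x, pt.x, abs_tol=1e-9)
            assert math.isclose(back.y, pt.y, abs_tol=1e-9)

    def test_endpoints_map_to_unit_interval(self):
        r, p = Point(0, 0), Point(10, 0)
        assert to_local(r, r, p) == Point(0, 0)
        lp = to_local(p, r, p)
        assert math.isclose(lp.x, 1.0) and math.isclose(lp.y, 0.0)

    def test_perpendicular_offset_is_v_axis(self):
        r, p = Point(0, 0), Point(10, 0)
        local = to_local(Point(5, -5), r, p)
        assert math.isclose(local.x, 0.5)
        assert math.isclose(abs(local.y), 0.5)

    def test_degenerate_frame(self):
        r = p = Point(5, 5)
        origin, u, v = _axis_frame(r, p)
        # frame stays finite and invertible even with coincident anchors
        assert all(map(math.isfinite, (u.x, u.y, v.x, v.y)))


class TestRoundTrip:
    def test_counts_preserved(self, toy_doc_normalized):
        back = _roundtrip(toy_doc_normalized)
        assert len(back.elements) == len(toy_doc_normalized.elements)
        assert len(back.reactions) == len(toy_doc_normalized.reactions)
        assert len(back.compartments) == len(toy_doc_normalized.compartments)

    def test_species_geometry_exact(self, toy_doc_normalized):
        back = _roundtrip(toy_doc_normalized)
        assert _species_boxes(back.layouts[0]) == _species_boxes(
            toy_doc_normalized.layouts[0]
        )

    def test_classes_survive(self, toy_doc_normalized):
        back = _roundtrip(toy_doc_normalized)
        for e in toy_doc_normalized.elements:
            # gene-like classes are CellDesigner-representable in the toy doc
            assert back.element(e.id).element_class == e.element_class

    def test_roles_and_modifiers_survive(self, toy_doc_normalized):
        back = _roundtrip(toy_doc_normalized)
        for r in toy_doc_normalized.reactions:
            rt = back.reaction(r.id)
            assert len(rt.reactants) == len(r.reactants)
            assert len(rt.products) == len(r.products)
            assert [m.role for m in rt.modifiers] == [m.role for m in r.modifiers]

    def test_duplicate_alias_count_preserved(self, toy_doc_normalized):
        n_before = len(toy_doc_normalized.layouts[0].glyphs_of_kind(GlyphKind.SPECIES))
        back = _roundtrip(toy_doc_normalized)
        assert len(back.layouts[0].glyphs_of_kind(GlyphKind.SPECIES)) == n_before

    def test_included_species_counts(self, toy_doc_normalized):
        counts = species_counts(_roundtrip(toy_doc_normalized))
        subunits = sum(
            1 for e in toy_doc_normalized.elements if e.parent_complex_ref is not None
        )
        assert counts["included"] == subunits
        assert counts["total"] == len(toy_doc_normalized.elements)
        assert counts["top_level"] + counts["included"] == counts["total"]

    def test_edit_points_survive(self, minimal):
        doc = minimal["one-reaction-two-species"]
        g = next(
            g for g in doc.layouts[0].glyphs if g.kind == GlyphKind.REACTION
        )
        start, end = g.curve[0].start, g.curve[0].end
        bend = Point((start.x + end.x) / 2, start.y - 40)
        g.curve = [CurveSegment("line", start, bend), CurveSegment("line", bend, end)]
        back = _roundtrip(doc)
        rg = next(
            g for g in back.layouts[0].glyphs if g.kind == GlyphKind.REACTION
        )
        pts = [rg.curve[0].start] + [s.end for s in rg.curve]
        assert any(
            abs(p.x - bend.x) < GEOM_TOL and abs(p.y - bend.y) < GEOM_TOL for p in pts
        )

    def test_second_round_trip_is_fixed_point(self, toy_doc_normalized):
        once = write_celldesigner(_roundtrip(toy_doc_normalized))
        twice = write_celldesigner(read_celldesigner(once))
        assert once == twice


class TestWireFormat:
    def test_level2_with_celldesigner_extension(self, toy_cd):
        root = etree.fromstring(toy_cd)
        assert root.get("level") == "2" and root.get("version") == "4"
        assert root.nsmap.get("celldesigner") == CD_NS

    def test_included_species_outside_core_list(self, toy_cd):
        root = etree.fromstring(toy_cd)
        core_ns = etree.QName(root).namespace
        core_species = {
            s.get("id") for s in root.findall(f".//{{{core_ns}}}species")
        }
        included = {
            s.get("id")
            for s in root.findall(f".//{{{CD_NS}}}listOfIncludedSpecies/{{{CD_NS}}}species")
        }
        assert included and not included & core_species

    def test_argb_colors(self, toy_cd):
        root = etree.fromstring(toy_cd)
        paints = root.findall(f".//{{{CD_NS}}}paint")
        assert paints
        for p in paints:
            color = p.get("color")
            assert len(color) == 8
            int(color, 16)

    def test_unmappable_class_warns_with_fallback(self, minimal):
        doc = minimal["one-species"]
        doc.elements[0].element_class = ElementClass.NUCLEIC_ACID_FEATURE
        messages = []
        data = write_celldesigner(doc, warn=messages.append)
        assert messages and "GENE" in messages[0]
        back = read_celldesigner(data)
        assert back.elements[0].element_class == ElementClass.GENE


class TestErrors:
    def test_parse_error(self):
        with pytest.raises(ModelError) as exc:
            read_celldesigner(b"nope")
        assert exc.value.code == "parse-error"

    def test_not_celldesigner(self):
        plain = (
            b'<sbml xmlns="http://www.sbml.org/sbml/level2/version4" '
            b'level="2" version="4"><model id="m"/></sbml>'
        )
        with pytest.raises(ModelError) as exc:
            read_celldesigner(plain)
        assert exc.value.code == "not-celldesigner"

    def test_no_layout(self, toy_doc_normalized):
        toy_doc_normalized.layouts.clear()
        with pytest.raises(ModelError) as exc:
            write_celldesigner(toy_doc_normalized)
        assert exc.value.code == "no-layout"
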