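import pytest
from lxml import etree

from sbdiagram import fixtures, normalize_geometry
from sbdiagram.model import (
    Document,
    ElementClass,
    GlyphKind,
    ModelError,
    ReactionClass,
    Role,
)
from sbdiagram.sbml_io import read_sbml, write_sbml

GEOM_TOL = 1e-6


def _roundtrip(doc):
    return read_sbml(write_sbml(doc))


def _glyph_boxes(layout):
    return sorted(
        (g.kind.value, round(g.bbox.x, 9), round(g.bbox.y, 9),
         round(g.bbox.width, 9), round(g.bbox.height, 9))
        for g in layout.glyphs
        if g.bbox is not None and g.kind != GlyphKind.TEXT
    )


class TestRoundTrip:
    def test_counts_preserved(self, toy_doc_normalized):
        back = _roundtrip(toy_doc_normalized)
        assert len(back.elements) == len(toy_doc_normalized.elements)
        assert len(back.reactions) == len(toy_doc_normalized.reactions)
        assert len(back.compartments) == len(toy_doc_normalized.compartments)
        assert len(back.layouts) == len(toy_doc_normalized.layouts)
        assert len(back.layouts[0].glyphs) == len(toy_doc_normalized.layouts[0].glyphs)

    def test_geometry_exact(self, toy_doc_normalized):
        back = _roundtrip(toy_doc_normalized)
        for orig, rt in zip(
            sorted(toy_doc_normalized.layouts[0].glyphs, key=lambda g: g.id),
            sorted(back.layouts[0].glyphs, key=lambda g: g.id),
        ):
            assert orig.id == rt.id
            if orig.bbox is not None:
                assert abs(orig.bbox.x - rt.bbox.x) < GEOM_TOL
                assert abs(orig.bbox.y - rt.bbox.y) < GEOM_TOL
                assert abs(orig.bbox.width - rt.bbox.width) < GEOM_TOL
                assert abs(orig.bbox.height - rt.bbox.height) < GEOM_TOL
            for so, sr in zip(orig.curve, rt.curve):
                assert so.kind == sr.kind
                for po, pr in ((so.start, sr.start), (so.end, sr.end)):
                    assert abs(po.x - pr.x) < GEOM_TOL and abs(po.y - pr.y) < GEOM_TOL

    def test_classes_survive_via_sbo(self, toy_doc_normalized):
        back = _roundtrip(toy_doc_normalized)
        for e in toy_doc_normalized.elements:
            assert back.element(e.id).element_class == e.element_class
        for r in toy_doc_normalized.reactions:
            assert back.reaction(r.id).reaction_class == r.reaction_class

    def test_roles_survive(self, toy_doc_normalized):
        back = _roundtrip(toy_doc_normalized)
        for r in toy_doc_normalized.reactions:
            rt = back.reaction(r.id)
            assert [p.role for p in rt.reactants] == [p.role for p in r.reactants]
            assert [p.role for p in rt.products] == [p.role for p in r.products]
            assert [p.role for p in rt.modifiers] == [p.role for p in r.modifiers]

    def test_modifications_survive(self, toy_doc_normalized):
        modified = [e for e in toy_doc_normalized.elements if e.modifications]
        assert modified
        back = _roundtrip(toy_doc_normalized)
        for e in modified:
            rt = back.element(e.id)
            assert [(m.residue_label, m.state) for m in rt.modifications] == [
                (m.residue_label, m.state) for m in e.modifications
            ]

    def test_complex_membership_survives(self, toy_doc_normalized):
        back = _roundtrip(toy_doc_normalized)
        for e in toy_doc_normalized.elements:
            assert back.element(e.id).parent_complex_ref == e.parent_complex_ref

    def test_multiple_layouts_survive(self, toy_doc_normalized):
        doc = toy_doc_normalized
        import copy

        second = copy.deepcopy(doc.layouts[0])
        second.id = "layout_alt"
        doc.layouts.append(second)
        back = _roundtrip(doc)
        assert [l.id for l in back.layouts] == ["layout_0", "layout_alt"]

    def test_styles_survive(self, toy_doc_normalized):
        back = _roundtrip(toy_doc_normalized)
        assert len(back.styles) == len(toy_doc_normalized.styles)
        orig_fills = sorted(s.fill.to_hex_rgba() for s in toy_doc_normalized.styles)
        back_fills = sorted(s.fill.to_hex_rgba() for s in back.styles)
        assert orig_fills == back_fills

    def test_second_round_trip_is_fixed_point(self, toy_doc_normalized):
        once = write_sbml(_roundtrip(toy_doc_normalized))
        twice = write_sbml(read_sbml(once))
        assert once == twice


class TestPassthrough:
    def test_notes_and_annotation_preserved(self, toy_doc_normalized):
        doc = toy_doc_normalized
        doc.add_passthrough(
            doc.elements[0].id,
            '<notes xmlns="http://www.sbml.org/sbml/level3/version1/core">'
            "<p>curated</p></notes>",
        )
        doc.add_passthrough(
            doc.elements[0].id, '<foreign xmlns="http://example.org/x" keep="1"/>'
        )
        data = write_sbml(doc)
        assert b"curated" in data
        back = read_sbml(data)
        frags = back.passthrough.get(doc.elements[0].id, [])
        assert any("curated" in f for f in frags)
        assert any("example.org/x" in f for f in frags)


class TestErrors:
    def test_parse_error(self):
        with pytest.raises(ModelError) as exc:
            read_sbml(b"this is not xml")
        assert exc.value.code == "parse-error"

    def test_not_sbml(self):
        with pytest.raises(ModelError) as exc:
            read_sbml(b"<root><child/></root>")
        assert exc.value.code == "invalid-sbml"

    def test_invalid_document_rejected_on_write(self, toy_doc_normalized):
        toy_doc_normalized.elements[0].id = toy_doc_normalized.elements[1].id
        with pytest.raises(ModelError) as exc:
            write_sbml(toy_doc_normalized)
        assert exc.value.code == "invalid-document"


class TestWireFormat:
    def test_level3_with_package_declarations(self, toy_sbml):
        root = etree.fromstring(toy_sbml)
        assert root.get("level") == "3"
        ns = {k or "_": v for k, v in root.nsmap.items()}
        assert "layout" in ns and "render" in ns

    def test_sbo_terms_on_species_and_reactions(self, toy_sbml):
        root = etree.fromstring(toy_sbml)
        core = "http://www.sbml.org/sbml/level3/version1/core"
        species = root.findall(f".//{{{core}}}species")
        assert species and all(s.get("sboTerm", "").startswith("SBO:") for s in species)
        reactions = root.findall(f".//{{{core}}}reaction")
        assert reactions and all(
            r.get("sboTerm", "").startswith("SBO:") for r in reactions
        )

    def test_reads_level2_core(self):
        l2 = b"""<?xml version="1.0"?>
        <sbml xmlns="http://www.sbml.org/sbml/level2/version4" level="2" version="4">
          <model id="m">
            <listOfCompartments><compartment id="c"/></listOfCompartments>
            <listOfSpecies>
              <species id="s1" compartment="c" name="P"/>
            </listOfSpecies>
            <listOfReactions>
              <reaction id="r1">
                <listOfReactants><speciesReference species="s1"/></listOfReactants>
                <listOfProducts><speciesReference species="s1"/></listOfProducts>
              </reaction>
            </listOfReactions>
          </model>
        </sbml>"""
        doc = read_sbml(l2)
        assert len(doc.elements) == 1 and len(doc.reactions) == 1
        assert doc.layouts == []
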