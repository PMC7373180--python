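import pytest
from lxml import etree

from sbdiagram import schemas
from sbdiagram.model import (
    ElementClass,
    GlyphKind,
    ModelError,
    ReactionClass,
    Role,
)
from sbdiagram.sbgnml_io import SBGN_NS, read_sbgnml, write_sbgnml

GEOM_TOL = 1e-6


def _roundtrip(doc):
    return read_sbgnml(write_sbgnml(doc))


def _entity_boxes(layout):
    return sorted(
        (round(g.bbox.x, 6), round(g.bbox.y, 6), round(g.bbox.width, 6),
         round(g.bbox.height, 6))
        for g in layout.glyphs_of_kind(GlyphKind.SPECIES)
    )


class TestRoundTrip:
    def test_glyph_counts_preserved(self, toy_doc_normalized):
        src = toy_doc_normalized.layouts[0]
        back = _roundtrip(toy_doc_normalized)
        dst = back.layouts[0]
        for kind in (GlyphKind.SPECIES, GlyphKind.COMPARTMENT, GlyphKind.REACTION):
            assert len(dst.glyphs_of_kind(kind)) == len(src.glyphs_of_kind(kind))

    def test_entity_geometry_exact(self, toy_doc_normalized):
        back = _roundtrip(toy_doc_normalized)
        assert _entity_boxes(back.layouts[0]) == _entity_boxes(
            toy_doc_normalized.layouts[0]
        )

    def test_classes_survive_up_to_pd_vocabulary(self, toy_doc_normalized):
        from sbdiagram import mapping

        back = _roundtrip(toy_doc_normalized)
        expected = sorted(
            mapping.element_to_sbgn(e.element_class)
            for e in toy_doc_normalized.elements
        )
        # SBGN has no per-element identity; compare the class multiset of
        # glyph-backed elements (clones add one entry per extra glyph)
        got = [mapping.element_to_sbgn(e.element_class) for e in back.elements]
        for cls in expected:
            assert cls in got
            got.remove(cls)

    def test_state_variables_survive(self, minimal):
        doc = minimal["modified-protein"]
        back = _roundtrip(doc)
        mods = back.elements[0].modifications
        assert [(m.residue_label, m.state) for m in mods] == [
            ("S45", "phosphorylated"),
            ("Y204", "phosphorylated"),
        ]

    def test_complex_nesting_survives(self, minimal):
        back = _roundtrip(minimal["complex-with-subunits"])
        complexes = [e for e in back.elements if e.element_class == ElementClass.COMPLEX]
        assert len(complexes) == 1
        subs = [e for e in back.elements if e.parent_complex_ref == complexes[0].id]
        assert len(subs) == 2
        sub_glyphs = [
            g for g in back.layouts[0].glyphs if g.parent_glyph_ref is not None
        ]
        assert len(sub_glyphs) == 2

    def test_second_round_trip_is_fixed_point(self, toy_doc_normalized):
        from sbdiagram.convert import normalize_geometry

        once = write_sbgnml(normalize_geometry(_roundtrip(toy_doc_normalized)))
        twice = write_sbgnml(normalize_geometry(read_sbgnml(once)))
        assert once == twice


class TestCloneMarkers:
    def test_duplicates_get_clone_markers(self, minimal):
        data = write_sbgnml(minimal["duplicate-pair"])
        root = etree.fromstring(data)
        clones = root.findall(f".//{{{SBGN_NS}}}clone")
        assert len(clones) == 2

    def test_clones_become_distinct_elements(self, minimal):
        back = _roundtrip(minimal["duplicate-pair"])
        assert len(back.elements) == 2
        assert all(
            g.cloned for g in back.layouts[0].glyphs_of_kind(GlyphKind.SPECIES)
        )


class TestStrictness:
    def _influence_doc(self, minimal):
        doc = minimal["one-reaction-two-species"]
        doc.reactions[0].reaction_class = ReactionClass.POSITIVE_INFLUENCE
        return doc

    def test_strict_rejects_influence(self, minimal):
        with pytest.raises(ModelError) as exc:
            write_sbgnml(self._influence_doc(minimal), strict=True)
        assert exc.value.code == "unmappable-reaction"

    def test_lenient_emits_plain_arc_and_warns(self, minimal):
        messages = []
        data = write_sbgnml(
            self._influence_doc(minimal), strict=False, warn=messages.append
        )
        assert messages
        root = etree.fromstring(data)
        arcs = root.findall(f".//{{{SBGN_NS}}}arc")
        assert [a.get("class") for a in arcs] == ["stimulation"]
        assert schemas.validation_errors(data, "sbgnml") == []

    def test_phenotype_in_complex_rejected(self, minimal):
        doc = minimal["complex-with-subunits"]
        doc.elements[1].element_class = ElementClass.PHENOTYPE
        with pytest.raises(ModelError) as exc:
            write_sbgnml(doc)
        assert exc.value.code == "unmappable-class"


class TestWireFormat:
    def test_processes_have_ports(self, toy_sbgn):
        root = etree.fromstring(toy_sbgn)
        procs = [
            g
            for g in root.findall(f".//{{{SBGN_NS}}}glyph")
            if g.get("class") in ("process", "omitted process", "uncertain process",
                                  "association", "dissociation")
        ]
        assert procs
        for p in procs:
            assert len(p.findall(f"{{{SBGN_NS}}}port")) == 2

    def test_consumption_production_directions(self, minimal):
        data = write_sbgnml(minimal["one-reaction-two-species"])
        root = etree.fromstring(data)
        arcs = {a.get("class"): a for a in root.findall(f".//{{{SBGN_NS}}}arc")}
        assert set(arcs) == {"consumption", "production"}
        assert arcs["consumption"].get("target", "").endswith(".in")
        assert arcs["production"].get("source", "").endswith(".out")

    def test_schema_valid(self, toy_sbgn):
        assert schemas.validation_errors(toy_sbgn, "sbgnml") == []

    def test_reads_other_minor_versions(self, toy_sbgn):
        for version in ("0.1", "0.3"):
            data = toy_sbgn.replace(
                b"http://sbgn.org/libsbgn/0.2",
                f"http://sbgn.org/libsbgn/{version}".encode(),
            )
            doc = read_sbgnml(data)
            assert doc.elements


class TestErrors:
    def test_parse_error(self):
        with pytest.raises(ModelError) as exc:
            read_sbgnml(b"not xml")
        assert exc.value.code == "parse-error"

    def test_not_sbgnml(self):
        with pytest.raises(ModelError) as exc:
            read_sbgnml(b'<x xmlns="http://example.org/other"/>')
        assert exc.value.code == "not-sbgnml"

    def test_unsupported_sublanguage(self, toy_sbgn):
        data = toy_sbgn.replace(b"process description", b"entity relationship")
        with pytest.raises(ModelError) as exc:
            read_sbgnml(data)
        assert exc.value.code == "unsupported-sublanguage"

    def test_no_layout(self, toy_doc_normalized):
        toy_doc_normalized.layouts.clear()
        with pytest.raises(ModelError) as exc:
            write_sbgnml(toy_doc_normalized)
        assert exc.value.code == "no-layout"
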