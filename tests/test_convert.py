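import copy
import itertools

import pytest

from sbdiagram import fixtures, normalize_geometry
from sbdiagram.convert import (
    ConversionReport,
    convert,
    detect_format,
    read_document,
    write_document,
)
from sbdiagram.model import GlyphKind, ModelError, validate

GEOM_TOL = 1e-6


class TestDetectFormat:
    def test_all_three(self, toy_sbml, toy_cd, toy_sbgn):
        assert detect_format(toy_sbml) == "sbml"
        assert detect_format(toy_cd) == "celldesigner"
        assert detect_format(toy_sbgn) == "sbgnml"

    def test_celldesigner_wins_over_plain_sbml(self, toy_cd):
        # a CellDesigner file is SBML too; the more specific reader must win
        doc = read_document(toy_cd, source="auto")
        assert doc.source_format == "celldesigner"

    def test_not_xml(self):
        with pytest.raises(ModelError) as exc:
            detect_format(b"hello")
        assert exc.value.code == "unknown-format"

    def test_unrelated_xml(self):
        with pytest.raises(ModelError) as exc:
            detect_format(b'<doc xmlns="http://example.org/z"/>')
        assert exc.value.code == "unknown-format"


class TestAllDirections:
    @pytest.mark.parametrize(
        "source,target",
        list(itertools.permutations(["sbml", "celldesigner", "sbgnml"], 2)),
    )
    def test_conversion_preserves_counts_and_geometry(
        self, source, target, toy_doc_normalized
    ):
        src_bytes = write_document(toy_doc_normalized, source)
        out, report = convert(src_bytes, target=target, source=source)
        src_doc = read_document(src_bytes)
        dst_doc = read_document(out)

        src_layout, dst_layout = src_doc.layouts[0], dst_doc.layouts[0]
        for kind in (GlyphKind.SPECIES, GlyphKind.COMPARTMENT, GlyphKind.REACTION):
            assert len(dst_layout.glyphs_of_kind(kind)) == len(
                src_layout.glyphs_of_kind(kind)
            ), kind

        def boxes(layout, kind):
            return sorted(
                (round(g.bbox.x, 6), round(g.bbox.y, 6),
                 round(g.bbox.width, 6), round(g.bbox.height, 6))
                for g in layout.glyphs_of_kind(kind)
                if g.bbox is not None
            )

        for a, b in zip(
            boxes(src_layout, GlyphKind.SPECIES), boxes(dst_layout, GlyphKind.SPECIES)
        ):
            assert all(abs(x - y) < GEOM_TOL for x, y in zip(a, b))

        assert validate(dst_doc) == []

    @pytest.mark.parametrize("fmt", ["sbml", "celldesigner", "sbgnml"])
    def test_identity_conversion_canonicalizes(self, fmt, toy_doc_normalized):
        src = write_document(toy_doc_normalized, fmt)
        once, _ = convert(src, target=fmt, source=fmt)
        twice, _ = convert(once, target=fmt, source=fmt)
        assert once == twice


class TestLossWarnings:
    def test_layouts_dropped_exactly_once(self, toy_doc_normalized):
        doc = toy_doc_normalized
        extra = copy.deepcopy(doc.layouts[0])
        extra.id = "layout_alt"
        doc.layouts.append(extra)
        data = write_document(doc, "sbml")
        for target in ("celldesigner", "sbgnml"):
            _, report = convert(data, target=target)
            assert report.rules().count("layouts-dropped") == 1

    def test_no_layout_warning_when_single_layout(self, toy_sbml):
        _, report = convert(toy_sbml, target="sbgnml")
        assert "layouts-dropped" not in report.rules()

    def test_label_positions_dropped_only_for_celldesigner(self, toy_sbml):
        _, report = convert(toy_sbml, target="celldesigner")
        assert report.rules().count("label-positions-dropped") == 1

    def test_duplicate_identity_lost_only_for_sbgnml(self, toy_sbml):
        _, report = convert(toy_sbml, target="sbgnml")
        assert report.rules().count("duplicate-identity-lost") == 1
        _, report = convert(toy_sbml, target="celldesigner")
        assert "duplicate-identity-lost" not in report.rules()

    def test_no_duplicate_warning_without_duplicates(self, minimal):
        data = write_document(
            normalize_geometry(minimal["one-reaction-two-species"]), "sbml"
        )
        _, report = convert(data, target="sbgnml")
        assert "duplicate-identity-lost" not in report.rules()

    def test_report_json_lines(self, toy_sbml):
        _, report = convert(toy_sbml, target="sbgnml")
        import json

        lines = report.to_json_lines().splitlines()
        assert lines
        for line in lines:
            rec = json.loads(line)
            assert set(rec) == {"rule_id", "severity", "object_id", "message"}


class TestNormalizeGeometry:
    def test_idempotent(self, toy_doc):
        once = normalize_geometry(copy.deepcopy(toy_doc))
        twice = normalize_geometry(copy.deepcopy(once))
        a = write_document(once, "sbml")
        b = write_document(twice, "sbml")
        assert a == b

    def test_synthesizes_reaction_curves(self, minimal):
        doc = minimal["one-reaction-two-species"]
        rg = next(g for g in doc.layouts[0].glyphs if g.kind == GlyphKind.REACTION)
        rg.curve = []
        normalize_geometry(doc)
        assert rg.curve and rg.curve[0].kind == "line"

    def test_synthesizes_labels(self, minimal):
        doc = minimal["one-species"]
        assert not doc.layouts[0].glyphs_of_kind(GlyphKind.TEXT)
        normalize_geometry(doc)
        texts = doc.layouts[0].glyphs_of_kind(GlyphKind.TEXT)
        assert len(texts) == 1
        assert texts[0].text == doc.elements[0].name

    def test_translates_negative_coordinates(self, minimal):
        from sbdiagram.model import bbox

        doc = minimal["one-species"]
        doc.layouts[0].glyphs[0].bbox = bbox(-50, -20, 100, 50)
        normalize_geometry(doc)
        b = doc.layouts[0].glyphs[0].bbox
        assert b.x >= 0 and b.y >= 0
        assert (b.width, b.height) == (100, 50)


class TestConvertErrors:
    def test_unknown_target(self, toy_sbml):
        with pytest.raises(ModelError) as exc:
            convert(toy_sbml, target="dot")
        assert exc.value.code == "unknown-format"

    def test_no_layout_for_layout_requiring_target(self):
        plain = (
            b'<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core" '
            b'level="3" version="1"><model id="m"><listOfCompartments>'
            b'<compartment id="c" constant="true"/></listOfCompartments>'
            b"</model></sbml>"
        )
        with pytest.raises(ModelError) as exc:
            convert(plain, target="sbgnml")
        assert exc.value.code == "no-layout"
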