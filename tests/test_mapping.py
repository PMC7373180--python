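import pytest

from sbdiagram import mapping
from sbdiagram.model import ElementClass, ModelError, ReactionClass, Role


class TestElementClassSbo:
    def test_every_class_has_an_sbo_term(self):
        for cls in ElementClass:
            term = mapping.class_to_sbo(cls)
            assert term.startswith("SBO:") and len(term) == 11

    def test_sbo_round_trip(self):
        for cls in ElementClass:
            assert mapping.sbo_to_class(mapping.class_to_sbo(cls)) == cls

    def test_unknown_sbo_is_none(self):
        assert mapping.sbo_to_class("SBO:9999999") is None


class TestElementSbgn:
    def test_direct_classes_round_trip(self):
        for cls in (
            ElementClass.MACROMOLECULE,
            ElementClass.SIMPLE_CHEMICAL,
            ElementClass.NUCLEIC_ACID_FEATURE,
            ElementClass.COMPLEX,
            ElementClass.PHENOTYPE,
            ElementClass.UNSPECIFIED,
            ElementClass.SOURCE_SINK,
        ):
            label = mapping.element_to_sbgn(cls)
            back_cls, back_sbo = mapping.sbgn_to_element(label)
            assert back_cls == cls
            assert back_sbo == mapping.class_to_sbo(cls)

    def test_fallbacks_are_deterministic(self):
        assert mapping.element_to_sbgn(ElementClass.GENE) == "nucleic acid feature"
        assert mapping.element_to_sbgn(ElementClass.RNA) == "nucleic acid feature"
        assert mapping.element_to_sbgn(ElementClass.RECEPTOR) == "macromolecule"
        assert mapping.element_to_sbgn(ElementClass.ION) == "simple chemical"

    def test_sbo_term_overrides_class(self):
        # a recognized SBO term is more specific than the class enum
        assert (
            mapping.element_to_sbgn(
                ElementClass.UNSPECIFIED, mapping.class_to_sbo(ElementClass.COMPLEX)
            )
            == "complex"
        )

    def test_process_class_rejected_as_entity(self):
        with pytest.raises(ModelError) as exc:
            mapping.sbgn_to_element("process")
        assert exc.value.code == "not-an-entity"


class TestCellDesigner:
    def test_species_type_round_trip(self):
        for cls, cd in [
            (ElementClass.MACROMOLECULE, "PROTEIN"),
            (ElementClass.SIMPLE_CHEMICAL, "SIMPLE_MOLECULE"),
            (ElementClass.GENE, "GENE"),
            (ElementClass.RNA, "RNA"),
            (ElementClass.RECEPTOR, "RECEPTOR"),
            (ElementClass.ION, "ION"),
            (ElementClass.PHENOTYPE, "PHENOTYPE"),
            (ElementClass.COMPLEX, "COMPLEX"),
            (ElementClass.UNSPECIFIED, "UNKNOWN"),
        ]:
            assert mapping.class_to_celldesigner(cls) == cd
            assert mapping.celldesigner_type_to_class(cd) == cls

    def test_alias_types_read(self):
        assert mapping.celldesigner_type_to_class("ANTISENSE_RNA") == ElementClass.RNA
        assert mapping.celldesigner_type_to_class("DRUG") == ElementClass.SIMPLE_CHEMICAL
        assert (
            mapping.celldesigner_type_to_class("TRUNCATED") == ElementClass.MACROMOLECULE
        )

    def test_unknown_type_maps_to_unspecified(self):
        assert mapping.celldesigner_type_to_class("NO_SUCH") == ElementClass.UNSPECIFIED

    def test_class_without_cd_equivalent(self):
        # the writer substitutes GENE (and warns); the table itself has no row
        assert mapping.class_to_celldesigner(ElementClass.NUCLEIC_ACID_FEATURE) == "UNKNOWN"

    def test_modification_types(self):
        assert (
            mapping.role_to_celldesigner_modification(Role.INHIBITOR, None) == "INHIBITION"
        )
        assert (
            mapping.role_to_celldesigner_modification(Role.MODIFIER, "catalysis")
            == "CATALYSIS"
        )


class TestReactions:
    def test_reaction_sbo_round_trip(self):
        for cls in ReactionClass:
            term = mapping.reaction_class_to_sbo(cls)
            assert mapping.sbo_to_reaction_class(term) == cls

    def test_process_round_trip(self):
        for cls in (
            ReactionClass.STATE_TRANSITION,
            ReactionClass.KNOWN_TRANSITION_OMITTED,
            ReactionClass.UNKNOWN_TRANSITION,
            ReactionClass.ASSOCIATION,
            ReactionClass.DISSOCIATION,
        ):
            proc = mapping.reaction_to_sbgn_process(cls)
            assert proc in mapping.PROCESS_CLASSES
            assert mapping.sbgn_process_to_reaction(proc) == cls

    def test_influences_have_no_process(self):
        assert mapping.reaction_to_sbgn_process(ReactionClass.POSITIVE_INFLUENCE) is None
        assert mapping.reaction_to_sbgn_process(ReactionClass.NEGATIVE_INFLUENCE) is None


class TestArcs:
    def test_role_arcs_round_trip(self):
        for role, arc in [
            (Role.SUBSTRATE, "consumption"),
            (Role.PRODUCT, "production"),
            (Role.ACTIVATOR, "stimulation"),
            (Role.INHIBITOR, "inhibition"),
            (Role.MODIFIER, "modulation"),
        ]:
            assert mapping.role_to_arc(role, None) == arc
            assert mapping.arc_to_role(arc)[0] == role

    def test_catalysis_arc(self):
        assert mapping.role_to_arc(Role.MODIFIER, "catalysis") == "catalysis"
        assert mapping.role_to_arc(Role.ACTIVATOR, "catalysis") == "catalysis"
        role, kind = mapping.arc_to_role("catalysis")
        assert role == Role.ACTIVATOR and kind == "catalysis"

    def test_side_roles_share_arcs(self):
        assert mapping.role_to_arc(Role.SIDE_SUBSTRATE, None) == "consumption"
        assert mapping.role_to_arc(Role.SIDE_PRODUCT, None) == "production"


class TestTableIntegrity:
    def test_sbo_terms_unique_per_kind(self):
        element_terms = [mapping.class_to_sbo(c) for c in ElementClass]
        assert len(set(element_terms)) == len(element_terms)
        reaction_terms = [mapping.reaction_class_to_sbo(c) for c in ReactionClass]
        assert len(set(reaction_terms)) == len(reaction_terms)

    def test_no_sbo_collision_between_kinds(self):
        element_terms = {mapping.class_to_sbo(c) for c in ElementClass}
        reaction_terms = {mapping.reaction_class_to_sbo(c) for c in ReactionClass}
        assert not element_terms & reaction_terms
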