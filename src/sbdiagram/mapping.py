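"""Table-driven translation between the vocabularies of the three notations.

SBML carries semantics as SBO terms, SBGN-ML as glyph/arc class strings,
CellDesigner as its own type strings.  All lookups below run over a single
declarative table (``data/class_map.tsv``) shipped with the package, so the
community mapping of SBO terms to SBGN notation can be revised without code
changes.  Every lookup is pure and total: unknown inputs fall back to the
"unspecified" row and are reported through the optional ``warn`` callback
rather than raised.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Callable, Optional

from .model import ElementClass, ModelError, ReactionClass, Role

WarnFn = Optional[Callable[[str], None]]


@dataclass(frozen=True)
class MappingRow:
    kind: str  # element | reaction | role
    internal: str
    sbo: Optional[str]
    sbgn: Optional[str]
    celldesigner: Optional[str]


def _load_table() -> list[MappingRow]:
    text = resources.files("sbdiagram.data").joinpath("class_map.tsv").read_text()
    rows: list[MappingRow] = []
    for rec in csv.reader(
        (l for l in text.splitlines() if l.strip() and not l.startswith("#")),
        delimiter="\t",
    ):
        kind, internal, sbo, sbgn, cd = (c.strip() for c in rec)
        rows.append(
            MappingRow(
                kind,
                internal,
                None if sbo == "-" else sbo,
                None if sbgn == "-" else sbgn,
                None if cd == "-" else cd,
            )
        )
    # reverse-lookup determinism: each non-empty cell appears at most once per kind
    for col in ("sbo", "sbgn", "celldesigner"):
        for kind in ("element", "reaction", "role"):
            cells = [getattr(r, col) for r in rows if r.kind == kind and getattr(r, col)]
            assert len(cells) == len(set(cells)), f"ambiguous {col} cell in {kind} table"
    return rows


TABLE: list[MappingRow] = _load_table()

_ELEMENT_ROWS = {r.internal: r for r in TABLE if r.kind == "element"}
_REACTION_ROWS = {r.internal: r for r in TABLE if r.kind == "reaction"}
_ROLE_ROWS = {r.internal: r for r in TABLE if r.kind == "role"}

#: classes with no PD glyph class of their own render as the closest PD class
#: (the finer class survives via the SBO term / CellDesigner type string)
SBGN_FALLBACK_ELEMENT: dict[ElementClass, str] = {
    ElementClass.GENE: "nucleic acid feature",
    ElementClass.RNA: "nucleic acid feature",
    ElementClass.RECEPTOR: "macromolecule",
    ElementClass.ION: "simple chemical",
}
SBGN_FALLBACK_REACTION: dict[ReactionClass, str] = {
    ReactionClass.TRANSPORT: "process",
    ReactionClass.UNKNOWN: "uncertain process",
}

#: PD arc classes that a modifier link may use when the source format
#: distinguishes catalysis from plain stimulation
CATALYSIS_ARC = "catalysis"

#: SBML layout package speciesReferenceGlyph role attribute values
SBML_ROLE = {
    Role.SUBSTRATE: "substrate",
    Role.SIDE_SUBSTRATE: "sidesubstrate",
    Role.PRODUCT: "product",
    Role.SIDE_PRODUCT: "sideproduct",
    Role.MODIFIER: "modifier",
    Role.ACTIVATOR: "activator",
    Role.INHIBITOR: "inhibitor",
    Role.UNDEFINED: "undefined",
}
SBML_ROLE_INV = {v: k for k, v in SBML_ROLE.items()}


# ---------------------------------------------------------------------------
# element classes
# ---------------------------------------------------------------------------


def class_to_sbo(element_class: ElementClass) -> str:
    row = _ELEMENT_ROWS[element_class.value]
    assert row.sbo is not None
    return row.sbo


def sbo_to_class(sbo_term: str) -> Optional[ElementClass]:
    for row in _ELEMENT_ROWS.values():
        if row.sbo == sbo_term:
            return ElementClass(row.internal)
    return None


def element_to_sbgn(
    element_class: ElementClass, sbo_term: Optional[str] = None, warn: WarnFn = None
) -> str:
    """PD glyph class for an element.

    A recognized SBO term is more specific than the (possibly defaulted)
    class enum and wins; anything unmappable falls back to
    "unspecified entity".
    """
    if sbo_term:
        from_sbo = sbo_to_class(sbo_term)
        if from_sbo is not None:
            element_class = from_sbo
    row = _ELEMENT_ROWS.get(element_class.value)
    if row is not None and row.sbgn is not None:
        return row.sbgn
    if element_class in SBGN_FALLBACK_ELEMENT:
        return SBGN_FALLBACK_ELEMENT[element_class]
    if warn:
        warn(f"element class {element_class.value!r} has no PD glyph class; using fallback")
    return "unspecified entity"


def sbgn_to_element(sbgn_class: str) -> tuple[ElementClass, str]:
    """Inverse lookup: PD entity-pool class -> (internal class, SBO term)."""
    for row in _ELEMENT_ROWS.values():
        if row.sbgn == sbgn_class:
            cls = ElementClass(row.internal)
            return cls, row.sbo or ""
    raise ModelError("not-an-entity", f"{sbgn_class!r} is not a PD entity-pool class")


def is_entity_class(sbgn_class: str) -> bool:
    return any(row.sbgn == sbgn_class for row in _ELEMENT_ROWS.values())


# ---------------------------------------------------------------------------
# CellDesigner type strings
# ---------------------------------------------------------------------------

#: CellDesigner species classes beyond the canonical table rows
_CD_SPECIES_ALIASES = {
    "ANTISENSE_RNA": ElementClass.RNA,
    "TRUNCATED": ElementClass.MACROMOLECULE,
    "DRUG": ElementClass.SIMPLE_CHEMICAL,
}


def celldesigner_type_to_class(type_string: str, warn: WarnFn = None) -> ElementClass:
    """Internal class for a CellDesigner speciesIdentity class string."""
    t = (type_string or "").strip().upper()
    for row in _ELEMENT_ROWS.values():
        if row.celldesigner == t:
            return ElementClass(row.internal)
    if t in _CD_SPECIES_ALIASES:
        return _CD_SPECIES_ALIASES[t]
    if warn:
        warn(f"unknown CellDesigner species type {type_string!r}; treating as unspecified")
    return ElementClass.UNSPECIFIED


def class_to_celldesigner(element_class: ElementClass) -> str:
    row = _ELEMENT_ROWS[element_class.value]
    return row.celldesigner or "UNKNOWN"


#: reaction types CellDesigner distinguishes that the internal enum folds
_CD_REACTION_ALIASES = {
    "TRANSCRIPTION": ReactionClass.STATE_TRANSITION,
    "TRANSLATION": ReactionClass.STATE_TRANSITION,
    "TRUNCATION": ReactionClass.STATE_TRANSITION,
    "TRANSPORTATION": ReactionClass.TRANSPORT,
    "REDUCED_MODULATION": ReactionClass.POSITIVE_INFLUENCE,
    "REDUCED_PHYSICAL_STIMULATION": ReactionClass.POSITIVE_INFLUENCE,
    "REDUCED_TRIGGER": ReactionClass.POSITIVE_INFLUENCE,
}


def celldesigner_reaction_type_to_class(type_string: str, warn: WarnFn = None) -> ReactionClass:
    t = (type_string or "").strip().upper()
    for row in _REACTION_ROWS.values():
        if row.celldesigner == t:
            return ReactionClass(row.internal)
    if t in _CD_REACTION_ALIASES:
        return _CD_REACTION_ALIASES[t]
    if warn:
        warn(f"unknown CellDesigner reaction type {type_string!r}; treating as state transition")
    return ReactionClass.STATE_TRANSITION


def reaction_class_to_celldesigner(reaction_class: ReactionClass) -> str:
    row = _REACTION_ROWS[reaction_class.value]
    return row.celldesigner or "STATE_TRANSITION"


#: CellDesigner reaction-modification type -> (role, modifier_kind)
CD_MODIFICATION_TYPE = {
    "CATALYSIS": (Role.ACTIVATOR, "catalysis"),
    "UNKNOWN_CATALYSIS": (Role.ACTIVATOR, "catalysis"),
    "INHIBITION": (Role.INHIBITOR, None),
    "UNKNOWN_INHIBITION": (Role.INHIBITOR, None),
    "PHYSICAL_STIMULATION": (Role.ACTIVATOR, None),
    "TRIGGER": (Role.ACTIVATOR, None),
    "MODULATION": (Role.MODIFIER, None),
}


def role_to_celldesigner_modification(role: Role, modifier_kind: Optional[str]) -> str:
    if modifier_kind == "catalysis":
        return "CATALYSIS"
    return {
        Role.INHIBITOR: "INHIBITION",
        Role.ACTIVATOR: "PHYSICAL_STIMULATION",
    }.get(role, "MODULATION")


# ---------------------------------------------------------------------------
# reactions <-> SBO / SBGN process classes
# ---------------------------------------------------------------------------


def reaction_class_to_sbo(reaction_class: ReactionClass) -> str:
    row = _REACTION_ROWS[reaction_class.value]
    assert row.sbo is not None
    return row.sbo


def sbo_to_reaction_class(sbo_term: str) -> Optional[ReactionClass]:
    for row in _REACTION_ROWS.values():
        if row.sbo == sbo_term:
            return ReactionClass(row.internal)
    return None


def reaction_to_sbgn_process(reaction_class: ReactionClass) -> Optional[str]:
    """PD process-node class, or None when PD cannot express the reaction
    (activity-flow-style influences)."""
    row = _REACTION_ROWS[reaction_class.value]
    if row.sbgn is not None:
        return row.sbgn
    return SBGN_FALLBACK_REACTION.get(reaction_class)


def sbgn_process_to_reaction(sbgn_class: str) -> Optional[ReactionClass]:
    for row in _REACTION_ROWS.values():
        if row.sbgn == sbgn_class:
            return ReactionClass(row.internal)
    return None


PROCESS_CLASSES = frozenset(
    r.sbgn for r in _REACTION_ROWS.values() if r.sbgn is not None
)


# ---------------------------------------------------------------------------
# roles <-> SBGN arc classes
# ---------------------------------------------------------------------------


def role_to_arc(role: Role, modifier_kind: Optional[str] = None, warn: WarnFn = None) -> str:
    """PD arc class for a participant role.

    Substrate-like roles consume, product-like roles produce; a modifier
    flagged as catalytic gets the dedicated catalysis arc.  The undefined
    role has no PD arc and falls back to modulation.
    """
    if modifier_kind == "catalysis" and role in (Role.MODIFIER, Role.ACTIVATOR):
        return CATALYSIS_ARC
    if role in (Role.SUBSTRATE, Role.SIDE_SUBSTRATE):
        return "consumption"
    if role in (Role.PRODUCT, Role.SIDE_PRODUCT):
        return "production"
    row = _ROLE_ROWS[role.value]
    if row.sbgn is not None:
        return row.sbgn
    if warn:
        warn(f"role {role.value!r} has no PD arc class; using modulation")
    return "modulation"


def arc_to_role(arc_class: str) -> tuple[Role, Optional[str]]:
    """Inverse: PD arc class -> (role, modifier_kind)."""
    if arc_class == CATALYSIS_ARC:
        return Role.ACTIVATOR, "catalysis"
    if arc_class == "necessary stimulation":
        return Role.ACTIVATOR, "necessary-stimulation"
    for row in _ROLE_ROWS.values():
        if row.sbgn == arc_class:
            return Role(row.internal), None
    raise ModelError("unknown-arc", f"unknown PD arc class {arc_class!r}")


ARC_CLASSES = frozenset(
    {CATALYSIS_ARC, "necessary stimulation"}
    | {r.sbgn for r in _ROLE_ROWS.values() if r.sbgn is not None}
)
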