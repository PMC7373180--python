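"""Internal superset model for layout-aware molecular-network diagrams.

The three interchange notations handled by this package (SBML with the
layout/render packages, CellDesigner's SBML extension, SBGN-ML Process
Description) describe overlapping but not identical information.  The types
here form a superset of all three, so that any document can be read into
memory without loss and re-serialized to any of the notations, with loss
reported explicitly rather than silently.

Coordinate convention (shared by all three formats and applied throughout
the package): top-left origin, y grows downward, dimensionless "diagram
points".

Structure and geometry are kept in separate layers.  ``Element`` /
``Compartment`` / ``Reaction`` describe the network itself — a hypergraph
whose reactions connect arbitrarily many participants.  ``Glyph`` objects
inside a ``Layout`` describe where things are drawn; a species may own
several glyphs (node duplication), and a document may carry several layouts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional
import math


class ElementClass(str, Enum):
    MACROMOLECULE = "macromolecule"
    SIMPLE_CHEMICAL = "simple-chemical"
    NUCLEIC_ACID_FEATURE = "nucleic-acid-feature"
    GENE = "gene"
    RNA = "rna"
    RECEPTOR = "receptor"
    ION = "ion"
    PHENOTYPE = "phenotype"
    COMPLEX = "complex"
    UNSPECIFIED = "unspecified"
    SOURCE_SINK = "source-sink"


class ReactionClass(str, Enum):
    STATE_TRANSITION = "state-transition"
    TRANSPORT = "transport"
    KNOWN_TRANSITION_OMITTED = "known-transition-omitted"
    UNKNOWN_TRANSITION = "unknown-transition"
    ASSOCIATION = "association"
    DISSOCIATION = "dissociation"
    POSITIVE_INFLUENCE = "positive-influence"
    NEGATIVE_INFLUENCE = "negative-influence"
    UNKNOWN = "unknown"


class Role(str, Enum):
    SUBSTRATE = "substrate"
    SIDE_SUBSTRATE = "side-substrate"
    PRODUCT = "product"
    SIDE_PRODUCT = "side-product"
    MODIFIER = "modifier"
    ACTIVATOR = "activator"
    INHIBITOR = "inhibitor"
    UNDEFINED = "undefined"


#: roles a Participant in a reaction's modifier list may carry
MODIFIER_ROLES = frozenset({Role.MODIFIER, Role.ACTIVATOR, Role.INHIBITOR})


class GlyphKind(str, Enum):
    SPECIES = "species"
    COMPARTMENT = "compartment"
    REACTION = "reaction"
    TEXT = "text"


class Severity(str, Enum):
    ERROR = "error"
    WARNING = "warning"


@dataclass(frozen=True)
class Point:
    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite point ({self.x}, {self.y})")


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box: top-left origin plus non-negative dimensions."""

    origin: Point
    width: float
    height: float

    def __post_init__(self) -> None:
        if self.width < 0 or self.height < 0:
            raise ValueError("bounding box with negative dimensions")

    @property
    def x(self) -> float:
        return self.origin.x

    @property
    def y(self) -> float:
        return self.origin.y

    @property
    def center(self) -> Point:
        return Point(self.x + self.width / 2.0, self.y + self.height / 2.0)

    def contains(self, other: "BoundingBox") -> bool:
        return (
            other.x >= self.x
            and other.y >= self.y
            and other.x + other.width <= self.x + self.width
            and other.y + other.height <= self.y + self.height
        )


def bbox(x: float, y: float, w: float, h: float) -> BoundingBox:
    """Shorthand constructor used pervasively by the I/O modules."""
    return BoundingBox(Point(x, y), w, h)


@dataclass(frozen=True)
class ColorRGBA:
    r: int
    g: int
    b: int
    a: int = 255

    def __post_init__(self) -> None:
        for channel in (self.r, self.g, self.b, self.a):
            if not 0 <= channel <= 255:
                raise ValueError(f"color channel {channel} out of [0, 255]")

    def to_hex_rgba(self) -> str:
        return f"#{self.r:02X}{self.g:02X}{self.b:02X}{self.a:02X}"

    def to_hex_rgb(self) -> str:
        return f"#{self.r:02X}{self.g:02X}{self.b:02X}"

    def to_argb_hex(self) -> str:
        """CellDesigner stores colors as 8 hex digits, alpha first."""
        return f"{self.a:02x}{self.r:02x}{self.g:02x}{self.b:02x}"

    @classmethod
    def from_argb_hex(cls, s: str) -> "ColorRGBA":
        s = s.strip().lstrip("#")
        if len(s) == 6:
            s = "ff" + s
        if len(s) != 8:
            raise ValueError(f"bad ARGB color string {s!r}")
        a, r, g, b = (int(s[i : i + 2], 16) for i in range(0, 8, 2))
        return cls(r, g, b, a)

    @classmethod
    def from_hex(cls, s: str) -> "ColorRGBA":
        """Parse #RGB / #RRGGBB / #RRGGBBAA (render-package style)."""
        s = s.strip().lstrip("#")
        if len(s) == 3:
            s = "".join(c * 2 for c in s)
        if len(s) == 6:
            s += "ff"
        if len(s) != 8:
            raise ValueError(f"bad RGBA color string {s!r}")
        r, g, b, a = (int(s[i : i + 2], 16) for i in range(0, 8, 2))
        return cls(r, g, b, a)


@dataclass(frozen=True)
class FontSpec:
    family: str = "sans-serif"
    size: float = 11.0
    weight: str = "normal"  # normal | bold
    slant: str = "normal"  # normal | italic

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError("font size must be positive")


@dataclass(frozen=True)
class ModificationState:
    """A residue-level state, e.g. a phosphorylated serine.

    ``residue_label`` names the site (position or residue name, may be
    empty); ``state`` is an open vocabulary — the common post-translational
    states get canonical spellings, anything else passes through verbatim.
    """

    residue_label: str = ""
    state: str = "unknown"

    KNOWN_STATES = (
        "phosphorylated",
        "ubiquitinated",
        "methylated",
        "acetylated",
        "empty",
        "unknown",
    )

    def __post_init__(self) -> None:
        if not self.state:
            raise ValueError("modification state may not be empty")


@dataclass
class Element:
    """A species-level node: protein, small molecule, gene, complex, ..."""

    id: str
    name: str = ""
    element_class: ElementClass = ElementClass.UNSPECIFIED
    sbo_term: Optional[str] = None
    compartment_ref: Optional[str] = None
    parent_complex_ref: Optional[str] = None
    modifications: list[ModificationState] = field(default_factory=list)
    is_hypothetical: bool = False


@dataclass
class Compartment:
    id: str
    name: str = ""
    parent_ref: Optional[str] = None


@dataclass
class Participant:
    element_ref: str
    role: Role = Role.UNDEFINED
    #: finer modifier semantics (e.g. "catalysis") when the source format
    #: distinguishes it beyond the role enum
    modifier_kind: Optional[str] = None


@dataclass
class Reaction:
    id: str
    reaction_class: ReactionClass = ReactionClass.STATE_TRANSITION
    reactants: list[Participant] = field(default_factory=list)
    products: list[Participant] = field(default_factory=list)
    modifiers: list[Participant] = field(default_factory=list)

    def participants(self) -> Iterable[Participant]:
        yield from self.reactants
        yield from self.products
        yield from self.modifiers


@dataclass(frozen=True)
class CurveSegment:
    kind: str  # "line" | "cubic-bezier"
    start: Point
    end: Point
    control1: Optional[Point] = None
    control2: Optional[Point] = None

    def __post_init__(self) -> None:
        if self.kind == "cubic-bezier":
            if self.control1 is None or self.control2 is None:
                raise ValueError("cubic-bezier segment requires both control points")
        elif self.kind == "line":
            if self.control1 is not None or self.control2 is not None:
                raise ValueError("line segment carries no control points")
        else:
            raise ValueError(f"unknown segment kind {self.kind!r}")

    def points(self) -> list[Point]:
        pts = [self.start, self.end]
        if self.control1 is not None:
            pts.append(self.control1)
        if self.control2 is not None:
            pts.append(self.control2)
        return pts


def line(x0: float, y0: float, x1: float, y1: float) -> CurveSegment:
    return CurveSegment("line", Point(x0, y0), Point(x1, y1))


@dataclass
class ParticipantLink:
    """Arc from a reaction glyph to one participating species glyph."""

    glyph_ref: str
    role: Role = Role.UNDEFINED
    curve: list[CurveSegment] = field(default_factory=list)
    modifier_kind: Optional[str] = None


@dataclass
class Glyph:
    id: str
    kind: GlyphKind
    model_ref: Optional[str] = None
    bbox: Optional[BoundingBox] = None
    curve: list[CurveSegment] = field(default_factory=list)
    participant_links: list[ParticipantLink] = field(default_factory=list)
    text: Optional[str] = None
    style_ref: Optional[str] = None
    parent_glyph_ref: Optional[str] = None
    #: SBGN clone marker: this glyph is one of several depictions of its species
    cloned: bool = False

    def sample_points(self) -> list[Point]:
        """All points that define this glyph's extent (bbox corners, curve
        anchors and bezier control points)."""
        pts: list[Point] = []
        if self.bbox is not None:
            b = self.bbox
            pts.append(b.origin)
            pts.append(Point(b.x + b.width, b.y + b.height))
        for seg in self.curve:
            pts.extend(seg.points())
        for link in self.participant_links:
            for seg in link.curve:
                pts.extend(seg.points())
        return pts


@dataclass
class Selector:
    """What a render style applies to: explicit glyphs, roles or classes."""

    glyph_ids: list[str] = field(default_factory=list)
    roles: list[Role] = field(default_factory=list)
    element_classes: list[ElementClass] = field(default_factory=list)

    def is_empty(self) -> bool:
        return not (self.glyph_ids or self.roles or self.element_classes)


@dataclass
class Style:
    id: str
    applies_to: Selector = field(default_factory=Selector)
    stroke: ColorRGBA = ColorRGBA(0, 0, 0)
    stroke_width: float = 1.0
    fill: ColorRGBA = ColorRGBA(255, 255, 255)
    font: Optional[FontSpec] = None
    explicit_shape: Optional[str] = None  # "rounded-rectangle" | "ellipse" | "polygon:n"


@dataclass
class Layout:
    id: str
    canvas: BoundingBox = field(default_factory=lambda: bbox(0, 0, 0, 0))
    glyphs: list[Glyph] = field(default_factory=list)

    def glyph(self, glyph_id: str) -> Glyph:
        for g in self.glyphs:
            if g.id == glyph_id:
                return g
        raise KeyError(glyph_id)

    def glyphs_of_kind(self, kind: GlyphKind) -> list[Glyph]:
        return [g for g in self.glyphs if g.kind == kind]


@dataclass
class Document:
    """The superset container: one network, any number of layouts/styles.

    ``passthrough`` preserves XML fragments the model does not interpret
    (annotations, notes, kinetic laws, decorative graphics) byte-exactly,
    keyed by the id of the object that owned them, so converting a document
    never silently destroys content.
    """

    elements: list[Element] = field(default_factory=list)
    compartments: list[Compartment] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    layouts: list[Layout] = field(default_factory=list)
    styles: list[Style] = field(default_factory=list)
    passthrough: dict[str, list[str]] = field(default_factory=dict)
    source_format: str = "synthetic"  # sbml | celldesigner | sbgnml | synthetic

    # -- lookups -----------------------------------------------------------
    def element(self, element_id: str) -> Element:
        for e in self.elements:
            if e.id == element_id:
                return e
        raise KeyError(element_id)

    def compartment(self, compartment_id: str) -> Compartment:
        for c in self.compartments:
            if c.id == compartment_id:
                return c
        raise KeyError(compartment_id)

    def reaction(self, reaction_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == reaction_id:
                return r
        raise KeyError(reaction_id)

    def layout(self, layout_id: str) -> Layout:
        for l in self.layouts:
            if l.id == layout_id:
                return l
        raise KeyError(layout_id)

    def has_element(self, element_id: str) -> bool:
        return any(e.id == element_id for e in self.elements)

    def add_passthrough(self, owner_id: str, fragment: str) -> None:
        self.passthrough.setdefault(owner_id, []).append(fragment)


@dataclass(frozen=True)
class Violation:
    rule_id: str
    severity: Severity
    object_id: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.severity.value}] {self.rule_id} @ {self.object_id}: {self.message}"


#: catalogue of validation rules; ``validate`` only ever emits these ids
RULE_CATALOGUE: dict[str, str] = {
    "duplicate-id": "two model objects share one identifier",
    "dangling-ref": "a reference does not resolve to an object of the expected kind",
    "complex-cycle": "parent_complex_ref / compartment parent chain forms a cycle",
    "bad-modifier-role": "a modifier participant carries a non-modifier role",
    "empty-reaction": "a reaction has neither reactants nor products",
    "malformed-curve": "a curve segment violates its kind's control-point rule",
    "missing-bbox": "an entity glyph has no bounding box",
    "containment": "a child glyph's bbox is not inside its parent glyph's bbox",
    "no-reaction-curve": "a reaction glyph has no curve",
    "empty-selector": "a style selects nothing",
}


class ModelError(ValueError):
    """Raised for hard usage errors; carries a machine-readable code."""

    def __init__(self, code: str, message: str = ""):
        self.code = code
        self.message = message or code
        super().__init__(message or code)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def validate(doc: Document) -> list[Violation]:
    """Check a document against the structural rules of the model.

    Errors are violations that make the document unserializable (dangling
    references, duplicate ids, cyclic containment); warnings flag cosmetic
    defects tolerated in real-world files (glyph overhang outside its
    parent, a reaction glyph with no curve).
    """
    out: list[Violation] = []

    def err(rule: str, oid: str, msg: str) -> None:
        out.append(Violation(rule, Severity.ERROR, oid, msg))

    def warn(rule: str, oid: str, msg: str) -> None:
        out.append(Violation(rule, Severity.WARNING, oid, msg))

    element_ids = [e.id for e in doc.elements]
    compartment_ids = [c.id for c in doc.compartments]
    reaction_ids = [r.id for r in doc.reactions]

    # id uniqueness per namespace
    for label, ids in (
        ("element", element_ids),
        ("compartment", compartment_ids),
        ("reaction", reaction_ids),
        ("layout", [l.id for l in doc.layouts]),
        ("style", [s.id for s in doc.styles]),
    ):
        seen: set[str] = set()
        for i in ids:
            if i in seen:
                err("duplicate-id", i, f"duplicate {label} id")
            seen.add(i)

    elements = {e.id: e for e in doc.elements}
    compartments = {c.id: c for c in doc.compartments}

    # element-level references
    for e in doc.elements:
        if e.compartment_ref is not None and e.compartment_ref not in compartments:
            err("dangling-ref", e.id, f"compartment_ref {e.compartment_ref!r} unknown")
        if e.parent_complex_ref is not None:
            parent = elements.get(e.parent_complex_ref)
            if parent is None:
                err("dangling-ref", e.id, f"parent_complex_ref {e.parent_complex_ref!r} unknown")
            elif parent.element_class != ElementClass.COMPLEX:
                err("dangling-ref", e.id, "parent_complex_ref does not name a complex")

    # cycles in parent chains
    out.extend(
        _cycle_check({e.id: e.parent_complex_ref for e in doc.elements}, "complex-cycle")
    )
    out.extend(_cycle_check({c.id: c.parent_ref for c in doc.compartments}, "complex-cycle"))

    # reactions
    for r in doc.reactions:
        if not r.reactants and not r.products:
            err("empty-reaction", r.id, "reaction with neither reactants nor products")
        for p in r.participants():
            if p.element_ref not in elements:
                err("dangling-ref", r.id, f"participant {p.element_ref!r} unknown")
        for p in r.modifiers:
            if p.role not in MODIFIER_ROLES:
                err("bad-modifier-role", r.id, f"modifier with role {p.role.value!r}")

    # layouts
    for layout in doc.layouts:
        glyphs = {g.id: g for g in layout.glyphs}
        seen_g: set[str] = set()
        for g in layout.glyphs:
            if g.id in seen_g:
                err("duplicate-id", g.id, "duplicate glyph id in layout")
            seen_g.add(g.id)

        for g in layout.glyphs:
            if g.model_ref is not None:
                pool = {
                    GlyphKind.SPECIES: elements,
                    GlyphKind.COMPARTMENT: compartments,
                    GlyphKind.REACTION: {r.id: r for r in doc.reactions},
                    GlyphKind.TEXT: {**elements, **compartments},
                }[g.kind]
                if g.model_ref not in pool:
                    err("dangling-ref", g.id, f"model_ref {g.model_ref!r} unknown")
            if g.kind in (GlyphKind.SPECIES, GlyphKind.COMPARTMENT, GlyphKind.TEXT):
                if g.bbox is None:
                    err("missing-bbox", g.id, f"{g.kind.value} glyph without bbox")
            if g.kind == GlyphKind.REACTION and not g.curve:
                warn("no-reaction-curve", g.id, "reaction glyph without curve")
            if g.parent_glyph_ref is not None:
                parent = glyphs.get(g.parent_glyph_ref)
                if parent is None:
                    err("dangling-ref", g.id, f"parent_glyph_ref {g.parent_glyph_ref!r} unknown")
                elif (
                    parent.bbox is not None
                    and g.bbox is not None
                    and not parent.bbox.contains(g.bbox)
                ):
                    warn("containment", g.id, "glyph bbox extends outside its parent glyph")
            for link in g.participant_links:
                if link.glyph_ref not in glyphs:
                    err("dangling-ref", g.id, f"participant link to unknown glyph {link.glyph_ref!r}")

    for s in doc.styles:
        if s.applies_to.is_empty():
            err("empty-selector", s.id, "style selects nothing")

    return out


def _cycle_check(parent_of: dict[str, Optional[str]], rule: str) -> list[Violation]:
    out = []
    for start in parent_of:
        seen = {start}
        cur = parent_of.get(start)
        while cur is not None and cur in parent_of:
            if cur in seen:
                out.append(Violation(rule, Severity.ERROR, start, "cyclic parent chain"))
                break
            seen.add(cur)
            cur = parent_of[cur]
    return out


def canvas_bounds(layout: Layout) -> BoundingBox:
    """Minimal axis-aligned box covering every glyph bbox and curve point."""
    xs: list[float] = []
    ys: list[float] = []
    for g in layout.glyphs:
        for p in g.sample_points():
            xs.append(p.x)
            ys.append(p.y)
    if not xs:
        raise ModelError("no-geometry", f"layout {layout.id!r} has no glyph geometry")
    x0, x1 = min(xs), max(xs)
    y0, y1 = min(ys), max(ys)
    return BoundingBox(Point(x0, y0), x1 - x0, y1 - y0)


def style_for_glyph(
    doc: Document, glyph: Glyph, element_class: Optional[ElementClass] = None
) -> Optional[Style]:
    """First style whose selector matches the glyph (explicit ref wins,
    then id selectors, then element-class selectors)."""
    if glyph.style_ref is not None:
        for s in doc.styles:
            if s.id == glyph.style_ref:
                return s
    for s in doc.styles:
        if glyph.id in s.applies_to.glyph_ids:
            return s
    if element_class is not None:
        for s in doc.styles:
            if element_class in s.applies_to.element_classes:
                return s
    return None


def duplicate_groups(doc: Document, layout_id: str) -> list[list[str]]:
    """Groups (size >= 2) of species-glyph ids drawing one element.

    Node duplication draws a highly connected species (water, ATP, a hub
    protein) several times to reduce edge crossings; all depictions still
    reference the single species definition.  Singletons are excluded.
    """
    layout = doc.layout(layout_id)  # KeyError on unknown layout id
    by_ref: dict[str, list[str]] = {}
    for g in layout.glyphs:
        if g.kind == GlyphKind.SPECIES and g.model_ref is not None:
            by_ref.setdefault(g.model_ref, []).append(g.id)
    return [ids for ids in by_ref.values() if len(ids) >= 2]
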