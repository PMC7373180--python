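# Methods

## Superset data model

All conversions go through one in-memory `Document`:

* `elements` — pools (species) with a biological `element_class`
  (macromolecule, simple chemical, complex, receptor, gene, RNA, phenotype,
  …), optional residue `modifications`, optional `parent_complex_ref` for
  complex subunits, and a `compartment_ref`;
* `compartments` — with optional `parent_ref` nesting;
* `reactions` — participants with roles (substrate, product, side variants,
  modifier, activator, inhibitor) and an optional modifier kind such as
  catalysis;
* `layouts` — one or more; each holds `glyphs` (species, compartment,
  reaction, text) with bounding boxes, curves (polyline and cubic-Bézier
  segments), glyph containment (`parent_glyph_ref`), clone flags, and links
  from reaction glyphs to participant glyphs;
* `styles` — stroke/fill/width/font with selectors by glyph id, role, or
  element class;
* `passthrough` — verbatim XML fragments (notes, kinetic laws, foreign
  annotations, CellDesigner decorative graphics) keyed by owner id, re-emitted
  where the target format can hold them.

The model is a superset: each format populates the subset it can express,
and each writer reads only what it can serialize. What a writer cannot
serialize triggers a structured warning (see *Loss ledger*).

## Semantic mapping

Element and reaction classes are carried across formats through SBO terms on
SBML species/reactions (e.g. macromolecule → `SBO:0000245`, simple chemical →
`SBO:0000247`, state transition → `SBO:0000176`), through CellDesigner
`speciesIdentity` class strings, and through SBGN-ML glyph classes. The
mapping tables live in `sbdiagram/mapping.py` and are exact inverses wherever
both formats can express the class; classes one notation lacks fall back
deterministically (e.g. nucleic-acid feature → CellDesigner `GENE`, with a
warning). Participant roles map to SBML speciesReference SBO terms, to
CellDesigner reactant/product/modification lines, and to SBGN-ML arc classes
(consumption, production, catalysis, stimulation, inhibition, modulation).

## Coordinate conventions

All geometry is normalized to one frame: y grows downward, the canvas origin
is (0, 0), and positions are absolute top-left corners of bounding boxes.
Readers translate each format into this frame; `normalize_geometry`
(idempotent) then

* synthesizes a straight reaction curve between reactant/product centroids
  when a reaction glyph has none,
* synthesizes label text glyphs for unlabelled species/compartments —
  centered for plain nodes, in the top strip for compartments and the bottom
  strip for complexes so labels stay off the contents,
* translates layouts that reach into negative coordinates back to the
  origin, and recomputes the canvas from glyph extents.

### CellDesigner edit points

CellDesigner stores reaction bend points in a local frame anchored on the
reaction's endpoints. The convention, established empirically against files
CellDesigner itself writes, is: origin at the reactant anchor **R**, first
basis vector **u** = **P** − **R** (product anchor minus reactant anchor),
second basis vector **v** = (−u_y, u_x), with points stored as fractional
(s, t) such that absolute = **R** + s·**u** + t·**v**. `to_local` /
`to_absolute` in `celldesigner_io.py` implement the exact inverse pair; when
the anchors coincide the frame degenerates, so **u** falls back to the unit
x-vector to keep the pair invertible.

## Round-trip guarantees and numerics

* Write∘read is a fixed point for each format: reading a file the package
  wrote and writing it again reproduces the bytes.
* All six conversion directions conserve glyph counts exactly and species
  bounding boxes to within 1e-6. Coordinates are serialized with the
  shortest decimal representation that round-trips (`repr` of the float;
  integers without a trailing `.0`), so geometry that stays in IEEE-754
  doubles round-trips without error; the 1e-6 tolerance allows for formats
  that store derived quantities (CellDesigner stores reaction geometry as
  fractions of the inter-anchor frame).
* The single structural exception is documented and warned about: SBGN-ML
  clone glyphs cannot reference the species they duplicate, so they come
  back as distinct clone-marked species.

## Auxiliary annotations

Content plain SBML cannot express — complex membership, hypothetical
species, glyph containment, clone flags, style class-selectors, residue
modifications — rides inside `<annotation>` elements in a self-describing
auxiliary namespace (`https://sbdiagram.dev/ns/sbml-extras`), the extension
point SBML prescribes for tool-specific data. Third-party SBML parsers
ignore it; `python-libsbml`, when installed, reads the emitted files with
zero errors (see `tests/test_libsbml_crosscheck.py`). SBGN-ML styling
likewise travels in `<extension>` elements under
`https://sbdiagram.dev/ns/render`.

## Schema validation

`sbdiagram/data/` bundles subset XML schemas for SBML L3 core + layout +
render and for SBGN-ML PD, covering exactly the constructs the writers emit
(plus skipped wildcards for foreign content). The layout package's
`xsi:type="LineSegment|CubicBezier"` values are conventionally unprefixed
and thus resolve against the default (core) namespace, so the core subset
defines those two complex types, derived from the layout package's
curve-segment base type. `sbdiagram.schemas.validation_errors` runs lxml's
XSD validator against the bundled schemas.

## Loss ledger

Four expressiveness gaps are tracked; each produces exactly one warning per
conversion, and only when the source uses the feature:

| rule id | gap |
| --- | --- |
| `layouts-dropped` | only SBML holds multiple layouts per model |
| `label-positions-dropped` | CellDesigner always centers labels on shapes |
| `duplicate-identity-lost` | SBGN-ML clone markers carry no identity |
| `decorative-graphics-dropped` | CellDesigner free-form texts/layers have no counterpart |

Reports serialize to JSON lines (`--report` on the CLI) with
`rule_id`, `severity`, `object_id`, `message`.

## Synthetic network generator

`sbdiagram.fixtures.make_toy_document(n_species, n_reactions,
n_compartments, seed)` produces deterministic, validation-clean documents on
a jittered grid, exercising every model feature: a complex with subunits, a
duplicated (clone) species, nested compartments, an inhibitor, a
phosphorylated residue, and class-keyed styles. `benchmark_like(name)`
instantiates the generator at the sizes of two published disease-map
extracts (37/20 and 152/132 species/reactions) and at pathway scale
(5000/2500). The generator is a stand-in, not a biological model: its
topology is random within the stated structural guarantees, which is
sufficient for conversion, validation, and performance measurement but not
for biological interpretation.

## Rendering

SVG is generated directly (one `<g>` per glyph, SBGN-mandated shapes per
element class); PNG is rasterized from the same shape primitives with
Pillow; PDF is written as a single-page vector content stream with Helvetica
text. Label widths use a built-in metric table, so rendering needs no font
files and is byte-deterministic.

## Limitations

* SBGN-ML *entity relationship* and *activity flow* sublanguages are not
  supported (PD only).
* CellDesigner files older than the 4.x schema generation are read on a
  best-effort basis.
* Reaction-level kinetics are passed through verbatim, never interpreted.
* Regulatory influences without a process node are rejected in strict mode
  when writing SBGN-ML and approximated by a stimulation/inhibition arc in
  lenient mode.
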