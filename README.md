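# sbdiagram

Convert molecular-network diagrams between the three layout-aware
systems-biology formats — **SBML Level 3 + layout/render**, the
**CellDesigner SBML extension**, and **SBGN-ML Process Description** — and
export any of them to **SVG**, **PNG**, or **PDF**.

## The problem

Disease maps and signalling-pathway diagrams are drawn once, in one tool, and
then needed everywhere else. The three de-facto exchange formats all store a
reaction network *plus* a hand-made layout, but they disagree about almost
everything else:

* **SBML layout/render** separates model from appearance, supports multiple
  layouts per model, and attaches free-form styles — but has no notion of
  complex membership in the layout, residue modifications, or clone markers.
* **CellDesigner** stores rich biological typing (receptors, ion channels,
  phosphosites, heterodimers) and duplicated *aliases* of one species, but
  pins every label to its shape's center and encodes reaction geometry in an
  idiosyncratic local coordinate frame ("edit points").
* **SBGN-ML PD** is the graphically precise standard — every glyph class has
  a mandated shape — but clone markers carry no identity, and regulatory
  influences without a process node are outside the sublanguage.

Converting pairwise between them therefore loses information in
format-specific ways, and ad-hoc converters tend to lose it *silently*.
`sbdiagram` routes every conversion through a single superset data model, so
one reader and one writer per format cover all six directions, and every
known expressiveness gap produces exactly one structured warning instead of
silent loss. Anything a format carries that the model does not (notes,
foreign annotations, kinetic laws, decorative graphics) is preserved verbatim
and re-emitted when the target can hold it.

## Worked example

Convert the bundled CellDesigner example to SBGN-ML:

```console
$ sbdiagram convert fixtures/toy.celldesigner.xml toy.sbgn --to sbgnml
warning [duplicate-identity-lost] layout_0: 2 duplicate glyphs emitted with clone markers; which species each clone duplicates is not expressible in SBGN-ML
wrote toy.sbgn (celldesigner -> sbgnml, 1 warning(s))
```

The warning is the loss ledger at work: the source diagram shows one species
in two places (a CellDesigner alias pair); SBGN-ML can mark both glyphs as
clones but cannot say they are the *same* species, so the conversion says so
— exactly once.

The same conversion from Python:

```python
from pathlib import Path
from sbdiagram.convert import convert

sbgn, report = convert(Path("fixtures/toy.celldesigner.xml").read_bytes(),
                       target="sbgnml")
for w in report.warnings:
    print(f"[{w.rule_id}] {w.message}")
```

```text
[duplicate-identity-lost] 2 duplicate glyphs emitted with clone markers; which species each clone duplicates is not expressible in SBGN-ML
```

The emitted file begins:

```xml
<?xml version='1.0' encoding='UTF-8'?>
<sbgn xmlns="http://sbgn.org/libsbgn/0.2">
  <map language="process description">
    <glyph class="compartment" id="c0">
      <label text="compartment_0">
        <bbox x="17.806185464674407" y="18.530414154436528" w="484.2084051588448" h="18"/>
      </label>
      <bbox x="17.806185464674407" y="18.530414154436528" w="484.2084051588448" h="314.14121001888697"/>
      ...
```

Render any of the three formats to an image:

```console
$ sbdiagram export-image fixtures/toy.celldesigner.xml toy.png --scale 2
$ sbdiagram list-formats
sbml          read/write SBML Level 3 with layout and render packages
celldesigner  read/write CellDesigner SBML extension (Level 2 Version 4)
sbgnml        read/write SBGN-ML Process Description
svg           write only Scalable Vector Graphics (export only)
png           write only Portable Network Graphics raster (export only)
pdf           write only Portable Document Format vector page (export only)
```

`fixtures/toy.svg` is a committed rendering of the example network.

## What is checked

* **Round trips.** All six conversion directions conserve glyph counts
  exactly and species geometry to within 1e-6 (the sole documented
  exception: SBGN-ML clone glyphs come back as separate clone-marked
  species, because the format cannot express their shared identity).
* **Schema validity.** Emitted SBML and SBGN-ML validate against bundled
  XML schemas; when `python-libsbml` happens to be installed, its validator
  is used as an independent cross-check.
* **Scale.** A 5000-species / 2500-reaction document converts through
  CellDesigner → SBML → SBGN-ML and renders to SVG in seconds per step.
* **Loud loss.** Each expressiveness gap (extra layouts, label positions,
  duplicate identity, decorative graphics) warns exactly once, and only when
  the source actually uses the feature.

## Reproduction

```bash
pip install --no-build-isolation -e .
python -m pytest -q tests/                 # full test suite
python scripts/acceptance.py --seed 1 --out results/acceptance.json
python scripts/make_fixtures.py            # regenerate fixtures/ byte-identically
```

`scripts/acceptance.py` prints and records the headline quantities: the
benchmark network counts (37/20 and 152/132 species/reactions), per-step
timings of the pathway-scale pipeline, the maximum round-trip geometry error,
schema error counts, and loss-warning coverage.

All example networks are synthetic, produced by the deterministic generator
in `sbdiagram.fixtures`; the two benchmark-sized networks are synthetic
stand-ins that match the species/reaction/compartment counts of two published
disease-map extracts.

See `docs/methods.md` for the data model, coordinate conventions, and the
exact mapping tables.
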