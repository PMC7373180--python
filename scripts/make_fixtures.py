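#!/usr/bin/env python
"""Regenerate the small committed example files under fixtures/.

Every file is produced deterministically from the synthetic network
generator, so this script always reproduces the committed bytes exactly.

Usage:
    python scripts/make_fixtures.py
"""

from __future__ import annotations

from pathlib import Path

from sbdiagram import fixtures, normalize_geometry, render_svg
from sbdiagram.convert import write_document

OUT = Path(__file__).resolve().parent.parent / "fixtures"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    toy = normalize_geometry(fixtures.make_toy_document(10, 5, 2, seed=1))
    (OUT / "toy.sbml.xml").write_bytes(write_document(toy, "sbml"))
    (OUT / "toy.celldesigner.xml").write_bytes(write_document(toy, "celldesigner"))
    (OUT / "toy.sbgn").write_bytes(write_document(toy, "sbgnml"))
    (OUT / "toy.svg").write_bytes(render_svg(toy))

    minimal = normalize_geometry(
        fixtures.minimal_examples()["one-reaction-two-species"]
    )
    (OUT / "minimal_reaction.sbml.xml").write_bytes(write_document(minimal, "sbml"))

    for path in sorted(OUT.iterdir()):
        print(f"{path.name}: {path.stat().st_size} bytes")


if __name__ == "__main__":
    main()
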