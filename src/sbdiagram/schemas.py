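"""Schema validation of emitted documents against bundled subset schemas.

The schemas cover the constructs this library reads and writes (SBML Level 3
core + layout + render; SBGN-ML 0.2 Process Description).  They are subsets:
a document that fails here is structurally wrong, while a pass asserts
conformance for the covered vocabulary, attributes and nesting.  Auxiliary-
namespace attributes and annotation/extension payloads are allowed through,
as both standards prescribe for foreign content.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

from lxml import etree

from .model import ModelError

_SCHEMA_FILES = {
    "sbml": "sbml_core_subset.xsd",
    "sbgnml": "sbgn_pd_subset.xsd",
}


@lru_cache(maxsize=None)
def _schema(format: str) -> etree.XMLSchema:
    try:
        filename = _SCHEMA_FILES[format]
    except KeyError:
        raise ModelError(
            "unknown-format", f"no bundled schema for format {format!r}"
        ) from None
    data_dir = resources.files("sbdiagram") / "data"
    with resources.as_file(data_dir / filename) as path:
        return etree.XMLSchema(etree.parse(str(path)))


def validation_errors(data: bytes, format: str) -> list[str]:
    """Validate serialized bytes; returns human-readable schema violations."""
    schema = _schema(format)
    try:
        tree = etree.fromstring(data)
    except etree.XMLSyntaxError as exc:
        return [f"not well-formed XML: {exc}"]
    if schema.validate(tree):
        return []
    return [
        f"line {e.line}: {e.message}" for e in schema.error_log  # type: ignore[union-attr]
    ]


def assert_valid(data: bytes, format: str) -> None:
    """Raise :class:`ModelError` (code ``schema-invalid``) on any violation."""
    errors = validation_errors(data, format)
    if errors:
        raise ModelError(
            "schema-invalid",
            f"{format} document violates the bundled schema: "
            + "; ".join(errors[:5])
            + (f" (+{len(errors) - 5} more)" if len(errors) > 5 else ""),
        )
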