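import pytest

from sbdiagram import fixtures, normalize_geometry
from sbdiagram.convert import write_document


@pytest.fixture
def toy_doc():
    """Mid-sized document with all structural features present."""
    return fixtures.make_toy_document(10, 5, 2, seed=1)


@pytest.fixture
def toy_doc_normalized(toy_doc):
    return normalize_geometry(toy_doc)


@pytest.fixture
def minimal():
    return fixtures.minimal_examples()


@pytest.fixture
def toy_sbml(toy_doc_normalized):
    return write_document(toy_doc_normalized, "sbml")


@pytest.fixture
def toy_cd(toy_doc_normalized):
    return write_document(toy_doc_normalized, "celldesigner")


@pytest.fixture
def toy_sbgn(toy_doc_normalized):
    return write_document(toy_doc_normalized, "sbgnml")
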