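import pytest

from labflow.fixtures import build_paternity_example
from labflow.xpdl import translate_ontology


@pytest.fixture(scope="session")
def paternity():
    """(ontology, protocol, translation unit) for the worked example."""
    ont, protocol = build_paternity_example()
    return ont, protocol, translate_ontology(ont)


@pytest.fixture()
def paternity_package(paternity, tmp_path):
    """The worked example written to disk as its two linked files."""
    from labflow.serialization import write_package

    ont, protocol, tu = paternity
    pkg = write_package(tu, protocol, ont, tmp_path, name="paternity_test")
    return ont, protocol, tu, pkg
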