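import pytest

from mcrokit import build_core_schema, to_instance_graph
from mcrokit.fixtures import load_sample_card


@pytest.fixture(scope="session")
def core():
    return build_core_schema()


@pytest.fixture(scope="session")
def pci_card():
    return load_sample_card("pci")


@pytest.fixture(scope="session")
def hiv_card():
    return load_sample_card("hiv")


@pytest.fixture(scope="session")
def pci_graph(pci_card, core):
    return to_instance_graph(pci_card, core)
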