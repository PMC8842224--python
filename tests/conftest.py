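import pytest

from adenofep.dataset import load_compound_table
from adenofep.fepmap import design_network
from adenofep.synthetic_data import FEP_SELECTION_18


@pytest.fixture(scope="session")
def table():
    return load_compound_table()


@pytest.fixture(scope="session")
def selection18(table):
    return table.subset(FEP_SELECTION_18)


@pytest.fixture(scope="session")
def network18(selection18):
    return design_network(
        {r.compound_id: r.smiles for r in selection18.records}, n_closure_edges=11
    )
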