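import pytest

from surfacer.fixtures import generate_proteome, generate_psm_table
from surfacer.proteome_io import ProteinRecord


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """A 100-protein, 50%-surface synthetic bundle shared across tests."""
    directory = tmp_path_factory.mktemp("bundle")
    return generate_proteome(100, 0.5, seed=7, out_dir=directory)


@pytest.fixture(scope="session")
def psm_path(bundle):
    return generate_psm_table(bundle, n_psms=2000, scm_specificity=0.8, seed=7)


@pytest.fixture
def simple_proteins():
    return {
        "P1": ProteinRecord("P1", "", "MKAAANGTKLLNGSAVKAAAK"),
        "P2": ProteinRecord("P2", "", "MSSTTKAANPSKAAANAS"),
    }
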