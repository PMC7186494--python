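from pathlib import Path

import pytest

from qmrescore import ToyBackend, assign_formal_charges, make_library, make_toy_pocket

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA_DIR


@pytest.fixture(scope="session")
def toy_backend() -> ToyBackend:
    return ToyBackend()


@pytest.fixture(scope="session")
def pocket():
    return make_toy_pocket(seed=0, n_residues=20)


@pytest.fixture(scope="session")
def charged_pocket(pocket):
    return assign_formal_charges(pocket)


@pytest.fixture(scope="session")
def small_library(charged_pocket):
    """5 ligands + 15 decoys, no deliberate clash; 3 dual-state molecules."""
    return make_library(
        charged_pocket, seed=0, n_ligands=5, n_decoys=15, include_clash=False
    )
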