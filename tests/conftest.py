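import numpy as np
import pytest

from endofc.fixtures import make_binding_study, write_fixture
from endofc.interface import RadiiTable
from endofc.model import get_scheme


@pytest.fixture(scope="session")
def binding_study():
    """Synthetic enzyme-Fc study with ground truth (seed fixed)."""
    return make_binding_study(seed=1)


@pytest.fixture(scope="session")
def study_files(binding_study, tmp_path_factory):
    structures, truth = binding_study
    d = tmp_path_factory.mktemp("study")
    files = {role: write_fixture(st, d / f"{role}.pdb") for role, st in structures.items()}
    return files, truth


@pytest.fixture(scope="session")
def element_radii():
    return RadiiTable.element()


@pytest.fixture(scope="session")
def endos2_scheme():
    return get_scheme("endos2")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
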