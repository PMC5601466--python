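import numpy as np
import pytest

from mechunfold.io import StructureModel


@pytest.fixture
def single_atom_model():
    """One carbon-like atom at the origin."""
    return StructureModel(
        names=["C"], elements=["C"], resids=np.array([1]), resnames=["SPH"],
        chains=["A"], coords=np.zeros((1, 3)))


def write_text(tmp_path, name, content):
    path = tmp_path / name
    path.write_text(content)
    return path


@pytest.fixture
def write_file(tmp_path):
    return lambda name, content: write_text(tmp_path, name, content)
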