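import numpy as np
import pytest

from dhanmkf.io_data import AssociationMatrix, EntityIndex
from dhanmkf.synthetic import SyntheticSpec, generate, similarity_inputs


@pytest.fixture
def small_matrix() -> AssociationMatrix:
    values = np.array(
        [
            [1, 0, 1],
            [0, 1, 0],
            [1, 1, 0],
            [0, 0, 1],
        ]
    )
    return AssociationMatrix(
        values,
        EntityIndex(("cA", "cB", "cC", "cD"), "circRNA"),
        EntityIndex(("d1", "d2", "d3"), "drug"),
    )


@pytest.fixture(scope="session")
def fixture_dataset():
    """Default planted-block fixture with its similarity matrices."""
    data = generate(SyntheticSpec(seed=0))
    css, dss = similarity_inputs(data)
    return data, css, dss


@pytest.fixture(scope="session")
def tiny_dataset():
    """Smaller fixture for training-loop tests."""
    data = generate(
        SyntheticSpec(n_circ=30, n_drug=20, n_blocks=2, seq_len=80, seed=3)
    )
    css, dss = similarity_inputs(data)
    return data, css, dss
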