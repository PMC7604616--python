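import numpy as np
import pytest

from zipquant.synthetic import CellSimParams, gen_cell


@pytest.fixture(scope="session")
def disk_cell():
    """Concentric disk cell (R=100 px) with a 30 px nucleus on a 256 px image."""
    return gen_cell(CellSimParams(image_size=256, cell_radius=100, nucleus_radius=30))


@pytest.fixture()
def rng():
    return np.random.default_rng(20230917)
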