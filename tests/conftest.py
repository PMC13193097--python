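import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def disk_geometry():
    """900 um^2 disk cell with a 15% concentric nucleus at 0.13 um/px."""
    from lysoquant import make_cell_geometry

    return make_cell_geometry(900.0, 0.15, 0.13, "disk", seed=0)
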