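import numpy as np
import pytest

from enp.decomposition import CELL_POSITIONS, LoadCellFrame


def make_frame(values, timestamp=0.0):
    """Frame from 8 values in canonical cell order, or a single scalar."""
    if np.isscalar(values):
        values = [values] * 8
    return LoadCellFrame(
        timestamp=timestamp, readings={p: float(v) for p, v in zip(CELL_POSITIONS, values)}
    )


def random_frame(rng, max_kg=30.0):
    return make_frame(rng.uniform(0.1, max_kg, size=8))


@pytest.fixture
def uniform_frame():
    """10 kg on each of the eight cells: perfectly symmetric stance."""
    return make_frame(10.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
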