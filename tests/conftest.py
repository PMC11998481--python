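import numpy as np
import pytest

import beatrack as bt
from beatrack.cluster import Adjacency
from beatrack.montage import template_montage_32


@pytest.fixture(scope="session")
def montage():
    return template_montage_32()


@pytest.fixture(scope="session")
def adjacency(montage):
    return Adjacency.from_montage(montage)


@pytest.fixture(scope="session")
def tonal_two_bars():
    return bt.gen_tonal_sequence(2, 46.0, seed=7)


@pytest.fixture(scope="session")
def study_envelope():
    """~60-s envelope of a tonal stimulus at the analysis rate."""
    seq = bt.gen_tonal_sequence(12, 46.0, seed=2)
    return bt.render_envelope(seq, 150.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
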