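import numpy as np
import pytest

from affectencode import synthetic as syn
from affectencode.feature_space import build_feature_space


@pytest.fixture(scope="session")
def csva_space():
    return build_feature_space("CSVA")


@pytest.fixture(scope="session")
def small_experiment():
    """Desk-scale synthetic study at SNR 2 shared across test modules."""
    return syn.gen_experiment(syn.SimConfig(seed=7, snr=2.0))


@pytest.fixture()
def rng(request):
    # deterministic and order-independent: seed derived from the test name
    import zlib

    h = zlib.crc32(request.node.name.encode()) % (2 ** 31)
    return np.random.default_rng(h)
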