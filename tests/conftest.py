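import numpy as np
import pytest

from paox.optics import default_table
from paox.phantom import forward_pa, make_placenta_phantom


@pytest.fixture(scope="session")
def table():
    return default_table()


@pytest.fixture(scope="session")
def noise_free_scan(table):
    """A 60%-saturated placental phantom imaged without noise, with its mask."""
    truth, mask = make_placenta_phantom(so2=0.60, total_hb=1.0, seed=0)
    scan = forward_pa(truth, table, noise_sd=0.0, seed=0)
    return truth, mask, scan


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
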