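import numpy as np
import pytest

from qt1seg.imaging_io import Polygon
from qt1seg.phantom import (
    PhantomSpec,
    make_phantom,
    simulate_ir,
    simulate_spgr,
)
from qt1seg.t1_mapping import compute_t1_map

FA_LO, FA_HI, TR = 4.0, 18.0, 5.3
TI = 200.0


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def truth(default_spec):
    return make_phantom(default_spec, seed=1)


@pytest.fixture(scope="session")
def noiseless_images(truth):
    """IR + SPGR pair without noise, registered."""
    return {
        "ir": simulate_ir(truth, ti=TI),
        "lo": simulate_spgr(truth, FA_LO, TR),
        "hi": simulate_spgr(truth, FA_HI, TR),
    }


@pytest.fixture(scope="session")
def noiseless_t1map(noiseless_images):
    return compute_t1_map(noiseless_images["lo"], noiseless_images["hi"])


@pytest.fixture(scope="session")
def outer_polygon(default_spec):
    return Polygon(default_spec.outer.polygon(24))


@pytest.fixture(scope="session")
def inner_polygon(default_spec):
    return Polygon(default_spec.inner.polygon(24))
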