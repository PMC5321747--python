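import numpy as np
import pytest

import tomodiff as td


@pytest.fixture(scope="session")
def pspec():
    return td.PhantomSpec()


@pytest.fixture(scope="session")
def phantom(pspec):
    return td.build_phantom(pspec)


@pytest.fixture(scope="session")
def wedge():
    return td.WedgeSpec()


@pytest.fixture(scope="session")
def full_wedge():
    return td.WedgeSpec(tilt_min=-90.0, tilt_max=90.0)


@pytest.fixture(scope="session")
def small_pspec():
    # same geometry on a coarser grid: fast Monte-Carlo alignment trials
    return td.PhantomSpec(box_size=36, voxel_size=6.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
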