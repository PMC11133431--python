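import numpy as np
import pytest

import parcelcorr as pc


@pytest.fixture(scope="session")
def dkt62():
    return pc.load_dkt62()


@pytest.fixture(scope="session")
def parc31():
    """Left-hemisphere-only parcellation (expression-atlas setting)."""
    return pc.make_sphere_parcellation(31, seed=101, hemispheres="left")


@pytest.fixture(scope="session")
def ensemble_dkt(dkt62):
    """A 200-spin ensemble for fast significance tests."""
    return pc.make_spin_ensemble(dkt62, 200, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
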