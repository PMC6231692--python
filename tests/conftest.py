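import numpy as np
import pytest

from shapersa import stimuli as st
from shapersa import synth
from shapersa.features import pixel_features


def standard_ids():
    return [st.stimulus_id(g, j, m) for g in st.GROUPS for j in range(1, 9) for m in "ab"]


@pytest.fixture(scope="session")
def ids64():
    return standard_ids()


@pytest.fixture(scope="session")
def shape_set():
    """One default shape set shared across the session (generation is ~1 s)."""
    return st.build_shape_set(seed=11)


@pytest.fixture(scope="session")
def pixel_matrix(shape_set):
    return pixel_features(shape_set.images(), shape_set.ids())


@pytest.fixture(scope="session")
def geometry(ids64):
    return synth.make_geometry_profile(ids64, seed=7)


@pytest.fixture(scope="session")
def neural_dataset(ids64, geometry):
    return synth.simulate_neurons(ids64, geometry, n_units=119, noise_scale=1.0, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
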