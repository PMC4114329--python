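import numpy as np
import pytest

import rehosim as rs


@pytest.fixture
def rng():
    return np.random.default_rng(20240501)


@pytest.fixture(scope="session")
def fast_store():
    """Small single-study fast-path data store with a clear sex effect."""
    spec = rs.CohortSpec(
        studies=[rs.StudySpec("Demo", 50, 50, effect_strength=0.15)],
        grid_shape=(12, 12, 12),
        seed=101,
    )
    return rs.DataStore.from_subject_maps(rs.make_reho_maps(spec))


@pytest.fixture(scope="session")
def table1():
    return rs.table1_fixture()
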