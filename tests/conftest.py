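import numpy as np
import pytest

from tditrace import make_calibration
from tditrace.synthetic import make_fixture_suite

SUITE_SEED = 7


@pytest.fixture(scope="session")
def suite():
    """Deterministic synthetic fixture suite shared by the whole session."""
    return make_fixture_suite(SUITE_SEED)


@pytest.fixture(scope="session")
def suite_by_name(suite):
    return {fx.name: fx for fx in suite}


@pytest.fixture
def unit_cal():
    """Screen-oriented calibration: baseline row 100, 1 cm/s per row upward."""
    return make_calibration(
        time_refs=((0, 0.0), (100, 1.0)),
        velocity_refs=((100, 0.0), (101, -1.0)),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
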