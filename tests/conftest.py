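import numpy as np
import pytest

from rxcov import canonical_scenario, make_fixture_table


@pytest.fixture
def rng():
    return np.random.default_rng(20230103)


@pytest.fixture
def small_scenario():
    """Canonical two-group scenario at the default group size."""
    return canonical_scenario(noise_scenario=1, n_per_group=12, seed=3)


@pytest.fixture
def fixture_table(small_scenario):
    """Tidy 6-analyte measurement table with duplicate aliquots."""
    return make_fixture_table(small_scenario, gamma=0.5, seed=11)
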