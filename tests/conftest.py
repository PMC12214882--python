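import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from hrdsense.features import derive_features
from hrdsense.synthetic import SimulationConfig, simulate_channel_counts, simulate_cohort


@pytest.fixture(scope="session")
def wgs_train_cohort():
    """Default WGS training cohort (100 HRD + 100 HRP), counts level."""
    catalogs, labels = simulate_channel_counts(SimulationConfig(seed=7))
    return catalogs, labels


@pytest.fixture(scope="session")
def wgs_train_features(wgs_train_cohort):
    catalogs, labels = wgs_train_cohort
    return [derive_features(c, "WGS") for c in catalogs], labels


@pytest.fixture(scope="session")
def wgs_test_features():
    catalogs, labels = simulate_channel_counts(
        SimulationConfig(n_hrd=50, n_hrp=50, seed=1007, sample_prefix="T")
    )
    return [derive_features(c, "WGS") for c in catalogs], labels


@pytest.fixture(scope="session")
def record_cohort():
    """Small record-level cohort for classifier round-trips and IO tests."""
    return simulate_cohort(SimulationConfig(n_hrd=8, n_hrp=8, seed=5))
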