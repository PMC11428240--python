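import numpy as np
import pandas as pd
import pytest

from bovitherm import featuresets, preprocess, synthetic, thermal


@pytest.fixture(scope="session")
def small_config():
    """A fast cohort config (~500 rows) for unit tests."""
    return synthetic.GeneratorConfig(seed=7, n_days=5, cows_per_day_range=(90, 110))


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return synthetic.gen_cohort(small_config)


@pytest.fixture(scope="session")
def processed_small(small_cohort):
    table, _ = small_cohort
    processed, report = preprocess.preprocess_table(table)
    return processed, report


@pytest.fixture(scope="session")
def featured_small(processed_small):
    processed, _ = processed_small
    return thermal.compute_features(processed)


@pytest.fixture(scope="session")
def registry():
    return featuresets.build_registry()


@pytest.fixture
def rng():
    return np.random.default_rng(0)
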