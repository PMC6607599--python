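import numpy as np
import pytest

from stomapore.evaluation import run_suite
from stomapore.pipeline import PipelineConfig
from stomapore.synthgen import generate_dataset

SUITE_SEED = 11
SUITE_N = 400


@pytest.fixture(scope="session")
def dark_suite():
    """Stratified 400-stoma dark-field dataset (100 per opening-degree bin)."""
    return generate_dataset(SUITE_N, seed=SUITE_SEED, field="dark")


@pytest.fixture(scope="session")
def dark_suite_results(dark_suite):
    """Pipeline results over the dark-field suite (shared across tests)."""
    return run_suite(dark_suite, PipelineConfig(field_mode="dark"))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
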