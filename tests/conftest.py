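import warnings

import numpy as np
import pytest

from cafrisk.cohort import GenerationConfig, default_schema, generate, planted_signal_dataset

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=UserWarning, module="sklearn")


@pytest.fixture(scope="session")
def small_cohort():
    """Seeded cohort at the reference study's group sizes (360 CAF / 181 no-CAF)."""
    return generate(default_schema(), GenerationConfig(seed=7))


@pytest.fixture(scope="session")
def planted_data():
    """Separable planted-signal table: 2 informative + 2 noise features."""
    return planted_signal_dataset(n=200, n_informative=2, n_noise=2, effect_size=2.5, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
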