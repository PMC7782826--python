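import numpy as np
import pytest

from sleepseg.synth import SynthConfig, generate_dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_dataset():
    """A dozen short synthetic records for fast unit tests."""
    config = SynthConfig(n_records=12, record_length=2 ** 12, seed=7)
    items, manifest = generate_dataset(config)
    return items, manifest, config


@pytest.fixture(scope="session")
def medium_dataset():
    """Enough records for distributional checks (prevalence, dispersion)."""
    config = SynthConfig(n_records=100, record_length=2 ** 13, seed=11)
    items, manifest = generate_dataset(config)
    return items, manifest, config
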