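import numpy as np
import pytest

from nifbkit import (
    GroupSpec,
    SyntheticConfig,
    default_fingerprint,
    default_panel,
    generate_dataset,
)


@pytest.fixture(scope="session")
def fingerprint():
    return default_fingerprint()


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def small_dataset():
    """Noise-free labelled dataset: 2 groups, 20 records, 20% contaminants."""
    config = SyntheticConfig(
        seed=11,
        groups=(
            GroupSpec("Bacteria", "Firmicutes", 10, (0.5, 0.3, 0.2)),
            GroupSpec("Archaea", "Euryarchaeota", 10, (1.0, 0.0, 0.0)),
        ),
        contaminant_fraction=0.2,
        substitution_rate=0.0,
    )
    return generate_dataset(config)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
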