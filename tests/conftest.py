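import numpy as np
import pytest

from causalrules import GeneratorParams, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def two_rule_dataset():
    """A medium dataset with a known 2-rule decomposition (effect size 5)."""
    return generate_dataset(
        GeneratorParams(n=2000, p=10, n_rules=2, effect_size=5.0, seed=11)
    )


@pytest.fixture(scope="session")
def four_rule_dataset():
    return generate_dataset(
        GeneratorParams(n=4000, p=10, n_rules=4, effect_size=5.0, seed=13)
    )
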