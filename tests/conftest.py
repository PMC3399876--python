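import numpy as np
import pytest

from figlink import GeneratorConfig, generate_corpus, golden_fixtures


@pytest.fixture(scope="session")
def small_corpus():
    """Six annotated synthetic articles under the default study conditions."""
    return generate_corpus(GeneratorConfig(n_articles=6, seed=42))


@pytest.fixture(scope="session")
def train_corpus():
    """Twenty annotated synthetic articles for fitting models."""
    return generate_corpus(GeneratorConfig(n_articles=20, seed=7))


@pytest.fixture(scope="session")
def golden():
    return golden_fixtures()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
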