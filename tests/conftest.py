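import numpy as np
import pytest

from misinfowatch.synthetic import GeneratorConfig, generate_corpus


@pytest.fixture(scope="session")
def small_world():
    """A 2,000-tweet synthetic corpus with ground truth, shared across tests."""
    corpus, truth = generate_corpus(GeneratorConfig(n_tweets=2000, seed=42))
    return corpus, truth


@pytest.fixture(scope="session")
def medium_world():
    """A 8,000-tweet corpus for tests that need more statistical weight."""
    corpus, truth = generate_corpus(GeneratorConfig(n_tweets=8000, seed=7))
    return corpus, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
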