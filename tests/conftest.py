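import pytest

from phenonest.scheme import copd_scheme
from phenonest.synthetic import GeneratorConfig, generate_corpus


@pytest.fixture(scope="session")
def scheme():
    return copd_scheme()


@pytest.fixture(scope="session")
def small_corpus():
    """A small deterministic nested corpus shared across read-only tests."""
    return generate_corpus(GeneratorConfig(seed=42, n_documents=12))
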