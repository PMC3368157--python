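import pytest

from bioeve.synthetic import CorpusConfig, generate


@pytest.fixture(scope="session")
def small_corpus():
    """A 20-document synthetic corpus with default (rich-mention) conditions."""
    return generate(CorpusConfig(n_docs=20, seed=17))


@pytest.fixture(scope="session")
def medium_corpus():
    """A 50-document corpus for linear-scan oracle comparisons."""
    return generate(CorpusConfig(n_docs=50, seed=23))
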