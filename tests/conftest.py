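import pytest

from connextract.synthetic import (
    GeneratorConfig,
    generate_corpus,
    make_toy_lexicon,
)


@pytest.fixture(scope="session")
def toy_lexicon():
    """Small lexicon + reference connectome shared across tests."""
    return make_toy_lexicon(size=20, depth=3, seed=11)


@pytest.fixture(scope="session")
def small_corpus(toy_lexicon):
    """30-document synthetic corpus with its truth ledger."""
    lexicon, reference = toy_lexicon
    config = GeneratorConfig(n_documents=30, lexicon_size=20, seed=7)
    docs, ledger = generate_corpus(config, lexicon, reference)
    return docs, ledger, lexicon, reference


@pytest.fixture(scope="session")
def default_corpus():
    """The default study conditions: 200 documents, seed 42, no noise."""
    config = GeneratorConfig()
    lexicon, reference = make_toy_lexicon(
        config.lexicon_size, config.lexicon_depth, config.seed
    )
    docs, ledger = generate_corpus(config, lexicon, reference)
    return docs, ledger, lexicon, reference
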