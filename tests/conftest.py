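import warnings

import pytest

from genenorm.normalizer import build_index
from genenorm.pipeline import train_pipeline
from genenorm.synthetic import generate_corpus, generate_lexicon


@pytest.fixture(scope="session")
def small_lexicon():
    entries, species_lex = generate_lexicon(60, n_species=3, seed=7)
    return entries, species_lex


@pytest.fixture(scope="session")
def small_index(small_lexicon):
    entries, _ = small_lexicon
    return build_index(entries)


@pytest.fixture(scope="session")
def small_corpus(small_lexicon):
    entries, species_lex = small_lexicon
    return generate_corpus(entries, species_lex, 40, seed=11)


@pytest.fixture(scope="session")
def heldout_corpus(small_lexicon):
    entries, species_lex = small_lexicon
    return generate_corpus(entries, species_lex, 10, seed=12)


@pytest.fixture(scope="session")
def trained_pipeline(small_lexicon, small_index, small_corpus):
    _, species_lex = small_lexicon
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return train_pipeline(small_corpus, small_index, species_lex)
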