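from datetime import date

import pytest

from notepol.corpus_synth import SynthConfig, generate_corpus
from notepol.ingest_preprocess import (
    lemmatize,
    remove_stopwords,
    tokenize_and_split,
)
from notepol.lexicons import (
    fixture_path,
    load_fixture_lexicons,
    read_lemma_table,
    read_stopwords,
)


@pytest.fixture(scope="session")
def lexicons():
    return load_fixture_lexicons()


@pytest.fixture(scope="session")
def lemma_table():
    return read_lemma_table(fixture_path("lemmas"))


@pytest.fixture(scope="session")
def stopwords():
    return read_stopwords(fixture_path("stopwords"))


@pytest.fixture(scope="session")
def small_corpus():
    """80-patient corpus with duplicates and both groups; seed-fixed."""
    cfg = SynthConfig(
        n_patients=80,
        notes_per_patient=6,
        duplicate_rate=0.05,
        date_range=(date(2020, 1, 1), date(2020, 6, 30)),
        seed=13,
    )
    return generate_corpus(cfg)


@pytest.fixture(scope="session")
def small_tokenized(small_corpus, lemma_table, stopwords):
    notes, _ = small_corpus
    return [
        remove_stopwords(lemmatize(tokenize_and_split(n), lemma_table), stopwords)
        for n in notes
    ]
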