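import pytest
from hypothesis import HealthCheck, settings

from radtriage.bayes_classifier import train
from radtriage.synthetic_reports import (
    SyntheticCorpusSpec,
    generate_corpus,
    generate_training_pair,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

TRAIN_SEED = 11
TEST_SEED = 42


@pytest.fixture(scope="session")
def training_corpus():
    return generate_training_pair(seed=TRAIN_SEED)


@pytest.fixture(scope="session")
def trained_model(training_corpus):
    return train(training_corpus)


@pytest.fixture(scope="session")
def test_corpus_with_meta():
    return generate_corpus(SyntheticCorpusSpec(seed=TEST_SEED), return_metadata=True)


@pytest.fixture(scope="session")
def test_corpus(test_corpus_with_meta):
    corpus, _meta = test_corpus_with_meta
    return corpus
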