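import numpy as np
import pytest
from hypothesis import settings

import mibot
from mibot.nlu import ABSTAINED, Prediction, normalize_text
from mibot.simulator import ZERO_NOISE, UtteranceGrammar, generate_corpus

settings.register_profile("suite", derandomize=True, max_examples=60)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def full_taxonomy():
    return mibot.load_full_taxonomy()


@pytest.fixture(scope="session")
def seed_taxonomy():
    return mibot.load_seed_taxonomy()


@pytest.fixture(scope="session")
def grammar():
    return UtteranceGrammar.load()


@pytest.fixture(scope="session")
def full_corpus(full_taxonomy, grammar):
    """Noiseless synthetic corpus over every category-polarity pair."""
    return generate_corpus(full_taxonomy, 10, noise=ZERO_NOISE, seed=11,
                           grammar=grammar)


@pytest.fixture(scope="session")
def full_model(full_taxonomy, full_corpus):
    return mibot.train_classifier(full_corpus, full_taxonomy, seed=0)


class StubClassifier:
    """Deterministic classifier stub: exact normalized-text lookup, else
    abstention. Lets dialogue tests pin the labels a conversation sees."""

    def __init__(self, mapping: dict[str, str], confidence: float = 0.9):
        self.mapping = {
            " ".join(normalize_text(k)): v for k, v in mapping.items()
        }
        self.confidence = confidence

    def __call__(self, text: str) -> Prediction:
        key = " ".join(normalize_text(text))
        if key in self.mapping:
            return Prediction("detected", self.mapping[key], self.confidence)
        return ABSTAINED


@pytest.fixture
def stub_classifier():
    return StubClassifier
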