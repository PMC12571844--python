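import numpy as np
import pytest

from ohcmatch import (ExpertMatchingModel, GeneratorConfig, TrainConfig,
                      generate_corpus)


TINY_GEN = dict(n_interactions=120, n_patients=60, n_physicians=15,
                title_len_mean=6.0, content_len_mean=20.0, reply_len_mean=8.0,
                mean_replies=10.0, signal_strength=0.8)


@pytest.fixture(scope="session")
def tiny_corpus():
    """Small but fully structured corpus shared by read-only tests."""
    corpus, latent = generate_corpus(GeneratorConfig(**TINY_GEN, seed=11))
    return corpus, latent


@pytest.fixture(scope="session")
def tiny_results(tiny_corpus):
    """A fitted model on the tiny corpus (1 epoch: structure, not skill)."""
    corpus, _ = tiny_corpus
    model = ExpertMatchingModel(corpus, train_config=TrainConfig(seed=3,
                                                                 epochs=1))
    return model.fit(seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
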