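import numpy as np
import pytest

from rrg.model import ModelConfig, VEDModel
from rrg.synthetic import CorpusConfig, generate_corpus
from rrg.text import build_vocabulary


@pytest.fixture(scope="session")
def small_corpus():
    """A 24/8/8-study corpus shared by unit tests (read-only)."""
    return generate_corpus(CorpusConfig(n_train=24, n_validation=8, n_test=8),
                           seed=123)


@pytest.fixture(scope="session")
def small_vocab(small_corpus):
    return build_vocabulary(s.report.text for s in small_corpus.train)


@pytest.fixture(scope="session")
def tiny_model(small_vocab):
    """Small untrained model for contract tests (shared, never mutated)."""
    cfg = ModelConfig(vocab_size=len(small_vocab), dim=32, enc_depth=1,
                      enc_heads=2, dec_layers=2, dec_heads=2, max_len=32)
    return VEDModel(cfg, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
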