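import numpy as np
import pytest

from qdsum.config import tiny_config
from qdsum.corpus import make_batch
from qdsum.model import Summarizer
from qdsum.synthetic_data import SynthConfig, generate_corpus, model_vocabulary

TINY_SYNTH = dict(
    vocab_size=120, n_examples=8, mean_question_len=6, mean_summary_len=8,
    mean_n_sentences=3, mean_doc_len=18, copy_rate=0.6, oov_rate=0.2, seed=11,
)


@pytest.fixture(scope="session")
def tiny_corpus():
    return generate_corpus(SynthConfig(**TINY_SYNTH))


@pytest.fixture(scope="session")
def tiny_vocab():
    return model_vocabulary(SynthConfig(**TINY_SYNTH))


@pytest.fixture(scope="session")
def tiny_batch(tiny_corpus, tiny_vocab):
    return make_batch(tiny_corpus, tiny_vocab)


@pytest.fixture(scope="session")
def tiny_model(tiny_vocab):
    return Summarizer(len(tiny_vocab), tiny_config(), seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
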