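import numpy as np
import pytest

from bionerkit.char_lm import LMConfig, train_lm
from bionerkit.core_types import Sentence
from bionerkit.synthetic_data import GeneratorSpec, generate_corpus, generate_lm_text


def make_sentence(words, doc_id="doc"):
    return Sentence.from_words(words, doc_id=doc_id)


@pytest.fixture(scope="session")
def template_text():
    return generate_lm_text("", "template", 6000, seed=5)


@pytest.fixture(scope="session")
def tiny_lms(template_text):
    """A trained forward/backward char-LM pair (small, shared per session)."""
    cfg = LMConfig(char_embedding_dim=8, hidden_dim=16, epochs=4, seed=5)
    fwd = train_lm(template_text, cfg, direction="forward")
    bwd = train_lm(template_text, cfg, direction="backward")
    return fwd, bwd


@pytest.fixture(scope="session")
def gene_corpus():
    return generate_corpus(GeneratorSpec(name="genes", n_train=50, n_dev=10, n_test=10, seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
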