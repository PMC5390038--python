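import numpy as np
import pytest

from mwulex.corpus_io import Corpus, Utterance


def random_corpus(rng: np.random.Generator, n_utterances: int = 50,
                  vocab: int = 30, max_len: int = 8) -> Corpus:
    """A corpus of random utterances over a small Zipf-ish vocabulary."""
    words = [f"w{i}" for i in range(vocab)]
    weights = 1.0 / np.arange(1, vocab + 1)
    weights /= weights.sum()
    utts = []
    for k in range(n_utterances):
        length = int(rng.integers(1, max_len + 1))
        toks = tuple(rng.choice(words, size=length, p=weights))
        utts.append(Utterance(tokens=toks, source_line=k + 1))
    return Corpus(utterances=utts, label="random")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_corpus():
    lines = ["that's right", "oh dear", "sit down", "sit down",
             "oh dear me", "right you are"]
    return Corpus([Utterance(tuple(l.split()), i + 1) for i, l in enumerate(lines)])
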