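import pytest

from chemtagger.document import Token, TokenSequence
from chemtagger.ngram import default_model


def make_sequence(words: list[str], offset: int = 0) -> TokenSequence:
    """Build a space-joined TokenSequence from surfaces (test convenience)."""
    text = " ".join(words)
    tokens = []
    pos = 0
    for i, w in enumerate(words):
        tokens.append(Token(surface=w, start=offset + pos, end=offset + pos + len(w), index=i))
        pos += len(w) + 1
    return TokenSequence(text=text, offset=offset, tokens=tuple(tokens))


@pytest.fixture(scope="session")
def fixture_ngram_model():
    """N-gram model trained on the packaged fixture word lists."""
    return default_model()


@pytest.fixture(scope="session")
def tiny_ngram_model():
    """Model from a handful of words, for fast oracle-style checks."""
    from chemtagger.ngram import build_word_lists, train

    lists = build_word_lists(
        {"benzene", "toluene", "pyridine"}, {"house", "mouse", "about"}
    )
    return train(lists)
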