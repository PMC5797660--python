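import pytest

from xsit import Corpus, GoldLexicon, Situation, build_vocabulary, tokenize_utterance

OBJECTS = frozenset({"book", "bird", "rattle", "face"})


@pytest.fixture
def worked_example():
    """Two consecutive situations from a mother-infant book-reading exchange:
    same attended object <book>, utterances of seven and six words."""
    s1 = Situation(
        index=1,
        words=tokenize_utterance("ahhah look we can read books david"),
        visible_objects=OBJECTS,
        attended_object="book",
    )
    s2 = Situation(
        index=2,
        words=tokenize_utterance("its a look and see book"),
        visible_objects=OBJECTS,
        attended_object="book",
    )
    return s1, s2


@pytest.fixture
def worked_corpus(worked_example):
    corpus = Corpus.from_situations(worked_example)
    return corpus, build_vocabulary(corpus)


@pytest.fixture
def toy_corpus():
    """Three situations over two objects with fully-observed naming."""
    sits = [
        Situation(1, ("look", "a", "ball"), {"ball", "cup"}, "ball"),
        Situation(2, ("the", "cup", "there"), {"ball", "cup"}, "cup"),
        Situation(3, ("ball", "again"), {"ball"}, "ball"),
    ]
    corpus = Corpus.from_situations(sits)
    return corpus, build_vocabulary(corpus)


@pytest.fixture
def toy_gold():
    return GoldLexicon({("ball", "ball"), ("cup", "cup")})
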