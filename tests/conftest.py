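import pytest

from epilex import (
    Corpus,
    GroupSpec,
    LabelSpace,
    LabelingEvent,
    build_switch_corpus,
)


@pytest.fixture
def space3() -> LabelSpace:
    return LabelSpace(("buk", "puk", "duk"))


@pytest.fixture
def adult() -> GroupSpec:
    return GroupSpec("adult", 0.80)


@pytest.fixture
def audio() -> GroupSpec:
    return GroupSpec("audio", 0.15)


@pytest.fixture
def single_speaker_corpus() -> Corpus:
    """One speaker, seven identical 'buk' tokens."""
    return build_switch_corpus("single", tokens=7)


@pytest.fixture
def multi_speaker_corpus() -> Corpus:
    """Seven distinct speakers, one 'buk' token each."""
    return build_switch_corpus("multiple", tokens=7)


@pytest.fixture
def disagreement_corpus(space3) -> Corpus:
    """Two speakers naming the same object differently (buk vs puk)."""
    return Corpus(
        events=(
            LabelingEvent("a", "g", "obj", "buk"),
            LabelingEvent("b", "g", "obj", "puk"),
        ),
        label_space=space3,
    )
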