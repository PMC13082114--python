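import numpy as np
import pytest

from uorfded.annotation import Span, TranscriptModel, UORFCompilation, UORFRecord


@pytest.fixture
def toy_transcript() -> TranscriptModel:
    """utr5 [0,30), morf [30,330), utr3 [330,400)."""
    return TranscriptModel("TOY1", 400, Span(0, 30), Span(30, 330), Span(330, 400))


@pytest.fixture
def toy_uorf() -> UORFRecord:
    return UORFRecord("uorf1", "TOY1", Span(6, 15), "AUG", frozenset({"test"}))


@pytest.fixture
def toy_annotation(toy_transcript, toy_uorf):
    return {toy_transcript.transcript_id: toy_transcript}, UORFCompilation((toy_uorf,), ("test",))


def make_compilation(records):
    return UORFCompilation(tuple(records))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
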