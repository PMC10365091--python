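import numpy as np
import pytest

from gazemil.gaze_data import Fixation, ReadingSession, Sentence, TranscriptWord
from gazemil.report_labeler import load_vocabulary


@pytest.fixture(scope="session")
def vocab():
    return load_vocabulary()


def make_sentence(index, text, start, word_duration=0.4, gap=0.05):
    """Build a Sentence with evenly spaced word timestamps."""
    words = []
    t = start
    for token in text.split():
        words.append(TranscriptWord(token, t, t + word_duration))
        t += word_duration + gap
    return Sentence(index, tuple(words))


def make_session(sentences, fixations=(), size=128, recording_start=0.0, ppd=20.0):
    return ReadingSession(
        image_id="test",
        image_width=size,
        image_height=size,
        fixations=list(fixations),
        sentences=list(sentences),
        recording_start=recording_start,
        pixels_per_degree=ppd,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_sentence_session():
    """Two dictated sentences with fixations spread over the recording."""
    s0 = make_sentence(0, "the lungs are clear .".replace(" .", "."), 10.0)
    s1 = make_sentence(1, "there is cardiomegaly.", 14.0)
    fixations = [
        Fixation(20.0 + i, 30.0, 0.5 * i, 0.5 * i + 0.4, pixels_per_degree=10.0)
        for i in range(36)
    ]
    return make_session([s0, s1], fixations)
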