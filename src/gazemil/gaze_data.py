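"""Data model and readers for eye-tracking reading sessions.

A *reading session* is one radiologist reading one radiograph while
dictating a report: a table of gaze fixations (where the gaze was
stabilized, and when) plus a word-level timestamped transcript of the
dictation. Sessions arrive pre-fixated, i.e. raw gaze samples have
already been collapsed into fixations by the eye tracker, as in the
public chest-radiograph eye-tracking datasets this layout mirrors.

Times are seconds as floats throughout; readers convert from
milliseconds when the dialect declares it. Image coordinates are
0-based with pixel-center convention; fixation ``(x, y)`` indexes
(column, row).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import pandas as pd

logger = logging.getLogger(__name__)

#: Sentence-final punctuation used by :func:`segment_sentences`.
SENTENCE_FINAL = (".", "?", "!")


class GazeDataError(ValueError):
    """Malformed or inconsistent gaze/transcript input."""


@dataclass(frozen=True)
class Fixation:
    """A period of stabilized gaze at one image location.

    Parameters
    ----------
    x, y:
        Position in image pixel coordinates (column, row).
    start, end:
        Onset/offset in seconds; ``end >= start``.
    pixels_per_degree:
        Optional angular calibration for this fixation (pixels per
        degree of visual angle); used as the Gaussian sigma when
        rendering heatmaps.
    """

    x: float
    y: float
    start: float
    end: float
    pixels_per_degree: float | None = None

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise GazeDataError(
                f"fixation end {self.end} precedes start {self.start}"
            )

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class TranscriptWord:
    """One dictated word with its utterance interval in seconds."""

    text: str
    start: float
    end: float

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise GazeDataError(
                f"word {self.text!r}: end {self.end} precedes start {self.start}"
            )


@dataclass(frozen=True)
class Sentence:
    """An ordered run of transcript words forming one dictated sentence."""

    index: int
    words: tuple[TranscriptWord, ...]

    def __post_init__(self) -> None:
        if not self.words:
            raise GazeDataError("sentence must contain at least one word")

    @property
    def start(self) -> float:
        return self.words[0].start

    @property
    def end(self) -> float:
        return self.words[-1].end

    @property
    def text(self) -> str:
        return " ".join(w.text for w in self.words)


@dataclass
class ReadingSession:
    """One image reading: fixations plus the timestamped dictation."""

    image_id: str
    image_width: int
    image_height: int
    fixations: list[Fixation] = field(default_factory=list)
    sentences: list[Sentence] = field(default_factory=list)
    recording_start: float = 0.0
    pixels_per_degree: float | None = None

    def __post_init__(self) -> None:
        self.fixations = sorted(self.fixations, key=lambda f: f.start)
        for f in self.fixations:
            if f.start < self.recording_start:
                raise GazeDataError(
                    f"fixation at t={f.start} precedes recording start "
                    f"{self.recording_start}"
                )
        starts = [s.start for s in self.sentences]
        if starts != sorted(starts):
            raise GazeDataError("sentences are not ordered by start time")
        for a, b in zip(self.sentences, self.sentences[1:]):
            if b.start < a.end:
                raise GazeDataError(
                    f"sentences {a.index} and {b.index} overlap in time"
                )

    def out_of_bounds_fixations(self) -> list[int]:
        """Indices of fixations falling outside the image rectangle."""
        return [
            i
            for i, f in enumerate(self.fixations)
            if not (0 <= f.x < self.image_width and 0 <= f.y < self.image_height)
        ]


@dataclass(frozen=True)
class FixationDialect:
    """Column mapping for delimited fixation tables.

    The default matches the column names used by public reading-session
    datasets for chest radiographs (``x_position`` etc.). ``time_unit``
    may be ``"s"`` or ``"ms"``.
    """

    x: str = "x_position"
    y: str = "y_position"
    start: str = "timestamp_start_fixation"
    end: str = "timestamp_end_fixation"
    pixels_per_degree: str | None = "angular_resolution_x_pixels_per_degree"
    time_unit: str = "s"

    def time_scale(self) -> float:
        if self.time_unit == "s":
            return 1.0
        if self.time_unit == "ms":
            return 1e-3
        raise GazeDataError(f"unknown time unit {self.time_unit!r}")


DEFAULT_DIALECT = FixationDialect()

#: Compact dialect used by the synthetic-data writer.
SIMPLE_DIALECT = FixationDialect(
    x="x", y="y", start="start", end="end", pixels_per_degree=None
)


def read_fixations(
    path, dialect: FixationDialect = DEFAULT_DIALECT
) -> list[Fixation]:
    """Read a delimited fixation table, returning fixations sorted by onset.

    Rows violating the ``end >= start`` invariant or containing
    non-finite/non-numeric cells are dropped with a warning naming the
    row. A missing mandatory column raises :class:`GazeDataError`.
    """
    df = pd.read_csv(path)
    mandatory = [dialect.x, dialect.y, dialect.start, dialect.end]
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise GazeDataError(f"{path}: missing mandatory column(s) {missing}")
    scale = dialect.time_scale()
    has_ppd = (
        dialect.pixels_per_degree is not None
        and dialect.pixels_per_degree in df.columns
    )
    out: list[Fixation] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        rec = dict(zip(df.columns, row))
        try:
            x = float(rec[dialect.x])
            y = float(rec[dialect.y])
            t0 = float(rec[dialect.start]) * scale
            t1 = float(rec[dialect.end]) * scale
        except (TypeError, ValueError) as exc:
            raise GazeDataError(
                f"{path}: non-numeric cell in row {row_no}: {exc}"
            ) from exc
        if t1 < t0:
            warnings.warn(
                f"{path}: row {row_no} has end < start ({t1} < {t0}); dropped",
                stacklevel=2,
            )
            continue
        ppd = float(rec[dialect.pixels_per_degree]) if has_ppd else None
        if ppd is not None and not ppd == ppd:  # NaN cell
            ppd = None
        out.append(Fixation(x, y, t0, t1, pixels_per_degree=ppd))
    out.sort(key=lambda f: f.start)
    return out


def write_fixations(
    fixations: list[Fixation], path, dialect: FixationDialect = DEFAULT_DIALECT
) -> None:
    """Write fixations as CSV in the given dialect (inverse of the reader)."""
    scale = dialect.time_scale()
    cols = {
        dialect.x: [f.x for f in fixations],
        dialect.y: [f.y for f in fixations],
        dialect.start: [f.start / scale for f in fixations],
        dialect.end: [f.end / scale for f in fixations],
    }
    if dialect.pixels_per_degree is not None:
        cols[dialect.pixels_per_degree] = [
            f.pixels_per_degree for f in fixations
        ]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.6f")


def read_transcript(path) -> list[TranscriptWord]:
    """Read a word-level transcript CSV with ``word,start,end`` columns."""
    df = pd.read_csv(path, keep_default_na=False)
    missing = [c for c in ("word", "start", "end") if c not in df.columns]
    if missing:
        raise GazeDataError(f"{path}: missing transcript column(s) {missing}")
    words = [
        TranscriptWord(str(w), float(s), float(e))
        for w, s, e in zip(df["word"], df["start"], df["end"])
    ]
    if any(b.start < a.start for a, b in zip(words, words[1:])):
        raise GazeDataError(f"{path}: transcript words not ordered by start")
    return words


def write_transcript(words: list[TranscriptWord], path) -> None:
    pd.DataFrame(
        {
            "word": [w.text for w in words],
            "start": [w.start for w in words],
            "end": [w.end for w in words],
        }
    ).to_csv(path, index=False, float_format="%.6f")


def segment_sentences(words: list[TranscriptWord]) -> list[Sentence]:
    """Split an ordered word list into sentences.

    A sentence ends after any token ending in sentence-final punctuation
    (``.``, ``?``, ``!``); trailing unpunctuated words form a final
    sentence. Word count is conserved.
    """
    sentences: list[Sentence] = []
    current: list[TranscriptWord] = []
    for w in words:
        current.append(w)
        if w.text.rstrip().endswith(SENTENCE_FINAL):
            sentences.append(Sentence(len(sentences), tuple(current)))
            current = []
    if current:
        sentences.append(Sentence(len(sentences), tuple(current)))
    return sentences


def shift_session_times(session: ReadingSession, offset: float) -> ReadingSession:
    """Return a copy of ``session`` with all times shifted by ``offset``."""
    fix = [
        replace(f, start=f.start + offset, end=f.end + offset)
        for f in session.fixations
    ]
    sents = [
        Sentence(
            s.index,
            tuple(
                TranscriptWord(w.text, w.start + offset, w.end + offset)
                for w in s.words
            ),
        )
        for s in session.sentences
    ]
    return ReadingSession(
        image_id=session.image_id,
        image_width=session.image_width,
        image_height=session.image_height,
        fixations=fix,
        sentences=sents,
        recording_start=session.recording_start + offset,
        pixels_per_degree=session.pixels_per_degree,
    )
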