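"""Rule-based detection of abnormality-label mentions in dictated reports.

Finds, per sentence, which of the ten study labels are mentioned and
whether the mention is negated, and records the utterance end times of
the first and last matched phrase — the timestamps that the fixation
window rule keys on. This is a transparent phrase/negation matcher with
a shipped, editable vocabulary grouping the public datasets' source
terms into the ten study labels (e.g. "cardiomegaly" asserts Enlarged
Cardiac Silhouette; "pulmonary edema" asserts both Edema and Opacity);
it is intentionally simple, configuration-driven and versioned rather
than a full report-parsing rule engine.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import yaml

from .gaze_data import Sentence

#: The ten study labels, in canonical order.
STUDY_LABELS = (
    "Abnormal Mediastinal Contour",
    "Atelectasis",
    "Enlarged Cardiac Silhouette",
    "Consolidation",
    "Edema",
    "Fracture",
    "Lung Lesion",
    "Opacity",
    "Pleural Abnormality",
    "Pneumothorax",
)

DEFAULT_NEGATION_CUES = (
    "no",
    "not",
    "without",
    "negative for",
    "clear of",
    "free of",
    "absence of",
)

_WORD_RE = re.compile(r"[a-z0-9']+")


@dataclass(frozen=True)
class LabelVocabulary:
    """Match/unmatch phrases for one label.

    ``match_phrases`` assert the label; an ``unmatch_phrase`` blocks any
    match it contains (e.g. "mass effect" blocks "mass").
    ``negation_cues`` defaults to the shared cue list.
    """

    label: str
    match_phrases: tuple[str, ...]
    unmatch_phrases: tuple[str, ...] = ()
    negation_cues: tuple[str, ...] = DEFAULT_NEGATION_CUES


@dataclass(frozen=True)
class Mention:
    """All matches of one label within one sentence, merged.

    ``span`` is the (start, stop) word-index range covering every
    matched phrase of the label in the sentence; ``first_mention_end``
    and ``last_mention_end`` are the utterance end times (seconds) of
    the first and last matched phrase.
    """

    label: str
    sentence_index: int
    span: tuple[int, int]
    first_mention_end: float
    last_mention_end: float
    negated: bool
    hedged: bool = False

    def __post_init__(self) -> None:
        if self.last_mention_end < self.first_mention_end:
            raise ValueError("last_mention_end precedes first_mention_end")
        if not 0 <= self.span[0] < self.span[1]:
            raise ValueError(f"invalid span {self.span}")


@dataclass
class Vocabulary:
    """The full labeler configuration: one entry per label plus cue lists."""

    entries: dict[str, LabelVocabulary]
    negation_cues: tuple[str, ...] = DEFAULT_NEGATION_CUES
    hedge_cues: tuple[str, ...] = ()
    drop_hedged: bool = False

    labels = property(lambda self: tuple(self.entries))


def load_vocabulary(path=None) -> Vocabulary:
    """Load a vocabulary YAML; with no path, the shipped default."""
    if path is None:
        text = (
            resources.files("gazemil.data")
            .joinpath("label_vocabulary.yaml")
            .read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    neg = tuple(raw.get("negation_cues", DEFAULT_NEGATION_CUES))
    hedge = tuple(raw.get("hedge_cues", ()))
    entries = {}
    for label, spec in raw["labels"].items():
        entries[label] = LabelVocabulary(
            label=label,
            match_phrases=tuple(p.lower() for p in spec.get("match", ())),
            unmatch_phrases=tuple(p.lower() for p in spec.get("unmatch", ())),
            negation_cues=neg,
        )
    return Vocabulary(entries=entries, negation_cues=neg, hedge_cues=hedge)


def _tokens(sentence: Sentence) -> list[str]:
    """Lowercased alphanumeric tokens, one per transcript word."""
    out = []
    for w in sentence.words:
        m = _WORD_RE.findall(w.text.lower())
        out.append("".join(m))
    return out


def _phrase_tokens(phrase: str) -> list[str]:
    return _WORD_RE.findall(phrase.lower())


def _find_spans(tokens: list[str], phrase: str) -> list[tuple[int, int]]:
    """All (start, stop) word-index spans where ``phrase`` occurs."""
    pt = _phrase_tokens(phrase)
    n = len(pt)
    if n == 0:
        return []
    return [
        (i, i + n)
        for i in range(len(tokens) - n + 1)
        if tokens[i : i + n] == pt
    ]


def detect_negation(
    sentence: Sentence,
    span: tuple[int, int],
    cues: tuple[str, ...] = DEFAULT_NEGATION_CUES,
) -> bool:
    """True iff a negation cue precedes ``span`` within the sentence.

    Sentences are the scope unit: a cue anywhere before the span (with
    no intervening sentence-final punctuation, which by construction
    only the last token can carry) negates the span.
    """
    if not 0 <= span[0] < span[1] <= len(sentence.words):
        raise ValueError(f"span {span} outside sentence of {len(sentence.words)} words")
    tokens = _tokens(sentence)
    for cue in cues:
        for c0, c1 in _find_spans(tokens, cue):
            if c1 <= span[0]:
                return True
    return False


def _detect_hedge(tokens: list[str], cues: tuple[str, ...]) -> bool:
    return any(_find_spans(tokens, cue) for cue in cues)


def find_mentions(
    sentences: list[Sentence], vocab: Vocabulary
) -> list[Mention]:
    """Detect label mentions (with negation) in segmented sentences.

    Matching is longest-phrase-first per label: a token consumed by a
    longer phrase of a label is not re-matched by a shorter phrase of
    the same label. Different labels match independently, so a phrase
    grouped under two labels yields one mention per label sharing the
    span. All matches of one label in one sentence merge into a single
    :class:`Mention`; the merged mention is negated only if every
    contributing match is negated. Deterministic for fixed inputs.
    """
    if not vocab.entries:
        raise ValueError("vocabulary is empty")
    mentions: list[Mention] = []
    for sentence in sentences:
        tokens = _tokens(sentence)
        hedged = _detect_hedge(tokens, vocab.hedge_cues)
        for label, entry in vocab.entries.items():
            blocked: list[tuple[int, int]] = []
            for up in entry.unmatch_phrases:
                blocked.extend(_find_spans(tokens, up))
            consumed: set[int] = set()
            matches: list[tuple[int, int]] = []
            for phrase in sorted(
                entry.match_phrases, key=lambda p: -len(_phrase_tokens(p))
            ):
                for s0, s1 in _find_spans(tokens, phrase):
                    if any(i in consumed for i in range(s0, s1)):
                        continue
                    if any(b0 <= s0 and s1 <= b1 for b0, b1 in blocked):
                        continue
                    consumed.update(range(s0, s1))
                    matches.append((s0, s1))
            if not matches:
                continue
            matches.sort()
            negs = [
                detect_negation(sentence, m, entry.negation_cues)
                for m in matches
            ]
            if vocab.drop_hedged and hedged and not all(negs):
                continue
            span = (min(m[0] for m in matches), max(m[1] for m in matches))
            ends = sorted(sentence.words[m[1] - 1].end for m in matches)
            mentions.append(
                Mention(
                    label=label,
                    sentence_index=sentence.index,
                    span=span,
                    first_mention_end=ends[0],
                    last_mention_end=ends[-1],
                    negated=all(negs),
                    hedged=hedged,
                )
            )
    mentions.sort(key=lambda m: (m.sentence_index, m.label))
    return mentions


def positive_mentions(mentions: list[Mention]) -> list[Mention]:
    """Mentions asserting presence — the only ones that drive heatmaps."""
    return [m for m in mentions if not m.negated]
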