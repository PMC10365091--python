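"""Label-specific gaze heatmaps from dictation-aligned fixation windows.

Radiologists' gaze leads their speech: while dictating a sentence about
a finding they have typically already been looking at it, starting
roughly 1.5 s before the sentence — or during the previous sentence,
whichever window is shorter. The extraction here exploits that: for
each positive label mention it selects the fixations inside a temporal
window anchored on the mentioning sentence, renders them as a sum of
duration-weighted Gaussians (sigma = one degree of visual angle), and
max-aggregates per-mention maps into one heatmap per label.

The window is a :class:`WindowPolicy`; the default reproduces
``max(previous sentence start, sentence start - 1.5 s)`` →
``last mention end``. :func:`sweep_policies` evaluates grids of
policies against gold masks, mirroring the two-stage delay validation
used to select 1.5 s.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from enum import Enum

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .gaze_data import Fixation, ReadingSession
from .report_labeler import Mention

#: Default angular calibration: pixels per degree of visual angle at the
#: 512-px working resolution. Scale proportionally for other sizes.
DEFAULT_PIXELS_PER_DEGREE = 85.0

#: Gaussians are truncated at this many sigmas when rendered; the
#: omitted tail is < 3.4e-4 of the peak.
TRUNCATE_SIGMAS = 4.0

#: Delay grids of the two-stage window validation.
STAGE1_DELAYS = (2.5, 5.0, 7.5)
STAGE2_DELAYS = (0.5, 0.75, 1.0, 1.25, 1.5, 1.75, 2.0, 2.5, 3.0, 3.5, 4.0, 4.5, 5.0)

DEFAULT_THRESHOLD_GRID = tuple(np.round(np.arange(0.05, 1.0, 0.05), 2))


class StartRule(str, Enum):
    """How the window's start time is anchored."""

    MENTION_SENTENCE_START_MINUS_DELAY_CAPPED_PREV = (
        "mention_sentence_start_minus_delay_capped_prev"
    )
    FIRST_MENTION_MINUS_DELAY_CAPPED_PREV = "first_mention_minus_delay_capped_prev"
    SENTENCE_END_MINUS_DELAY_CAPPED_PREV = "sentence_end_minus_delay_capped_prev"
    REPORT_START = "report_start"
    PREV_SENTENCE_START = "prev_sentence_start"
    PREV_SENTENCE_END = "prev_sentence_end"
    MENTION_SENTENCE_START = "mention_sentence_start"
    RECORDING_START = "recording_start"


class EndRule(str, Enum):
    MENTION_SENTENCE_START = "mention_sentence_start"
    MENTION_SENTENCE_END = "mention_sentence_end"
    FIRST_MENTION_END = "first_mention_end"
    LAST_MENTION_END = "last_mention_end"


@dataclass(frozen=True)
class WindowPolicy:
    """A (start rule, end rule, delay) triple defining fixation windows."""

    start_rule: StartRule = StartRule.MENTION_SENTENCE_START_MINUS_DELAY_CAPPED_PREV
    end_rule: EndRule = EndRule.LAST_MENTION_END
    delay: float = 1.5

    def __post_init__(self) -> None:
        if self.delay < 0:
            raise ValueError(f"delay must be >= 0, got {self.delay}")


DEFAULT_POLICY = WindowPolicy()


@dataclass
class GazeHeatmap:
    """Per-label continuous map in image space, values in [0, 1]."""

    label: str
    map: np.ndarray
    n_fixations: int

    def __post_init__(self) -> None:
        self.map = np.asarray(self.map, dtype=np.float64)
        if self.map.min() < 0 or self.map.max() > 1 + 1e-12:
            raise ValueError("heatmap values must lie in [0, 1]")
        # off-image fixations can leave the map empty; otherwise peak is 1
        if self.map.max() > 0 and not np.isclose(self.map.max(), 1.0):
            raise ValueError("non-empty heatmap must have max 1")


def mention_window(
    session: ReadingSession, mention: Mention, policy: WindowPolicy = DEFAULT_POLICY
) -> tuple[float, float]:
    """Window (t0, t1) of fixations attributed to ``mention``.

    For the first sentence, "previous sentence" anchors fall back to the
    recording start. ``t1 < t0`` denotes an empty window.
    """
    try:
        sent = session.sentences[mention.sentence_index]
    except IndexError as exc:
        raise KeyError(
            f"mention references sentence {mention.sentence_index}, "
            f"session has {len(session.sentences)}"
        ) from exc
    if mention.sentence_index > 0:
        prev = session.sentences[mention.sentence_index - 1]
        prev_start, prev_end = prev.start, prev.end
    else:
        prev_start = prev_end = session.recording_start

    r = policy.start_rule
    if r is StartRule.MENTION_SENTENCE_START_MINUS_DELAY_CAPPED_PREV:
        t0 = max(prev_start, sent.start - policy.delay)
    elif r is StartRule.FIRST_MENTION_MINUS_DELAY_CAPPED_PREV:
        t0 = max(prev_start, mention.first_mention_end - policy.delay)
    elif r is StartRule.SENTENCE_END_MINUS_DELAY_CAPPED_PREV:
        t0 = max(prev_start, sent.end - policy.delay)
    elif r is StartRule.REPORT_START:
        t0 = session.sentences[0].start
    elif r is StartRule.PREV_SENTENCE_START:
        t0 = prev_start
    elif r is StartRule.PREV_SENTENCE_END:
        t0 = prev_end
    elif r is StartRule.MENTION_SENTENCE_START:
        t0 = sent.start
    elif r is StartRule.RECORDING_START:
        t0 = session.recording_start
    else:  # pragma: no cover
        raise ValueError(f"unknown start rule {r}")

    e = policy.end_rule
    if e is EndRule.MENTION_SENTENCE_START:
        t1 = sent.start
    elif e is EndRule.MENTION_SENTENCE_END:
        t1 = sent.end
    elif e is EndRule.FIRST_MENTION_END:
        t1 = mention.first_mention_end
    elif e is EndRule.LAST_MENTION_END:
        t1 = mention.last_mention_end
    else:  # pragma: no cover
        raise ValueError(f"unknown end rule {e}")
    return (t0, t1)


def select_fixations(
    session: ReadingSession, t0: float, t1: float
) -> list[Fixation]:
    """Fixations with strictly positive overlap with [t0, t1].

    Returned fixations have their intervals clipped to the window, so
    their durations equal the overlap length (partial overlaps count
    partially rather than all-or-nothing).
    """
    if t1 < t0:
        return []
    out = []
    for f in session.fixations:
        lo, hi = max(f.start, t0), min(f.end, t1)
        if hi - lo > 0:
            out.append(replace(f, start=lo, end=hi))
    return out


def render_heatmap(
    fixations: list[Fixation],
    image_shape: tuple[int, int],
    sigma: float | None = None,
) -> np.ndarray:
    """Sum duration-weighted Gaussians at fixation locations, max-normalized.

    Each fixation contributes ``duration * exp(-r^2 / (2 sigma_f^2))``
    centred at its location, with ``sigma_f`` its own pixels-per-degree
    calibration when present, else ``sigma``. The summed map is divided
    by its maximum so the peak equals 1; with no fixations the map is
    all zeros. Gaussians are truncated at 4 sigma.
    """
    h, w = image_shape
    if h <= 0 or w <= 0:
        raise ValueError(f"non-positive image shape {image_shape}")
    acc = np.zeros((h, w), dtype=np.float64)
    for f in fixations:
        s = f.pixels_per_degree if f.pixels_per_degree is not None else sigma
        if s is None:
            s = DEFAULT_PIXELS_PER_DEGREE
        if s <= 0:
            raise ValueError(f"non-positive sigma {s}")
        r = TRUNCATE_SIGMAS * s
        x0, x1 = int(np.floor(f.x - r)), int(np.ceil(f.x + r)) + 1
        y0, y1 = int(np.floor(f.y - r)), int(np.ceil(f.y + r)) + 1
        x0, x1 = max(x0, 0), min(x1, w)
        y0, y1 = max(y0, 0), min(y1, h)
        if x0 >= x1 or y0 >= y1:
            continue
        xs = np.arange(x0, x1) - f.x
        ys = np.arange(y0, y1) - f.y
        g = np.exp(-(ys[:, None] ** 2 + xs[None, :] ** 2) / (2.0 * s * s))
        acc[y0:y1, x0:x1] += f.duration * g
    peak = acc.max()
    if peak > 0:
        acc /= peak
    return acc


def heatmap_for_label(
    session: ReadingSession,
    label: str,
    mentions: list[Mention],
    policy: WindowPolicy = DEFAULT_POLICY,
    sigma: float | None = None,
) -> GazeHeatmap:
    """Combine per-mention maps of one label by pixelwise maximum.

    Each mention's map is rendered from its own window and normalized to
    max 1 before aggregation, so every mentioned location peaks at 1.
    Mentions must all carry ``label`` and be non-negated. Label mentions
    within one sentence were already merged by the labeler, so they
    share one window and one map by construction.
    """
    for m in mentions:
        if m.label != label:
            raise ValueError(f"mention label {m.label!r} != {label!r}")
        if m.negated:
            raise ValueError("negated mentions cannot drive heatmaps")
    shape = (session.image_height, session.image_width)
    if sigma is None:
        sigma = session.pixels_per_degree
    combined = np.zeros(shape, dtype=np.float64)
    n_fix = 0
    for m in mentions:
        t0, t1 = mention_window(session, m, policy)
        fixs = select_fixations(session, t0, t1)
        n_fix += len(fixs)
        combined = np.maximum(combined, render_heatmap(fixs, shape, sigma))
    return GazeHeatmap(label=label, map=combined, n_fixations=n_fix)


def whole_session_heatmap(
    session: ReadingSession, sigma: float | None = None
) -> np.ndarray:
    """Heatmap from every fixation of the session, ignoring dictation.

    The label-agnostic baseline: one pooled map for all labels of a
    case, against which label-specific extraction is compared.
    """
    if sigma is None:
        sigma = session.pixels_per_degree
    return render_heatmap(
        session.fixations, (session.image_height, session.image_width), sigma
    )


def binary_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection-over-union of two binary masks; empty union -> 0."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def sweep_policies(
    cases,
    start_rules=tuple(StartRule),
    end_rules=tuple(EndRule),
    delays=STAGE1_DELAYS,
    threshold_grid=DEFAULT_THRESHOLD_GRID,
    sigma: float | None = None,
) -> pd.DataFrame:
    """Grid-search window policies against gold masks.

    ``cases`` is an iterable of ``(session, mentions, masks)`` triples
    where ``masks`` maps each positive label to a binary gold mask at
    image resolution. For every policy whose windows are not all empty,
    heatmaps are extracted for each positive (case, label) pair and the
    binarization threshold maximizing the mean IoU over pairs is chosen
    from ``threshold_grid`` (ties toward the lower threshold); the row
    with the best mean IoU is flagged. Delays only apply to start rules
    that use one; delay-free rules contribute a single row with delay 0.
    """
    cases = list(cases)
    if not cases or all(not masks for _, _, masks in cases):
        raise ValueError("policy sweep requires cases with gold masks")
    thresholds = np.asarray(sorted(threshold_grid), dtype=np.float64)
    delayed = {
        StartRule.MENTION_SENTENCE_START_MINUS_DELAY_CAPPED_PREV,
        StartRule.FIRST_MENTION_MINUS_DELAY_CAPPED_PREV,
        StartRule.SENTENCE_END_MINUS_DELAY_CAPPED_PREV,
    }
    rows = []
    for sr in start_rules:
        sr_delays = delays if sr in delayed else (0.0,)
        for er in end_rules:
            for d in sr_delays:
                policy = WindowPolicy(start_rule=sr, end_rule=er, delay=d)
                per_thr = np.zeros_like(thresholds)
                n_pairs = 0
                n_windows = 0
                for session, mentions, masks in cases:
                    by_label: dict[str, list[Mention]] = {}
                    for m in mentions:
                        if not m.negated and m.label in masks:
                            by_label.setdefault(m.label, []).append(m)
                    for label, ms in by_label.items():
                        for m in ms:
                            t0, t1 = mention_window(session, m, policy)
                            if t1 >= t0:
                                n_windows += 1
                        hm = heatmap_for_label(
                            session, label, ms, policy, sigma=sigma
                        )
                        mask = np.asarray(masks[label], dtype=bool)
                        for i, thr in enumerate(thresholds):
                            per_thr[i] += binary_iou(hm.map > thr, mask)
                        n_pairs += 1
                if n_windows == 0 or n_pairs == 0:
                    continue  # duration < 0 for every mention: excluded
                per_thr /= n_pairs
                best_i = int(np.argmax(per_thr))  # argmax ties -> lower thr
                rows.append(
                    {
                        "start_rule": sr.value,
                        "end_rule": er.value,
                        "delay": d,
                        "best_threshold": float(thresholds[best_i]),
                        "mean_iou": float(per_thr[best_i]),
                        "n_pairs": n_pairs,
                    }
                )
    table = pd.DataFrame(rows)
    if len(table):
        table["is_best"] = False
        table.loc[table["mean_iou"].idxmax(), "is_best"] = True
    return table


def save_heatmap(hm: GazeHeatmap, png_path, meta: dict | None = None) -> None:
    """Write a heatmap as 16-bit PNG plus a JSON sidecar."""
    arr = np.round(hm.map * 65535.0).astype(np.uint16)
    iio.imwrite(png_path, arr)
    sidecar = dict(meta or {})
    sidecar.update({"label": hm.label, "n_fixations": hm.n_fixations})
    with open(str(png_path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1)


def load_heatmap(png_path) -> GazeHeatmap:
    arr = iio.imread(png_path).astype(np.float64) / 65535.0
    with open(str(png_path) + ".json") as fh:
        meta = json.load(fh)
    return GazeHeatmap(
        label=meta["label"], map=arr, n_fixations=meta["n_fixations"]
    )
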