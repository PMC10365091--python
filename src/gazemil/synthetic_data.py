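"""Synthetic reading sessions with known lesions, gaze and dictation.

Emulates the behavioural structure that dictation-aligned heatmap
extraction relies on, with every latent variable known:

* grayscale images with smooth background texture and additive
  elliptical intensity bumps at label-characteristic locations, each
  with its ground-truth binary mask;
* a dictated transcript: an initial silent scanning interval, then one
  short sentence per positive finding (using the labeler's own phrase
  vocabulary, so extraction closes the loop end to end), with silent
  pauses between sentences and occasional negated distractor sentences
  about absent findings;
* gaze: dispersed scanning fixations over the whole image outside
  mention periods, and fixations clustered on the mentioned lesion from
  ``gaze_lag`` seconds before the mentioning sentence until the mention
  ends — the gaze-leads-speech behaviour the window rule is built
  around. Fixation durations are log-normal.

Label grouping is honoured: phrases like "pulmonary edema" assert both
Edema and the umbrella Opacity label, so the generator closes positives
over the grouping (Opacity is positive, with the member lesion inside
its mask, whenever a member finding is) and the invariant "every
positive label has a mask and a mentioning sentence" holds exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import gaussian_filter

from .annotation_grid import rle_decode, rle_encode
from .gaze_data import (
    DEFAULT_DIALECT,
    Fixation,
    ReadingSession,
    TranscriptWord,
    read_fixations,
    read_transcript,
    segment_sentences,
    write_fixations,
    write_transcript,
)
from .report_labeler import STUDY_LABELS

#: Phrase dictated for each label (drawn from the labeler vocabulary).
GENERATOR_PHRASES = {
    "Abnormal Mediastinal Contour": "widened mediastinum",
    "Atelectasis": "atelectasis",
    "Enlarged Cardiac Silhouette": "cardiomegaly",
    "Consolidation": "consolidation",
    "Edema": "pulmonary edema",
    "Fracture": "acute fracture",
    "Lung Lesion": "lung nodule or mass",
    "Opacity": "lung opacity",
    "Pleural Abnormality": "pleural effusion",
    "Pneumothorax": "pneumothorax",
}

#: Labels whose phrases also assert the umbrella Opacity label.
OPACITY_MEMBERS = ("Edema", "Atelectasis", "Consolidation", "Lung Lesion")

#: Characteristic lesion location per label, as (x, y) image fractions.
#: Loosely anatomical (cardiac findings central-low, pneumothorax
#: apical, pleural findings lateral-basal); what matters for the study
#: design is that labels are spatially distinguishable.
LABEL_ANCHORS = {
    "Abnormal Mediastinal Contour": (0.50, 0.35),
    "Atelectasis": (0.30, 0.60),
    "Enlarged Cardiac Silhouette": (0.42, 0.68),
    "Consolidation": (0.72, 0.55),
    "Edema": (0.62, 0.38),
    "Fracture": (0.18, 0.40),
    "Lung Lesion": (0.78, 0.28),
    "Opacity": (0.35, 0.30),
    "Pleural Abnormality": (0.80, 0.78),
    "Pneumothorax": (0.22, 0.18),
}


@dataclass(frozen=True)
class SimParams:
    """Study conditions for the generator; defaults are the package's
    reference cohort (see docs/methods.md for rationale per parameter)."""

    n_cases: int = 50
    image_size: int = 128
    labels: tuple[str, ...] = STUDY_LABELS
    prevalence: float = 0.15
    lesion_radius_range: tuple[float, float] = (0.08, 0.18)
    gaze_lag: float = 1.5
    fixation_rate: float = 3.0
    on_lesion_dispersion: float = 0.06
    scan_fraction: float = 0.15
    speech_rate: float = 2.5
    inter_sentence_pause: float = 2.0
    initial_silence: float = 4.0
    negation_rate: float = 0.3
    lesion_contrast: tuple[float, float] = (0.3, 0.5)
    noise_sigma: float = 0.03
    #: one degree of visual angle as a fraction of image width. A
    #: radiograph viewed on a reading workstation spans roughly 20
    #: degrees, so one degree covers ~5% of the image.
    degree_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must lie in [0, 1]")
        if self.gaze_lag < 0:
            raise ValueError("gaze lag must be >= 0")
        if self.fixation_rate <= 0 or self.speech_rate <= 0:
            raise ValueError("rates must be > 0")

    @property
    def pixels_per_degree(self) -> float:
        """Per-fixation angular calibration written into the sessions."""
        return self.degree_fraction * self.image_size


@dataclass
class SyntheticCase:
    """One generated case with full ground truth."""

    case_id: str
    image: np.ndarray
    masks: dict[str, np.ndarray]
    labels: dict[str, bool]
    session: ReadingSession | None
    true_lag: float

    @property
    def positive_labels(self) -> list[str]:
        return [k for k, v in self.labels.items() if v]


def _ellipse_mask(size, cx, cy, a, b, theta) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    dx, dy = xx - cx, yy - cy
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _sample_lesion(params: SimParams, label: str, rng) -> np.ndarray:
    size = params.image_size
    ax, ay = LABEL_ANCHORS.get(label, (0.5, 0.5))
    cx = np.clip(ax + rng.uniform(-0.08, 0.08), 0.12, 0.88) * size
    cy = np.clip(ay + rng.uniform(-0.08, 0.08), 0.12, 0.88) * size
    r0, r1 = params.lesion_radius_range
    a = rng.uniform(r0, r1) * size
    b = rng.uniform(r0, r1) * size
    theta = rng.uniform(0.0, np.pi)
    return _ellipse_mask(size, cx, cy, a, b, theta)


def _sentence_words(phrase: str, start: float, rate: float, rng) -> list[TranscriptWord]:
    tokens = ["there", "is"] + phrase.split()
    tokens[-1] += " ."  # keep punctuation attached to the final word
    words = []
    t = start
    for tok in tokens:
        dur = rng.uniform(0.8, 1.2) / rate
        words.append(TranscriptWord(tok.replace(" .", "."), t, t + dur))
        t += dur + rng.uniform(0.02, 0.08)
    return words


def _negated_words(phrase: str, start: float, rate: float, rng):
    tokens = ["no"] + phrase.split()
    tokens[-1] += "."
    words = []
    t = start
    for tok in tokens:
        dur = rng.uniform(0.8, 1.2) / rate
        words.append(TranscriptWord(tok, t, t + dur))
        t += dur + rng.uniform(0.02, 0.08)
    return words


def simulate_case(params: SimParams, rng, case_id: str = "case") -> SyntheticCase:
    """Generate one case: image, masks, transcript and gaze.

    Raises a warning-free degenerate-case error only on invalid params;
    a case may legitimately have no positive label (pure scanning).
    """
    size = params.image_size

    # -- positives, with closure over the Opacity grouping -------------
    positives = {
        lab: bool(rng.random() < params.prevalence) for lab in params.labels
    }
    own_masks: dict[str, np.ndarray] = {}  # each label's own lesion
    for lab in params.labels:
        if positives[lab]:
            own_masks[lab] = _sample_lesion(params, lab, rng)
    opacity_dictated = positives.get("Opacity", False)
    masks = dict(own_masks)
    if "Opacity" in params.labels:
        members = [m for m in OPACITY_MEMBERS if positives.get(m)]
        if members:
            positives["Opacity"] = True
            opac = masks.get("Opacity", np.zeros((size, size), dtype=bool))
            for m in members:
                opac = opac | masks[m]
            masks["Opacity"] = opac

    # -- image ----------------------------------------------------------
    smooth = gaussian_filter(rng.standard_normal((size, size)), sigma=size / 12.0)
    std = smooth.std()
    if std > 0:
        smooth /= std
    image = 0.35 + 0.08 * smooth
    for lab, mask in masks.items():
        lo, hi = params.lesion_contrast
        bump = gaussian_filter(mask.astype(float), sigma=size / 64.0)
        image += rng.uniform(lo, hi) * bump
    image += params.noise_sigma * rng.standard_normal((size, size))
    image = np.clip(image, 0.0, 1.0)

    # -- transcript ------------------------------------------------------
    # one sentence per *dictated* positive (implied Opacity rides along
    # with its member's phrase unless Opacity was drawn on its own)
    dictated = [
        lab
        for lab in params.labels
        if positives[lab] and (lab != "Opacity" or opacity_dictated)
    ]
    order = list(rng.permutation(len(dictated)))
    dictated = [dictated[i] for i in order]
    distractors: list[str] = []
    candidates = [
        lab
        for lab in params.labels
        if not positives[lab]
        and not (lab in OPACITY_MEMBERS and positives.get("Opacity"))
    ]
    if candidates and rng.random() < params.negation_rate:
        distractors.append(candidates[rng.integers(len(candidates))])

    sentence_plan: list[tuple[str | None, str]] = [
        (lab, GENERATOR_PHRASES[lab]) for lab in dictated
    ]
    for lab in distractors:
        pos = rng.integers(len(sentence_plan) + 1)
        sentence_plan.insert(pos, (None, GENERATOR_PHRASES[lab]))

    words: list[TranscriptWord] = []
    lesion_periods: list[tuple[float, float, str]] = []
    t = params.initial_silence
    for target, phrase in sentence_plan:
        if target is None:
            sw = _negated_words(phrase, t, params.speech_rate, rng)
        else:
            sw = _sentence_words(phrase, t, params.speech_rate, rng)
        words.extend(sw)
        if target is not None:
            mention_end = sw[-1].end  # phrase ends the sentence
            lesion_periods.append((sw[0].start - params.gaze_lag, mention_end, target))
        t = sw[-1].end + params.inter_sentence_pause * rng.uniform(0.9, 1.1)
    end_time = (words[-1].end if words else params.initial_silence) + 1.0

    # -- gaze -------------------------------------------------------------
    mean_duration = max(1.0 / params.fixation_rate - 0.05, 0.05)
    mu = np.log(mean_duration) - 0.35**2 / 2.0
    disp = params.on_lesion_dispersion * size
    centers = {}
    for t0, t1, lab in lesion_periods:
        ys, xs = np.nonzero(own_masks[lab])  # gaze targets the dictated lesion
        centers[(t0, t1, lab)] = (xs.mean(), ys.mean())
    fixations: list[Fixation] = []
    t = rng.uniform(0.0, 0.1)
    while t < end_time:
        dur = float(np.exp(rng.normal(mu, 0.35)))
        dur = min(dur, end_time - t)
        if dur <= 0:
            break
        mid = t + dur / 2.0
        period = next(
            (p for p in lesion_periods if p[0] <= mid <= p[1]), None
        )
        if period is not None and rng.random() >= params.scan_fraction:
            cx, cy = centers[period]
            x = float(np.clip(rng.normal(cx, disp), 0, size - 1))
            y = float(np.clip(rng.normal(cy, disp), 0, size - 1))
        else:
            x = float(rng.uniform(0, size - 1))
            y = float(rng.uniform(0, size - 1))
        fixations.append(
            Fixation(x, y, t, t + dur, pixels_per_degree=params.pixels_per_degree)
        )
        t += dur + rng.uniform(0.02, 0.06)

    session = ReadingSession(
        image_id=case_id,
        image_width=size,
        image_height=size,
        fixations=fixations,
        sentences=segment_sentences(words),
        recording_start=0.0,
        pixels_per_degree=params.pixels_per_degree,
    )
    return SyntheticCase(
        case_id=case_id,
        image=image,
        masks=masks,
        labels=positives,
        session=session,
        true_lag=params.gaze_lag,
    )


@dataclass
class SyntheticDataset:
    """Disjoint splits plus an unannotated pool (image-level labels only)."""

    train: list[SyntheticCase]
    val: list[SyntheticCase]
    test: list[SyntheticCase]
    unannotated: list[SyntheticCase]
    params: SimParams = field(default_factory=SimParams)


def strip_annotations(case: SyntheticCase) -> SyntheticCase:
    """Drop localization ground truth and gaze, keeping image-level labels."""
    return replace(case, masks={}, session=None)


def simulate_dataset(
    params: SimParams,
    seed: int,
    n_train: int = 50,
    n_val: int = 20,
    n_test: int = 30,
    n_unannotated: int = 0,
) -> SyntheticDataset:
    """Generate reproducible, case-disjoint splits from one seed."""
    rng = np.random.default_rng(seed)
    counts = {
        "train": n_train,
        "val": n_val,
        "test": n_test,
        "unann": n_unannotated,
    }
    splits: dict[str, list[SyntheticCase]] = {k: [] for k in counts}
    idx = 0
    for split, n in counts.items():
        for _ in range(n):
            case = simulate_case(params, rng, case_id=f"case{idx:05d}")
            splits[split].append(case)
            idx += 1
    splits["unann"] = [strip_annotations(c) for c in splits["unann"]]
    return SyntheticDataset(
        train=splits["train"],
        val=splits["val"],
        test=splits["test"],
        unannotated=splits["unann"],
        params=params,
    )


def write_case(case: SyntheticCase, directory) -> None:
    """Write one case in the CSV/PNG/JSON layout the readers consume."""
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    iio.imwrite(d / "image.png", np.round(case.image * 65535).astype(np.uint16))
    meta = {
        "case_id": case.case_id,
        "labels": case.labels,
        "true_lag": case.true_lag,
        "masks": {lab: rle_encode(m) for lab, m in case.masks.items()},
    }
    with open(d / "case.json", "w") as fh:
        json.dump(meta, fh)
    if case.session is not None:
        write_fixations(case.session.fixations, d / "fixations.csv")
        words = [w for s in case.session.sentences for w in s.words]
        write_transcript(words, d / "transcript.csv")


def read_case(directory) -> SyntheticCase:
    from pathlib import Path

    d = Path(directory)
    image = iio.imread(d / "image.png").astype(np.float64) / 65535.0
    with open(d / "case.json") as fh:
        meta = json.load(fh)
    masks = {lab: rle_decode(enc) for lab, enc in meta["masks"].items()}
    session = None
    if (d / "fixations.csv").exists():
        fixations = read_fixations(d / "fixations.csv", DEFAULT_DIALECT)
        sentences = segment_sentences(read_transcript(d / "transcript.csv"))
        ppd = fixations[0].pixels_per_degree if fixations else None
        session = ReadingSession(
            image_id=meta["case_id"],
            image_width=image.shape[1],
            image_height=image.shape[0],
            fixations=fixations,
            sentences=sentences,
            pixels_per_degree=ppd,
        )
    return SyntheticCase(
        case_id=meta["case_id"],
        image=image,
        masks=masks,
        labels=meta["labels"],
        session=session,
        true_lag=meta["true_lag"],
    )


def write_dataset(dataset: SyntheticDataset, directory) -> None:
    from pathlib import Path

    d = Path(directory)
    for split in ("train", "val", "test", "unannotated"):
        for case in getattr(dataset, split):
            write_case(case, d / split / case.case_id)
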