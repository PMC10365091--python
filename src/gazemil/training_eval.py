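"""Training protocol, augmentation, model/threshold selection and
IoU/AUC evaluation.

The full-scale protocol (60 epochs, AMSGrad, lr 0.001, weight decay
1e-5, batch 20, rotation <= 45 deg / translation <= 15% / scale <= 15%
augmentation, lambda_A = 3, lambda_T = 300, five seeds) is captured in
:class:`TrainConfig`; experiments in this package run a desk-scale
variant of it (smaller cohorts, fewer epochs, three seeds) documented
in docs/methods.md. The evaluation conventions follow the study
design: the best epoch per method is chosen by mean validation AUC,
the heatmap binarization threshold per method and label by mean
validation IoU across seeds over a full threshold grid, and the heatmap
source per method (decoder output vs spatial activations) by validation
IoU; test IoU is computed per positive (image, label) pair against
ground-truth masks after nearest-neighbor upscaling, and AUC per label
from the soft-OR image probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.ndimage import affine_transform
from sklearn.metrics import roc_auc_score

from .estimator import MILGridClassifier
from .heatmap_extraction import (
    DEFAULT_POLICY,
    WindowPolicy,
    binary_iou,
    heatmap_for_label,
    whole_session_heatmap,
)
from .report_labeler import Vocabulary, find_mentions, load_vocabulary
from .synthetic_data import SimParams, SyntheticCase, simulate_dataset

DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.05, 1.0, 0.05), 2))


@dataclass(frozen=True)
class TrainConfig:
    """Training constants; defaults equal the full-scale protocol."""

    epochs: int = 60
    learning_rate: float = 0.001
    weight_decay: float = 0.00001
    batch_size: int = 20
    rotation: float = 45.0
    translation: float = 0.15
    scale: float = 0.15
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4)
    lambda_a: float = 3.0
    lambda_t: float = 300.0
    normalization: str = "balanced"
    annotation_threshold: float = 0.15
    image_size: int = 512
    backbone: str = "resnet50_shaped"
    multi_resolution: bool = True
    multi_task: bool = True


#: Desk-scale variant used by the package's own experiments and tests.
DESK_CONFIG = TrainConfig(
    epochs=10,
    seeds=(0, 1, 2),
    image_size=128,
    backbone="tiny",
)


def _estimator_from_config(config: TrainConfig, seed: int, **overrides):
    kwargs = dict(
        image_size=config.image_size,
        backbone=config.backbone,
        multi_resolution=config.multi_resolution,
        multi_task=config.multi_task,
        epochs=config.epochs,
        learning_rate=config.learning_rate,
        weight_decay=config.weight_decay,
        batch_size=config.batch_size,
        lambda_a=config.lambda_a,
        lambda_t=config.lambda_t if config.multi_task else 0.0,
        normalization=config.normalization,
        rotation=config.rotation,
        translation=config.translation,
        scale=config.scale,
        annotation_threshold=config.annotation_threshold,
        random_state=seed,
    )
    kwargs.update(overrides)
    return MILGridClassifier(**kwargs)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def augment_case(
    image: np.ndarray,
    maps: dict[int, np.ndarray] | None,
    rng,
    rotation: float = 45.0,
    translation: float = 0.15,
    scale: float = 0.15,
):
    """Apply one random rotation/translation/scale draw to an image and
    all of its annotation maps identically.

    Maps are interpolated bilinearly and re-binarized downstream by the
    grid-conversion threshold. Out-of-frame regions become black,
    consistent with letterbox padding.
    """
    h, w = image.shape
    theta = np.deg2rad(rng.uniform(-rotation, rotation))
    s = 1.0 + rng.uniform(-scale, scale)
    t = rng.uniform(-translation, translation, size=2) * np.array([h, w])
    center = (np.array([h, w]) - 1) / 2.0
    fwd = s * np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    )
    inv = np.linalg.inv(fwd)
    offset = center - inv @ (center + t)
    out_img = affine_transform(
        image, inv, offset=offset, order=1, mode="constant", cval=0.0
    )
    out_maps = None
    if maps is not None:
        out_maps = {
            k: affine_transform(
                np.asarray(m, dtype=np.float64),
                inv,
                offset=offset,
                order=1,
                mode="constant",
                cval=0.0,
            )
            for k, m in maps.items()
        }
    return out_img, out_maps


# ---------------------------------------------------------------------------
# supervision preparation
# ---------------------------------------------------------------------------

def extract_case_heatmaps(
    case: SyntheticCase,
    vocab: Vocabulary,
    policy: WindowPolicy = DEFAULT_POLICY,
    label_specific: bool = True,
) -> dict[str, np.ndarray]:
    """Gaze heatmaps per positive label from the case's reading session.

    With ``label_specific=False`` every positive label receives the
    same whole-session heatmap (the pooled baseline of the label-
    specific-heatmap ablation).
    """
    if case.session is None:
        return {}
    mentions = find_mentions(case.session.sentences, vocab)
    by_label: dict[str, list] = {}
    for m in mentions:
        if not m.negated:
            by_label.setdefault(m.label, []).append(m)
    if not label_specific:
        pooled = whole_session_heatmap(case.session)
        return {lab: pooled for lab in by_label}
    return {
        lab: heatmap_for_label(case.session, lab, ms, policy).map
        for lab, ms in by_label.items()
    }


def prepare_training_data(
    cases: list[SyntheticCase],
    labels: tuple[str, ...],
    supervision: str,
    vocab: Vocabulary | None = None,
    policy: WindowPolicy = DEFAULT_POLICY,
    label_specific: bool = True,
):
    """Images, multilabel targets and per-sample annotation maps.

    ``supervision`` is ``"et"`` (gaze heatmaps through the extraction
    pipeline), ``"ellipse"`` (ground-truth masks as binary maps, taking
    the identical path), or ``"unannotated"`` (image-level labels
    only). Returns ``(X, y, maps)`` ready for
    :class:`~gazemil.estimator.MILGridClassifier`.
    """
    if supervision not in ("et", "ellipse", "unannotated"):
        raise ValueError(f"unknown supervision {supervision!r}")
    if supervision == "et" and vocab is None:
        vocab = load_vocabulary()
    X = np.stack([c.image for c in cases]).astype(np.float32)
    y = np.array(
        [[bool(c.labels.get(lab)) for lab in labels] for c in cases], dtype=bool
    )
    maps: list[dict[int, np.ndarray] | None] = []
    for case in cases:
        if supervision == "unannotated":
            maps.append(None)
            continue
        if supervision == "ellipse":
            named = {lab: m.astype(np.float64) for lab, m in case.masks.items()}
        else:
            named = extract_case_heatmaps(
                case, vocab, policy, label_specific=label_specific
            )
        maps.append(
            {labels.index(lab): m for lab, m in named.items() if lab in labels}
        )
    return X, y, maps


def train(
    train_cases: list[SyntheticCase],
    val_cases: list[SyntheticCase],
    labels: tuple[str, ...],
    config: TrainConfig = DESK_CONFIG,
    supervision: str = "et",
    seed: int = 0,
    unannotated_cases: list[SyntheticCase] | None = None,
    label_specific: bool = True,
) -> MILGridClassifier:
    """Fit one model under the given supervision regime.

    Annotated and unannotated pools are concatenated; the unannotated
    baseline is obtained by passing ``supervision="unannotated"``
    (indicator routing), not by a separate code path.
    """
    if not train_cases and not unannotated_cases:
        raise ValueError("empty training set")
    X, y, maps = prepare_training_data(
        train_cases, labels, supervision, label_specific=label_specific
    )
    if unannotated_cases:
        Xu, yu, mu = prepare_training_data(unannotated_cases, labels, "unannotated")
        X = np.concatenate([X, Xu])
        y = np.concatenate([y, yu])
        maps = maps + mu
    Xv = np.stack([c.image for c in val_cases]).astype(np.float32)
    yv = np.array(
        [[bool(c.labels.get(lab)) for lab in labels] for c in val_cases], dtype=bool
    )
    est = _estimator_from_config(config, seed)
    est.fit(X, y, maps=maps, X_val=Xv, y_val=yv)
    return est


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate_auc(scores: np.ndarray, y: np.ndarray) -> dict[int, float]:
    """Per-label ROC AUC; labels with a single class are absent."""
    out = {}
    for k in range(y.shape[1]):
        col = np.asarray(y[:, k], dtype=bool)
        if 0 < col.sum() < len(col):
            out[k] = float(roc_auc_score(col, scores[:, k]))
    return out


def _upscale_nearest(map2d: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    h, w = map2d.shape
    H, W = shape
    if H % h == 0 and W % w == 0:
        return np.repeat(np.repeat(map2d, H // h, axis=0), W // w, axis=1)
    from skimage.transform import resize

    return resize(map2d.astype(float), shape, order=0, preserve_range=True)


def iou_per_pair(
    heatmaps: np.ndarray,
    cases: list[SyntheticCase],
    labels: tuple[str, ...],
    threshold,
) -> list[tuple[int, int, float]]:
    """IoU for every positive (image, label) pair.

    ``heatmaps`` is (n, K, h, w) continuous; ``threshold`` a scalar or
    per-label array. Heatmaps are binarized, nearest-neighbor upscaled
    to mask resolution, and compared with the ground-truth mask.
    """
    thr = np.broadcast_to(np.asarray(threshold, dtype=float), (len(labels),))
    out = []
    for i, case in enumerate(cases):
        for k, lab in enumerate(labels):
            if not case.labels.get(lab) or lab not in case.masks:
                continue
            mask = case.masks[lab]
            binary = _upscale_nearest(heatmaps[i, k] > thr[k], mask.shape)
            out.append((i, k, binary_iou(binary, mask)))
    return out


def evaluate_iou(
    heatmaps: np.ndarray,
    cases: list[SyntheticCase],
    labels: tuple[str, ...],
    threshold,
) -> dict[str, float]:
    """Mean IoU per label over positive pairs; ``__mean__`` over labels."""
    pairs = iou_per_pair(heatmaps, cases, labels, threshold)
    per_label: dict[int, list[float]] = {}
    for _, k, v in pairs:
        per_label.setdefault(k, []).append(v)
    result = {labels[k]: float(np.mean(v)) for k, v in per_label.items()}
    result["__mean__"] = (
        float(np.mean(list(result.values()))) if result else float("nan")
    )
    return result


def select_threshold(
    heatmaps_per_seed: list[np.ndarray],
    cases: list[SyntheticCase],
    labels: tuple[str, ...],
    threshold_grid=DEFAULT_THRESHOLDS,
) -> np.ndarray:
    """Per-label threshold maximizing mean validation IoU across seeds.

    Ties break toward the lower threshold. Labels with no positive
    validation pair receive the lowest grid threshold.
    """
    grid = sorted(threshold_grid)
    if not grid:
        raise ValueError("empty threshold grid")
    best = np.full(len(labels), grid[0], dtype=float)
    best_iou = np.full(len(labels), -np.inf)
    for thr in grid:  # ascending: strict improvement keeps the lower tie
        per_label_values: dict[int, list[float]] = {}
        for hm in heatmaps_per_seed:
            for _, k, v in iou_per_pair(hm, cases, labels, thr):
                per_label_values.setdefault(k, []).append(v)
        for k, vals in per_label_values.items():
            mean_iou = np.mean(vals)
            if mean_iou > best_iou[k]:
                best_iou[k] = mean_iou
                best[k] = thr
    return best


def select_heatmap_source(val_iou_by_source: dict[str, float]) -> str:
    """Source with the higher validation IoU; ties pick ``spatial``
    (the simpler source, no decoder needed)."""
    if not val_iou_by_source:
        raise ValueError("no sources to select from")
    best = max(val_iou_by_source.values())
    if val_iou_by_source.get("spatial") == best:
        return "spatial"
    return max(val_iou_by_source, key=val_iou_by_source.get)


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------

def _evaluate_method(
    models: list[MILGridClassifier],
    val_cases: list[SyntheticCase],
    test_cases: list[SyntheticCase],
    labels: tuple[str, ...],
    threshold_grid=DEFAULT_THRESHOLDS,
) -> dict:
    """Source + threshold selection on validation, then test metrics."""
    Xv = np.stack([c.image for c in val_cases]).astype(np.float32)
    Xt = np.stack([c.image for c in test_cases]).astype(np.float32)
    yt = np.array(
        [[bool(c.labels.get(lab)) for lab in labels] for c in test_cases], dtype=bool
    )
    val_maps = {
        src: [m.predict_heatmaps(Xv, source=src) for m in models]
        for src in ("decoder", "spatial")
    }
    thresholds = {
        src: select_threshold(val_maps[src], val_cases, labels, threshold_grid)
        for src in ("decoder", "spatial")
    }
    val_iou = {
        src: float(
            np.mean(
                [
                    evaluate_iou(hm, val_cases, labels, thresholds[src])["__mean__"]
                    for hm in val_maps[src]
                ]
            )
        )
        for src in ("decoder", "spatial")
    }
    source = select_heatmap_source(val_iou)
    test_ious, test_aucs = [], []
    for m in models:
        hm = m.predict_heatmaps(Xt, source=source)
        test_ious.append(
            evaluate_iou(hm, test_cases, labels, thresholds[source])["__mean__"]
        )
        aucs = evaluate_auc(m.predict_proba(Xt), yt)
        test_aucs.append(float(np.mean(list(aucs.values()))))
    return {
        "source": source,
        "thresholds": thresholds[source],
        "val_iou": val_iou,
        "test_iou_per_seed": test_ious,
        "test_auc_per_seed": test_aucs,
        "test_iou": float(np.mean(test_ious)),
        "test_auc": float(np.mean(test_aucs)),
    }


def supervision_ordering_experiment(
    params: SimParams | None = None,
    config: TrainConfig = DESK_CONFIG,
    n_annotated: int = 60,
    n_unannotated: int = 120,
    n_val: int = 40,
    n_test: int = 60,
    data_seed: int = 0,
    methods: tuple[str, ...] = ("unannotated", "et", "ellipse"),
) -> dict:
    """Train the three supervision regimes and evaluate the ordering.

    Mirrors the baseline comparison of the full-scale study on the
    synthetic cohort: identical architecture, loss and hyperparameters
    across methods, differing only in the localization supervision
    (none / gaze heatmaps / ground-truth ellipses). Returns per-method
    test IoU and AUC, averaged over the configured seeds.
    """
    params = params or SimParams(image_size=config.image_size)
    data = simulate_dataset(
        params,
        seed=data_seed,
        n_train=n_annotated,
        n_val=n_val,
        n_test=n_test,
        n_unannotated=n_unannotated,
    )
    labels = params.labels
    results = {}
    for method in methods:
        models = [
            train(
                data.train,
                data.val,
                labels,
                config=config,
                supervision=method,
                seed=seed,
                unannotated_cases=data.unannotated,
            )
            for seed in config.seeds
        ]
        results[method] = _evaluate_method(models, data.val, data.test, labels)
    return results


def ablation_suite(
    combos: list[dict],
    params: SimParams | None = None,
    config: TrainConfig = DESK_CONFIG,
    n_annotated: int = 40,
    n_unannotated: int = 0,
    n_val: int = 20,
    n_test: int = 30,
    data_seed: int = 0,
) -> pd.DataFrame:
    """Toggle the method's components and report test IoU per combination.

    Each combo dict may set ``label_specific`` (gaze heatmaps per label
    vs one whole-session heatmap), ``balanced`` (balanced vs fixed
    [0.98, 1] normalization), ``multi_resolution`` and ``multi_task``.
    All-off reduces to plain MIL training on pooled heatmaps.
    """
    params = params or SimParams(image_size=config.image_size)
    data = simulate_dataset(
        params,
        seed=data_seed,
        n_train=n_annotated,
        n_val=n_val,
        n_test=n_test,
        n_unannotated=n_unannotated,
    )
    labels = params.labels
    rows = []
    for combo in combos:
        label_specific = combo.get("label_specific", True)
        cfg = replace(
            config,
            normalization="balanced" if combo.get("balanced", True) else "fixed_098",
            multi_resolution=combo.get("multi_resolution", True),
            multi_task=combo.get("multi_task", True),
        )
        models = [
            train(
                data.train,
                data.val,
                labels,
                config=cfg,
                supervision="et",
                seed=seed,
                unannotated_cases=data.unannotated or None,
                label_specific=label_specific,
            )
            for seed in cfg.seeds
        ]
        result = _evaluate_method(models, data.val, data.test, labels)
        rows.append(
            {
                "label_specific": label_specific,
                "balanced": combo.get("balanced", True),
                "multi_resolution": combo.get("multi_resolution", True),
                "multi_task": combo.get("multi_task", True),
                "source": result["source"],
                "test_iou": result["test_iou"],
                "test_auc": result["test_auc"],
            }
        )
    return pd.DataFrame(rows)
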