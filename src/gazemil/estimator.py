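"""Scikit-learn style estimator for the grid-based MIL classifier.

:class:`MILGridClassifier` trains the encoder/decoder network with the
MIL + multi-task objective. ``X`` is an array of letterbox-square
grayscale images in [0, 1], ``y`` a multilabel indicator matrix, and
``maps`` optionally supplies per-sample localization supervision
(continuous gaze heatmaps or binary lesion masks at image resolution);
samples without maps are trained as unannotated through the indicator
routing of the MIL loss, so the unannotated baseline is a data
configuration, not a separate code path.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .annotation_grid import to_grid, to_decoder_target
from .autodiff import Tensor
from .losses import (
    AnnotationStatus,
    LossWeights,
    NormalizationSpec,
    image_probability_batch,
    mil_loss_tensor,
    mtl_loss_tensor,
)
from .network import EncoderConfig, GazeMILNet
from .nn import AMSGrad


def _mean_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Mean per-label ROC AUC, skipping single-class labels."""
    from sklearn.metrics import roc_auc_score

    aucs = []
    for k in range(y.shape[1]):
        col = y[:, k]
        if 0 < col.sum() < len(col):
            aucs.append(roc_auc_score(col, scores[:, k]))
    return float(np.mean(aucs)) if aucs else float("nan")


class MILGridClassifier(BaseEstimator):
    """Weakly supervised multilabel image classifier with localization.

    Parameters mirror the training protocol of the full-scale study
    (AMSGrad, lr 1e-3, weight decay 1e-5, batch 20, lambda_A = 3,
    lambda_T = 300, balanced range normalization, rotation <= 45 deg /
    translation <= 15% / scaling <= 15% augmentation); ``epochs``
    defaults to a desk-scale value.

    Attributes
    ----------
    model_ : GazeMILNet
        The trained network (best validation epoch when validation data
        was supplied, else the final epoch).
    history_ : list of dict
        Per-epoch mean training loss and validation AUC.
    best_epoch_ : int
    n_classes_ : int
    """

    def __init__(
        self,
        image_size: int = 128,
        backbone: str = "tiny",
        multi_resolution: bool = True,
        multi_task: bool = True,
        epochs: int = 10,
        learning_rate: float = 0.001,
        weight_decay: float = 0.00001,
        batch_size: int = 20,
        lambda_a: float = 3.0,
        lambda_t: float = 300.0,
        normalization: str = "balanced",
        augment: bool = True,
        rotation: float = 45.0,
        translation: float = 0.15,
        scale: float = 0.15,
        annotation_threshold: float = 0.15,
        tiny_channels: tuple[int, ...] = (8, 16, 32, 64),
        head_channels: int = 64,
        decoder_channels: tuple[int, int] = (32, 16),
        random_state: int | None = None,
        verbose: int = 0,
    ):
        self.image_size = image_size
        self.backbone = backbone
        self.multi_resolution = multi_resolution
        self.multi_task = multi_task
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.lambda_a = lambda_a
        self.lambda_t = lambda_t
        self.normalization = normalization
        self.augment = augment
        self.rotation = rotation
        self.translation = translation
        self.scale = scale
        self.annotation_threshold = annotation_threshold
        self.tiny_channels = tiny_channels
        self.head_channels = head_channels
        self.decoder_channels = decoder_channels
        self.random_state = random_state
        self.verbose = verbose

    # ------------------------------------------------------------------
    def _encoder_config(self, n_classes: int) -> EncoderConfig:
        return EncoderConfig(
            backbone=self.backbone,
            input_size=self.image_size,
            n_classes=n_classes,
            multi_resolution=self.multi_resolution,
            tiny_channels=tuple(self.tiny_channels),
            head_channels=self.head_channels,
            decoder_channels=tuple(self.decoder_channels),
        )

    def _validate_inputs(self, X, y):
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=bool)
        if X.ndim != 3 or X.shape[1:] != (self.image_size, self.image_size):
            raise ValueError(
                f"X must be (n, {self.image_size}, {self.image_size}), "
                f"got {X.shape}"
            )
        if y.shape != (X.shape[0], y.shape[1]):
            raise ValueError("y must be (n_samples, n_classes)")
        return X, y

    def _batch_targets(self, images, y, maps, rng):
        """Assemble status/cell/decoder-target arrays for one batch."""
        from .training_eval import augment_case

        config = self.model_.config
        g, d = config.grid_size, config.decoder_size
        n, k = len(images), y.shape[1]
        statuses = np.full((n, k), AnnotationStatus.UNANNOTATED_NEGATIVE, dtype=np.int64)
        cells = np.zeros((n, k, g, g), dtype=bool)
        targets = np.zeros((n, k, d, d), dtype=np.float32)
        batch_imgs = np.empty((n, 1, self.image_size, self.image_size), dtype=np.float32)
        for i in range(n):
            img = images[i]
            case_maps = maps[i]
            if self.augment and rng is not None:
                img, case_maps = augment_case(
                    img,
                    case_maps,
                    rng,
                    rotation=self.rotation,
                    translation=self.translation,
                    scale=self.scale,
                )
            batch_imgs[i, 0] = (img - 0.5) * 2.0
            annotated = case_maps is not None
            for kk in range(k):
                if annotated:
                    if y[i, kk] and kk in case_maps:
                        statuses[i, kk] = AnnotationStatus.ANNOTATED_POSITIVE
                        cells[i, kk] = to_grid(
                            case_maps[kk], self.annotation_threshold, (g, g)
                        ).cells
                        targets[i, kk] = to_decoder_target(
                            case_maps[kk], self.annotation_threshold, (d, d)
                        )
                    elif y[i, kk]:
                        statuses[i, kk] = AnnotationStatus.UNANNOTATED_POSITIVE
                    else:
                        statuses[i, kk] = AnnotationStatus.ANNOTATED_NEGATIVE
                else:
                    statuses[i, kk] = (
                        AnnotationStatus.UNANNOTATED_POSITIVE
                        if y[i, kk]
                        else AnnotationStatus.UNANNOTATED_NEGATIVE
                    )
        return batch_imgs, statuses, cells, targets

    # ------------------------------------------------------------------
    def fit(self, X, y, maps=None, X_val=None, y_val=None):
        """Train the network; select the best epoch by validation AUC.

        ``maps``: per-sample ``None`` (unannotated) or a dict mapping
        class index -> continuous map in [0, 1] at image resolution.
        """
        X, y = self._validate_inputs(X, y)
        if X.shape[0] == 0:
            raise ValueError("empty training set")
        if maps is None:
            maps = [None] * len(X)
        if len(maps) != len(X):
            raise ValueError("maps must have one entry per sample")
        n_classes = y.shape[1]
        self.n_classes_ = n_classes
        seed = self.random_state if self.random_state is not None else 0
        rng = np.random.default_rng(seed)
        self.model_ = GazeMILNet(self._encoder_config(n_classes), seed=seed)
        weights = LossWeights(lambda_a=self.lambda_a, lambda_t=self.lambda_t)
        spec = NormalizationSpec(self.normalization)
        optimizer = AMSGrad(
            self.model_.parameters(),
            lr=self.learning_rate,
            weight_decay=self.weight_decay,
        )
        have_val = X_val is not None and y_val is not None
        if have_val:
            X_val = np.asarray(X_val, dtype=np.float32)
            y_val = np.asarray(y_val, dtype=bool)
        self.history_ = []
        self.loss_curve_ = []
        best_auc, best_state, best_epoch = -np.inf, None, 0
        n = len(X)
        for epoch in range(self.epochs):
            self.model_.train()
            order = rng.permutation(n)
            epoch_losses = []
            for b0 in range(0, n, self.batch_size):
                idx = order[b0 : b0 + self.batch_size]
                imgs, statuses, cells, targets = self._batch_targets(
                    [X[i] for i in idx], y[idx], [maps[i] for i in idx], rng
                )
                x_t = Tensor(imgs)
                if self.multi_task and (
                    statuses == AnnotationStatus.ANNOTATED_POSITIVE
                ).any():
                    out = self.model_(x_t)
                    loss = mil_loss_tensor(
                        out.grid_logits, statuses, cells, weights, spec
                    ) + self.lambda_t * mtl_loss_tensor(
                        out.decoder_logits, targets, statuses
                    )
                else:
                    feats, grid_logits = self.model_.encoder(x_t)
                    loss = mil_loss_tensor(
                        grid_logits, statuses, cells, weights, spec
                    )
                optimizer.zero_grad()
                loss.backward()
                optimizer.step()
                epoch_losses.append(float(loss.value))
                self.loss_curve_.append(float(loss.value))
            record = {"epoch": epoch, "train_loss": float(np.mean(epoch_losses))}
            if have_val:
                val_auc = _mean_auc(self.predict_proba(X_val), y_val)
                record["val_auc"] = val_auc
                if val_auc > best_auc:
                    best_auc, best_epoch = val_auc, epoch
                    best_state = self.model_.state_dict()
            self.history_.append(record)
            if self.verbose:
                print(f"[gazemil] {record}")
        if best_state is not None:
            self.model_.load_state_dict(best_state)
        self.best_epoch_ = best_epoch
        return self

    # ------------------------------------------------------------------
    def _forward_batches(self, X, need_decoder: bool):
        X = np.asarray(X, dtype=np.float32)
        self.model_.eval()
        grid, dec = [], []
        for b0 in range(0, len(X), self.batch_size):
            chunk = (X[b0 : b0 + self.batch_size, None] - 0.5) * 2.0
            x_t = Tensor(chunk.astype(np.float32))
            if need_decoder:
                out = self.model_(x_t)
                grid.append(out.grid_logits.value)
                dec.append(out.decoder_logits.value)
            else:
                _, logits = self.model_.encoder(x_t)
                grid.append(logits.value)
        return (
            np.concatenate(grid),
            np.concatenate(dec) if dec else None,
        )

    def predict_proba(self, X) -> np.ndarray:
        """Soft-OR image-level probabilities C_k(x), shape (n, K)."""
        check_is_fitted(self, "model_")
        grid, _ = self._forward_batches(X, need_decoder=False)
        return image_probability_batch(grid, NormalizationSpec(self.normalization))

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X) >= 0.5

    def predict_heatmaps(self, X, source: str = "decoder") -> np.ndarray:
        """Per-label localization maps in (0, 1).

        ``source`` is ``"decoder"`` (sigmoid of the decoder logits, half
        image resolution) or ``"spatial"`` (sigmoid of the grid logits,
        grid resolution).
        """
        check_is_fitted(self, "model_")
        if source == "decoder":
            _, dec = self._forward_batches(X, need_decoder=True)
            return expit(dec)
        if source == "spatial":
            grid, _ = self._forward_batches(X, need_decoder=False)
            return expit(grid)
        raise ValueError(f"unknown heatmap source {source!r}")
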