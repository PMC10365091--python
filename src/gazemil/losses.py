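"""Multiple-instance-learning and multi-task losses for grid classifiers.

The image-level probability for class ``k`` is a soft OR over grid
cells, ``C_k(x) = 1 - prod_j (1 - sigma(gamma_jk))``: the image is
positive if at least one cell is. Training minimizes

* for images with localization annotation: a per-cell cross-entropy
  against the annotated cell set ``B_kx`` written as one log-product;
* for unannotated positive images: ``-log C_k(x)``;
* for unannotated negative images: ``-log prod_j (1 - sigma(gamma_jk))``;

combined as ``L_I = E[ lambda_A 1_A L_A + 1_U+ L_U+ + 1_U- L_U- ]``.

Products of ~1000 factors in (0, 1) underflow and their range collapses
with grid size, so every factor is affinely remapped into
``[0.0056738**(1/nt), 1]`` where ``nt`` is the number of factors
("balanced range normalization"): the full product of floor-valued
factors is then 0.0056738 regardless of grid size, reproducing the
fixed [0.98, 1] per-factor range at nt = 256. A ``fixed_098`` mode
(the earlier scheme) and ``none`` are also provided. All log-products
are computed in log space; equivalence with extended-precision direct
products is asserted in the tests.

The multi-task term ``L_T`` is pixel-level cross-entropy between the
decoder's per-label logit maps and binarized gaze maps at half working
resolution, applied only to channels whose label is annotated-positive;
the total objective is ``L = L_I + lambda_T L_T``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np
from scipy.special import expit, log_expit, logsumexp

from .autodiff import Tensor, custom_op

#: Base of the balanced normalization range: the value of the full
#: product when every factor sits at its floor. 0.0056738**(1/256) is
#: 0.98 to five decimals, matching the fixed scheme at 256 factors.
BALANCED_BASE = 0.0056738


class AnnotationStatus(IntEnum):
    """Supervision available for one (image, class) pair."""

    ANNOTATED_POSITIVE = 0  # localization annotation with cell set B_kx
    ANNOTATED_NEGATIVE = 1  # annotated image, label absent (B_kx empty)
    UNANNOTATED_POSITIVE = 2
    UNANNOTATED_NEGATIVE = 3


@dataclass(frozen=True)
class LossWeights:
    """lambda_A weights annotated images in L_I; lambda_T weights L_T."""

    lambda_a: float = 3.0
    lambda_t: float = 300.0

    def __post_init__(self) -> None:
        if self.lambda_a < 0 or self.lambda_t < 0:
            raise ValueError("loss weights must be >= 0")


@dataclass(frozen=True)
class NormalizationSpec:
    """Range normalization applied to every product factor."""

    mode: str = "balanced"
    base: float = BALANCED_BASE

    def __post_init__(self) -> None:
        if self.mode not in ("balanced", "fixed_098", "none"):
            raise ValueError(f"unknown normalization mode {self.mode!r}")
        if not 0.0 < self.base < 1.0:
            raise ValueError("base must lie in (0, 1)")

    def floor(self, nt: int) -> float:
        """Lower endpoint of the factor range for an ``nt``-factor product."""
        if nt < 1:
            raise ValueError(f"factor count must be >= 1, got {nt}")
        if self.mode == "balanced":
            return float(self.base ** (1.0 / nt))
        if self.mode == "fixed_098":
            return 0.98
        return 0.0


BALANCED = NormalizationSpec("balanced")
FIXED_098 = NormalizationSpec("fixed_098")
NO_NORMALIZATION = NormalizationSpec("none")


@dataclass
class GridLogits:
    """Per-cell per-class logits, shape (n_classes, grid_h, grid_w)."""

    gamma: np.ndarray

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=np.float64)
        if self.gamma.ndim != 3:
            raise ValueError("gamma must be (n_classes, grid_h, grid_w)")
        if not np.all(np.isfinite(self.gamma)):
            raise ValueError("logits must be finite")

    @property
    def n_cells(self) -> int:
        return self.gamma.shape[1] * self.gamma.shape[2]

    @property
    def n_classes(self) -> int:
        return self.gamma.shape[0]


def normalize_factor(f, nt: int, spec: NormalizationSpec):
    """Affinely map a probability factor onto [floor(nt), 1]."""
    lo = spec.floor(nt)
    return lo + (1.0 - lo) * np.asarray(f, dtype=np.float64)


# ---------------------------------------------------------------------------
# stable log-space kernels (shared by the scalar API and the tape ops)
# ---------------------------------------------------------------------------

def _log_nf_sigma(gamma: np.ndarray, lo: float) -> np.ndarray:
    """log(lo + (1 - lo) * sigmoid(gamma)), overflow/underflow safe.

    Uses ``lo + (1-lo)s = 1 - (1-lo)(1-s)`` so large positive logits
    keep full precision; at lo = 0 this is just log-sigmoid.
    """
    if lo == 0.0:
        return log_expit(gamma)
    return np.log1p(-(1.0 - lo) * expit(-gamma))


def _dlog_nf_sigma(gamma: np.ndarray, lo: float) -> np.ndarray:
    """d/dgamma of :func:`_log_nf_sigma`; finite for any finite logit."""
    s = expit(gamma)
    s1 = expit(-gamma)
    if lo == 0.0:
        return s1
    return (1.0 - lo) * s * s1 / (1.0 - (1.0 - lo) * s1)


def _soft_or_neglog_and_grad(gamma_cells: np.ndarray, lo: float):
    """``-log C_k`` and its gradient for one bag of cell logits.

    ``S = sum_j log(nf(1 - sigma))`` is accumulated in log space;
    ``C_k = -expm1(S)``. When every complement factor rounds to exactly
    1 (all sigmoids underflow), the loss is evaluated through its
    asymptotic form ``-logsumexp(log(1-lo) + log sigmoid(gamma_j))``,
    which stays finite for logits of any magnitude.
    """
    g = np.asarray(gamma_cells, dtype=np.float64).ravel()
    log_f = _log_nf_sigma(-g, lo)  # log of normalized complement factors
    S = log_f.sum()
    if S < 0.0:
        ck = -np.expm1(S)
        loss = -np.log(ck)
        es = np.exp(S)
        s = expit(g)
        s1 = expit(-g)
        # complement factor written as lo + (1-lo)(1-s): no cancellation;
        # if it still underflows (lo = 0, huge logit) the ratio tends to s
        f = lo + (1.0 - lo) * s1
        ratio = np.where(f > 0.0, (1.0 - lo) * s * s1 / np.where(f > 0.0, f, 1.0), s)
        grad = -(es / ck) * ratio
    else:  # every factor exactly 1 in float: asymptotic branch
        t = np.log1p(-lo) + log_expit(g)
        lse = logsumexp(t)
        loss = -lse
        grad = -np.exp(t - lse) * expit(-g)
    return loss, grad.reshape(np.shape(gamma_cells))


def _cells_mask(b_kx, grid_shape: tuple[int, int]) -> np.ndarray:
    """Accept a cell-index set or a boolean grid; return a boolean grid."""
    if isinstance(b_kx, np.ndarray) and b_kx.shape == grid_shape:
        return b_kx.astype(bool)
    mask = np.zeros(grid_shape, dtype=bool)
    idx = sorted(b_kx)
    if idx:
        if idx[0] < 0 or idx[-1] >= grid_shape[0] * grid_shape[1]:
            raise ValueError("B_kx contains cell indices outside the grid")
        mask.ravel()[idx] = True
    return mask


# ---------------------------------------------------------------------------
# single-image scalar API
# ---------------------------------------------------------------------------

def image_probability(
    logits: GridLogits, k: int, spec: NormalizationSpec = BALANCED
) -> float:
    """Soft-OR probability C_k(x) = 1 - prod_j nf(1 - sigma(gamma_jk))."""
    lo = spec.floor(logits.n_cells)
    S = _log_nf_sigma(-logits.gamma[k], lo).sum()
    return float(-np.expm1(S))


def loss_annotated(
    logits: GridLogits, k: int, b_kx, spec: NormalizationSpec = BALANCED
) -> float:
    """Cross-entropy of all cells against the annotated cell set B_kx."""
    gamma = logits.gamma[k]
    lo = spec.floor(logits.n_cells)
    mask = _cells_mask(b_kx, gamma.shape)
    pos = _log_nf_sigma(gamma[mask], lo).sum()
    neg = _log_nf_sigma(-gamma[~mask], lo).sum()
    return float(-(pos + neg))


def loss_unannotated_positive(
    logits: GridLogits, k: int, spec: NormalizationSpec = BALANCED
) -> float:
    """-log C_k(x): at least one cell should be positive."""
    lo = spec.floor(logits.n_cells)
    loss, _ = _soft_or_neglog_and_grad(logits.gamma[k], lo)
    return float(loss)


def loss_unannotated_negative(
    logits: GridLogits, k: int, spec: NormalizationSpec = BALANCED
) -> float:
    """-log prod_j nf(1 - sigma): all cells should be negative."""
    lo = spec.floor(logits.n_cells)
    return float(-_log_nf_sigma(-logits.gamma[k], lo).sum())


def mil_loss(
    batch,
    weights: LossWeights = LossWeights(),
    spec: NormalizationSpec = BALANCED,
) -> float:
    """Mean MIL loss over a batch of ``(GridLogits, statuses, cell_sets)``.

    ``statuses`` maps class index -> :class:`AnnotationStatus`;
    ``cell_sets`` maps class index -> B_kx for annotated-positive
    classes. Annotated pairs are weighted by ``lambda_A``.
    """
    terms = []
    for logits, statuses, cell_sets in batch:
        for k in range(logits.n_classes):
            status = statuses[k]
            if status in (
                AnnotationStatus.ANNOTATED_POSITIVE,
                AnnotationStatus.ANNOTATED_NEGATIVE,
            ):
                b = cell_sets.get(k, set()) if cell_sets else set()
                terms.append(weights.lambda_a * loss_annotated(logits, k, b, spec))
            elif status == AnnotationStatus.UNANNOTATED_POSITIVE:
                terms.append(loss_unannotated_positive(logits, k, spec))
            else:
                terms.append(loss_unannotated_negative(logits, k, spec))
    if not terms:
        raise ValueError("empty batch")
    return float(np.mean(terms))


def mtl_loss(
    decoder_logits: np.ndarray, targets: np.ndarray, statuses: np.ndarray
) -> float:
    """Pixel cross-entropy on annotated-positive channels; others are 0.

    ``decoder_logits`` and ``targets`` are (n_classes, H, W) (or
    batched (N, n_classes, H, W)); ``statuses`` holds one
    :class:`AnnotationStatus` per channel. The expectation runs over
    all (image, class) channels, with non-annotated-positive channels
    contributing zero.
    """
    z = np.asarray(decoder_logits, dtype=np.float64)
    t = np.asarray(targets, dtype=np.float64)
    if z.shape != t.shape:
        raise ValueError(f"shape mismatch {z.shape} vs {t.shape}")
    if z.ndim == 3:
        z, t = z[None], t[None]
        statuses = np.asarray(statuses)[None]
    statuses = np.asarray(statuses)
    if statuses.shape != z.shape[:2]:
        raise ValueError("statuses must have one entry per (image, class)")
    # BCE with logits: -[t log s + (1-t) log(1-s)] = softplus(z) - t z
    bce = np.logaddexp(0.0, z) - t * z
    per_channel = bce.mean(axis=(2, 3))
    mask = statuses == AnnotationStatus.ANNOTATED_POSITIVE
    return float((per_channel * mask).mean())


def total_loss(l_i: float, l_t: float, weights: LossWeights = LossWeights()) -> float:
    """L = L_I + lambda_T * L_T."""
    return l_i + weights.lambda_t * l_t


# ---------------------------------------------------------------------------
# batched tape ops used during training
# ---------------------------------------------------------------------------

def mil_loss_tensor(
    gamma: Tensor,
    statuses: np.ndarray,
    cells: np.ndarray,
    weights: LossWeights = LossWeights(),
    spec: NormalizationSpec = BALANCED,
) -> Tensor:
    """Batched MIL loss on the autodiff tape.

    ``gamma`` is (N, K, gh, gw); ``statuses`` (N, K) of
    :class:`AnnotationStatus`; ``cells`` (N, K, gh, gw) boolean B_kx
    (all-False outside annotated-positive pairs). Returns the scalar
    mean over (N, K) pairs.
    """
    gv = gamma.value.astype(np.float64)
    n, k, gh, gw = gv.shape
    nt = gh * gw
    lo = spec.floor(nt)
    statuses = np.asarray(statuses)
    cells = np.asarray(cells, dtype=bool)

    lnp_pos = _log_nf_sigma(gv, lo)
    lnp_neg = _log_nf_sigma(-gv, lo)
    d_pos = _dlog_nf_sigma(gv, lo)
    d_neg = _dlog_nf_sigma(-gv, lo)

    is_a = statuses <= AnnotationStatus.ANNOTATED_NEGATIVE
    is_up = statuses == AnnotationStatus.UNANNOTATED_POSITIVE
    is_un = statuses == AnnotationStatus.UNANNOTATED_NEGATIVE

    per_pair = np.zeros((n, k), dtype=np.float64)
    grad = np.zeros_like(gv)

    la_terms = np.where(cells, lnp_pos, lnp_neg).sum(axis=(2, 3))
    la_grad = np.where(cells, d_pos, -d_neg)
    per_pair += np.where(is_a, -weights.lambda_a * la_terms, 0.0)
    grad += np.where(is_a[..., None, None], -weights.lambda_a * la_grad, 0.0)

    per_pair += np.where(is_un, -lnp_neg.sum(axis=(2, 3)), 0.0)
    grad += np.where(is_un[..., None, None], d_neg, 0.0)

    for idx in np.argwhere(is_up):
        i, j = idx
        loss_up, grad_up = _soft_or_neglog_and_grad(gv[i, j], lo)
        per_pair[i, j] += loss_up
        grad[i, j] += grad_up

    value = per_pair.mean()
    scale = 1.0 / (n * k)

    def bw(g, gamma=gamma, grad=grad, scale=scale):
        gamma._accumulate(np.asarray(g) * scale * grad.astype(gamma.value.dtype))

    return custom_op(np.asarray(value), (gamma,), bw)


def mtl_loss_tensor(
    decoder_logits: Tensor, targets: np.ndarray, statuses: np.ndarray
) -> Tensor:
    """Batched multi-task loss on the tape; see :func:`mtl_loss`."""
    t = np.asarray(targets, dtype=decoder_logits.value.dtype)
    if t.shape != decoder_logits.value.shape:
        raise ValueError(
            f"shape mismatch {decoder_logits.value.shape} vs {t.shape}"
        )
    mask = (
        np.asarray(statuses) == AnnotationStatus.ANNOTATED_POSITIVE
    ).astype(decoder_logits.value.dtype)
    bce = decoder_logits.softplus() - decoder_logits * t
    per_channel = bce.mean(axis=(2, 3))
    return (per_channel * mask).mean()


def image_probability_batch(
    gamma: np.ndarray, spec: NormalizationSpec = BALANCED
) -> np.ndarray:
    """C_k(x) for a (N, K, gh, gw) logit array -> (N, K) probabilities."""
    gamma = np.asarray(gamma, dtype=np.float64)
    nt = gamma.shape[2] * gamma.shape[3]
    lo = spec.floor(nt)
    S = _log_nf_sigma(-gamma, lo).sum(axis=(2, 3))
    return -np.expm1(S)
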