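"""MIL/MTL loss closed forms, normalization, and oracle equivalence.

The independent oracle computes every product literally in extended
precision (numpy longdouble) without any log-space rewriting, and the
log-space implementation must agree to 1e-10 on small grids.
"""

import numpy as np
import pytest

from gazemil.autodiff import Tensor
from gazemil.losses import (
    BALANCED,
    BALANCED_BASE,
    FIXED_098,
    NO_NORMALIZATION,
    AnnotationStatus,
    GridLogits,
    LossWeights,
    NormalizationSpec,
    image_probability,
    loss_annotated,
    loss_unannotated_negative,
    loss_unannotated_positive,
    mil_loss,
    mil_loss_tensor,
    mtl_loss,
    mtl_loss_tensor,
    normalize_factor,
    total_loss,
)

SPECS = [BALANCED, FIXED_098, NO_NORMALIZATION]


# ---------------------------------------------------------------------------
# extended-precision direct-product oracle
# ---------------------------------------------------------------------------

def _sig_ld(g):
    g = np.asarray(g, dtype=np.longdouble)
    return 1.0 / (1.0 + np.exp(-g))


def oracle_ck(gamma, lo):
    s = _sig_ld(gamma).ravel()
    return float(1.0 - np.prod(lo + (1.0 - np.longdouble(lo)) * (1.0 - s)))


def oracle_loss_annotated(gamma, mask, lo):
    s = _sig_ld(gamma).ravel()
    m = np.asarray(mask, bool).ravel()
    lo = np.longdouble(lo)
    factors = np.where(m, lo + (1 - lo) * s, lo + (1 - lo) * (1 - s))
    return float(-np.sum(np.log(factors)))


def oracle_loss_up(gamma, lo):
    return float(-np.log(np.longdouble(oracle_ck(gamma, lo))))


def oracle_loss_un(gamma, lo):
    s = _sig_ld(gamma).ravel()
    lo = np.longdouble(lo)
    return float(-np.sum(np.log(lo + (1 - lo) * (1 - s))))


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

class TestNormalizeFactor:
    def test_floor_at_256_factors_is_098(self):
        assert BALANCED.floor(256) == pytest.approx(0.98, abs=1e-5)

    def test_upper_endpoint_fixed(self):
        for nt in (1, 7, 256):
            assert normalize_factor(1.0, nt, BALANCED) == pytest.approx(1.0)

    def test_single_factor_floor_is_base(self):
        assert normalize_factor(0.0, 1, BALANCED) == pytest.approx(BALANCED_BASE)

    def test_fixed_mode_ignores_factor_count(self):
        assert FIXED_098.floor(1) == FIXED_098.floor(1024) == 0.98

    def test_invalid_factor_count(self):
        with pytest.raises(ValueError):
            BALANCED.floor(0)

    @pytest.mark.parametrize("nt", [1, 4, 64, 256, 1024])
    def test_full_floor_product_equals_base(self, nt):
        product = np.longdouble(BALANCED.floor(nt)) ** nt
        assert float(product) == pytest.approx(BALANCED_BASE, rel=1e-9)

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError):
            NormalizationSpec("softmaxish")


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------

class TestClosedForms:
    def test_ck_zero_when_all_cells_negative(self):
        logits = GridLogits(np.full((1, 2, 2), -40.0))
        assert image_probability(logits, 0, NO_NORMALIZATION) == pytest.approx(0.0)

    def test_ck_single_cell_equals_sigmoid(self):
        logits = GridLogits(np.zeros((1, 1, 1)))
        assert image_probability(logits, 0, NO_NORMALIZATION) == pytest.approx(0.5)

    def test_annotated_loss_vanishes_at_perfect_match(self):
        gamma = np.full((1, 2, 2), -40.0)
        gamma[0, 0, 0] = 40.0
        loss = loss_annotated(GridLogits(gamma), 0, {0}, NO_NORMALIZATION)
        assert loss == pytest.approx(0.0, abs=1e-6)

    def test_annotated_loss_uniform_half(self):
        loss = loss_annotated(GridLogits(np.zeros((1, 2, 2))), 0, {3}, NO_NORMALIZATION)
        assert loss == pytest.approx(4 * np.log(2))

    def test_annotated_loss_bounded_under_balanced(self, rng):
        for _ in range(20):
            gamma = rng.normal(scale=50, size=(1, 4, 4))
            loss = loss_annotated(GridLogits(gamma), 0, set(), BALANCED)
            assert loss <= -np.log(BALANCED_BASE) + 1e-9

    def test_unannotated_positive_vanishes_with_one_hot_cell(self):
        gamma = np.full((1, 2, 2), -40.0)
        gamma[0, 1, 1] = 40.0
        loss = loss_unannotated_positive(GridLogits(gamma), 0, NO_NORMALIZATION)
        assert loss == pytest.approx(0.0, abs=1e-6)

    def test_unannotated_negative_vanishes_when_all_off(self):
        loss = loss_unannotated_negative(
            GridLogits(np.full((1, 2, 2), -40.0)), 0, NO_NORMALIZATION
        )
        assert loss == pytest.approx(0.0, abs=1e-6)

    def test_mtl_half_probability_gives_log2(self):
        z = np.zeros((2, 4, 4))
        t = np.zeros((2, 4, 4))
        statuses = np.array(
            [AnnotationStatus.ANNOTATED_POSITIVE, AnnotationStatus.UNANNOTATED_NEGATIVE]
        )
        # expectation over both channels; only one is annotated-positive
        assert mtl_loss(z, t, statuses) == pytest.approx(np.log(2) / 2)

    def test_mtl_no_annotated_positive_channels(self):
        z = np.random.default_rng(0).normal(size=(3, 4, 4))
        statuses = np.full(3, AnnotationStatus.UNANNOTATED_POSITIVE)
        assert mtl_loss(z, np.zeros_like(z), statuses) == 0.0

    def test_mtl_shape_mismatch(self):
        with pytest.raises(ValueError):
            mtl_loss(np.zeros((1, 4, 4)), np.zeros((1, 8, 8)), [0])

    def test_total_loss_arithmetic(self):
        w = LossWeights(lambda_a=3.0, lambda_t=300.0)
        assert total_loss(1.0, 0.01, w) == pytest.approx(4.0)
        assert total_loss(2.5, 123.0, LossWeights(lambda_t=0.0)) == 2.5


class TestMilLoss:
    def _batch_entry(self, gamma, statuses, cells=None):
        return (GridLogits(gamma), statuses, cells or {})

    def test_all_negative_confident_batch_is_zero(self):
        gamma = np.full((3, 2, 2), -40.0)
        statuses = {k: AnnotationStatus.UNANNOTATED_NEGATIVE for k in range(3)}
        val = mil_loss([self._batch_entry(gamma, statuses)], spec=NO_NORMALIZATION)
        assert val == pytest.approx(0.0, abs=1e-6)

    def test_two_image_hand_computation(self):
        # image 1: one class, annotated positive, 1x1 grid, sigma=0.5
        # image 2: one class, unannotated positive, sigma=0.5
        g = np.zeros((1, 1, 1))
        batch = [
            (GridLogits(g), {0: AnnotationStatus.ANNOTATED_POSITIVE}, {0: {0}}),
            (GridLogits(g), {0: AnnotationStatus.UNANNOTATED_POSITIVE}, {}),
        ]
        w = LossWeights(lambda_a=3.0)
        # hand: L_A = -log 0.5 ; L_U+ = -log 0.5 ; mean(3*log2, log2) = 2 log2
        val = mil_loss(batch, weights=w, spec=NO_NORMALIZATION)
        assert val == pytest.approx(2 * np.log(2))

    def test_lambda_a_zero_silences_annotated_images(self, rng):
        gamma = rng.normal(size=(2, 2, 2))
        statuses = {0: AnnotationStatus.ANNOTATED_POSITIVE,
                    1: AnnotationStatus.ANNOTATED_NEGATIVE}
        entry = (GridLogits(gamma), statuses, {0: {1}})
        val = mil_loss([entry], weights=LossWeights(lambda_a=0.0), spec=BALANCED)
        assert val == 0.0

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            mil_loss([])


# ---------------------------------------------------------------------------
# oracle equivalence and monotonicity
# ---------------------------------------------------------------------------

class TestOracleEquivalence:
    @pytest.mark.parametrize("spec", SPECS, ids=[s.mode for s in SPECS])
    def test_log_space_matches_direct_products(self, spec, rng):
        for _ in range(40):
            gh, gw = rng.integers(1, 5, size=2)
            gamma = rng.normal(scale=3.0, size=(3, gh, gw))
            logits = GridLogits(gamma)
            lo = spec.floor(gh * gw)
            for k in range(3):
                mask = rng.random((gh, gw)) > 0.5
                assert image_probability(logits, k, spec) == pytest.approx(
                    oracle_ck(gamma[k], lo), abs=1e-10
                )
                assert loss_annotated(logits, k, mask, spec) == pytest.approx(
                    oracle_loss_annotated(gamma[k], mask, lo), abs=1e-10, rel=1e-10
                )
                assert loss_unannotated_positive(logits, k, spec) == pytest.approx(
                    oracle_loss_up(gamma[k], lo), abs=1e-10, rel=1e-10
                )
                assert loss_unannotated_negative(logits, k, spec) == pytest.approx(
                    oracle_loss_un(gamma[k], lo), abs=1e-10, rel=1e-10
                )

    def test_ck_strictly_increasing_in_each_logit(self, rng):
        gamma = rng.normal(size=(1, 3, 3))
        base = image_probability(GridLogits(gamma), 0, BALANCED)
        for j in range(9):
            bumped = gamma.copy()
            bumped[0, j // 3, j % 3] += 1e-4
            up = image_probability(GridLogits(bumped), 0, BALANCED)
            assert up > base


class TestUnderflowGuard:
    @pytest.mark.parametrize("spec", [BALANCED, FIXED_098], ids=["balanced", "fixed"])
    def test_losses_finite_for_extreme_logits(self, spec, rng):
        gamma = rng.choice([-1e4, 1e4], size=(1, 32, 32))
        logits = GridLogits(gamma)
        mask = rng.random((32, 32)) > 0.5
        for value in (
            loss_annotated(logits, 0, mask, spec),
            loss_unannotated_positive(logits, 0, spec),
            loss_unannotated_negative(logits, 0, spec),
            image_probability(logits, 0, spec),
        ):
            assert np.isfinite(value)

    def test_gradients_finite_for_extreme_logits(self, rng):
        gamma = Tensor(
            rng.choice([-1e4, 1e4], size=(1, 2, 8, 8)), requires_grad=True
        )
        statuses = np.array(
            [[AnnotationStatus.UNANNOTATED_POSITIVE, AnnotationStatus.ANNOTATED_POSITIVE]]
        )
        cells = np.zeros((1, 2, 8, 8), dtype=bool)
        cells[0, 1, :4] = True
        loss = mil_loss_tensor(gamma, statuses, cells, spec=BALANCED)
        loss.backward()
        assert np.isfinite(loss.value)
        assert np.all(np.isfinite(gamma.grad))


class TestTensorOps:
    def test_mil_tensor_matches_scalar_api(self, rng):
        gamma = rng.normal(scale=2.0, size=(2, 3, 2, 2))
        statuses = np.array(
            [
                [AnnotationStatus.ANNOTATED_POSITIVE,
                 AnnotationStatus.UNANNOTATED_NEGATIVE,
                 AnnotationStatus.UNANNOTATED_POSITIVE],
                [AnnotationStatus.ANNOTATED_NEGATIVE,
                 AnnotationStatus.UNANNOTATED_POSITIVE,
                 AnnotationStatus.UNANNOTATED_NEGATIVE],
            ]
        )
        cells = np.zeros((2, 3, 2, 2), dtype=bool)
        cells[0, 0, 0, 1] = True
        w = LossWeights(lambda_a=3.0)
        tensor_val = float(
            mil_loss_tensor(Tensor(gamma), statuses, cells, w, BALANCED).value
        )
        batch = [
            (GridLogits(gamma[0]), dict(enumerate(statuses[0])), {0: {1}}),
            (GridLogits(gamma[1]), dict(enumerate(statuses[1])), {}),
        ]
        assert tensor_val == pytest.approx(mil_loss(batch, w, BALANCED), rel=1e-12)

    def test_mil_tensor_gradient_against_finite_differences(self, rng):
        statuses = np.array([[0, 2], [3, 1]])
        cells = np.zeros((2, 2, 2, 2), dtype=bool)
        cells[0, 0, 1, 1] = True
        x0 = rng.normal(size=(2, 2, 2, 2))

        def f(arr):
            return float(mil_loss_tensor(Tensor(arr), statuses, cells).value)

        t = Tensor(x0.copy(), requires_grad=True)
        mil_loss_tensor(t, statuses, cells).backward()
        eps = 1e-6
        for idx in np.ndindex(x0.shape):
            bump = x0.copy()
            bump[idx] += eps
            hi = f(bump)
            bump[idx] -= 2 * eps
            lo_v = f(bump)
            assert t.grad[idx] == pytest.approx((hi - lo_v) / (2 * eps), abs=1e-5)

    def test_mtl_tensor_matches_scalar(self, rng):
        z = rng.normal(size=(2, 3, 4, 4))
        t = (rng.random((2, 3, 4, 4)) > 0.5).astype(float)
        statuses = rng.integers(0, 4, size=(2, 3))
        tensor_val = float(mtl_loss_tensor(Tensor(z), t, statuses).value)
        assert tensor_val == pytest.approx(mtl_loss(z, t, statuses), rel=1e-6)
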