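"""Closed-form values, brute-force oracles and gradients of the losses."""

import math

import numpy as np
import pytest

from mmdda._autograd import Tensor
from mmdda.objectives import (KernelConfig, LossBundle, classification_loss,
                              consistency_loss, correlation_loss, domain_loss,
                              gaussian_kernel, kernel_gram, total_loss)

from conftest import numeric_gradient

CFG = KernelConfig()


def brute_force_correlation(mri, pet, sigma=1.0, eps=1e-6):
    """Explicit double loop over the cross-modal kernel matrix."""
    total = 0.0
    for x in mri:
        for y in pet:
            k = math.exp(-np.sum((x - y) ** 2) / (2 * sigma ** 2))
            total -= k * math.log(k + eps)
    return total


class TestGaussianKernel:
    def test_identical_vectors_give_one(self, rng):
        x = rng.normal(size=5)
        assert gaussian_kernel(x, x.copy(), CFG).item() == pytest.approx(1.0)

    def test_unit_distance_closed_form(self):
        value = gaussian_kernel(np.array([1.0, 0.0]), np.array([0.0, 0.0]), CFG)
        assert value.item() == pytest.approx(math.exp(-0.5), abs=1e-9)

    def test_symmetry(self, rng):
        x, y = rng.normal(size=4), rng.normal(size=4)
        assert gaussian_kernel(x, y, CFG).item() == pytest.approx(
            gaussian_kernel(y, x, CFG).item(), abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            gaussian_kernel(np.zeros(3), np.zeros(4), CFG)

    def test_sigma_validation(self):
        with pytest.raises(ValueError):
            KernelConfig(sigma=0.0)


class TestCorrelationLoss:
    def test_identical_single_pair(self):
        f = np.array([[1.0, 2.0, 3.0]])
        # K = 1 forced; loss = -log(1 + 1e-6) ~= -1e-6
        assert correlation_loss(f, f.copy(), CFG).item() == pytest.approx(
            -math.log(1 + 1e-6), abs=1e-12)

    def test_unit_distance_single_pair(self):
        mri = np.array([[1.0, 0.0]])
        pet = np.array([[0.0, 0.0]])
        k = math.exp(-0.5)
        expected = -k * math.log(k + 1e-6)
        assert correlation_loss(mri, pet, CFG).item() == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.30325, abs=5e-5)

    @pytest.mark.parametrize("n", [2, 3, 5])
    def test_matches_brute_force_double_sum(self, n, rng):
        mri = rng.normal(size=(n, 4))
        pet = rng.normal(size=(n, 4))
        assert correlation_loss(mri, pet, CFG).item() == pytest.approx(
            brute_force_correlation(mri, pet), abs=1e-9)

    def test_empty_batch_raises(self):
        with pytest.raises(ValueError):
            correlation_loss(np.empty((0, 3)), np.empty((0, 3)), CFG)

    def test_single_pair_shape_on_dense_grid(self):
        """-K log(K+eps): non-negative on (0,1) with maximum near K = 1/e."""
        k = np.linspace(1e-4, 0.9999, 2001)
        values = -k * np.log(k + CFG.epsilon)
        assert (values >= 0).all()
        assert k[np.argmax(values)] == pytest.approx(1 / math.e, abs=2e-3)
        # O(eps) dip below zero exactly at K = 1
        assert -1.0 * math.log(1 + CFG.epsilon) < 0

    def test_gradient_check(self, rng):
        mri = Tensor(rng.normal(size=(2, 3)), requires_grad=True)
        pet = Tensor(rng.normal(size=(2, 3)), requires_grad=True)
        correlation_loss(mri, pet, CFG).backward()

        for t in (mri, pet):
            num = numeric_gradient(
                lambda: correlation_loss(mri.data, pet.data, CFG).item(), t.data)
            np.testing.assert_allclose(t.grad, num, atol=1e-6)

    def test_consistency_and_classification_gradients(self, rng):
        f_s = Tensor(rng.normal(size=6), requires_grad=True)
        f_t = Tensor(rng.normal(size=6), requires_grad=True)
        consistency_loss(f_s, f_t).backward()
        num = numeric_gradient(
            lambda: consistency_loss(f_s.data, f_t.data).item(), f_s.data)
        np.testing.assert_allclose(f_s.grad, num, atol=1e-6)

        logits = Tensor(rng.normal(size=(3, 2)), requires_grad=True)
        labels = [0, 1, 1]
        classification_loss(logits.softmax(-1), labels).backward()
        num = numeric_gradient(
            lambda: classification_loss(
                Tensor(logits.data).softmax(-1), labels).item(), logits.data)
        np.testing.assert_allclose(logits.grad, num, atol=1e-6)


class TestConsistencyLoss:
    def test_equal_vectors_zero(self, rng):
        v = rng.normal(size=6)
        assert consistency_loss(v, v.copy()).item() == 0.0

    def test_closed_form(self):
        assert consistency_loss(np.array([2.0, 0.0]),
                                np.array([0.0, 0.0])).item() == pytest.approx(2.0)

    def test_symmetry(self, rng):
        a, b = rng.normal(size=5), rng.normal(size=5)
        assert consistency_loss(a, b).item() == pytest.approx(
            consistency_loss(b, a).item())

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            consistency_loss(np.zeros(3), np.zeros(4))


class TestCrossEntropyLosses:
    @pytest.mark.parametrize("loss_fn", [classification_loss, domain_loss])
    def test_uniform_prediction(self, loss_fn):
        assert loss_fn(np.array([[0.5, 0.5]]), [1]).item() == pytest.approx(
            math.log(2), abs=1e-9)

    @pytest.mark.parametrize("loss_fn", [classification_loss, domain_loss])
    def test_confident_correct_prediction(self, loss_fn):
        assert loss_fn(np.array([[0.0, 1.0]]), [1]).item() == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("loss_fn", [classification_loss, domain_loss])
    def test_point_eight(self, loss_fn):
        assert loss_fn(np.array([[0.2, 0.8]]), [1]).item() == pytest.approx(
            -math.log(0.8), abs=1e-9)
        assert -math.log(0.8) == pytest.approx(0.22314, abs=5e-6)

    def test_mean_over_batch(self):
        probs = np.array([[0.2, 0.8], [0.5, 0.5]])
        expected = (-math.log(0.8) + math.log(2)) / 2
        assert classification_loss(probs, [1, 0]).item() == pytest.approx(expected)

    def test_invalid_rows_raise(self):
        with pytest.raises(ValueError):
            classification_loss(np.array([[0.7, 0.7]]), [1])
        with pytest.raises(ValueError):
            classification_loss(np.array([[0.5, 0.5]]), [2])


class TestTotalLoss:
    def test_sum_of_components(self):
        bundle = total_loss(cor_s=0.1, cor_t=0.2, mse=0.3, cls=0.4, dom=0.5)
        assert bundle.total == pytest.approx(1.5)

    def test_phase1_composition(self):
        bundle = total_loss(cor_s=0.7, cls=0.3)
        assert bundle.total == pytest.approx(1.0)
        assert bundle.cor_t == bundle.mse == bundle.dom == 0.0

    def test_nan_component_raises(self):
        with pytest.raises(FloatingPointError, match="cor_s"):
            total_loss(cor_s=float("nan"))

    def test_bundle_identity_property(self):
        bundle = LossBundle(cor_s=1, cor_t=2, mse=3, cls=4, dom=5)
        assert bundle.total == bundle.cor_s + bundle.cor_t + bundle.mse + \
            bundle.cls + bundle.dom


def test_kernel_gram_matches_pairwise_kernel(rng):
    mri = rng.normal(size=(3, 4))
    pet = rng.normal(size=(3, 4))
    gram = kernel_gram(mri, pet, CFG).data
    for i in range(3):
        for j in range(3):
            assert gram[i, j] == pytest.approx(
                gaussian_kernel(mri[i], pet[j], CFG).item(), abs=1e-12)
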