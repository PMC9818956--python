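"""Similarity metrics, diffusion regularizer, composed training losses."""

import numpy as np
import pytest

from penreg.homography import PairedLandmarks
from penreg.losses import (
    diffusion_regularizer,
    semisupervised_loss,
    semisupervised_loss_grad,
    similarity_mse,
    similarity_ncc,
    similarity_ssd,
    unsupervised_loss,
    unsupervised_loss_grad,
)
from penreg.warp import warp_image_dense


class TestSimilarities:
    def test_mse_identical_zero(self, rng):
        img = rng.random((8, 8))
        assert similarity_mse(img, img) == 0.0

    def test_mse_unit_difference(self):
        assert similarity_mse(np.ones((4, 4)), np.zeros((4, 4))) == 1.0

    def test_mse_elementwise_oracle(self, rng):
        a, b = rng.random((7, 9)), rng.random((7, 9))
        expect = float(np.mean([(x - y) ** 2 for x, y in zip(a.ravel(), b.ravel())]))
        assert similarity_mse(a, b) == pytest.approx(expect, rel=1e-12)

    def test_mse_respects_mask(self, rng):
        a, b = rng.random((6, 6)), rng.random((6, 6))
        mask = np.zeros((6, 6))
        mask[2, 2] = 1
        assert similarity_mse(a, b, mask) == pytest.approx((a[2, 2] - b[2, 2]) ** 2)

    def test_ssd_is_n_times_mse(self, rng):
        a, b = rng.random((12, 10)), rng.random((12, 10))
        assert similarity_ssd(a, b) == pytest.approx(120 * similarity_mse(a, b), rel=1e-9)

    def test_ssd_small_example(self):
        a = np.zeros((2, 2))
        assert similarity_ssd(a + 1.0, a) == 4.0

    def test_ncc_self_correlation(self, rng):
        img = rng.random((8, 8))
        assert similarity_ncc(img, img) == pytest.approx(1.0)

    def test_ncc_affine_invariance(self, rng):
        img = rng.random((8, 8))
        assert similarity_ncc(img, 2.5 * img + 0.3) == pytest.approx(1.0)
        assert similarity_ncc(img, -img + 0.7) == pytest.approx(-1.0)

    def test_ncc_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            similarity_ncc(np.ones((4, 4)), np.random.rand(4, 4))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            similarity_mse(np.zeros((3, 3)), np.zeros((4, 3)))


class TestDiffusionRegularizer:
    def test_constant_field_zero(self):
        field = np.full((6, 7, 2), 3.2)
        assert diffusion_regularizer(field) == 0.0

    def test_linear_field_counts_valid_differences(self):
        h, w = 5, 8
        field = np.zeros((h, w, 2))
        field[:, :, 0] = np.arange(w)[None, :]  # dx(x, y) = x
        # every forward x-difference of dx is 1; there are h * (w - 1) of them
        assert diffusion_regularizer(field) == h * (w - 1)

    def test_matches_double_loop_oracle(self, rng):
        field = rng.uniform(-1, 1, (6, 6, 2))
        total = 0.0
        for c in range(2):
            for y in range(6):
                for x in range(5):
                    total += (field[y, x + 1, c] - field[y, x, c]) ** 2
            for y in range(5):
                for x in range(6):
                    total += (field[y + 1, x, c] - field[y, x, c]) ** 2
        assert diffusion_regularizer(field) == pytest.approx(total, rel=1e-12)

    def test_nonnegative_and_zero_iff_constant(self, rng):
        field = rng.uniform(-2, 2, (5, 5, 2))
        assert diffusion_regularizer(field) > 0
        assert diffusion_regularizer(np.zeros((5, 5, 2))) == 0.0


class TestComposedLosses:
    def test_perfect_alignment_zero(self, rng):
        img = rng.random((8, 8))
        field = np.zeros((8, 8, 2))
        assert unsupervised_loss(img, img, field, lambda_=0.5) == 0.0

    def test_lambda_zero_is_similarity(self, rng):
        fixed, moving = rng.random((8, 8)), rng.random((8, 8))
        field = rng.uniform(-0.8, 0.8, (8, 8, 2))
        warped = warp_image_dense(moving, field)
        assert unsupervised_loss(fixed, moving, field, lambda_=0.0) == pytest.approx(
            similarity_mse(fixed, warped)
        )

    def test_composition_of_parts(self, rng):
        """Loss = similarity + lambda * (diffusion sum) / n_pixels."""
        fixed, moving = rng.random((8, 10)), rng.random((8, 10))
        field = rng.uniform(-0.8, 0.8, (8, 10, 2))
        lam = 0.37
        warped = warp_image_dense(moving, field)
        expect = similarity_mse(fixed, warped) + lam * diffusion_regularizer(field) / 80
        assert unsupervised_loss(fixed, moving, field, lambda_=lam) == pytest.approx(expect)

    def test_unknown_similarity_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown similarity"):
            unsupervised_loss(
                rng.random((4, 4)), rng.random((4, 4)), np.zeros((4, 4, 2)),
                similarity="mae",
            )

    def test_landmark_term_three_four_five(self, rng):
        fixed, moving = rng.random((16, 16)), rng.random((16, 16))
        field = np.zeros((16, 16, 2))
        # zero field: mapped landmark = moving point (3, 4), fixed (0, 0)
        lms = PairedLandmarks([(0.0, 0.0)], [(3.0, 4.0)], ["background"])
        semi = semisupervised_loss(fixed, moving, field, lms, lambda_=0.0, mu=1.0)
        unsup = unsupervised_loss(fixed, moving, field, lambda_=0.0)
        assert semi - unsup == pytest.approx(25.0)

    def test_mu_zero_reduces_to_unsupervised(self, rng):
        fixed, moving = rng.random((8, 8)), rng.random((8, 8))
        field = rng.uniform(-1, 1, (8, 8, 2))
        lms = PairedLandmarks([(2.0, 2.0)], [(3.0, 4.0)], ["foreground"])
        assert semisupervised_loss(fixed, moving, field, lms, mu=0.0) == pytest.approx(
            unsupervised_loss(fixed, moving, field)
        )

    def test_empty_landmarks_rejected(self, rng):
        with pytest.raises(ValueError):
            semisupervised_loss(
                rng.random((4, 4)), rng.random((4, 4)), np.zeros((4, 4, 2)), None
            )


class TestLossGradients:
    """Analytic gradients with respect to the field vs central differences."""

    @pytest.mark.parametrize("similarity", ["mse", "ncc", "ssd"])
    def test_unsupervised_gradient(self, rng, similarity):
        fixed, moving = rng.random((8, 8)), rng.random((8, 8))
        field = rng.uniform(-1.4, 1.4, (8, 8, 2))
        _, g = unsupervised_loss_grad(fixed, moving, field, 0.01, similarity)
        self._check(
            lambda: unsupervised_loss(fixed, moving, field, 0.01, similarity),
            field, g, rng,
        )

    def test_semisupervised_gradient(self, rng):
        fixed, moving = rng.random((8, 8)), rng.random((8, 8))
        field = rng.uniform(-1.4, 1.4, (8, 8, 2))
        lms = PairedLandmarks(
            [(2.2, 3.1), (5.6, 4.4)], [(2.9, 3.3), (5.1, 5.0)],
            ["foreground", "background"],
        )
        _, g = semisupervised_loss_grad(fixed, moving, field, lms, 0.01, 1.0, "mse")
        self._check(
            lambda: semisupervised_loss(fixed, moving, field, lms, 0.01, 1.0, "mse"),
            field, g, rng,
        )

    @staticmethod
    def _check(f, field, grad, rng, n=25, eps=1e-6, rtol=1e-4):
        flat = field.ravel()
        for i in rng.choice(flat.size, size=n, replace=False):
            old = flat[i]
            flat[i] = old + eps
            up = f()
            flat[i] = old - eps
            dn = f()
            flat[i] = old
            fd = (up - dn) / (2 * eps)
            an = grad.ravel()[i]
            assert abs(fd - an) <= rtol * max(abs(fd), abs(an), 1e-6)
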