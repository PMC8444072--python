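import numpy as np
import pytest

from orthomoments.krawtchouk import (
    km_invariant_features,
    km_moments,
    km_reconstruct,
    krawtchouk_basis,
)


def weighted_krawtchouk_exact(n, x, p, N):
    """Independent oracle: exact rational arithmetic for the terminating
    hypergeometric sum and the binomial weight, combined in log space
    (the exact integers overflow a float for large N)."""
    import math
    from fractions import Fraction
    from math import comb, factorial

    p = Fraction(p)
    # k_n(x) = sum_k (-n)_k (-x)_k / ((-(N-1))_k k!) p^-k  (terminating)
    k_val, term = Fraction(0), Fraction(1)
    for k in range(min(n, x) + 1):
        k_val += term
        denom = (-(N - 1) + k) * (k + 1)
        if denom == 0:
            break
        term = term * Fraction((-n + k) * (-x + k), denom) / p
    w = Fraction(comb(N - 1, x)) * p**x * (1 - p) ** (N - 1 - x)
    rho = ((1 - p) / p) ** n * Fraction(
        factorial(n) * factorial(N - 1 - n), factorial(N - 1)
    )
    if k_val == 0:
        return 0.0
    sign = 1.0 if k_val > 0 else -1.0

    def flog(fr):
        return math.log(abs(fr.numerator)) - math.log(fr.denominator)

    return sign * math.exp(flog(k_val) + 0.5 * (flog(w) - flog(rho)))


class TestBasis:
    def test_order_zero_row_is_sqrt_binomial_weight(self):
        from scipy.stats import binom

        b = krawtchouk_basis(1, 10, 0.3)
        np.testing.assert_allclose(b.K[0], np.sqrt(binom.pmf(np.arange(10), 9, 0.3)), atol=1e-12)
        assert abs((b.K[0] ** 2).sum() - 1.0) < 1e-12

    def test_first_order_root(self):
        # k_1(x; p, N-1) = 1 - x/(p(N-1)) vanishes at x = p(N-1) = 2
        b = krawtchouk_basis(2, 5, 0.5)
        assert abs(b.K[1, 2]) < 1e-12
        # and the weighted row agrees with the exact 2F1 evaluation
        for x in range(5):
            assert abs(b.K[1, x] - weighted_krawtchouk_exact(1, x, 0.5, 5)) < 1e-12

    @pytest.mark.parametrize("l,N,p", [(8, 8, 0.5), (16, 16, 0.3), (20, 64, 0.5)])
    def test_orthonormality(self, l, N, p):
        b = krawtchouk_basis(l, N, p)
        np.testing.assert_allclose(b.K @ b.K.T, np.eye(l), atol=1e-10)

    def test_large_grid_matches_exact_oracle(self):
        # stability regime of the wing images: N = 724, order 200
        b = krawtchouk_basis(200, 724, 0.5)
        assert np.all(np.isfinite(b.K))
        for n, x in [(0, 0), (50, 362), (120, 50), (199, 700)]:
            exact = weighted_krawtchouk_exact(n, x, 0.5, 724)
            assert abs(b.K[n, x] - exact) <= 1e-10 * max(1.0, abs(exact))

    def test_order_beyond_grid_rejected(self):
        with pytest.raises(ValueError):
            krawtchouk_basis(9, 8, 0.5)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.2])
    def test_invalid_p_rejected(self, p):
        with pytest.raises(ValueError):
            krawtchouk_basis(4, 8, p)


class TestMoments:
    def test_zero_image(self):
        b = krawtchouk_basis(4, 6, 0.5)
        assert np.all(km_moments(np.zeros((6, 6)), b, b).Q == 0)

    def test_delta_image_is_outer_product(self):
        bx = krawtchouk_basis(5, 5, 0.5)
        by = krawtchouk_basis(5, 7, 0.5)
        img = np.zeros((5, 7))
        img[2, 4] = 1.0
        Q = km_moments(img, bx, by).Q
        np.testing.assert_allclose(Q, np.outer(bx.K[:, 2], by.K[:, 4]), atol=1e-12)

    def test_matches_brute_force_double_sum(self, rng):
        img = rng.random((8, 8))
        b = krawtchouk_basis(8, 8, 0.5)
        Q = km_moments(img, b, b).Q
        brute = np.zeros((8, 8))
        for n in range(8):
            for m in range(8):
                brute[n, m] = sum(
                    b.K[n, x] * b.K[m, y] * img[x, y] for x in range(8) for y in range(8)
                )
        np.testing.assert_allclose(Q, brute, atol=1e-10)

    def test_dim_mismatch_rejected(self):
        b = krawtchouk_basis(4, 6, 0.5)
        with pytest.raises(ValueError):
            km_moments(np.zeros((5, 6)), b, b)

    def test_parseval_at_full_order(self, rng):
        img = (rng.random((12, 12)) > 0.5).astype(float)
        b = krawtchouk_basis(12, 12, 0.5)
        Q = km_moments(img, b, b).Q
        assert abs((Q**2).sum() - (img**2).sum()) < 1e-9 * (img**2).sum()


class TestReconstruction:
    def test_full_order_roundtrip_binary(self, rng):
        img = (rng.random((16, 16)) > 0.5).astype(float)
        b = krawtchouk_basis(16, 16, 0.5)
        rec = km_reconstruct(km_moments(img, b, b), b, b)
        assert np.max(np.abs(rec - img)) < 1e-9

    def test_zero_moments_to_zero_image(self):
        b = krawtchouk_basis(6, 6, 0.5)
        m = km_moments(np.zeros((6, 6)), b, b)
        assert np.all(km_reconstruct(m, b, b) == 0)

    def test_truncation_mse_monotone(self, rng):
        img = (rng.random((16, 16)) > 0.5).astype(float)

        def mse_at(l):
            b = krawtchouk_basis(l, 16, 0.5)
            return np.mean((km_reconstruct(km_moments(img, b, b), b, b) - img) ** 2)

        assert mse_at(4) >= mse_at(8) >= mse_at(16) - 1e-15


class TestInvariantFeatures:
    def test_feature_length_is_order_squared(self, ellipse_image):
        img = ellipse_image((64, 96), 32, 48, 12, 30)
        assert km_invariant_features(img, 20).shape == (400,)

    def test_half_turn_symmetry(self, ellipse_image):
        img = ellipse_image((64, 96), 28, 40, 10, 26)
        fa = km_invariant_features(img, 16)
        fb = km_invariant_features(np.rot90(img, 2).copy(), 16)
        assert np.linalg.norm(fa - fb) / np.linalg.norm(fa) < 1e-6

    def test_translation_rotation_scale_robust(self, ellipse_image):
        frame = (192, 256)
        base = ellipse_image(frame, 90, 120, 30, 90)
        fa = km_invariant_features(base, 40, frame=frame)
        moved = ellipse_image(frame, 80, 113, 36, 108)  # shifted, scaled x1.2
        rotated = ellipse_image(frame, 100, 110, 24, 72, rot=0.3)
        for other in (moved, rotated):
            fb = km_invariant_features(other, 40, frame=frame)
            assert np.linalg.norm(fa - fb) / np.linalg.norm(fa) < 0.05

    def test_zero_mass_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            km_invariant_features(np.zeros((32, 32)), 8)
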