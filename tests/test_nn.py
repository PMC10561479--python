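"""Convolution kernels (dilated and plain) and their hand-written gradients."""

import numpy as np
import pytest

from dmfnet.nn import BatchNorm2d, conv2d, conv2d_input_grad, conv2d_param_grads


def naive_conv(x, w, b, d):
    """Direct evaluation of the dilated cross-correlation sum (the oracle)."""
    n, c, h, wd = x.shape
    f = w.shape[0]
    xp = np.zeros((n, c, h + 2 * d, wd + 2 * d))
    xp[:, :, d : d + h, d : d + wd] = x
    y = np.zeros((n, f, h, wd))
    for s in range(n):
        for fo in range(f):
            for i in range(3):
                for j in range(3):
                    for ci in range(c):
                        y[s, fo] += w[fo, ci, i, j] * xp[s, ci, i * d : i * d + h, j * d : j * d + wd]
            if b is not None:
                y[s, fo] += b[fo]
    return y


def zero_inflate(w, d):
    """Spread a 3x3 kernel onto a (2d+1)x(2d+1) grid with zeros between taps."""
    f, c = w.shape[:2]
    k = 2 * d + 1
    out = np.zeros((f, c, k, k))
    out[:, :, ::d, ::d] = w
    return out


def naive_conv_anykernel(x, w, pad):
    """Plain (dilation-1) correlation with an arbitrary odd kernel."""
    n, c, h, wd = x.shape
    f, _, kh, kw = w.shape
    xp = np.zeros((n, c, h + 2 * pad, wd + 2 * pad))
    xp[:, :, pad : pad + h, pad : pad + wd] = x
    y = np.zeros((n, f, h, wd))
    for s in range(n):
        for fo in range(f):
            for i in range(kh):
                for j in range(kw):
                    for ci in range(c):
                        y[s, fo] += w[fo, ci, i, j] * xp[s, ci, i : i + h, j : j + wd]
    return y


class TestDilatedConv:
    def test_identity_kernel_reproduces_delta(self):
        x = np.zeros((1, 1, 9, 9))
        x[0, 0, 4, 4] = 1.0
        w = np.zeros((1, 1, 3, 3))
        w[0, 0, 1, 1] = 1.0
        np.testing.assert_allclose(conv2d(x, w, None, 1), x)

    def test_d2_delta_footprint_is_nine_spread_taps(self):
        # ones-kernel on a centred delta: support exactly at {-2, 0, +2}^2
        x = np.zeros((1, 1, 11, 11))
        x[0, 0, 5, 5] = 1.0
        w = np.ones((1, 1, 3, 3))
        y = conv2d(x, w, None, 2)[0, 0]
        expected = np.zeros((11, 11))
        for di in (-2, 0, 2):
            for dj in (-2, 0, 2):
                expected[5 + di, 5 + dj] = 1.0
        np.testing.assert_allclose(y, expected)

    @pytest.mark.parametrize("d", [1, 2, 3])
    def test_matches_direct_sum_oracle(self, d, rng):
        x = rng.standard_normal((2, 3, 10, 9))
        w = rng.standard_normal((4, 3, 3, 3))
        b = rng.standard_normal(4)
        np.testing.assert_allclose(conv2d(x, w, b, d), naive_conv(x, w, b, d), atol=1e-10)

    def test_d2_equals_zero_inflated_ordinary_conv(self, rng):
        # 50 random 16x16 inputs: dilation-2 conv == plain conv with the
        # kernel zero-inflated to 5x5
        w = rng.standard_normal((2, 2, 3, 3))
        w5 = zero_inflate(w, 2)
        for _ in range(50):
            x = rng.standard_normal((1, 2, 16, 16))
            got = conv2d(x, w, None, 2)
            exp = naive_conv_anykernel(x, w5, 2)
            np.testing.assert_allclose(got, exp, atol=1e-6)

    def test_invalid_dilation_rejected(self):
        with pytest.raises(ValueError, match="dilation"):
            conv2d(np.zeros((1, 1, 8, 8)), np.zeros((1, 1, 3, 3)), None, 0)


class TestConvGradients:
    @pytest.mark.parametrize("d", [1, 2])
    def test_gradients_match_finite_differences(self, d, rng):
        x = rng.standard_normal((2, 2, 6, 7))
        w = rng.standard_normal((3, 2, 3, 3))
        b = rng.standard_normal(3)
        y = conv2d(x, w, b, d)
        dx = conv2d_input_grad(y.copy(), w, d)
        dw, db = conv2d_param_grads(y.copy(), x, w, d)

        def objective():
            return 0.5 * float((conv2d(x, w, b, d) ** 2).sum())

        eps = 1e-6
        for arr, grad in ((x, dx), (w, dw), (b, db)):
            idx = tuple(rng.integers(s) for s in arr.shape)
            orig = arr[idx]
            arr[idx] = orig + eps
            fp = objective()
            arr[idx] = orig - eps
            fm = objective()
            arr[idx] = orig
            num = (fp - fm) / (2 * eps)
            assert num == pytest.approx(grad[idx], rel=1e-5, abs=1e-7)

    def test_d2_gradient_footprint_is_5x5(self, rng):
        # derivative of one output pixel w.r.t. the input must vanish
        # outside a 5x5 window (and sit exactly on the 9 dilated taps)
        w = rng.standard_normal((1, 1, 3, 3))
        dy = np.zeros((1, 1, 15, 15))
        dy[0, 0, 7, 7] = 1.0
        dx = conv2d_input_grad(dy, w, 2)[0, 0]
        nz = np.argwhere(dx != 0)
        assert len(nz) == 9
        assert np.all(np.abs(nz - 7) <= 2)  # inside the 5x5 window
        for r, c in nz:
            assert (r - 7) % 2 == 0 and (c - 7) % 2 == 0


class TestBatchNorm:
    def test_train_forward_normalises_batch(self, rng):
        bn = BatchNorm2d(3, dtype=np.float64)
        x = rng.standard_normal((4, 3, 8, 8)) * 2.0 + 1.0
        y = bn.forward(x.copy(), train=True)
        assert np.allclose(y.mean(axis=(0, 2, 3)), 0.0, atol=1e-7)
        assert np.allclose(y.std(axis=(0, 2, 3)), 1.0, atol=1e-3)

    def test_eval_uses_running_statistics(self, rng):
        bn = BatchNorm2d(2, dtype=np.float64)
        x = rng.standard_normal((4, 2, 8, 8)) * 3.0 + 2.0
        for _ in range(200):
            bn.forward(x.copy(), train=True)
        y = bn.forward(x.copy(), train=False)
        # converged running stats reproduce the batch normalisation
        assert np.allclose(y.mean(axis=(0, 2, 3)), 0.0, atol=1e-2)
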