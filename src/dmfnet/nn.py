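"""Minimal convolutional-network building blocks with explicit backprop.

Everything here operates on ``(N, C, H, W)`` float arrays.  A same-size 3x3
convolution with dilation ``d`` (stride 1, padding ``d``, so a kernel covers
a ``(2d+1) x (2d+1)`` footprint while the output stays ``H x W``) is
evaluated as one GEMM per sample: the three kernel-row offsets of the padded
input are stacked into a ``(3C, H*Wp)`` matrix and multiplied by a
``(3F, 3C)`` rearrangement of the kernels, after which the three kernel-
column blocks of the product are summed with their column shifts.  This
keeps the hot loop inside BLAS without a full im2col buffer; scratch
matrices are pooled and reused across calls.

The backward passes are written by hand (no autodiff framework is used):

* gradient w.r.t. the input is a convolution with the channel-transposed,
  spatially flipped kernel at the same dilation;
* gradient w.r.t. the weights is, per sample, a single GEMM between the
  column-shifted upstream gradient and the row-shifted input windows, which
  yields all nine tap gradients at once.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "conv2d",
    "conv2d_input_grad",
    "conv2d_param_grads",
    "Conv2d",
    "BatchNorm2d",
    "ConvBlock",
    "Tanh",
]

# scratch buffers keyed by (role, shape, dtype); single-threaded reuse
_POOL: dict = {}


def _buf(role: str, shape: tuple, dtype) -> np.ndarray:
    key = (role, shape, np.dtype(dtype).name)
    arr = _POOL.get(key)
    if arr is None:
        arr = np.zeros(shape, dtype)
        _POOL[key] = arr
    return arr


def _check_dilation(d: int) -> None:
    if int(d) != d or d < 1:
        raise ValueError(f"dilation must be a positive integer, got {d!r}")


def _fill_rows(R: np.ndarray, xp: np.ndarray, d: int, h: int) -> None:
    """Stack the three kernel-row offsets of the padded sample into R (3C, H*Wp)."""
    c, _, wp = xp.shape
    rv = R.reshape(3, c, h, wp)
    for i in range(3):
        rv[i] = xp[:, i * d : i * d + h, :]


def _tap_matrix(w: np.ndarray, dtype) -> np.ndarray:
    """Rearrange (F, C, 3, 3) kernels into the (3F, 3C) GEMM operand.

    Row ``j*F + f`` and column ``i*C + c`` hold ``w[f, c, i, j]``: rows index
    the kernel-column shift applied to the output, columns the kernel-row
    shift applied to the input.
    """
    return np.ascontiguousarray(w.transpose(3, 0, 2, 1), dtype).reshape(
        3 * w.shape[0], 3 * w.shape[1]
    )


def conv2d(
    x: np.ndarray,
    w: np.ndarray,
    b: np.ndarray | None = None,
    dilation: int = 1,
    out: np.ndarray | None = None,
) -> np.ndarray:
    """Same-size 3x3 cross-correlation with dilation.

    Parameters
    ----------
    x : (N, C, H, W) input activations.
    w : (F, C, 3, 3) kernels.
    b : (F,) bias or None.
    dilation : spacing between kernel taps; padding equals ``dilation`` so
        the output is again (N, F, H, W).
    """
    _check_dilation(dilation)
    d = dilation
    n, c, h, wd = x.shape
    if w.ndim != 4 or w.shape[1] != c or w.shape[2:] != (3, 3):
        raise ValueError(f"weight shape {w.shape} incompatible with input {x.shape}")
    f = w.shape[0]
    hp, wp = h + 2 * d, wd + 2 * d
    dt = x.dtype
    T = _tap_matrix(w, dt)
    # xp's border stays zero across calls: only the interior is rewritten
    xp = _buf("xp", (c, hp, wp), dt)
    R = _buf("rows", (3 * c, h * wp), dt)
    G = _buf("gemm", (3 * f, h * wp), dt)
    gv = G.reshape(3, f, h, wp)
    # caller-provided output buffer: every element is overwritten below
    y = out if out is not None else np.empty((n, f, h, wd), dt)
    for s in range(n):
        xp[:, d : d + h, d : d + wd] = x[s]
        _fill_rows(R, xp, d, h)
        np.matmul(T, R, out=G)
        ys = y[s]
        np.copyto(ys, gv[0, :, :, 0:wd])
        np.add(ys, gv[1, :, :, d : d + wd], out=ys)
        np.add(ys, gv[2, :, :, 2 * d : 2 * d + wd], out=ys)
    if b is not None:
        y += b.reshape(1, f, 1, 1).astype(dt, copy=False)
    return y


def conv2d_input_grad(dy: np.ndarray, w: np.ndarray, dilation: int = 1, out=None) -> np.ndarray:
    """Gradient of conv2d w.r.t. its input: transposed, flipped-kernel conv."""
    wt = w.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1]
    return conv2d(dy, wt, None, dilation, out=out)


def conv2d_param_grads(
    dy: np.ndarray, x: np.ndarray, w: np.ndarray, dilation: int = 1, bias: bool = True
) -> tuple[np.ndarray, np.ndarray | None]:
    """Gradients of conv2d w.r.t. weights (and bias)."""
    d = dilation
    n, c, h, wd = x.shape
    f = w.shape[0]
    hp, wp = h + 2 * d, wd + 2 * d
    dt = dy.dtype
    xp = _buf("xp", (c, hp, wp), dt)
    R = _buf("rows", (3 * c, h * wp), dt)
    D = _buf("dyw", (3 * f, h * wp), dt)
    dv = D.reshape(3, f, h, wp)
    G = _buf("wgrad", (3 * f, 3 * c), dt)
    acc = np.zeros((3 * f, 3 * c), dt)
    for s in range(n):
        xp[:, d : d + h, d : d + wd] = x[s]
        _fill_rows(R, xp, d, h)
        for j in range(3):
            dv[j, :, :, j * d : j * d + wd] = dy[s]
            dv[j, :, :, : j * d] = 0.0
            dv[j, :, :, j * d + wd :] = 0.0
        np.matmul(D, R.T, out=G)
        acc += G
    # acc[j*F + f, i*C + c] -> dW[f, c, i, j]
    dw = np.ascontiguousarray(acc.reshape(3, f, 3, c).transpose(1, 3, 2, 0))
    db = dy.sum(axis=(0, 2, 3), dtype=dt) if bias else None
    return dw, db


class Conv2d:
    """3x3 convolution layer with parameters, Kaiming fan-in initialisation.

    ``gain=2`` (He) is used ahead of ReLU; linear layers (the 1-filter noise
    taps) use ``gain=1`` so the fused tap sum does not saturate the Tanh.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        dilation: int = 1,
        bias: bool = True,
        gain: float = 2.0,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        _check_dilation(dilation)
        rng = rng or np.random.default_rng()
        fan_in = in_channels * 9
        std = np.sqrt(gain / fan_in)
        self.w = (rng.standard_normal((out_channels, in_channels, 3, 3)) * std).astype(dtype)
        self.b = np.zeros(out_channels, dtype) if bias else None
        self.dilation = dilation
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b) if bias else None
        self._x = None
        self._bufs: dict = {}  # per-layer activation/gradient buffers

    def _buf(self, role: str, shape: tuple, dtype) -> np.ndarray:
        key = (role, shape, np.dtype(dtype).name)
        arr = self._bufs.get(key)
        if arr is None:
            arr = np.empty(shape, dtype)
            self._bufs[key] = arr
        return arr

    def release_buffers(self) -> None:
        self._bufs.clear()
        self._x = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        n, _, h, wd = x.shape
        out = self._buf("y", (n, self.w.shape[0], h, wd), x.dtype)
        return conv2d(x, self.w, self.b, self.dilation, out=out)

    def backward(self, dy: np.ndarray, need_dx: bool = True) -> np.ndarray | None:
        dw, db = conv2d_param_grads(dy, self._x, self.w, self.dilation, self.b is not None)
        self.gw += dw
        if db is not None:
            self.gb += db
        x_shape = None if not need_dx else dy.shape[:1] + (self.w.shape[1],) + dy.shape[2:]
        self._x = None
        if need_dx:
            out = self._buf("dx", x_shape, dy.dtype)
            return conv2d_input_grad(dy, self.w, self.dilation, out=out)
        return None

    def parameters(self):
        out = [("w", self.w)]
        if self.b is not None:
            out.append(("b", self.b))
        return out

    def gradients(self):
        out = [("w", self.gw)]
        if self.b is not None:
            out.append(("b", self.gb))
        return out


class BatchNorm2d:
    """Per-channel batch normalisation with running statistics for inference.

    ``forward`` normalises in place (the conv output it receives is not
    needed elsewhere) and, in training mode, keeps the normalised activations
    for the backward pass.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1, dtype=np.float32):
        self.gamma = np.ones(channels, dtype)
        self.beta = np.zeros(channels, dtype)
        self.running_mean = np.zeros(channels, dtype)
        self.running_var = np.ones(channels, dtype)
        self.eps = eps
        self.momentum = momentum
        self.ggamma = np.zeros_like(self.gamma)
        self.gbeta = np.zeros_like(self.beta)
        self._xhat = None
        self._inv = None
        self._bufs: dict = {}

    def release_buffers(self) -> None:
        self._bufs.clear()
        self._xhat = self._inv = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        c = x.shape[1]
        sh = (1, c, 1, 1)
        eps = np.asarray(self.eps, x.dtype)
        if train:
            mean = x.mean(axis=(0, 2, 3), dtype=x.dtype)
            xhat = self._bufs.get(x.shape)
            if xhat is None or xhat.dtype != x.dtype:
                xhat = np.empty_like(x)
                self._bufs = {x.shape: xhat}
            np.subtract(x, mean.reshape(sh), out=xhat)
            xv = xhat.reshape(x.shape[0], c, -1)
            var = np.einsum("ncp,ncp->c", xv, xv) / (x.size // c)
            m = self.momentum
            self.running_mean += m * (mean - self.running_mean)
            self.running_var += m * (var - self.running_var)
            inv = 1.0 / np.sqrt(var + eps)
            xhat *= inv.reshape(sh)
            self._xhat, self._inv = xhat, inv
            np.multiply(xhat, self.gamma.reshape(sh), out=x)
            x += self.beta.reshape(sh)
            return x
        inv = 1.0 / np.sqrt(self.running_var.astype(x.dtype) + eps)
        scale = (self.gamma * inv).astype(x.dtype)
        shift = (self.beta - self.gamma * inv * self.running_mean).astype(x.dtype)
        np.multiply(x, scale.reshape(sh), out=x)
        x += shift.reshape(sh)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        c = dy.shape[1]
        sh = (1, c, 1, 1)
        m = dy.size // c
        tmp = _buf("bn_tmp", dy.shape, dy.dtype)
        np.multiply(dy, xhat, out=tmp)
        dgamma = tmp.sum(axis=(0, 2, 3), dtype=dy.dtype)
        dbeta = dy.sum(axis=(0, 2, 3), dtype=dy.dtype)
        self.ggamma += dgamma
        self.gbeta += dbeta
        # dx = gamma*inv * (dy - mean(dy) - xhat*mean(dy*xhat)), in place
        xhat *= (dgamma / m).reshape(sh)
        dy -= xhat
        dy -= (dbeta / m).reshape(sh)
        dy *= (self.gamma * inv).reshape(sh)
        self._xhat = self._inv = None
        return dy

    def parameters(self):
        return [("gamma", self.gamma), ("beta", self.beta)]

    def gradients(self):
        return [("gamma", self.ggamma), ("beta", self.gbeta)]

    def state(self):
        return [("running_mean", self.running_mean), ("running_var", self.running_var)]


class ConvBlock:
    """conv [+ BN] [+ activation] composite used for every layer of the net."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        dilation: int = 1,
        bn: bool = True,
        activation: str = "relu",
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        if activation not in ("relu", "none"):
            raise ValueError(f"unsupported block activation {activation!r}")
        gain = 2.0 if activation == "relu" else 1.0
        self.conv = Conv2d(in_channels, out_channels, dilation, bias=not bn, gain=gain, rng=rng, dtype=dtype)
        self.bn = BatchNorm2d(out_channels, dtype=dtype) if bn else None
        self.activation = activation
        self._out = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = self.conv.forward(x, train)
        if self.bn is not None:
            y = self.bn.forward(y, train)
        if self.activation == "relu":
            np.maximum(y, 0.0, out=y)
            if train:
                self._out = y
        return y

    def backward(self, dy: np.ndarray, need_dx: bool = True) -> np.ndarray | None:
        """Consumes ``dy`` (may modify it in place); returns the input gradient."""
        if self.activation == "relu":
            np.multiply(dy, self._out > 0, out=dy)
            self._out = None
        if self.bn is not None:
            dy = self.bn.backward(dy)
        return self.conv.backward(dy, need_dx)

    def modules(self):
        return [self.conv] + ([self.bn] if self.bn is not None else [])


class Tanh:
    def __init__(self):
        self._out = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = np.tanh(x)
        if train:
            self._out = y
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * (1.0 - self._out * self._out)
        self._out = None
        return dx
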