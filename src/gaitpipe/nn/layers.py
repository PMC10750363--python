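"""Minimal 3D-CNN layer kit (numpy).

All layers operate on float32 arrays in ``(N, C, T, H, W)`` layout and
implement an explicit ``forward``/``backward`` pair.  Convolutions are
lowered to a single BLAS matmul through an im2col view built with
``numpy.lib.stride_tricks.sliding_window_view``; the backward pass scatters
the column gradient back with one strided add per kernel offset, so no
python loop runs over image positions.

The kit is deliberately small: exactly the operations a bottleneck-block
residual 3D network needs (conv, batch norm, relu, max pool, global average
pool, linear) and nothing else.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv3d",
    "BatchNorm3d",
    "ReLU",
    "MaxPool3d",
    "GlobalAvgPool",
    "Linear",
    "sigmoid",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable two-branch form
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _triple(v):
    if np.isscalar(v):
        return (int(v),) * 3
    t = tuple(int(x) for x in v)
    if len(t) != 3:
        raise ValueError(f"expected scalar or length-3 tuple, got {v!r}")
    return t


class Layer:
    """Base: parameterised layers expose .params / .grads dicts."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self._cache = None

    def forward(self, x, train=False, keep_cache=True):  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover
        raise NotImplementedError

    def clear_cache(self):
        self._cache = None


def _im2col(xp: np.ndarray, ksize, stride):
    """(N, C, Tp, Hp, Wp) -> column matrix (N*P, C*kt*kh*kw) + out shape.

    ``xp`` is already padded.  P = To*Ho*Wo output positions.
    """
    kt, kh, kw = ksize
    st, sh, sw = stride
    n = xp.shape[0]
    view = np.lib.stride_tricks.sliding_window_view(xp, (kt, kh, kw), axis=(2, 3, 4))
    view = view[:, :, ::st, ::sh, ::sw]  # (N, C, To, Ho, Wo, kt, kh, kw)
    to, ho, wo = view.shape[2:5]
    # (N, To, Ho, Wo, C, kt, kh, kw) -> (N*P, C*k)
    col = np.ascontiguousarray(view.transpose(0, 2, 3, 4, 1, 5, 6, 7))
    col = col.reshape(n * to * ho * wo, -1)
    return col, (to, ho, wo)


class Conv3d(Layer):
    def __init__(self, c_in, c_out, ksize, stride=1, pad=0, *, bias=False, rng=None):
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.ksize = _triple(ksize)
        self.stride = _triple(stride)
        self.pad = _triple(pad)
        kt, kh, kw = self.ksize
        fan_in = c_in * kt * kh * kw
        rng = rng if rng is not None else np.random.default_rng(0)
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, kt, kh, kw))
        self.params["w"] = w.astype(np.float32)
        if bias:
            self.params["b"] = np.zeros(c_out, dtype=np.float32)

    def forward(self, x, train=False, keep_cache=True):
        pt, ph, pw = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pt), (ph, ph), (pw, pw))) if any(self.pad) else x
        col, (to, ho, wo) = _im2col(xp, self.ksize, self.stride)
        wmat = self.params["w"].reshape(self.c_out, -1).T  # (C*k, F)
        out = col @ wmat
        if "b" in self.params:
            out += self.params["b"]
        n = x.shape[0]
        out = out.reshape(n, to, ho, wo, self.c_out).transpose(0, 4, 1, 2, 3)
        if keep_cache:
            self._cache = (col, x.shape, (to, ho, wo))
        return np.ascontiguousarray(out)

    def backward(self, dout):
        col, xshape, (to, ho, wo) = self._cache
        n, c = xshape[0], xshape[1]
        dmat = np.ascontiguousarray(dout.transpose(0, 2, 3, 4, 1)).reshape(-1, self.c_out)
        self.grads["w"] = (col.T @ dmat).T.reshape(self.params["w"].shape)
        if "b" in self.params:
            self.grads["b"] = dmat.sum(axis=0)
        dcol = dmat @ self.params["w"].reshape(self.c_out, -1)  # (N*P, C*k)
        kt, kh, kw = self.ksize
        st, sh, sw = self.stride
        pt, ph, pw = self.pad
        tp, hp, wp = xshape[2] + 2 * pt, xshape[3] + 2 * ph, xshape[4] + 2 * pw
        dcol = dcol.reshape(n, to, ho, wo, c, kt, kh, kw).transpose(0, 4, 1, 2, 3, 5, 6, 7)
        dxp = np.zeros((n, c, tp, hp, wp), dtype=np.float32)
        for it in range(kt):
            for ih in range(kh):
                for iw in range(kw):
                    dxp[:, :, it:it + st * to:st, ih:ih + sh * ho:sh, iw:iw + sw * wo:sw] += \
                        dcol[..., it, ih, iw]
        if any(self.pad):
            return dxp[:, :, pt:tp - pt, ph:hp - ph, pw:wp - pw]
        return dxp


class BatchNorm3d(Layer):
    def __init__(self, c, eps=1e-5, momentum=0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params["gamma"] = np.ones(c, dtype=np.float32)
        self.params["beta"] = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def forward(self, x, train=False, keep_cache=True):
        sh = (1, -1, 1, 1, 1)
        if train:
            mean = x.mean(axis=(0, 2, 3, 4))
            var = x.var(axis=(0, 2, 3, 4))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(sh)) * inv.reshape(sh)
        out = self.params["gamma"].reshape(sh) * xhat + self.params["beta"].reshape(sh)
        if keep_cache:
            self._cache = (xhat, inv, train)
        return out.astype(np.float32)

    def backward(self, dout):
        xhat, inv, train = self._cache
        sh = (1, -1, 1, 1, 1)
        self.grads["gamma"] = (dout * xhat).sum(axis=(0, 2, 3, 4))
        self.grads["beta"] = dout.sum(axis=(0, 2, 3, 4))
        g = self.params["gamma"].reshape(sh)
        if not train:
            return (dout * g * inv.reshape(sh)).astype(np.float32)
        m = dout.shape[0] * dout.shape[2] * dout.shape[3] * dout.shape[4]
        dxhat = dout * g
        dx = (dxhat
              - dxhat.mean(axis=(0, 2, 3, 4)).reshape(sh)
              - xhat * (dxhat * xhat).mean(axis=(0, 2, 3, 4)).reshape(sh)) * inv.reshape(sh)
        return dx.astype(np.float32)


class ReLU(Layer):
    def forward(self, x, train=False, keep_cache=True):
        out = np.maximum(x, 0)
        if keep_cache:
            self._cache = x > 0
        return out

    def backward(self, dout):
        return dout * self._cache


class MaxPool3d(Layer):
    def __init__(self, ksize, stride, pad=0):
        super().__init__()
        self.ksize = _triple(ksize)
        self.stride = _triple(stride)
        self.pad = _triple(pad)

    def forward(self, x, train=False, keep_cache=True):
        pt, ph, pw = self.pad
        if any(self.pad):
            xp = np.pad(x, ((0, 0), (0, 0), (pt, pt), (ph, ph), (pw, pw)),
                        constant_values=-np.inf)
        else:
            xp = x
        n, c = x.shape[:2]
        # pool channels independently through the shared im2col
        col, (to, ho, wo) = _im2col(xp.reshape(n * c, 1, *xp.shape[2:]),
                                    self.ksize, self.stride)
        arg = col.argmax(axis=1)
        out = col[np.arange(col.shape[0]), arg]
        out = out.reshape(n, c, to, ho, wo)
        if keep_cache:
            self._cache = (arg, x.shape, (to, ho, wo))
        return np.ascontiguousarray(out.astype(np.float32))

    def backward(self, dout):
        arg, xshape, (to, ho, wo) = self._cache
        n, c = xshape[0], xshape[1]
        kt, kh, kw = self.ksize
        st, sh, sw = self.stride
        pt, ph, pw = self.pad
        tp, hp, wp = xshape[2] + 2 * pt, xshape[3] + 2 * ph, xshape[4] + 2 * pw
        k = kt * kh * kw
        dcol = np.zeros((n * c * to * ho * wo, k), dtype=np.float32)
        dcol[np.arange(dcol.shape[0]), arg] = dout.reshape(-1)
        dcol = dcol.reshape(n * c, to, ho, wo, 1, kt, kh, kw).transpose(0, 4, 1, 2, 3, 5, 6, 7)
        dxp = np.zeros((n * c, 1, tp, hp, wp), dtype=np.float32)
        for it in range(kt):
            for ih in range(kh):
                for iw in range(kw):
                    dxp[:, :, it:it + st * to:st, ih:ih + sh * ho:sh, iw:iw + sw * wo:sw] += \
                        dcol[..., it, ih, iw]
        dxp = dxp.reshape(n, c, tp, hp, wp)
        if any(self.pad):
            return dxp[:, :, pt:tp - pt, ph:hp - ph, pw:wp - pw]
        return dxp


class GlobalAvgPool(Layer):
    """Spatiotemporal mean: (N, C, T, H, W) -> (N, C)."""

    def forward(self, x, train=False, keep_cache=True):
        if keep_cache:
            self._cache = x.shape
        return x.mean(axis=(2, 3, 4))

    def backward(self, dout):
        n, c, t, h, w = self._cache
        return np.broadcast_to(
            dout.reshape(n, c, 1, 1, 1) / (t * h * w), (n, c, t, h, w)
        ).astype(np.float32)


class Linear(Layer):
    def __init__(self, d_in, d_out, rng=None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        bound = 1.0 / np.sqrt(d_in)
        self.params["w"] = rng.uniform(-bound, bound, size=(d_in, d_out)).astype(np.float32)
        self.params["b"] = np.zeros(d_out, dtype=np.float32)

    def forward(self, x, train=False, keep_cache=True):
        if keep_cache:
            self._cache = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, dout):
        x = self._cache
        self.grads["w"] = x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        return (dout @ self.params["w"].T).astype(np.float32)
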