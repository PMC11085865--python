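"""Compiled inner loops for the depthwise convolution.

The depthwise operator touches every pixel neighborhood once per filter
tap; expressing it as strided whole-array numpy operations costs one full
memory pass per tap.  These numba kernels fuse the taps into a single pass
with implicit zero padding.  A pure-numpy fallback keeps the package
importable without a working JIT.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True, fastmath=True)
def depthwise_forward(x, w, bias, stride, pad, out):  # pragma: no cover - jit
    n, h, wd, c = x.shape
    dk = w.shape[0]
    ho, wo = out.shape[1], out.shape[2]
    for nn in range(n):
        for oy in range(ho):
            iy0 = oy * stride - pad
            for ox in range(wo):
                ix0 = ox * stride - pad
                for ch in range(c):
                    out[nn, oy, ox, ch] = bias[ch]
                for i in range(dk):
                    iy = iy0 + i
                    if iy < 0 or iy >= h:
                        continue
                    for j in range(dk):
                        ix = ix0 + j
                        if ix < 0 or ix >= wd:
                            continue
                        for ch in range(c):
                            out[nn, oy, ox, ch] += w[i, j, ch] * x[nn, iy, ix, ch]


@njit(cache=True, fastmath=True)
def depthwise_backward(x, w, grad, stride, pad, dx, dw, db):  # pragma: no cover - jit
    n, h, wd, c = x.shape
    dk = w.shape[0]
    ho, wo = grad.shape[1], grad.shape[2]
    for nn in range(n):
        for oy in range(ho):
            iy0 = oy * stride - pad
            for ox in range(wo):
                ix0 = ox * stride - pad
                for ch in range(c):
                    db[ch] += grad[nn, oy, ox, ch]
                for i in range(dk):
                    iy = iy0 + i
                    if iy < 0 or iy >= h:
                        continue
                    for j in range(dk):
                        ix = ix0 + j
                        if ix < 0 or ix >= wd:
                            continue
                        for ch in range(c):
                            g = grad[nn, oy, ox, ch]
                            dw[i, j, ch] += g * x[nn, iy, ix, ch]
                            dx[nn, iy, ix, ch] += g * w[i, j, ch]


def depthwise_forward_numpy(x, w, bias, stride, pad, out):
    """Strided-slice reference implementation (fallback and test oracle)."""
    dk = w.shape[0]
    ho, wo = out.shape[1], out.shape[2]
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    out[...] = bias
    for i in range(dk):
        for j in range(dk):
            out += w[i, j] * xp[:, i:i + stride * (ho - 1) + 1:stride,
                                j:j + stride * (wo - 1) + 1:stride, :]


def depthwise_backward_numpy(x, w, grad, stride, pad, dx, dw, db):
    dk = w.shape[0]
    ho, wo = grad.shape[1], grad.shape[2]
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    dxp = np.zeros_like(xp)
    for i in range(dk):
        for j in range(dk):
            si = slice(i, i + stride * (ho - 1) + 1, stride)
            sj = slice(j, j + stride * (wo - 1) + 1, stride)
            dw[i, j] += np.einsum("nhwc,nhwc->c", grad, xp[:, si, sj, :])
            dxp[:, si, sj, :] += w[i, j] * grad
    db += grad.sum(axis=(0, 1, 2))
    h, w_ = x.shape[1], x.shape[2]
    dx += dxp[:, pad:pad + h, pad:pad + w_, :]


if not HAVE_NUMBA:  # pragma: no cover
    depthwise_forward = depthwise_forward_numpy  # type: ignore  # noqa: F811
    depthwise_backward = depthwise_backward_numpy  # type: ignore  # noqa: F811
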