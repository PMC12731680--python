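"""JIT-compiled convolution kernels (numba).

Direct stride-1 'valid' 3-D convolution on pre-padded inputs, with the
innermost loop running contiguously along the width axis so it
vectorizes. Same-padded convolution is obtained by reflecting zeros into
the pad margin before the call; the input gradient of a same-padded
convolution is the same kernel applied to the padded output gradient
with the spatially flipped, channel-transposed weights.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def _conv3d_valid_generic(xp, weight, bias):
    n_batch, c_in, dp, hp, wp = xp.shape
    c_out, _, kd, kh, kw = weight.shape
    d_out, h_out, w_out = dp - kd + 1, hp - kh + 1, wp - kw + 1
    out = np.empty((n_batch, c_out, d_out, h_out, w_out), dtype=np.float32)
    for n in range(n_batch):
        for o in range(c_out):
            for d in range(d_out):
                for h in range(h_out):
                    acc = np.full(w_out, bias[o], dtype=np.float32)
                    for c in range(c_in):
                        for i in range(kd):
                            for j in range(kh):
                                row = xp[n, c, d + i, h + j]
                                for l in range(kw):
                                    wv = weight[o, c, i, j, l]
                                    for w in range(w_out):
                                        acc[w] += wv * row[w + l]
                    out[n, o, d, h] = acc
    return out


@njit(cache=True, fastmath=True)
def _conv3d_valid_kw3(xp, weight, bias):
    # Width-3 taps unrolled into one fused pass (the hot case).
    n_batch, c_in, dp, hp, wp = xp.shape
    c_out, _, kd, kh, _ = weight.shape
    d_out, h_out, w_out = dp - kd + 1, hp - kh + 1, wp - 2
    out = np.empty((n_batch, c_out, d_out, h_out, w_out), dtype=np.float32)
    for n in range(n_batch):
        for o in range(c_out):
            for d in range(d_out):
                for h in range(h_out):
                    acc = np.full(w_out, bias[o], dtype=np.float32)
                    for c in range(c_in):
                        for i in range(kd):
                            for j in range(kh):
                                row = xp[n, c, d + i, h + j]
                                w0 = weight[o, c, i, j, 0]
                                w1 = weight[o, c, i, j, 1]
                                w2 = weight[o, c, i, j, 2]
                                for w in range(w_out):
                                    acc[w] += (w0 * row[w] + w1 * row[w + 1]
                                               + w2 * row[w + 2])
                    out[n, o, d, h] = acc
    return out


def conv3d_valid(xp: np.ndarray, weight: np.ndarray, bias: np.ndarray
                 ) -> np.ndarray:
    """Valid conv of padded ``xp (N,C,Dp,Hp,Wp)`` with ``weight (O,C,kd,kh,kw)``."""
    if weight.shape[4] == 3:
        return _conv3d_valid_kw3(xp, weight, bias)
    return _conv3d_valid_generic(xp, weight, bias)


@njit(cache=True, fastmath=True)
def _conv3d_grad_weight_generic(xp, grad_out, kd, kh, kw):
    n_batch, c_in = xp.shape[0], xp.shape[1]
    c_out, d_out, h_out, w_out = (grad_out.shape[1], grad_out.shape[2],
                                  grad_out.shape[3], grad_out.shape[4])
    gw = np.zeros((c_out, c_in, kd, kh, kw), dtype=np.float32)
    gb = np.zeros(c_out, dtype=np.float32)
    for n in range(n_batch):
        for o in range(c_out):
            for d in range(d_out):
                for h in range(h_out):
                    g = grad_out[n, o, d, h]
                    for w in range(w_out):
                        gb[o] += g[w]
                    for c in range(c_in):
                        for i in range(kd):
                            for j in range(kh):
                                row = xp[n, c, d + i, h + j]
                                for l in range(kw):
                                    s = np.float32(0.0)
                                    for w in range(w_out):
                                        s += g[w] * row[w + l]
                                    gw[o, c, i, j, l] += s
    return gw, gb


@njit(cache=True, fastmath=True)
def _conv3d_grad_weight_kw3(xp, grad_out, kd, kh):
    n_batch, c_in = xp.shape[0], xp.shape[1]
    c_out, d_out, h_out, w_out = (grad_out.shape[1], grad_out.shape[2],
                                  grad_out.shape[3], grad_out.shape[4])
    gw = np.zeros((c_out, c_in, kd, kh, 3), dtype=np.float32)
    gb = np.zeros(c_out, dtype=np.float32)
    for n in range(n_batch):
        for o in range(c_out):
            for d in range(d_out):
                for h in range(h_out):
                    g = grad_out[n, o, d, h]
                    for w in range(w_out):
                        gb[o] += g[w]
                    for c in range(c_in):
                        for i in range(kd):
                            for j in range(kh):
                                row = xp[n, c, d + i, h + j]
                                s0 = np.float32(0.0)
                                s1 = np.float32(0.0)
                                s2 = np.float32(0.0)
                                for w in range(w_out):
                                    gv = g[w]
                                    s0 += gv * row[w]
                                    s1 += gv * row[w + 1]
                                    s2 += gv * row[w + 2]
                                gw[o, c, i, j, 0] += s0
                                gw[o, c, i, j, 1] += s1
                                gw[o, c, i, j, 2] += s2
    return gw, gb


def conv3d_grad_weight(xp: np.ndarray, grad_out: np.ndarray,
                       kd: int, kh: int, kw: int):
    """Weight/bias gradients of the valid convolution above."""
    if kw == 3:
        return _conv3d_grad_weight_kw3(xp, grad_out, kd, kh)
    return _conv3d_grad_weight_generic(xp, grad_out, kd, kh, kw)
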