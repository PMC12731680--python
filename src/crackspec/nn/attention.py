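"""SimAM: parameter-free voxel-wise attention.

Each voxel is weighted by how distinct its response is within its
channel, via a closed-form energy — no trainable parameters. Two
energy formulations are provided:

* ``"direct"`` — the energy of a voxel is its squared deviation from the
  channel mean, normalized by the channel's mean squared deviation plus
  a stabilizer λ; the attention weight is the sigmoid of that energy.
* ``"canonical"`` — the closed-form minimal energy of the original SimAM
  derivation, ``e*_i = 4(σ² + λ) / ((x_i − μ)² + 2σ² + 2λ)``, with the
  weight taken as the sigmoid of the inverse energy ``1/e*``.

Under both, a voxel deviating strongly from its channel statistics
receives a weight near 1 while flat background saturates lower — the two
differ only in the shape of the response curve. The output is the
element-wise product of the weights with the input.
"""

from __future__ import annotations

import numpy as np

from ..errors import ParameterError
from .layers import Layer

VARIANTS = ("direct", "canonical")
DEFAULT_LAMBDA = 1e-4


def simam_energy(x: np.ndarray, lam: float = DEFAULT_LAMBDA,
                 variant: str = "direct") -> np.ndarray:
    """Per-voxel attention pre-activation for a ``(N,C,D,H,W)`` map.

    Returns the quantity whose sigmoid is the attention weight.
    """
    if lam <= 0:
        raise ParameterError("simam lambda must be positive")
    if variant not in VARIANTS:
        raise ParameterError(f"unknown SimAM variant {variant!r}")
    if int(np.prod(x.shape[2:])) < 2:
        raise ParameterError("SimAM needs at least 2 voxels per channel")
    mu = x.mean(axis=(2, 3, 4), keepdims=True)
    dev2 = (x - mu) ** 2
    msd = dev2.mean(axis=(2, 3, 4), keepdims=True)
    if variant == "direct":
        return dev2 / (msd + lam)
    energy = 4.0 * (msd + lam) / (dev2 + 2.0 * msd + 2.0 * lam)
    return 1.0 / energy


class SimAM3d(Layer):
    """Attention layer applying ``sigmoid(energy) ⊙ x``; zero parameters.

    The backward pass propagates gradients through the multiplicative
    weights only (the weights are treated as constants with respect to
    the input), a straight-through approximation of the exact gradient
    of the channel statistics.
    """

    def __init__(self, lam: float = DEFAULT_LAMBDA, variant: str = "direct"):
        if lam <= 0:
            raise ParameterError("simam lambda must be positive")
        if variant not in VARIANTS:
            raise ParameterError(f"unknown SimAM variant {variant!r}")
        self.lam = lam
        self.variant = variant
        self._weights = None

    def parameters(self):
        return []  # parameter-free by construction

    def attention_weights(self, x: np.ndarray) -> np.ndarray:
        e = simam_energy(x, self.lam, self.variant)
        return (1.0 / (1.0 + np.exp(-np.clip(e, -60.0, 60.0)))).astype(np.float32)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        w = self.attention_weights(x)
        if training:
            self._weights = w
        return (w * x).astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        gx = grad * self._weights
        self._weights = None
        return gx.astype(np.float32)
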