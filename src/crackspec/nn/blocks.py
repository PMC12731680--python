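"""Convolutional building blocks: residual and plain double-conv units.

The residual block follows y = ReLU(BN(Conv(ReLU(BN(Conv(x))))) + F(x)),
two same-padded 3x3x3 convolutions each with batch normalization, with
F(x) the identity when channel counts match and a 1x1x1 projection (plus
BN) otherwise. The shortcut keeps gradients flowing to the input even
when the main branch saturates.
"""

from __future__ import annotations

import numpy as np

from .layers import BatchNorm3d, Conv3d, Layer, ReLU


class ResBlock3d(Layer):
    """Two-conv residual unit with identity or projection shortcut."""

    def __init__(self, in_channels: int, out_channels: int,
                 kernel: tuple[int, int, int] = (3, 3, 3),
                 rng: np.random.Generator | None = None):
        self.conv1 = Conv3d(in_channels, out_channels, kernel, rng=rng)
        self.bn1 = BatchNorm3d(out_channels)
        self.relu1 = ReLU()
        self.conv2 = Conv3d(out_channels, out_channels, kernel, rng=rng)
        self.bn2 = BatchNorm3d(out_channels)
        self.relu_out = ReLU()
        if in_channels != out_channels:
            self.proj = Conv3d(in_channels, out_channels, (1, 1, 1), rng=rng)
            self.proj_bn = BatchNorm3d(out_channels)
        else:
            self.proj = None
            self.proj_bn = None

    def parameters(self):
        params = (self.conv1.parameters() + self.bn1.parameters()
                  + self.conv2.parameters() + self.bn2.parameters())
        if self.proj is not None:
            params += self.proj.parameters() + self.proj_bn.parameters()
        return params

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        main = self.conv1.forward(x, training)
        main = self.bn1.forward(main, training)
        main = self.relu1.forward(main, training)
        main = self.conv2.forward(main, training)
        main = self.bn2.forward(main, training)
        if self.proj is not None:
            shortcut = self.proj_bn.forward(self.proj.forward(x, training),
                                            training)
        else:
            shortcut = x
        return self.relu_out.forward(main + shortcut, training)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.relu_out.backward(grad)
        g_main = self.bn2.backward(g)
        g_main = self.conv2.backward(g_main)
        g_main = self.relu1.backward(g_main)
        g_main = self.bn1.backward(g_main)
        g_main = self.conv1.backward(g_main)
        if self.proj is not None:
            g_short = self.proj.backward(self.proj_bn.backward(g))
        else:
            g_short = g
        return g_main + g_short


class ConvBlock3d(Layer):
    """Plain double conv-BN-ReLU unit (the non-residual baseline block)."""

    def __init__(self, in_channels: int, out_channels: int,
                 kernel: tuple[int, int, int] = (3, 3, 3),
                 rng: np.random.Generator | None = None):
        self.conv1 = Conv3d(in_channels, out_channels, kernel, rng=rng)
        self.bn1 = BatchNorm3d(out_channels)
        self.relu1 = ReLU()
        self.conv2 = Conv3d(out_channels, out_channels, kernel, rng=rng)
        self.bn2 = BatchNorm3d(out_channels)
        self.relu2 = ReLU()

    def parameters(self):
        return (self.conv1.parameters() + self.bn1.parameters()
                + self.conv2.parameters() + self.bn2.parameters())

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        h = self.relu1.forward(self.bn1.forward(
            self.conv1.forward(x, training), training), training)
        return self.relu2.forward(self.bn2.forward(
            self.conv2.forward(h, training), training), training)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.bn2.backward(self.relu2.backward(grad))
        g = self.conv2.backward(g)
        g = self.bn1.backward(self.relu1.backward(g))
        return self.conv1.backward(g)
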