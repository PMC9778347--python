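"""The two building blocks of the segmentation encoder.

``InceptionResidualBlock`` (EB) aggregates features at three kernel scales
(1x1, and a configurable pair, by default 3x3 and 5x5) through four parallel
branches with batch normalisation, concatenates them, projects back with a
1x1 convolution and adds a residual path.  The branch bottleneck width is
``c_out // 8`` so the block stays far lighter than a plain double-3x3 stage.

``DenseSpatialAttention`` (DSAM) builds a single-channel spatial gate from
channel-wise average- and max-pooled maps passed through a chain of densely
connected blocks (each block's output is concatenated onto the running
feature, so after i blocks the feature has ``2 + i * growth`` channels).
The gate uses the swish activation and is applied multiplicatively:

    out = x * gate * swish(x)

which vanishes wherever x vanishes.  Neither block changes spatial size.
"""

from __future__ import annotations

import numpy as np

from .layers import AvgPool2d, BatchNorm, Conv2d, MaxPool2d, Module, UpsampleNearest2d
from .tensor import Tensor, concat, make_op, relu, swish, tmax, tmean

__all__ = ["InceptionResidualBlock", "DenseSpatialAttention", "swish"]


class InceptionResidualBlock(Module):
    """Multi-scale inception block with a residual path (EB)."""

    def __init__(self, c_in: int, c_out: int, kernel_pair=(3, 5), rng=None):
        rng = rng or np.random.default_rng(0)
        k1, k2 = kernel_pair
        if k1 % 2 != 1 or k2 % 2 != 1:
            raise ValueError("kernels must be odd")
        self.c_in, self.c_out = c_in, c_out
        c_mid = max(c_out // 8, 1)
        self.c_mid = c_mid
        # branch 1: bottleneck + BN
        self.b1_conv = Conv2d(c_in, c_mid, 1, rng=rng)
        self.b1_bn = BatchNorm(c_mid)
        # branch 2: bottleneck + BN, then stride-1 max pooling
        self.b2_conv = Conv2d(c_in, c_mid, 1, rng=rng)
        self.b2_bn = BatchNorm(c_mid)
        self.b2_pool = MaxPool2d(3, stride=1)
        # branch 3: bottleneck, then two k1 convolutions with BN
        self.b3_conv0 = Conv2d(c_in, c_mid, 1, rng=rng)
        self.b3_conv1 = Conv2d(c_mid, c_mid, k1, rng=rng)
        self.b3_bn1 = BatchNorm(c_mid)
        self.b3_conv2 = Conv2d(c_mid, c_mid, k1, rng=rng)
        self.b3_bn2 = BatchNorm(c_mid)
        # branch 4: same with the larger kernel
        self.b4_conv0 = Conv2d(c_in, c_mid, 1, rng=rng)
        self.b4_conv1 = Conv2d(c_mid, c_mid, k2, rng=rng)
        self.b4_bn1 = BatchNorm(c_mid)
        self.b4_conv2 = Conv2d(c_mid, c_mid, k2, rng=rng)
        self.b4_bn2 = BatchNorm(c_mid)
        # fuse + residual (batch-normalised so the skip path stays bounded)
        self.proj = Conv2d(4 * c_mid, c_out, 1, rng=rng)
        self.proj_bn = BatchNorm(c_out)
        if c_in != c_out:
            self.residual = Conv2d(c_in, c_out, 1, rng=rng)
            self.residual_bn = BatchNorm(c_out)
        else:
            self.residual = None
            self.residual_bn = None

    def forward(self, x: Tensor) -> Tensor:
        l1 = self.b1_bn(self.b1_conv(x))
        l2 = self.b2_pool(self.b2_bn(self.b2_conv(x)))
        l3 = self.b3_bn2(self.b3_conv2(self.b3_bn1(self.b3_conv1(self.b3_conv0(x)))))
        l4 = self.b4_bn2(self.b4_conv2(self.b4_bn1(self.b4_conv1(self.b4_conv0(x)))))
        fused = self.proj_bn(self.proj(concat([l1, l2, l3, l4], axis=1)))
        res = x if self.residual is None else self.residual_bn(self.residual(x))
        return relu(fused + res)


class DenseSpatialAttention(Module):
    """Spatial attention gated by a densely connected block chain (DSAM)."""

    def __init__(self, n_dense: int = 12, growth: int = 4, rng=None):
        if n_dense < 1:
            raise ValueError("n_dense must be >= 1")
        rng = rng or np.random.default_rng(0)
        self.n_dense, self.growth = n_dense, growth
        self.bns = []
        self.convs = []
        ch = 2  # avg-pool map || max-pool map
        for _ in range(n_dense):
            self.bns.append(BatchNorm(ch))
            self.convs.append(Conv2d(ch, growth, 3, rng=rng))
            ch += growth
        self.proj = Conv2d(ch, 1, 1, rng=rng)

    def channel_schedule(self) -> list[int]:
        """Running channel count after each dense block (input has 2)."""
        return [2 + (i + 1) * self.growth for i in range(self.n_dense)]

    def gate(self, x: Tensor) -> Tensor:
        avg = tmean(x, axis=1, keepdims=True)
        mx = tmax(x, axis=1, keepdims=True)
        feats = concat([avg, mx], axis=1)
        # the dense chain runs at half resolution when possible (the gate is
        # a smooth spatial map; this quarters the chain's cost)
        h, w = x.shape[2], x.shape[3]
        halve = h % 2 == 0 and w % 2 == 0 and h >= 8 and w >= 8
        if halve:
            feats = AvgPool2d(2)(feats)
        for bn, conv in zip(self.bns, self.convs):
            new = conv(relu(bn(feats)))
            feats = concat([feats, new], axis=1)
        gate = swish(self.proj(feats))
        if halve:
            gate = UpsampleNearest2d()(gate)
        return gate

    def forward(self, x: Tensor, gate_override=None) -> Tensor:
        g = self.gate(x) if gate_override is None else gate_override
        if isinstance(g, np.ndarray):
            g = make_op(g.astype(np.float32), [])
        return x * g * swish(x)
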