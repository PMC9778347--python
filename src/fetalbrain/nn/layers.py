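"""Neural-network layers over the autograd core.

2D convolutions pick between two equivalent schedules by fan-in: an im2col
gather with a single BLAS product for small fan-in, and a loop over kernel
offsets accumulating BLAS products of shifted views for large fan-in (where
the im2col gather becomes cache-hostile).  3D convolutions always use the
offset loop.  All layers keep spatial dimensions unless their stride says
otherwise, and all parameters are initialised from an explicit
``numpy.random.Generator`` for reproducibility.
"""

from __future__ import annotations

import numpy as np

from .tensor import Parameter, Tensor, make_op, relu, sigmoid

__all__ = [
    "Module", "Sequential", "Conv2d", "DepthwiseConv2d", "Conv3d",
    "ConvTranspose3d", "BatchNorm", "Linear", "MaxPool2d", "MaxPool3d",
    "AvgPool2d", "UpsampleNearest2d", "relu", "sigmoid",
]


class Module:
    """Base class: parameter discovery, train/eval mode, counting."""

    training: bool = True

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _children(self):
        for v in vars(self).values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item

    def modules(self):
        yield self
        for child in self._children():
            yield from child.modules()

    def parameters(self):
        for m in self.modules():
            for v in vars(m).values():
                if isinstance(v, Parameter):
                    yield v
                elif isinstance(v, (list, tuple)):
                    for item in v:
                        if isinstance(item, Parameter):
                            yield item

    def n_parameters(self) -> int:
        return sum(int(p.data.size) for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def state_arrays(self) -> list[np.ndarray]:
        """All learnable and running-stat arrays, in a stable order."""
        out = []
        for m in self.modules():
            for v in vars(m).values():
                if isinstance(v, Parameter):
                    out.append(v.data)
                elif isinstance(v, np.ndarray):
                    out.append(v)
        return out

    def load_state_arrays(self, arrays) -> None:
        slots = self.state_arrays()
        if len(slots) != len(arrays):
            raise ValueError(f"state mismatch: {len(slots)} slots vs {len(arrays)} arrays")
        for slot, arr in zip(slots, arrays):
            if slot.shape != arr.shape:
                raise ValueError(f"shape mismatch {slot.shape} vs {arr.shape}")
            slot[...] = arr


class Sequential(Module):
    def __init__(self, *mods):
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / max(fan_in, 1)), size=shape).astype(np.float32)


def _dot_out(w2: np.ndarray, xs: np.ndarray) -> np.ndarray:
    """(Cout, Cin) x (N, Cin, *sp) -> (N, Cout, *sp) via one BLAS call."""
    n, c = xs.shape[0], xs.shape[1]
    sp = xs.shape[2:]
    flat = xs.reshape(n, c, -1)
    out = np.matmul(w2, flat)  # broadcast over batch
    return out.reshape(n, w2.shape[0], *sp)


def _grad_w(gf: np.ndarray, xf: np.ndarray) -> np.ndarray:
    """Batched (N,Cout,F) x (N,C,F) -> (Cout,C) weight gradient."""
    return np.matmul(gf, xf.transpose(0, 2, 1)).sum(axis=0)


class Conv2d(Module):
    """Same-padded 2D convolution, odd kernel, optional stride."""

    def __init__(self, c_in, c_out, kernel=3, stride=1, rng=None, bias=True):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd")
        rng = rng or np.random.default_rng(0)
        self.c_in, self.c_out, self.kernel, self.stride = c_in, c_out, kernel, stride
        self.weight = Parameter(_he_init(rng, (c_out, c_in, kernel, kernel), c_in * kernel * kernel))
        self.bias = Parameter(np.zeros(c_out, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        k, s = self.kernel, self.stride
        w, b = self.weight, self.bias
        xd = x.data
        if xd.shape[1] != self.c_in:
            raise ValueError(f"expected {self.c_in} channels, got {xd.shape[1]}")
        n, _, h, wd = xd.shape
        p = k // 2
        ho = (h + 2 * p - k) // s + 1
        wo = (wd + 2 * p - k) // s + 1
        if k == 1 and s == 1:
            w2 = w.data.reshape(self.c_out, self.c_in)
            y = _dot_out(w2, xd)
            if b is not None:
                y = y + b.data.reshape(1, -1, 1, 1)

            def back(g):
                return _dot_out(w2.T.copy(), g)

            def back_w(g):
                gw = _grad_w(g.reshape(n, self.c_out, -1), xd.reshape(n, self.c_in, -1))
                return gw.reshape(w.data.shape)

            parents = [(x, back), (w, back_w)]
            if b is not None:
                parents.append((b, lambda g: g.sum(axis=(0, 2, 3))))
            return make_op(y, parents)

        xp = np.pad(xd, ((0, 0), (0, 0), (p, p), (p, p)))
        hs = (ho - 1) * s + 1
        ws = (wo - 1) * s + 1
        if self.c_in * k * k <= 128:
            # im2col: one BLAS product over all kernel offsets (small fan-in)
            win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
            win = win[:, :, ::s, ::s]  # (N, C, Ho, Wo, k, k)
            cols = np.ascontiguousarray(win.transpose(0, 1, 4, 5, 2, 3)).reshape(
                n, self.c_in * k * k, ho * wo
            )
            w2 = w.data.reshape(self.c_out, -1)
            y = np.matmul(w2, cols).reshape(n, self.c_out, ho, wo)
            if b is not None:
                y += b.data.reshape(1, -1, 1, 1)

            def back_x(g):
                dcols = np.matmul(w2.T.copy(), g.reshape(n, self.c_out, -1))
                dcols = dcols.reshape(n, self.c_in, k, k, ho, wo)
                gxp = np.zeros_like(xp)
                for di in range(k):
                    for dj in range(k):
                        gxp[:, :, di : di + hs : s, dj : dj + ws : s] += dcols[:, :, di, dj]
                return gxp[:, :, p : p + h, p : p + wd]

            def back_w(g):
                gw = _grad_w(g.reshape(n, self.c_out, -1), cols)
                return gw.reshape(w.data.shape)

            parents = [(x, back_x), (w, back_w)]
            if b is not None:
                parents.append((b, lambda g: g.sum(axis=(0, 2, 3))))
            return make_op(y, parents)

        # larger fan-in: accumulate one BLAS product per kernel offset
        # (avoids the cache-hostile im2col gather)
        y = np.zeros((n, self.c_out, ho * wo), dtype=np.float32)
        for di in range(k):
            for dj in range(k):
                xs = xp[:, :, di : di + hs : s, dj : dj + ws : s].reshape(n, self.c_in, -1)
                y += np.matmul(w.data[:, :, di, dj], xs)
        y = y.reshape(n, self.c_out, ho, wo)
        if b is not None:
            y += b.data.reshape(1, -1, 1, 1)

        def back_x2(g):
            gf = g.reshape(n, self.c_out, -1)
            gxp = np.zeros_like(xp)
            for di in range(k):
                for dj in range(k):
                    gxp[:, :, di : di + hs : s, dj : dj + ws : s] += np.matmul(
                        w.data[:, :, di, dj].T.copy(), gf
                    ).reshape(n, self.c_in, ho, wo)
            return gxp[:, :, p : p + h, p : p + wd]

        def back_w2(g):
            gf = g.reshape(n, self.c_out, -1)
            gw = np.empty_like(w.data)
            for di in range(k):
                for dj in range(k):
                    xs = xp[:, :, di : di + hs : s, dj : dj + ws : s].reshape(n, self.c_in, -1)
                    gw[:, :, di, dj] = _grad_w(gf, xs)
            return gw

        parents = [(x, back_x2), (w, back_w2)]
        if b is not None:
            parents.append((b, lambda g: g.sum(axis=(0, 2, 3))))
        return make_op(y, parents)


class DepthwiseConv2d(Module):
    """Per-channel k x k convolution; used as the stride-2 downsampler."""

    def __init__(self, channels, kernel=3, stride=2, rng=None):
        rng = rng or np.random.default_rng(0)
        self.channels, self.kernel, self.stride = channels, kernel, stride
        self.weight = Parameter(_he_init(rng, (channels, kernel, kernel), kernel * kernel))
        self.bias = Parameter(np.zeros(channels, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        k, s = self.kernel, self.stride
        xd = x.data
        n, c, h, wd = xd.shape
        if c != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {c}")
        p = k // 2
        ho = (h + 2 * p - k) // s + 1
        wo = (wd + 2 * p - k) // s + 1
        xp = np.pad(xd, ((0, 0), (0, 0), (p, p), (p, p)))
        w = self.weight
        y = np.zeros((n, c, ho, wo), dtype=np.float32)
        for di in range(k):
            for dj in range(k):
                xs = xp[:, :, di : di + (ho - 1) * s + 1 : s, dj : dj + (wo - 1) * s + 1 : s]
                y += w.data[None, :, di, dj, None, None] * xs
        y += self.bias.data.reshape(1, -1, 1, 1)

        def back_x(g):
            gxp = np.zeros_like(xp)
            for di in range(k):
                for dj in range(k):
                    gxp[:, :, di : di + (ho - 1) * s + 1 : s, dj : dj + (wo - 1) * s + 1 : s] += (
                        w.data[None, :, di, dj, None, None] * g
                    )
            return gxp[:, :, p : p + h, p : p + wd]

        def back_w(g):
            gw = np.empty_like(w.data)
            for di in range(k):
                for dj in range(k):
                    xs = xp[:, :, di : di + (ho - 1) * s + 1 : s, dj : dj + (wo - 1) * s + 1 : s]
                    gw[:, di, dj] = (g * xs).sum(axis=(0, 2, 3))
            return gw

        return make_op(y, [(x, back_x), (w, back_w),
                           (self.bias, lambda g: g.sum(axis=(0, 2, 3)))])


class Conv3d(Module):
    """Same-padded 3D convolution with odd kernel, stride 1."""

    def __init__(self, c_in, c_out, kernel=3, rng=None):
        rng = rng or np.random.default_rng(0)
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        self.weight = Parameter(_he_init(rng, (c_out, c_in, kernel, kernel, kernel),
                                         c_in * kernel ** 3))
        self.bias = Parameter(np.zeros(c_out, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        k = self.kernel
        p = k // 2
        xd = x.data
        n, c, d, h, wd = xd.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} channels, got {c}")
        xp = np.pad(xd, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
        w = self.weight
        y = np.zeros((n, self.c_out, d, h, wd), dtype=np.float32)
        for di in range(k):
            for dj in range(k):
                for dk in range(k):
                    xs = xp[:, :, di : di + d, dj : dj + h, dk : dk + wd]
                    y += _dot_out(w.data[:, :, di, dj, dk], xs)
        y += self.bias.data.reshape(1, -1, 1, 1, 1)

        def back_x(g):
            gxp = np.zeros_like(xp)
            for di in range(k):
                for dj in range(k):
                    for dk in range(k):
                        gxp[:, :, di : di + d, dj : dj + h, dk : dk + wd] += _dot_out(
                            w.data[:, :, di, dj, dk].T.copy(), g
                        )
            return gxp[:, :, p : p + d, p : p + h, p : p + wd]

        def back_w(g):
            gw = np.empty_like(w.data)
            gf = g.reshape(n, self.c_out, -1)
            for di in range(k):
                for dj in range(k):
                    for dk in range(k):
                        xs = xp[:, :, di : di + d, dj : dj + h, dk : dk + wd]
                        gw[:, :, di, dj, dk] = _grad_w(gf, xs.reshape(n, c, -1))
            return gw

        return make_op(y, [(x, back_x), (w, back_w),
                           (self.bias, lambda g: g.sum(axis=(0, 2, 3, 4)))])


class ConvTranspose3d(Module):
    """Stride-2, kernel-2 transposed 3D convolution (exact x2 upsampling)."""

    def __init__(self, c_in, c_out, rng=None):
        rng = rng or np.random.default_rng(0)
        self.c_in, self.c_out = c_in, c_out
        self.weight = Parameter(_he_init(rng, (c_in, c_out, 2, 2, 2), c_in))
        self.bias = Parameter(np.zeros(c_out, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        xd = x.data
        n, c, d, h, wd = xd.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} channels, got {c}")
        w = self.weight
        y = np.empty((n, self.c_out, 2 * d, 2 * h, 2 * wd), dtype=np.float32)
        for a in range(2):
            for b in range(2):
                for cc in range(2):
                    y[:, :, a::2, b::2, cc::2] = _dot_out(w.data[:, :, a, b, cc].T.copy(), xd)
        y += self.bias.data.reshape(1, -1, 1, 1, 1)

        def back_x(g):
            gx = np.zeros_like(xd)
            for a in range(2):
                for b in range(2):
                    for cc in range(2):
                        gx += _dot_out(w.data[:, :, a, b, cc], g[:, :, a::2, b::2, cc::2])
            return gx

        def back_w(g):
            gw = np.empty_like(w.data)
            xf = xd.reshape(n, c, -1)
            for a in range(2):
                for b in range(2):
                    for cc in range(2):
                        gs = g[:, :, a::2, b::2, cc::2].reshape(n, self.c_out, -1)
                        gw[:, :, a, b, cc] = _grad_w(xf, gs)
            return gw

        return make_op(y, [(x, back_x), (w, back_w),
                           (self.bias, lambda g: g.sum(axis=(0, 2, 3, 4)))])


class BatchNorm(Module):
    """Batch normalisation over the channel axis for 4D or 5D activations.

    Eval mode uses running statistics; until the layer has seen any training
    batch those are uninformative, so a never-trained layer normalises with
    the current batch statistics instead (keeping untrained forward passes
    numerically sane)."""

    def __init__(self, channels, eps: float = 1e-5, momentum: float = 0.1):
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._seen = False

    def forward(self, x: Tensor) -> Tensor:
        xd = x.data
        if xd.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {xd.shape[1]}")
        axes = (0,) + tuple(range(2, xd.ndim))
        bshape = (1, self.channels) + (1,) * (xd.ndim - 2)
        gamma, beta = self.gamma, self.beta
        if self.training or not self._seen:
            mu = xd.mean(axis=axes, keepdims=True)
            diff = xd - mu
            var = np.mean(diff * diff, axis=axes, keepdims=True)
            if not (np.isfinite(mu).all() and np.isfinite(var).all()):
                # extreme magnitudes (untrained attention products): redo in f64
                mu = xd.mean(axis=axes, keepdims=True, dtype=np.float64)
                diff = xd - mu
                var = np.mean(diff * diff, axis=axes, keepdims=True, dtype=np.float64)
            m = xd.size // self.channels
            if self.training:
                self._seen = True
                mu32 = mu.astype(np.float32).ravel()
                var32 = np.minimum(var, np.finfo(np.float32).max).astype(np.float32).ravel()
                self.running_mean += self.momentum * (mu32 - self.running_mean)
                self.running_var += self.momentum * (var32 - self.running_var)
            inv = (1.0 / np.sqrt(var + self.eps)).astype(np.float32)
            xhat = (diff * inv).astype(np.float32)
            y = gamma.data.reshape(bshape) * xhat + beta.data.reshape(bshape)

            def back_x(g):
                gsum = g.sum(axis=axes, keepdims=True)
                gx_sum = (g * xhat).sum(axis=axes, keepdims=True)
                return (gamma.data.reshape(bshape) * inv / m) * (
                    m * g - gsum - xhat * gx_sum
                )

            return make_op(
                y,
                [(x, back_x),
                 (gamma, lambda g: (g * xhat).sum(axis=axes).ravel()),
                 (beta, lambda g: g.sum(axis=axes).ravel())],
            )
        inv = 1.0 / np.sqrt(self.running_var.reshape(bshape) + self.eps)
        xhat = (xd - self.running_mean.reshape(bshape)) * inv
        y = gamma.data.reshape(bshape) * xhat + beta.data.reshape(bshape)
        return make_op(
            y,
            [(x, lambda g: g * gamma.data.reshape(bshape) * inv),
             (gamma, lambda g: (g * xhat).sum(axis=axes).ravel()),
             (beta, lambda g: g.sum(axis=axes).ravel())],
        )


class Linear(Module):
    def __init__(self, n_in, n_out, rng=None):
        rng = rng or np.random.default_rng(0)
        self.n_in, self.n_out = n_in, n_out
        self.weight = Parameter(_he_init(rng, (n_out, n_in), n_in))
        self.bias = Parameter(np.zeros(n_out, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        w, b = self.weight, self.bias
        y = x.data @ w.data.T + b.data
        return make_op(
            y,
            [(x, lambda g: g @ w.data),
             (w, lambda g: g.T @ x.data),
             (b, lambda g: g.sum(axis=0))],
        )


class MaxPool2d(Module):
    """Max pooling; stride 1 uses same-padding so spatial dims are kept."""

    def __init__(self, kernel=3, stride=1):
        self.kernel, self.stride = kernel, stride

    def forward(self, x: Tensor) -> Tensor:
        k, s = self.kernel, self.stride
        xd = x.data
        n, c, h, wd = xd.shape
        p = k // 2 if s == 1 else 0
        ho = (h + 2 * p - k) // s + 1
        wo = (wd + 2 * p - k) // s + 1
        xp = np.pad(xd, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
        out = np.full((n, c, ho, wo), -np.inf, dtype=np.float32)
        for di in range(k):
            for dj in range(k):
                np.maximum(
                    out,
                    xp[:, :, di : di + (ho - 1) * s + 1 : s, dj : dj + (wo - 1) * s + 1 : s],
                    out=out,
                )

        def back(g):
            counts = np.zeros_like(out)
            for di in range(k):
                for dj in range(k):
                    xs = xp[:, :, di : di + (ho - 1) * s + 1 : s, dj : dj + (wo - 1) * s + 1 : s]
                    counts += (xs == out)
            gshare = g / counts
            gxp = np.zeros_like(xp)
            for di in range(k):
                for dj in range(k):
                    sl = np.s_[:, :, di : di + (ho - 1) * s + 1 : s, dj : dj + (wo - 1) * s + 1 : s]
                    gxp[sl] += gshare * (xp[sl] == out)
            return gxp[:, :, p : p + h, p : p + wd].astype(np.float32)

        return make_op(out, [(x, back)])


class MaxPool3d(Module):
    """2x2x2, stride-2 max pooling for 5D activations."""

    def forward(self, x: Tensor) -> Tensor:
        xd = x.data
        out = np.full(
            (xd.shape[0], xd.shape[1], xd.shape[2] // 2, xd.shape[3] // 2, xd.shape[4] // 2),
            -np.inf, dtype=np.float32,
        )
        for a in range(2):
            for b in range(2):
                for cc in range(2):
                    np.maximum(out, xd[:, :, a::2, b::2, cc::2], out=out)

        def back(g):
            counts = np.zeros_like(out)
            for a in range(2):
                for b in range(2):
                    for cc in range(2):
                        counts += (xd[:, :, a::2, b::2, cc::2] == out)
            gshare = g / counts
            gx = np.zeros_like(xd)
            for a in range(2):
                for b in range(2):
                    for cc in range(2):
                        gx[:, :, a::2, b::2, cc::2] += gshare * (
                            xd[:, :, a::2, b::2, cc::2] == out
                        )
            return gx

        return make_op(out, [(x, back)])


class AvgPool2d(Module):
    """Average pooling by an integer factor (used for multi-scale routing)."""

    def __init__(self, factor: int):
        self.factor = factor

    def forward(self, x: Tensor) -> Tensor:
        f = self.factor
        xd = x.data
        n, c, h, w = xd.shape
        out = xd.reshape(n, c, h // f, f, w // f, f).mean(axis=(3, 5))

        def back(g):
            gg = np.repeat(np.repeat(g, f, axis=2), f, axis=3) / (f * f)
            return gg.astype(np.float32)

        return make_op(out, [(x, back)])


class UpsampleNearest2d(Module):
    def forward(self, x: Tensor) -> Tensor:
        xd = x.data
        out = np.repeat(np.repeat(xd, 2, axis=2), 2, axis=3)
        n, c, h, w = xd.shape

        def back(g):
            return g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5))

        return make_op(out, [(x, back)])
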