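"""The multi-view 2D segmentation network and its training harness.

One network is trained per anatomical view (axial, sagittal, coronal) on the
2D slices of that view; the per-slice class-score maps are stacked back along
the view axis to a score volume and later fused across views
(:mod:`fetalbrain.fusion`).

Architecture (``variant="full"``): a four-stage encoder of inception-residual
blocks (1, 2, 3 and 4 blocks per stage, channels doubling each stage) with a
dense-spatial-attention gate per stage and a stride-2 depthwise-convolution
downsampler; stage outputs are additionally average-pooled to the bottleneck
resolution and fused by a 1x1 convolution (multi-scale routing); the decoder
upsamples x2 four times, concatenating the stage skip and applying a
1x1 + 3x3 convolution pair with batch norm and ReLU; a 1x1 head with
per-class sigmoid (or optional softmax) produces the score maps.

Ablation variants: ``unet`` (a plain double-3x3-conv UNet with max-pool
downsampling and a classic double-conv decoder), ``inc_res`` (inception
blocks only), ``inc_res_dsam`` (adds the attention gates), ``full`` (adds
multi-scale bottleneck routing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn.tensor import Tensor, concat, make_op, relu, sigmoid
from .volume import ImageVolume, LabelVolume, extract_slices, view_axis

VARIANTS = ("unet", "inc_res", "inc_res_dsam", "full")


@dataclass
class ModelConfig:
    n_classes: int = 8                  # 7 tissues + background
    base_width: int = 32
    stages: int = 4
    eb_per_stage: tuple = (1, 2, 3, 4)
    use_dsam: bool = True
    use_multiscale: bool = True
    variant: str = "full"
    kernel_pair: tuple = (3, 5)
    head: str = "sigmoid"               # or "softmax"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant == "unet":
            self.use_dsam = False
            self.use_multiscale = False
        elif self.variant == "inc_res":
            self.use_dsam = False
            self.use_multiscale = False
        elif self.variant == "inc_res_dsam":
            self.use_dsam = True
            self.use_multiscale = False
        if len(self.eb_per_stage) != self.stages:
            raise ValueError("eb_per_stage length must equal stages")

    @property
    def stage_widths(self) -> tuple:
        return tuple(self.base_width * 2**i for i in range(self.stages))


@dataclass
class TrainConfig:
    lr: float = 1e-4
    adam_eps: float = 1e-8
    weight_decay: float = 0.0
    epochs: int = 10
    batch_size: int = 16
    loss_name: str = "combo"
    alpha: float = 0.5
    beta: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0 and 0.0 <= self.beta <= 1.0):
            raise ValueError("alpha and beta must lie in [0, 1]")


@dataclass
class ViewProbabilities:
    """Per-view stacked class-score volume, aligned with the source volume."""

    view: str
    scores: np.ndarray  # (n_classes, nx, ny, nz), values in [0, 1]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float32)
        if self.scores.ndim != 4:
            raise ValueError("scores must be (n_classes, nx, ny, nz)")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores contain non-finite values")

    def argmax_labels(self) -> np.ndarray:
        return np.argmax(self.scores, axis=0).astype(np.uint8)


class _ConvBNRelu(nn.Module):
    def __init__(self, c_in, c_out, kernel, rng):
        self.conv = nn.Conv2d(c_in, c_out, kernel, rng=rng)
        self.bn = nn.BatchNorm(c_out)

    def forward(self, x):
        return relu(self.bn(self.conv(x)))


class _EncoderStage(nn.Module):
    def __init__(self, c_in, c_out, n_eb, cfg: ModelConfig, rng):
        if cfg.variant == "unet":
            self.blocks = [_ConvBNRelu(c_in, c_out, 3, rng), _ConvBNRelu(c_out, c_out, 3, rng)]
            self.dsam = None
            self.down = nn.MaxPool2d(2, 2)
        else:
            blocks = [nn.InceptionResidualBlock(c_in, c_out, cfg.kernel_pair, rng)]
            for _ in range(n_eb - 1):
                blocks.append(nn.InceptionResidualBlock(c_out, c_out, cfg.kernel_pair, rng))
            self.blocks = blocks
            self.dsam = nn.DenseSpatialAttention(rng=rng) if cfg.use_dsam else None
            self.down = nn.DepthwiseConv2d(c_out, 3, 2, rng=rng)

    def forward(self, x):
        for b in self.blocks:
            x = b(x)
        if self.dsam is not None:
            x = self.dsam(x)
        return x  # caller applies .down

class _DecoderStage(nn.Module):
    def __init__(self, c_in, c_skip, c_out, cfg: ModelConfig, rng):
        self.up = nn.UpsampleNearest2d()
        if cfg.variant == "unet":
            # classic double 3x3 decoder
            self.conv1 = _ConvBNRelu(c_in + c_skip, c_out, 3, rng)
        else:
            self.conv1 = _ConvBNRelu(c_in + c_skip, c_out, 1, rng)
        self.conv2 = _ConvBNRelu(c_out, c_out, 3, rng)

    def forward(self, x, skip):
        x = self.up(x)
        x = concat([x, skip], axis=1)
        return self.conv2(self.conv1(x))


class SegNet(nn.Module):
    """Encoder-decoder slice segmentation network; see module docstring."""

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        w = cfg.stage_widths
        self.enc = []
        c_prev = 1
        for i in range(cfg.stages):
            self.enc.append(_EncoderStage(c_prev, w[i], cfg.eb_per_stage[i], cfg, rng))
            c_prev = w[i]
        bott = w[-1]
        if cfg.variant == "unet":
            self.bott1 = _ConvBNRelu(bott, bott, 3, rng)
            self.bott2 = _ConvBNRelu(bott, bott, 3, rng)
            self.ms_pools, self.ms_fuse = None, None
        elif cfg.use_multiscale:
            self.ms_pools = [nn.AvgPool2d(2 ** (cfg.stages - i)) for i in range(cfg.stages - 1)]
            self.ms_fuse = nn.Conv2d(sum(w), bott, 1, rng=rng)
            self.bott1 = self.bott2 = None
        else:
            self.ms_pools = self.ms_fuse = self.bott1 = self.bott2 = None
        self.dec = []
        c_in = bott
        for i in reversed(range(cfg.stages)):
            self.dec.append(_DecoderStage(c_in, w[i], w[i], cfg, rng))
            c_in = w[i]
        self.head = nn.Conv2d(w[0], cfg.n_classes, 1, rng=rng)

    # ------------------------------------------------------------------ core
    def _encode(self, x: Tensor):
        skips = []
        h = x
        for stage in self.enc:
            h = stage(h)
            skips.append(h)
            h = stage.down(h)
        if self.cfg.variant == "unet":
            h = self.bott2(self.bott1(h))
        elif self.cfg.use_multiscale:
            pooled = [pool(skips[i]) for i, pool in enumerate(self.ms_pools)]
            h = self.ms_fuse(concat(pooled + [h], axis=1))
        return h, skips

    def forward(self, x) -> Tensor:
        if isinstance(x, np.ndarray):
            x = Tensor(x)
        h_, wd = x.shape[2], x.shape[3]
        div = 2 ** self.cfg.stages
        if h_ % div or wd % div:
            raise ValueError(f"spatial dims {(h_, wd)} must be divisible by {div}")
        h, skips = self._encode(x)
        for i, dec in enumerate(self.dec):
            h = dec(h, skips[self.cfg.stages - 1 - i])
        logits = self.head(h)
        if self.cfg.head == "softmax":
            e = np.exp(logits.data - logits.data.max(axis=1, keepdims=True))
            sm = e / e.sum(axis=1, keepdims=True)

            def back(g):
                return sm * (g - (g * sm).sum(axis=1, keepdims=True))

            return make_op(sm.astype(np.float32), [(logits, back)])
        return sigmoid(logits)

    def bottleneck_features(self, x) -> np.ndarray:
        """Globally average-pooled bottleneck tensor, one vector per slice."""
        if isinstance(x, np.ndarray):
            x = Tensor(x)
        h, _ = self._encode(x)
        return h.data.mean(axis=(2, 3))


def build_model(cfg: ModelConfig, seed: int = 0) -> SegNet:
    return SegNet(cfg, seed=seed)


# --------------------------------------------------------------------- data
def normalize_volume(voxels: np.ndarray) -> np.ndarray:
    """Per-volume min-max normalisation to [0, 1]."""
    v = np.asarray(voxels, dtype=np.float32)
    lo, hi = float(v.min()), float(v.max())
    if hi - lo < 1e-12:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def slice_dataset(pairs, view: str, n_classes: int = 8):
    """Build (images, one-hot targets) slice arrays from (image, label) volumes."""
    xs, ys = [], []
    for img, lab in pairs:
        ivox = normalize_volume(img.voxels if isinstance(img, ImageVolume) else img)
        lvox = lab.labels if isinstance(lab, LabelVolume) else np.asarray(lab)
        if ivox.shape != lvox.shape:
            raise ValueError("image/label shape mismatch")
        for sl_i, sl_l in zip(extract_slices(ivox, view).slices,
                              extract_slices(lvox, view).slices):
            xs.append(sl_i[None])  # add channel axis
            ys.append(np.eye(n_classes, dtype=np.float32)[sl_l].transpose(2, 0, 1))
    return np.stack(xs), np.stack(ys)


def sample_training_slices(images: np.ndarray, targets: np.ndarray,
                           bg_stride: int = 1, rare_boost: int = 1):
    """Training-slice sampling for imbalanced tissue volumes.

    Keeps every brain-containing slice plus every ``bg_stride``-th
    background-only slice, and repeats slices containing the small interior
    tissues (labels 4-7) ``rare_boost`` times so their ~1% voxel share still
    yields a usable gradient signal in short training budgets.  The defaults
    keep everything once (no resampling).
    """
    fg = targets[:, 1:].any(axis=(1, 2, 3))
    keep = fg.copy()
    bg_idx = np.flatnonzero(~fg)
    keep[bg_idx[::bg_stride]] = True
    idx = np.flatnonzero(keep)
    if rare_boost > 1 and targets.shape[1] > 4:
        rare = np.flatnonzero(targets[:, 4:].any(axis=(1, 2, 3)))
        idx = np.concatenate([idx] + [rare] * (rare_boost - 1))
    return images[idx], targets[idx]


# ----------------------------------------------------------------- training
def train_view_model(model: SegNet, images: np.ndarray, targets: np.ndarray,
                     tc: TrainConfig, verbose: bool = False):
    """Train on slice arrays (N,1,H,W) / (N,K,H,W); returns (model, history)."""
    if len(images) == 0:
        raise ValueError("empty training set")
    if len(images) != len(targets):
        raise ValueError("images and targets differ in length")
    history: list[float] = []
    if tc.epochs == 0:
        return model, history
    loss_fn = nn.get_loss(tc.loss_name, alpha=tc.alpha, beta=tc.beta)
    opt = nn.Adam(model.parameters(), lr=tc.lr, eps=tc.adam_eps,
                  weight_decay=tc.weight_decay)
    rng = np.random.default_rng(tc.seed)
    model.train()
    n = len(images)
    for epoch in range(tc.epochs):
        order = rng.permutation(n)
        total, nb = 0.0, 0
        for start in range(0, n, tc.batch_size):
            idx = order[start : start + tc.batch_size]
            if len(idx) < 2:
                continue  # batch norm needs >= 2 samples
            xb, yb = images[idx], targets[idx]
            opt.zero_grad()
            pred = model(xb)
            loss = loss_fn(pred, yb)
            lv = float(loss.data)
            if not np.isfinite(lv):
                raise RuntimeError(
                    f"non-finite loss {lv} at epoch {epoch}, batch {start // tc.batch_size}"
                )
            loss.backward()
            opt.step()
            total += lv
            nb += 1
        history.append(total / max(nb, 1))
        if verbose:
            print(f"epoch {epoch + 1}/{tc.epochs}: loss {history[-1]:.4f}")
    model.eval()
    return model, history


# --------------------------------------------------------------- prediction
def _pad_to_multiple(arr2d: np.ndarray, div: int):
    h, w = arr2d.shape
    ph = (-h) % div
    pw = (-w) % div
    if ph or pw:
        arr2d = np.pad(arr2d, ((0, ph), (0, pw)), mode="reflect")
    return arr2d, (h, w)


def predict_view(model: SegNet, vol, view: str, batch_size: int = 32) -> ViewProbabilities:
    """Per-slice class scores stacked along the view axis into a score volume."""
    voxels = vol.voxels if isinstance(vol, ImageVolume) else np.asarray(vol)
    voxels = normalize_volume(voxels)
    axis = view_axis(view)
    div = 2 ** model.cfg.stages
    stack = extract_slices(voxels, view)
    padded = [_pad_to_multiple(s, div) for s in stack.slices]
    xs = np.stack([p[0][None] for p in padded])
    model.eval()
    outs = []
    for start in range(0, len(xs), batch_size):
        outs.append(model(xs[start : start + batch_size]).data)
    scores = np.concatenate(outs, axis=0)  # (n_slices, K, Hp, Wp)
    h, w = padded[0][1]
    scores = scores[:, :, :h, :w]
    full = np.moveaxis(scores, 0, 1 + axis)  # (K, nx, ny, nz)
    return ViewProbabilities(view=view, scores=full)
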