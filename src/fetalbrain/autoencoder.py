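"""3D convolutional autoencoder producing latent vectors for GA regression.

Encoder stages are Conv3d -> BatchNorm -> ReLU -> 2x2x2 max-pool (halving
each spatial dimension); the bottleneck is flattened and projected to a
latent vector (default 256).  The decoder mirrors the encoder with stride-2
transposed convolutions followed by Conv3d + BatchNorm + ReLU, ending in a
sigmoid head.  Volumes are min-max normalised per subject and resampled to
the configured cubic input shape (trilinear) before encoding; training
minimises mean squared reconstruction error with Adam.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import nn
from .model import normalize_volume
from .nn.tensor import Tensor, make_op, relu, sigmoid, tmean
from .volume import ImageVolume


@dataclass
class AEConfig:
    latent_dim: int = 256
    depth: int = 4
    base_width: int = 8
    input_shape: tuple = (32, 32, 32)
    lr: float = 1e-3
    epochs: int = 12
    batch_size: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        div = 2**self.depth
        if any(s % div for s in self.input_shape):
            raise ValueError(f"input shape {self.input_shape} not divisible by {div}")


class Autoencoder3d(nn.Module):
    def __init__(self, cfg: AEConfig):
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        widths = [cfg.base_width * 2**i for i in range(cfg.depth)]
        self.enc_convs, self.enc_bns = [], []
        c = 1
        for w in widths:
            self.enc_convs.append(nn.Conv3d(c, w, 3, rng=rng))
            self.enc_bns.append(nn.BatchNorm(w))
            c = w
        self.pool = nn.MaxPool3d()
        bs = tuple(s // 2**cfg.depth for s in cfg.input_shape)
        self.bott_shape = (widths[-1],) + bs
        flat = int(np.prod(self.bott_shape))
        self.to_latent = nn.Linear(flat, cfg.latent_dim, rng=rng)
        self.from_latent = nn.Linear(cfg.latent_dim, flat, rng=rng)
        self.dec_ups, self.dec_convs, self.dec_bns = [], [], []
        rev = list(reversed(widths))
        for i, w in enumerate(rev):
            w_out = rev[i + 1] if i + 1 < len(rev) else widths[0]
            self.dec_ups.append(nn.ConvTranspose3d(w, w, rng=rng))
            self.dec_convs.append(nn.Conv3d(w, w_out, 3, rng=rng))
            self.dec_bns.append(nn.BatchNorm(w_out))
        self.head = nn.Conv3d(widths[0], 1, 3, rng=rng)

    def encode(self, x) -> Tensor:
        if isinstance(x, np.ndarray):
            x = Tensor(x)
        h = x
        for conv, bn in zip(self.enc_convs, self.enc_bns):
            h = self.pool(relu(bn(conv(h))))
        n = h.shape[0]
        flat = h.data.reshape(n, -1)
        h_flat = make_op(flat, [(h, lambda g: g.reshape(h.shape))])
        return self.to_latent(h_flat)

    def decode(self, z: Tensor) -> Tensor:
        n = z.shape[0]
        h = self.from_latent(z)
        shape = (n,) + self.bott_shape
        h = make_op(h.data.reshape(shape), [(h, lambda g: g.reshape(n, -1))])
        for up, conv, bn in zip(self.dec_ups, self.dec_convs, self.dec_bns):
            h = relu(bn(conv(up(h))))
        return sigmoid(self.head(h))

    def forward(self, x) -> Tensor:
        return self.decode(self.encode(x))


def build_autoencoder(cfg: AEConfig) -> Autoencoder3d:
    return Autoencoder3d(cfg)


def prepare_volume(vol, input_shape) -> np.ndarray:
    """Min-max normalise and trilinearly resample to the model input shape."""
    voxels = vol.voxels if isinstance(vol, ImageVolume) else np.asarray(vol)
    v = normalize_volume(voxels)
    if v.shape != tuple(input_shape):
        factors = [t / s for t, s in zip(input_shape, v.shape)]
        v = ndimage.zoom(v, factors, order=1)
        # zoom can be off by one voxel; pad/crop to the exact shape
        v = _fit(v, input_shape)
    return v.astype(np.float32)


def _fit(v: np.ndarray, shape) -> np.ndarray:
    out = np.zeros(shape, dtype=v.dtype)
    sl_src = tuple(slice(0, min(a, b)) for a, b in zip(v.shape, shape))
    out[sl_src] = v[sl_src]
    return out


def train_autoencoder(model: Autoencoder3d, volumes, cfg: AEConfig,
                      verbose: bool = False):
    """Train on a list of volumes; returns (model, per-epoch MSE history)."""
    if len(volumes) < 2:
        raise ValueError("need at least 2 volumes")
    data = np.stack([prepare_volume(v, cfg.input_shape) for v in volumes])[:, None]
    history: list[float] = []
    if cfg.epochs == 0:
        return model, history
    opt = nn.Adam(model.parameters(), lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed)
    model.train()
    n = len(data)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        total, nb = 0.0, 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            if len(idx) < 2:
                continue
            xb = data[idx]
            opt.zero_grad()
            recon = model(xb)
            diff = recon - Tensor(xb)
            loss = tmean(diff * diff)
            lv = float(loss.data)
            if not np.isfinite(lv):
                raise RuntimeError(f"non-finite reconstruction loss at epoch {epoch}")
            loss.backward()
            opt.step()
            total += lv
            nb += 1
        history.append(total / max(nb, 1))
        if verbose:
            print(f"epoch {epoch + 1}/{cfg.epochs}: mse {history[-1]:.5f}")
    model.eval()
    return model, history


def encode_volume(model: Autoencoder3d, vol) -> np.ndarray:
    """Deterministic latent vector (eval mode) for one volume."""
    model.eval()
    x = prepare_volume(vol, model.cfg.input_shape)[None, None]
    return model.encode(x).data[0].copy()
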