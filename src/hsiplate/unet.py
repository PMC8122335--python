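"""U-net droplet segmentation.

An encoder-decoder convolutional network with skip concatenations predicts
a binary droplet mask from a single feature-band image.  Compared with a
global threshold, the network uses spatial context, so faint low-contrast
droplets lose fewer pixels.

Architecture: four encoder blocks of two same-padded 3x3 convolutions with
ReLU, each followed by 2x2 max pooling; channel widths 32-64-128-128 (the
doubling ladder capped at 128, so the deepest skip concatenates two
128-channel maps into a 256-channel map); a 128-channel bridge; dropout 0.5
at the two deepest levels; a decoder of 2x2 stride-2 transposed convolutions
with skip concatenation and two 3x3 convolutions per level; and a final 1x1
convolution to one sigmoid channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from .io import Image2D
from .nn import (
    Adam,
    Conv2D,
    ConvTranspose2D,
    Dropout,
    Layer,
    MaxPool2D,
    ReLU,
    TrainHistory,
    sigmoid,
    sigmoid_bce_loss,
)
from .segment import MaskImage

__all__ = ["UNetSpec", "UNet", "UNetSegmenter", "build_unet", "train_unet", "predict_mask"]


@dataclass
class UNetSpec:
    """Structural parameters of the segmentation network."""

    input_shape: tuple[int, int] = (128, 128)
    depth: int = 4  # encoder blocks (= pooling steps)
    base_channels: int = 32
    max_channels: int = 128
    dropout: float = 0.5
    in_channels: int = 1

    def encoder_channels(self) -> list[int]:
        """Channel width per encoder block: doubling, capped at max_channels."""
        return [min(self.base_channels * 2**i, self.max_channels) for i in range(self.depth)]

    def validate(self) -> None:
        H, W = self.input_shape
        f = 2**self.depth
        if H % f or W % f:
            raise ValueError(
                f"input {H}x{W} not divisible by 2^depth = {f}; "
                "pad or crop the image first"
            )


class _ConvBlock(Layer):
    """(conv 3x3 -> ReLU) x 2."""

    def __init__(self, c_in, c_out, rng, dtype):
        self.c1 = Conv2D(c_in, c_out, 3, rng, dtype)
        self.r1 = ReLU()
        self.c2 = Conv2D(c_out, c_out, 3, rng, dtype)
        self.r2 = ReLU()
        self._seq = [self.c1, self.r1, self.c2, self.r2]

    def params(self):
        return [p for l in self._seq for p in l.params()]

    def grads(self):
        return [g for l in self._seq for g in l.grads()]

    def forward(self, x, train=False):
        for l in self._seq:
            x = l.forward(x, train=train)
        return x

    def backward(self, grad):
        for l in reversed(self._seq):
            grad = l.backward(grad)
        return grad


class UNet(Layer):
    """The raw network: forward to logits, explicit backprop with skips."""

    def __init__(self, spec: UNetSpec, seed: int = 0, dtype=np.float32):
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(seed)
        chans = spec.encoder_channels()
        self.enc: list[_ConvBlock] = []
        self.enc_drop: list[Dropout | None] = []
        c_prev = spec.in_channels
        for i, c in enumerate(chans):
            self.enc.append(_ConvBlock(c_prev, c, rng, dtype))
            # dropout at the deepest encoder level only (plus the bridge)
            self.enc_drop.append(Dropout(spec.dropout, rng) if i == spec.depth - 1 else None)
            c_prev = c
        self.pools = [MaxPool2D() for _ in chans]
        bridge_c = chans[-1]
        self.bridge = _ConvBlock(c_prev, bridge_c, rng, dtype)
        self.bridge_drop = Dropout(spec.dropout, rng)
        self.ups: list[ConvTranspose2D] = []
        self.dec: list[_ConvBlock] = []
        c_prev = bridge_c
        for c in reversed(chans):
            self.ups.append(ConvTranspose2D(c_prev, c, rng, dtype))
            self.dec.append(_ConvBlock(2 * c, c, rng, dtype))  # concat doubles channels
            c_prev = c
        self.final = Conv2D(c_prev, 1, 1, rng, dtype)

    def _modules(self):
        mods = []
        for e, d in zip(self.enc, self.enc_drop):
            mods.append(e)
            if d is not None:
                mods.append(d)
        mods += self.pools + [self.bridge, self.bridge_drop]
        for u, d in zip(self.ups, self.dec):
            mods += [u, d]
        mods.append(self.final)
        return mods

    def params(self):
        return [p for m in self._modules() for p in m.params()]

    def grads(self):
        return [g for m in self._modules() for g in m.grads()]

    def forward(self, x, train=False):
        """x: (N, H, W, 1) -> logits (N, H, W, 1)."""
        skips = []
        for blk, drop, pool in zip(self.enc, self.enc_drop, self.pools):
            x = blk.forward(x, train=train)
            if drop is not None:
                x = drop.forward(x, train=train)
            skips.append(x)
            x = pool.forward(x, train=train)
        x = self.bridge.forward(x, train=train)
        x = self.bridge_drop.forward(x, train=train)
        self._skip_channels = [s.shape[3] for s in skips]
        for up, blk, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x, train=train)
            x = np.concatenate([skip, x], axis=3)
            x = blk.forward(x, train=train)
        return self.final.forward(x, train=train)

    def backward(self, grad):
        grad = self.final.backward(grad)
        skip_grads = []
        for up, blk, c_skip in zip(
            reversed(self.ups), reversed(self.dec), self._skip_channels
        ):
            grad = blk.backward(grad)
            skip_grads.append(grad[..., :c_skip])
            grad = up.backward(grad[..., c_skip:])
        grad = self.bridge_drop.backward(grad)
        grad = self.bridge.backward(grad)
        # skip_grads was filled shallow-to-deep; encoder backward runs deep-to-shallow
        for blk, drop, pool, gskip in zip(
            reversed(self.enc),
            reversed(self.enc_drop),
            reversed(self.pools),
            reversed(skip_grads),
        ):
            grad = pool.backward(grad) + gskip
            if drop is not None:
                grad = drop.backward(grad)
            grad = blk.backward(grad)
        return grad

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """(N, H, W) images -> (N, H, W) sigmoid mask probabilities."""
        x = np.asarray(images, dtype=np.float32)[..., None]
        return sigmoid(self.forward(x, train=False))[..., 0]

    def save(self, path) -> Path:
        path = Path(path)
        np.savez(path, *self.params())
        return path

    def load(self, path) -> "UNet":
        with np.load(path) as f:
            for p, key in zip(self.params(), f.files):
                p[...] = f[key]
        return self


def build_unet(spec: UNetSpec | None = None, seed: int = 0) -> UNet:
    """Construct an untrained U-net from a :class:`UNetSpec`."""
    return UNet(spec or UNetSpec(), seed=seed)


class UNetSegmenter(BaseEstimator):
    """Scikit-learn style wrapper: ``fit(images, masks)`` / ``predict(images)``.

    Parameters
    ----------
    depth, base_channels, max_channels, dropout : network structure
        (see :class:`UNetSpec`).
    epochs, batch_size, lr : training schedule (Adam on pixelwise binary
        cross-entropy).
    threshold : float
        Sigmoid cutoff used by :meth:`predict`.
    random_state : int
        Seeds weight init, dropout and batch shuffling; fits are
        reproducible bit-for-bit.
    """

    def __init__(self, depth: int = 4, base_channels: int = 32, max_channels: int = 128,
                 dropout: float = 0.5, epochs: int = 30, batch_size: int = 2,
                 lr: float = 1e-3, threshold: float = 0.5, random_state: int = 0):
        self.depth = depth
        self.base_channels = base_channels
        self.max_channels = max_channels
        self.dropout = dropout
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.threshold = threshold
        self.random_state = random_state

    def fit(self, X, y):
        """Train on images X (n, H, W) and boolean masks y (n, H, W)."""
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=np.float32)
        if X.ndim != 3 or y.shape != X.shape:
            raise ValueError("X and y must both be (n_images, H, W)")
        if len(X) == 0:
            raise ValueError("empty training set")
        spec = UNetSpec(
            input_shape=X.shape[1:],
            depth=self.depth,
            base_channels=self.base_channels,
            max_channels=self.max_channels,
            dropout=self.dropout,
        )
        self.model_ = UNet(spec, seed=self.random_state)
        opt = Adam(self.model_, lr=self.lr)
        rng = np.random.default_rng(self.random_state + 1)
        self.history_ = TrainHistory(metric_name="pixel_accuracy")
        n = len(X)
        for _ in range(self.epochs):
            order = rng.permutation(n)
            ep_loss, ep_acc = 0.0, 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb = X[idx][..., None]
                yb = y[idx][..., None]
                logits = self.model_.forward(xb, train=True)
                loss, grad = sigmoid_bce_loss(logits, yb)
                self.model_.backward(grad)
                opt.step()
                ep_loss += loss * len(idx)
                ep_acc += float(np.mean((logits > 0) == (yb > 0.5))) * len(idx)
            self.history_.append(ep_loss / n, ep_acc / n)
        return self

    def fit_pairs(self, pairs):
        """Fit from a list of ``(Image2D, mask)`` training pairs."""
        X = np.stack([p[0].data if isinstance(p[0], Image2D) else p[0] for p in pairs])
        y = np.stack([p[1] for p in pairs])
        return self.fit(X, y)

    def predict_proba(self, X) -> np.ndarray:
        return self.model_.predict_proba(np.asarray(X))

    def predict(self, X) -> np.ndarray:
        """(n, H, W) images -> (n, H, W) boolean masks."""
        return self.predict_proba(X) >= self.threshold

    def predict_mask(self, image, threshold: float | None = None) -> MaskImage:
        """Single image (2-D or Image2D) -> :class:`MaskImage` tagged 'unet'."""
        img = image.data if isinstance(image, Image2D) else np.asarray(image)
        if img.ndim != 2:
            raise ValueError("predict_mask expects a single 2-D image")
        if img.shape != tuple(self.model_.spec.input_shape):
            raise ValueError(
                f"image shape {img.shape} does not match the trained input "
                f"shape {tuple(self.model_.spec.input_shape)}"
            )
        t = self.threshold if threshold is None else threshold
        proba = self.model_.predict_proba(img[None])[0]
        return MaskImage(proba >= t, provenance="unet")


def train_unet(model: UNet, pairs, epochs: int = 30, seed: int = 0,
               batch_size: int = 2, lr: float = 1e-3) -> tuple[UNet, TrainHistory]:
    """Train an existing :class:`UNet` on (image, mask) pairs; seeded."""
    if len(pairs) == 0:
        raise ValueError("empty training set")
    X = np.stack(
        [p[0].data if isinstance(p[0], Image2D) else np.asarray(p[0]) for p in pairs]
    ).astype(np.float32)
    y = np.stack([np.asarray(p[1], dtype=np.float32) for p in pairs])
    opt = Adam(model, lr=lr)
    rng = np.random.default_rng(seed)
    history = TrainHistory(metric_name="pixel_accuracy")
    n = len(X)
    for _ in range(epochs):
        order = rng.permutation(n)
        ep_loss, ep_acc = 0.0, 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            xb, yb = X[idx][..., None], y[idx][..., None]
            logits = model.forward(xb, train=True)
            loss, grad = sigmoid_bce_loss(logits, yb)
            model.backward(grad)
            opt.step()
            ep_loss += loss * len(idx)
            ep_acc += float(np.mean((logits > 0) == (yb > 0.5))) * len(idx)
        history.append(ep_loss / n, ep_acc / n)
    return model, history


def predict_mask(model: UNet, image, threshold: float = 0.5) -> MaskImage:
    """Binarize the sigmoid output of ``model`` on one band image."""
    img = image.data if isinstance(image, Image2D) else np.asarray(image)
    if img.ndim != 2:
        raise ValueError("predict_mask expects a 2-D image")
    if img.shape != tuple(model.spec.input_shape):
        raise ValueError(
            f"image shape {img.shape} != model input {tuple(model.spec.input_shape)}"
        )
    return MaskImage(model.predict_proba(img[None])[0] >= threshold, provenance="unet")
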