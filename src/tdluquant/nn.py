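"""Minimal NumPy building blocks for the segmentation U-Net.

A deliberately small convolutional-network core: 3x3 same-padding
convolutions via im2col GEMM, ReLU, 2x2 max pooling, nearest-neighbor
upsampling, channel concatenation, masked softmax cross-entropy and Adam.
Everything is float32, layout (N, C, H, W), with exact manual gradients —
sized for CPU training on synthetic scenes rather than GPU-scale slides.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2d", "UNet", "Adam", "masked_softmax_cross_entropy", "softmax"]


def _im2col3(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (C*9, N*H*W) patches of every 3x3 window (pad 1)."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    # win: (N, C, H, W, 3, 3) -> (C, 3, 3, N, H, W)
    cols = win.transpose(1, 4, 5, 0, 2, 3).reshape(c * 9, n * h * w)
    return np.ascontiguousarray(cols, dtype=np.float32)


class Conv2d:
    """3x3 (or 1x1) convolution, stride 1, same padding, optional ReLU."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        rng: np.random.Generator,
        kernel: int = 3,
        relu: bool = True,
    ):
        self.c_in, self.c_out, self.kernel, self.relu = c_in, c_out, kernel, relu
        fan_in = c_in * kernel * kernel
        self.weight = rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, fan_in)).astype(
            np.float32
        )
        self.bias = np.zeros(c_out, dtype=np.float32)
        self.dweight = np.zeros_like(self.weight)
        self.dbias = np.zeros_like(self.bias)
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        if self.kernel == 1:
            cols = np.ascontiguousarray(
                x.transpose(1, 0, 2, 3).reshape(c, n * h * w), dtype=np.float32
            )
        else:
            cols = _im2col3(x)
        out = (self.weight @ cols + self.bias[:, None]).reshape(
            self.c_out, n, h, w
        ).transpose(1, 0, 2, 3)
        mask = None
        if self.relu:
            mask = out > 0
            out = np.where(mask, out, 0.0).astype(np.float32)
        if train:
            self._cache = (cols, mask, (n, h, w))
        return np.ascontiguousarray(out, dtype=np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, mask, (n, h, w) = self._cache
        self._cache = None
        if self.relu:
            dout = np.where(mask, dout, 0.0)
        dflat = np.ascontiguousarray(
            dout.transpose(1, 0, 2, 3).reshape(self.c_out, n * h * w),
            dtype=np.float32,
        )
        self.dweight += dflat @ cols.T
        self.dbias += dflat.sum(axis=1)
        if self.kernel == 1:
            dx = (self.weight.T @ dflat).reshape(self.c_in, n, h, w)
            return np.ascontiguousarray(dx.transpose(1, 0, 2, 3), dtype=np.float32)
        # dx = correlation of dout with spatially flipped kernels
        w_t = (
            self.weight.reshape(self.c_out, self.c_in, 9)[:, :, ::-1]
            .transpose(1, 0, 2)
            .reshape(self.c_in, self.c_out * 9)
        )
        dcols = _im2col3(np.ascontiguousarray(dout, dtype=np.float32))
        dx = (np.ascontiguousarray(w_t) @ dcols).reshape(self.c_in, n, h, w)
        return np.ascontiguousarray(dx.transpose(1, 0, 2, 3), dtype=np.float32)

    def parameters(self):
        return [
            (self.weight, self.dweight),
            (self.bias, self.dbias),
        ]

    def zero_grad(self) -> None:
        self.dweight[...] = 0.0
        self.dbias[...] = 0.0


def _maxpool2(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    xr = xr.reshape(n, c, h // 2, w // 2, 4)
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return np.ascontiguousarray(out), idx


def _maxpool2_backward(dout: np.ndarray, idx: np.ndarray, shape) -> np.ndarray:
    n, c, h, w = shape
    dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
    np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=-1)
    dx = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return np.ascontiguousarray(dx.reshape(n, c, h, w))


def _upsample2(x: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(x.repeat(2, axis=2).repeat(2, axis=3))


def _upsample2_backward(dout: np.ndarray) -> np.ndarray:
    n, c, h, w = dout.shape
    return np.ascontiguousarray(
        dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))
    )


class UNet:
    """Encoder-decoder with skip connections for multiclass segmentation.

    ``depth`` pooling levels halve the resolution each step while channel
    counts double from ``base_filters``; the decoder mirrors the encoder
    with nearest-neighbor upsampling and skip concatenation, ending in a
    1x1 classification head over ``n_classes`` logits.
    """

    def __init__(
        self,
        in_channels: int = 3,
        n_classes: int = 8,
        depth: int = 3,
        base_filters: int = 8,
        seed: int = 0,
    ):
        self.in_channels = in_channels
        self.n_classes = n_classes
        self.depth = depth
        self.base_filters = base_filters
        rng = np.random.default_rng(seed)
        f = base_filters
        self.enc: list[tuple[Conv2d, Conv2d]] = []
        c_prev = in_channels
        for level in range(depth):
            c = f * 2**level
            self.enc.append((Conv2d(c_prev, c, rng), Conv2d(c, c, rng)))
            c_prev = c
        c_bot = f * 2**depth
        self.bottleneck = (Conv2d(c_prev, c_bot, rng), Conv2d(c_bot, c_bot, rng))
        self.dec: list[tuple[Conv2d, Conv2d, Conv2d]] = []
        c_prev = c_bot
        for level in reversed(range(depth)):
            c = f * 2**level
            self.dec.append(
                (
                    Conv2d(c_prev, c, rng),  # channel reduction after upsampling
                    Conv2d(2 * c, c, rng),  # after skip concatenation
                    Conv2d(c, c, rng),
                )
            )
            c_prev = c
        self.head = Conv2d(c_prev, n_classes, rng, kernel=1, relu=False)
        self._cache: dict | None = None

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=np.float32)
        skips, pools = [], []
        for conv1, conv2 in self.enc:
            x = conv2.forward(conv1.forward(x, train), train)
            skips.append(x)
            x, idx = _maxpool2(x)
            pools.append((idx, skips[-1].shape))
        x = self.bottleneck[1].forward(self.bottleneck[0].forward(x, train), train)
        for (red, mix, conv2), skip in zip(self.dec, reversed(skips)):
            x = red.forward(_upsample2(x), train)
            x = np.concatenate([skip, x], axis=1)
            x = conv2.forward(mix.forward(x, train), train)
        logits = self.head.forward(x, train)
        if train:
            self._cache = {"pools": pools}
        return logits

    def backward(self, dlogits: np.ndarray) -> None:
        pools = self._cache["pools"]
        dx = self.head.backward(dlogits)
        dskips = []  # dskips[i] pairs with self.enc[i]'s skip
        for red, mix, conv2 in reversed(self.dec):
            dx = mix.backward(conv2.backward(dx))
            c = dx.shape[1] // 2
            dskips.append(dx[:, :c])
            dx = _upsample2_backward(red.backward(np.ascontiguousarray(dx[:, c:])))
        dx = self.bottleneck[0].backward(self.bottleneck[1].backward(dx))
        for (conv1, conv2), (idx, shape), dskip in zip(
            reversed(self.enc), reversed(pools), reversed(dskips)
        ):
            dx = _maxpool2_backward(dx, idx, shape) + dskip
            dx = conv1.backward(conv2.backward(dx))
        self._cache = None

    # -- plumbing -----------------------------------------------------------
    def _convs(self) -> list[Conv2d]:
        convs: list[Conv2d] = []
        for pair in self.enc:
            convs.extend(pair)
        convs.extend(self.bottleneck)
        for triple in self.dec:
            convs.extend(triple)
        convs.append(self.head)
        return convs

    def parameters(self):
        params = []
        for conv in self._convs():
            params.extend(conv.parameters())
        return params

    def zero_grad(self) -> None:
        for conv in self._convs():
            conv.zero_grad()

    def get_weights(self) -> list[np.ndarray]:
        out = []
        for conv in self._convs():
            out.extend([conv.weight.copy(), conv.bias.copy()])
        return out

    def set_weights(self, weights: list[np.ndarray]) -> None:
        it = iter(weights)
        for conv in self._convs():
            conv.weight[...] = next(it)
            conv.bias[...] = next(it)


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z, dtype=np.float32)
    return e / e.sum(axis=axis, keepdims=True)


def masked_softmax_cross_entropy(
    logits: np.ndarray,
    labels: np.ndarray,
    ignore_label: int = 0,
    class_weights: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Weighted mean pixelwise cross-entropy over labeled pixels, and its gradient.

    ``labels`` is (N, H, W) int; pixels equal to ``ignore_label``
    (unannotated background) contribute neither loss nor gradient.
    ``class_weights`` (length n_classes) rebalances rare classes; the loss
    is the weight-normalized mean so its scale is comparable across
    weightings.
    """
    n, k, h, w = logits.shape
    probs = softmax(logits, axis=1)
    valid = labels != ignore_label
    if not valid.any():
        raise ValueError("no labeled pixels in batch")
    flat = probs.transpose(0, 2, 3, 1).reshape(-1, k)
    lab = labels.reshape(-1)
    vmask = valid.reshape(-1)
    pixel_w = np.where(vmask, 1.0, 0.0)
    if class_weights is not None:
        pixel_w = pixel_w * np.asarray(class_weights, dtype=np.float64)[lab]
    w_total = float(pixel_w.sum())
    picked = flat[np.arange(flat.shape[0]), lab]
    loss = float(
        -(pixel_w * np.log(np.clip(picked, 1e-12, None))).sum() / w_total
    )
    grad_flat = flat.copy()
    grad_flat[np.arange(flat.shape[0]), lab] -= 1.0
    grad_flat *= (pixel_w / w_total)[:, None].astype(np.float32)
    grad = grad_flat.reshape(n, h, w, k).transpose(0, 3, 1, 2)
    return loss, np.ascontiguousarray(grad, dtype=np.float32)


class Adam:
    """Adam optimizer over the (param, grad) pairs of a network."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, (p, g) in enumerate(self.params):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
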