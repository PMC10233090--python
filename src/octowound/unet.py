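"""A compact NumPy implementation of the classical u-net.

Layers use channels-last ``(N, H, W, C)`` float32 arrays.  Convolutions are
computed with im2col + matmul; gradients are derived analytically
(transposed-kernel full convolution for the input gradient), so the whole
network trains with plain momentum SGD without any autograd framework.
The layer set is exactly what the u-net needs: 3x3 same-padding
convolutions, ReLU, 2x2 max-pooling, 2x nearest-neighbour upsampling,
channel concatenation for skip connections, and a 1x1 output convolution.
"""

from __future__ import annotations

import numpy as np

__all__ = ["UNet", "softmax_cross_entropy", "SGDMomentum"]


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, H, W, C) -> (N*H*W, C*k*k) patches with same padding."""
    n, h, w, c = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)), mode="constant")
    # (N, H, W, C, k, k) sliding view, then flatten (C, k, k) per pixel.
    view = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    return view.reshape(n * h * w, c * k * k)


class Conv2d:
    """Same-padding 2D convolution with bias (kernel 3x3 or 1x1)."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        self.c_in, self.c_out, self.k = c_in, c_out, k
        fan_in = c_in * k * k
        fan_out = c_out * k * k
        # Glorot initialisation: paired with zero-centred inputs it keeps
        # the hot momentum-SGD regime (lr 0.05) clear of dead-ReLU collapse.
        scale = np.sqrt(2.0 / (fan_in + fan_out))
        self.W = rng.normal(0.0, scale, size=(c_in, k, k, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._col: np.ndarray | None = None
        self._in_shape: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, _ = x.shape
        if self.k == 1:
            col = x.reshape(n * h * w, self.c_in)
        else:
            col = _im2col(x, self.k)
        y = col @ self.W.reshape(-1, self.c_out) + self.b
        if train:
            self._col = col
            self._in_shape = x.shape
        return y.reshape(n, h, w, self.c_out)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, _ = dy.shape
        dyf = dy.reshape(n * h * w, self.c_out)
        # The 1/npix of the mean loss is already inside dy (applied once at
        # the loss), so plain sums give the correct parameter gradients.
        self.dW = (self._col.T @ dyf).reshape(self.W.shape)
        self.db = dyf.sum(axis=0)
        # Input gradient: full correlation with the flipped, transposed kernel.
        if self.k == 1:
            dx = dyf @ self.W.reshape(self.c_in, self.c_out).T
        else:
            wt = self.W[:, ::-1, ::-1, :].transpose(3, 1, 2, 0)  # (F, k, k, C)
            dx = _im2col(dy, self.k) @ wt.reshape(-1, self.c_in)
        self._col = None
        return dx.reshape(self._in_shape)

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size


class ReLU:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2:
    """2x2 max pooling; gradient is split evenly across tied maxima."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        y = xr.max(axis=(2, 4))
        if train:
            self._xr = xr
            self._y = y
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        mask = self._xr == self._y[:, :, None, :, None, :]
        counts = mask.sum(axis=(2, 4), keepdims=True)
        dxr = mask * (dy[:, :, None, :, None, :] / counts)
        n, hh, _, ww, _, c = dxr.shape
        return dxr.reshape(n, hh * 2, ww * 2, c)


class Upsample2:
    """2x nearest-neighbour upsampling."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = dy.shape
        return dy.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class ConvBlock:
    """Two 3x3 conv + ReLU stages, the u-net's basic unit."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.conv1 = Conv2d(c_in, c_out, 3, rng)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(c_out, c_out, 3, rng)
        self.relu2 = ReLU()

    def forward(self, x, train=False):
        x = self.relu1.forward(self.conv1.forward(x, train), train)
        return self.relu2.forward(self.conv2.forward(x, train), train)

    def backward(self, dy):
        dy = self.conv2.backward(self.relu2.backward(dy))
        return self.conv1.backward(self.relu1.backward(dy))

    @property
    def convs(self):
        return [self.conv1, self.conv2]


class UNet:
    """Encoder-decoder u-net with skip connections and 7-way softmax head.

    ``depth`` down/up levels; channels double at each down level starting
    from ``base_channels``; spatial size must be divisible by ``2**depth``.
    """

    def __init__(self, depth: int, base_channels: int, n_classes: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.depth = depth
        self.base_channels = base_channels
        self.n_classes = n_classes
        chans = [base_channels * 2**i for i in range(depth + 1)]
        self.enc = []
        c_prev = 1
        for c in chans[:-1]:
            self.enc.append(ConvBlock(c_prev, c, rng))
            c_prev = c
        self.pools = [MaxPool2() for _ in range(depth)]
        self.bottleneck = ConvBlock(c_prev, chans[-1], rng)
        self.ups = [Upsample2() for _ in range(depth)]
        self.dec = []
        c_prev = chans[-1]
        for c in reversed(chans[:-1]):
            self.dec.append(ConvBlock(c_prev + c, c, rng))
            c_prev = c
        self.head = Conv2d(c_prev, n_classes, 1, rng)

    # -- plumbing -------------------------------------------------------
    def _all_convs(self):
        convs = []
        for b in self.enc:
            convs += b.convs
        convs += self.bottleneck.convs
        for b in self.dec:
            convs += b.convs
        convs.append(self.head)
        return convs

    @property
    def n_params(self) -> int:
        return sum(c.n_params for c in self._all_convs())

    # -- forward / backward --------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """(N, H, W, 1) intensities -> (N, H, W, n_classes) logits."""
        if x.ndim != 4:
            raise ValueError("expected (N, H, W, 1) input")
        h, w = x.shape[1:3]
        f = 2**self.depth
        if h % f or w % f:
            raise ValueError(
                f"input size {h}x{w} not divisible by 2**depth = {f}"
            )
        skips = []
        for block, pool in zip(self.enc, self.pools):
            x = block.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.bottleneck.forward(x, train)
        self._skip_channels = []
        for up, block, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x, train)
            self._skip_channels.append((skip.shape[-1], x.shape[-1]))
            x = np.concatenate([skip, x], axis=-1)
            x = block.forward(x, train)
        return self.head.forward(x, train)

    def backward(self, dlogits: np.ndarray) -> None:
        dx = self.head.backward(dlogits)
        dskips = []
        for block, up, (c_skip, _) in zip(
            reversed(self.dec), reversed(self.ups), reversed(self._skip_channels)
        ):
            dx = block.backward(dx)
            dskips.append(dx[..., :c_skip])
            dx = up.backward(dx[..., c_skip:])
        dx = self.bottleneck.backward(dx)
        # dskips were collected top-level-first; the encoder unwinds
        # deepest-first, so reverse them for pairing.
        for block, pool, dskip in zip(
            reversed(self.enc), reversed(self.pools), reversed(dskips)
        ):
            dx = pool.backward(dx) + dskip
            dx = block.backward(dx)

    # -- serialisation --------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for i, c in enumerate(self._all_convs()):
            out[f"conv{i}.W"] = c.W
            out[f"conv{i}.b"] = c.b
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, c in enumerate(self._all_convs()):
            c.W = np.asarray(state[f"conv{i}.W"], dtype=np.float32).reshape(c.W.shape)
            c.b = np.asarray(state[f"conv{i}.b"], dtype=np.float32).reshape(c.b.shape)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray, float]:
    """Mean pixel-wise cross-entropy.

    Returns ``(loss, dlogits, pixel_accuracy)`` where ``dlogits`` is the
    gradient of the mean loss w.r.t. the logits (already divided by the
    pixel count) and accuracy is the fraction of correctly argmax-classified
    pixels in the batch.
    """
    n, h, w, c = logits.shape
    flat = logits.reshape(-1, c)
    lab = labels.reshape(-1).astype(np.int64)
    m = flat.max(axis=1, keepdims=True)
    e = np.exp(flat - m)
    p = e / e.sum(axis=1, keepdims=True)
    npix = lab.size
    eps = 1e-12
    loss = float(-np.log(p[np.arange(npix), lab] + eps).mean())
    acc_flat = flat.argmax(axis=1) == lab
    dl = p
    dl[np.arange(npix), lab] -= 1.0
    dl /= npix  # gradient of the *mean* pixel loss
    dlogits = dl.reshape(n, h, w, c)
    acc = float(acc_flat.mean())
    return loss, dlogits, acc


class SGDMomentum:
    """Classical momentum SGD with L2 regularisation and norm clipping.

    Update: ``v <- momentum * v - lr * (grad + l2 * w); w <- w + v``.
    Gradients are jointly rescaled when their global L2 norm exceeds
    ``clip_norm`` — rare spike events otherwise capsize training at this
    learning rate, while ordinary steps (norms well below 1) pass
    untouched.
    """

    def __init__(
        self,
        model: UNet,
        lr: float,
        momentum: float,
        l2: float,
        clip_norm: float | None = 1.0,
    ):
        self.model = model
        self.lr, self.momentum, self.l2 = lr, momentum, l2
        self.clip_norm = clip_norm
        self._vel = [
            (np.zeros_like(c.W), np.zeros_like(c.b)) for c in model._all_convs()
        ]

    def step(self) -> None:
        convs = self.model._all_convs()
        if self.clip_norm is not None:
            gnorm = np.sqrt(
                sum(float((c.dW**2).sum() + (c.db**2).sum()) for c in convs)
            )
            if gnorm > self.clip_norm:
                scale = self.clip_norm / gnorm
                for c in convs:
                    c.dW *= scale
                    c.db *= scale
        for c, (vw, vb) in zip(convs, self._vel):
            np.multiply(vw, self.momentum, out=vw)
            vw -= self.lr * (c.dW + self.l2 * c.W)
            c.W += vw
            np.multiply(vb, self.momentum, out=vb)
            vb -= self.lr * c.db
            c.b += vb
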