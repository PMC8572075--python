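"""Minimal CPU convolutional-network engine (forward + manual backprop).

Just enough machinery for the 2D residual dilated segmentation network:
3x3 dilated convolutions, 1x1 convolutions, ReLU, residual addition, a
sigmoid head, a combined Dice + cross-entropy loss and an Adam optimizer.
Tensors are NHWC ``float32`` throughout; convolutions are evaluated as nine
shifted GEMMs, which keeps peak memory low and maps well onto BLAS.

Everything is deterministic given the seed used to initialize parameters
and the order in which batches are fed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv", "ReLU", "ResidualBlock", "SegNet", "Adam", "dice_bce_loss"]

_F32 = np.float32


class Conv:
    """k x k convolution with 'same' padding and optional dilation.

    Weights have shape ``(k, k, c_in, c_out)``; initialization is He-normal
    scaled by fan-in.
    """

    def __init__(self, c_in: int, c_out: int, k: int = 3, dilation: int = 1,
                 rng: np.random.Generator | None = None):
        if k not in (1, 3):
            raise ValueError("only 1x1 and 3x3 kernels are supported")
        if dilation < 1:
            raise ValueError("dilation factors must be >= 1")
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / (k * k * c_in))
        self.w = (rng.standard_normal((k, k, c_in, c_out)) * std).astype(_F32)
        self.b = np.zeros(c_out, dtype=_F32)
        self.k = k
        self.dilation = dilation
        self._cache = None

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if self.k == 1:
            if train:
                self._cache = x
            return x @ self.w[0, 0] + self.b
        d = self.dilation
        xp = np.pad(x, ((0, 0), (d, d), (d, d), (0, 0)))
        if train:
            self._cache = xp
        b_, h, w_, _ = x.shape
        out = np.broadcast_to(self.b, (b_, h, w_, self.w.shape[-1])).copy()
        for i in range(3):
            for j in range(3):
                patch = xp[:, i * d:i * d + h, j * d:j * d + w_, :]
                out += patch @ self.w[i, j]
        return out

    def backward(self, dy: np.ndarray):
        """Return (dx, [dw, db]) for the cached forward input."""
        if self._cache is None:
            raise RuntimeError("backward called before forward")
        db = dy.sum(axis=(0, 1, 2))
        if self.k == 1:
            x = self._cache
            dw = np.zeros_like(self.w)
            dw[0, 0] = x.reshape(-1, x.shape[-1]).T @ dy.reshape(-1, dy.shape[-1])
            dx = dy @ self.w[0, 0].T
            return dx, [dw, db]
        d = self.dilation
        xp = self._cache
        b_, h, w_, _ = dy.shape
        dy_flat = dy.reshape(-1, dy.shape[-1])
        dw = np.zeros_like(self.w)
        dxp = np.zeros_like(xp)
        for i in range(3):
            for j in range(3):
                patch = xp[:, i * d:i * d + h, j * d:j * d + w_, :]
                dw[i, j] = patch.reshape(-1, patch.shape[-1]).T @ dy_flat
                dxp[:, i * d:i * d + h, j * d:j * d + w_, :] += dy @ self.w[i, j].T
        dx = dxp[:, d:-d, d:-d, :]
        return dx, [dw, db]


class ReLU:
    def __init__(self):
        self._mask = None

    params: list = []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class ResidualBlock:
    """Two dilated 3x3 convolutions with a residual (identity) connection."""

    def __init__(self, channels: int, dilation: int, rng: np.random.Generator):
        self.conv1 = Conv(channels, channels, 3, dilation, rng)
        self.relu1 = ReLU()
        self.conv2 = Conv(channels, channels, 3, dilation, rng)
        self.relu2 = ReLU()

    @property
    def params(self):
        return self.conv1.params + self.conv2.params

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        h = self.relu1.forward(self.conv1.forward(x, train), train)
        h = self.conv2.forward(h, train)
        return self.relu2.forward(h + x, train)

    def backward(self, dy: np.ndarray):
        dy = self.relu2.backward(dy)
        dh, g2 = self.conv2.backward(dy)
        dh = self.relu1.backward(dh)
        dx, g1 = self.conv1.backward(dh)
        return dx + dy, g1 + g2


class AvgPool2x:
    """2x2 average pooling (requires even spatial dims)."""

    params: list = []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        b, h, w, c = x.shape
        return x.reshape(b, h // 2, 2, w // 2, 2, c).mean(axis=(2, 4))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.repeat(np.repeat(dy, 2, axis=1), 2, axis=2) * _F32(0.25)


class Upsample2x:
    """Nearest-neighbour 2x upsampling."""

    params: list = []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, h, w, c = dy.shape
        return dy.reshape(b, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class SegNet:
    """Residual dilated segmentation trunk with 1x1 lift and classifier.

    ``n_layers`` 3x3 convolutions form the trunk, grouped into residual
    blocks of ``span`` layers; a 1x1 lift maps the single input channel to
    the trunk width and a 1x1 head produces per-pixel lung logits.  With
    ``internal_stride=2`` the trunk runs at half resolution (average pool
    after the lift, nearest upsampling before the head), which quarters the
    arithmetic cost while dilations still supply long-range context.
    """

    def __init__(self, n_layers: int, span: int, channels: int,
                 dilations, seed: int = 0, internal_stride: int = 1):
        if n_layers % span != 0:
            raise ValueError("layer count must be a multiple of the residual span")
        n_blocks = n_layers // span
        dilations = list(dilations)
        if len(dilations) != n_blocks:
            raise ValueError(
                f"need one dilation per block: {n_blocks} blocks, "
                f"{len(dilations)} dilations"
            )
        if internal_stride not in (1, 2):
            raise ValueError("internal_stride must be 1 or 2")
        rng = np.random.default_rng(seed)
        self.lift = Conv(1, channels, 1, rng=rng)
        self.blocks = [ResidualBlock(channels, d, rng) for d in dilations]
        self.head = Conv(channels, 1, 1, rng=rng)
        self.pool = AvgPool2x() if internal_stride == 2 else None
        self.unpool = Upsample2x() if internal_stride == 2 else None
        self.n_layers = n_layers
        self.span = span
        self.channels = channels
        self.dilations = dilations
        self.seed = seed
        self.internal_stride = internal_stride

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def layers(self):
        return [self.lift, *self.blocks, self.head]

    @property
    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params)
        return out

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params))

    def forward_logits(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        h = self.lift.forward(x, train)
        if self.pool is not None:
            h = self.pool.forward(h, train)
        for block in self.blocks:
            h = block.forward(h, train)
        if self.unpool is not None:
            h = self.unpool.forward(h, train)
        return self.head.forward(h, train)

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Per-pixel lung probability for (N, H, W) or (H, W) input."""
        if images.ndim not in (2, 3):
            raise ValueError("expected (H, W) or (N, H, W) input")
        squeeze = images.ndim == 2
        x = images[None, ...] if squeeze else images
        logits = self.forward_logits(x[..., None].astype(_F32), train=False)[..., 0]
        probs = _sigmoid(logits)
        return probs[0] if squeeze else probs

    def backward(self, dlogits: np.ndarray):
        grads_rev = []
        dy, g = self.head.backward(dlogits)
        grads_rev.append(g)
        if self.unpool is not None:
            dy = self.unpool.backward(dy)
        for block in reversed(self.blocks):
            dy, g = block.backward(dy)
            grads_rev.append(g)
        if self.pool is not None:
            dy = self.pool.backward(dy)
        _, g = self.lift.backward(dy)
        grads_rev.append(g)
        grads = []
        for g in reversed(grads_rev):
            grads.extend(g)
        return grads

    def state(self) -> dict:
        arrays = {f"p{i}": p for i, p in enumerate(self.params)}
        arrays["meta"] = np.array(
            [self.n_layers, self.span, self.channels, self.seed,
             self.internal_stride],
            dtype=np.int64,
        )
        arrays["dilations"] = np.array(self.dilations, dtype=np.int64)
        return arrays

    def load_state(self, arrays: dict) -> None:
        for i, p in enumerate(self.params):
            src = np.asarray(arrays[f"p{i}"], dtype=_F32)
            if src.shape != p.shape:
                raise ValueError("checkpoint does not match this architecture")
            p[...] = src

    @classmethod
    def from_state(cls, arrays: dict) -> "SegNet":
        meta = [int(v) for v in arrays["meta"]]
        n_layers, span, channels, seed = meta[:4]
        stride = meta[4] if len(meta) > 4 else 1
        model = cls(n_layers, span, channels,
                    [int(d) for d in arrays["dilations"]], seed=seed,
                    internal_stride=stride)
        model.load_state(arrays)
        return model


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def dice_bce_loss(logits: np.ndarray, targets: np.ndarray,
                  eps: float = 1.0):
    """Soft-Dice + binary cross-entropy loss and its gradient w.r.t. logits.

    Returns ``(loss, dlogits)``; the Dice term is computed over the whole
    batch, which stabilizes batches containing little lung.
    """
    p = _sigmoid(logits)
    t = targets.astype(np.float64)
    n = p.size

    # numerically safe BCE via logits
    bce = np.mean(np.maximum(logits, 0) - logits * t + np.log1p(np.exp(-np.abs(logits))))
    dl_bce = (p - t) / n

    inter = float((p * t).sum())
    denom = float(p.sum() + t.sum()) + eps
    dice = (2.0 * inter + eps) / denom
    # d(1 - dice)/dp = -(2 t denom - (2 inter + eps)) / denom^2
    dl_dice_dp = -(2.0 * t * denom - (2.0 * inter + eps)) / denom**2
    dl_dice = dl_dice_dp * p * (1.0 - p)

    loss = float(bce + (1.0 - dice))
    return loss, (dl_bce + dl_dice).astype(_F32)


class Adam:
    """Adam optimizer updating parameters in place."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.m = [np.zeros_like(p, dtype=np.float64) for p in params]
        self.v = [np.zeros_like(p, dtype=np.float64) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            g = g.astype(np.float64)
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(p.dtype)
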