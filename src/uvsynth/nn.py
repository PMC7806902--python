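"""Minimal numpy CNN stack: conv layers, a U-net, and Adam.

All arrays are float32 in NCHW layout.  Every layer keeps its forward cache
on the instance, so a layer instance is used at exactly one site in a
network.  Gradients are written into ``layer.grads`` by ``backward`` and
consumed by :class:`Adam`.

Randomness is always drawn from an explicit ``numpy.random.Generator`` so
that training is bit-reproducible given a seed.
"""

from __future__ import annotations

import numpy as np

F32 = np.float32


def he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(F32)


class Layer:
    """Base class: parameters in ``params``, matching grads in ``grads``."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x, train=False, rng=None):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - abstract
        raise NotImplementedError


class Conv2d(Layer):
    """k x k convolution, 'same' padding, stride 1 or 2, via im2col."""

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if rng is None:
            rng = np.random.default_rng(0)
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        self.params["W"] = he_init(rng, (cout, cin, k, k), cin * k * k)
        self.params["b"] = np.zeros(cout, dtype=F32)
        self._cache = None

    def forward(self, x, train=False, rng=None):
        n, c, h, w = x.shape
        if c != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {c}")
        k, s = self.k, self.stride
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        W = self.params["W"]
        # convolution as a sum over kernel offsets of channel matmuls:
        # avoids the cache-hostile im2col gather
        acc = np.zeros((n, self.cout, ho * wo), dtype=F32)
        for i in range(k):
            for j in range(k):
                v = np.ascontiguousarray(
                    xp[:, :, i:i + s * ho:s, j:j + s * wo:s]).reshape(n, c, -1)
                acc += W[:, :, i, j] @ v
        acc += self.params["b"][:, None]
        self._cache = (xp, x.shape, ho, wo)
        return acc.reshape(n, self.cout, ho, wo)

    def backward(self, dy):
        xp, xshape, ho, wo = self._cache
        n, c, h, w = xshape
        k, s = self.k, self.stride
        p = k // 2
        W = self.params["W"]
        dyf = dy.reshape(n, self.cout, ho * wo)
        dW = np.empty_like(W)
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                v = np.ascontiguousarray(
                    xp[:, :, i:i + s * ho:s, j:j + s * wo:s]).reshape(n, c, -1)
                dW[:, :, i, j] = np.tensordot(dyf, v, axes=([0, 2], [0, 2]))
                dv = (W[:, :, i, j].T @ dyf).reshape(n, c, ho, wo)
                dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += dv
        self.grads["W"] = dW
        self.grads["b"] = dy.sum(axis=(0, 2, 3))
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class Dense(Layer):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        self.params["W"] = he_init(rng, (cin, cout), cin)
        self.params["b"] = np.zeros(cout, dtype=F32)
        self._x = None

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, 0).astype(F32)

    def backward(self, dy):
        return np.where(self._mask, dy, 0).astype(F32)


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.2):
        super().__init__()
        self.alpha = alpha

    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x).astype(F32)

    def backward(self, dy):
        return np.where(self._mask, dy, self.alpha * dy).astype(F32)


class Sigmoid(Layer):
    def forward(self, x, train=False, rng=None):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))
        return self._y.astype(F32)

    def backward(self, dy):
        return (dy * self._y * (1.0 - self._y)).astype(F32)


class Dropout(Layer):
    """Inverted dropout; identity when ``train`` is False or rate == 0."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._mask = None

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        self._mask = (rng.random(x.shape) >= self.rate).astype(F32) / (1 - self.rate)
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class UpsampleNearest2(Layer):
    def forward(self, x, train=False, rng=None):
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dy):
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class GlobalAvgPool(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._shape
        return (np.repeat(dy[:, :, None, None], h, 2).repeat(w, 3)
                / (h * w)).astype(F32)


# ---------------------------------------------------------------------------
# networks


class UNet:
    """Encoder/decoder with skip connections.

    ``depth`` down/up levels; channel width doubles per level starting at
    ``base_channels``.  Dropout is applied after the decoder convolutions of
    the levels listed in ``dropout_levels`` (level depth-1 = innermost).
    ``head`` is 'sigmoid' (bounded image output) or 'linear' (logits, e.g.
    for a softmax segmentation head applied by the caller).
    """

    def __init__(self, in_channels: int, out_channels: int, depth: int = 3,
                 base_channels: int = 8, dropout_rate: float = 0.5,
                 dropout_levels: tuple[int, ...] | None = None,
                 head: str = "sigmoid", seed: int = 0):
        if head not in ("sigmoid", "linear"):
            raise ValueError("head must be 'sigmoid' or 'linear'")
        rng = np.random.default_rng(seed)
        c = base_channels
        self.depth = depth
        self.in_channels, self.out_channels = in_channels, out_channels
        self.head = head
        if dropout_levels is None:
            dropout_levels = tuple(i for i in (depth - 1, depth - 2) if i >= 0)
        self.enc, self.enc_act = [], []
        self.down, self.down_act = [], []
        for i in range(depth):
            ci = in_channels if i == 0 else c * 2 ** i
            self.enc.append(Conv2d(ci, c * 2 ** i, rng=rng))
            self.enc_act.append(LeakyReLU(0.1))
            self.down.append(Conv2d(c * 2 ** i, c * 2 ** (i + 1), stride=2, rng=rng))
            self.down_act.append(LeakyReLU(0.1))
        self.bott = Conv2d(c * 2 ** depth, c * 2 ** depth, rng=rng)
        self.bott_act = LeakyReLU(0.1)
        self.up, self.up_conv, self.up_act = [], [], []
        self.dec, self.dec_act, self.dec_drop = [], [], []
        for i in reversed(range(depth)):
            self.up.append(UpsampleNearest2())
            self.up_conv.append(Conv2d(c * 2 ** (i + 1), c * 2 ** i, rng=rng))
            self.up_act.append(LeakyReLU(0.1))
            self.dec.append(Conv2d(2 * c * 2 ** i, c * 2 ** i, rng=rng))
            self.dec_act.append(LeakyReLU(0.1))
            rate = dropout_rate if i in dropout_levels else 0.0
            self.dec_drop.append(Dropout(rate))
        self.final = Conv2d(c, out_channels, k=1, rng=rng)
        self.final_act = Sigmoid() if head == "sigmoid" else None
        self._skip_ch = [c * 2 ** i for i in range(depth)]

    # -- parameter plumbing -------------------------------------------------
    def layers(self):
        out = []
        out.extend(self.enc)
        out.extend(self.down)
        out.append(self.bott)
        out.extend(self.up_conv)
        out.extend(self.dec)
        out.append(self.final)
        return out

    def get_state(self):
        return [{k: v.copy() for k, v in l.params.items()} for l in self.layers()]

    def set_state(self, state):
        for l, p in zip(self.layers(), state):
            for k in l.params:
                l.params[k][...] = p[k]

    # -- forward / backward -------------------------------------------------
    def forward(self, x, train: bool = False, rng=None):
        if x.shape[2] % 2 ** self.depth or x.shape[3] % 2 ** self.depth:
            raise ValueError(
                f"spatial size {x.shape[2:]} not divisible by 2^{self.depth}")
        h = x.astype(F32, copy=False)
        skips = []
        self._trace = [h.shape]
        for i in range(self.depth):
            h = self.enc_act[i].forward(self.enc[i].forward(h))
            skips.append(h)
            h = self.down_act[i].forward(self.down[i].forward(h))
            self._trace.append(h.shape)
        h = self.bott_act.forward(self.bott.forward(h))
        for j, i in enumerate(reversed(range(self.depth))):
            h = self.up[j].forward(h)
            h = self.up_act[j].forward(self.up_conv[j].forward(h))
            h = np.concatenate([skips[i], h], axis=1)
            h = self.dec_act[j].forward(self.dec[j].forward(h))
            h = self.dec_drop[j].forward(h, train=train, rng=rng)
        h = self.final.forward(h)
        if self.final_act is not None:
            h = self.final_act.forward(h)
        return h

    def backward(self, dy):
        if self.final_act is not None:
            dy = self.final_act.backward(dy)
        dh = self.final.backward(dy)
        dskips = [None] * self.depth
        for j in reversed(range(self.depth)):
            i = self.depth - 1 - j
            dh = self.dec_drop[j].backward(dh)
            dh = self.dec[j].backward(self.dec_act[j].backward(dh))
            cs = self._skip_ch[i]
            dskips[i] = dh[:, :cs]
            dh = dh[:, cs:]
            dh = self.up_conv[j].backward(self.up_act[j].backward(dh))
            dh = self.up[j].backward(dh)
        dh = self.bott.backward(self.bott_act.backward(dh))
        for i in reversed(range(self.depth)):
            dh = self.down[i].backward(self.down_act[i].backward(dh))
            dh = dh + dskips[i]
            dh = self.enc[i].backward(self.enc_act[i].backward(dh))
        return dh


class PairDiscriminator:
    """Scalar-probability discriminator on (conditioning, candidate) pairs.

    The two images are stacked along channels; stride-2 convolutions reduce
    them to a global-average-pooled vector and a single squashed logit per
    sample.  The returned probability is clamped to (eps, 1-eps); gradients
    are taken through the unclamped sigmoid.
    """

    EPS = 1e-6

    def __init__(self, in_channels: int, depth: int = 3, base_channels: int = 8,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        c = base_channels
        self.in_channels = in_channels
        self.convs, self.acts = [], []
        ci = in_channels
        for i in range(depth):
            self.convs.append(Conv2d(ci, c * 2 ** i, stride=2, rng=rng))
            self.acts.append(LeakyReLU(0.2))
            ci = c * 2 ** i
        self.pool = GlobalAvgPool()
        self.dense = Dense(ci, 1, rng=rng)
        self._p_raw = None

    def layers(self):
        return [*self.convs, self.dense]

    def get_state(self):
        return [{k: v.copy() for k, v in l.params.items()} for l in self.layers()]

    def set_state(self, state):
        for l, p in zip(self.layers(), state):
            for k in l.params:
                l.params[k][...] = p[k]

    def forward(self, cond, cand):
        if cond.shape[0] != cand.shape[0] or cond.shape[2:] != cand.shape[2:]:
            raise ValueError("conditioning/candidate shape mismatch")
        h = np.concatenate([cond, cand], axis=1).astype(F32, copy=False)
        if h.shape[1] != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} stacked channels, got {h.shape[1]}")
        self._cand_ch = cand.shape[1]
        for conv, act in zip(self.convs, self.acts):
            h = act.forward(conv.forward(h))
        z = self.dense.forward(self.pool.forward(h))[:, 0]
        self._p_raw = 1.0 / (1.0 + np.exp(-np.clip(z, -30, 30)))
        return np.clip(self._p_raw, self.EPS, 1.0 - self.EPS)

    def backward(self, dp):
        """Backprop d(loss)/d(probability); returns (d_cond, d_cand)."""
        dz = (dp * self._p_raw * (1.0 - self._p_raw)).astype(F32)
        dh = self.pool.backward(self.dense.backward(dz[:, None]))
        for conv, act in zip(reversed(self.convs), reversed(self.acts)):
            dh = conv.backward(act.backward(dh))
        cc = self._cand_ch
        return dh[:, :-cc], dh[:, -cc:]


class Adam:
    """Adam over the parameters of a list of layers."""

    def __init__(self, layers, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.layers = list(layers)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()}
                  for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()}
                  for l in self.layers]

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for l, m, v in zip(self.layers, self.m, self.v):
            for k, p in l.params.items():
                g = l.grads.get(k)
                if g is None:
                    continue
                m[k] = self.b1 * m[k] + (1 - self.b1) * g
                v[k] = self.b2 * v[k] + (1 - self.b2) * g * g
                p -= self.lr * (m[k] / b1t) / (np.sqrt(v[k] / b2t) + self.eps)
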