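"""Minimal numpy neural-network engine for the shallow decoder.

Implements exactly the pieces the decoder architecture needs — stride-1
'same' convolution, per-channel batch normalization, ELU, non-overlapping
max pooling, a dense softmax head, Adam, and reverse-mode gradients all
the way back to the input (used both for training and for the
sensitivity maps).  Everything is float64 and deterministic given a
seed.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigError


def _im2col(xp: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(N, C, Hp, Wp) -> (N*Ho*Wo, C*kh*kw) patch matrix (valid windows)."""
    windows = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw),
                                                       axis=(2, 3))
    N, C, Ho, Wo = windows.shape[:4]
    return (windows.transpose(0, 2, 3, 1, 4, 5)
            .reshape(N * Ho * Wo, C * kh * kw)), (N, Ho, Wo)


class Conv2D:
    """Stride-1 'same' convolution (im2col); weights He-initialized."""

    def __init__(self, in_ch: int, out_ch: int, kh: int, kw: int,
                 rng: np.random.Generator):
        scale = np.sqrt(2.0 / (in_ch * kh * kw))
        self.w = rng.normal(0.0, scale, size=(out_ch, in_ch, kh, kw))
        self.b = np.zeros(out_ch)
        self.kh, self.kw = kh, kw
        # asymmetric 'same' padding for even kernels
        self.pt, self.pl = (kh - 1) // 2, (kw - 1) // 2
        self.pb, self.pr = kh - 1 - self.pt, kw - 1 - self.pl
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        xp = np.pad(x, ((0, 0), (0, 0), (self.pt, self.pb),
                        (self.pl, self.pr)))
        cols, (N, H, W) = _im2col(xp, self.kh, self.kw)
        self._cols = cols
        out_ch = self.w.shape[0]
        y = cols @ self.w.reshape(out_ch, -1).T + self.b
        return y.reshape(N, H, W, out_ch).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray,
                 need_dx: bool = True) -> np.ndarray | None:
        N, out_ch, H, W = dy.shape
        dymat = dy.transpose(0, 2, 3, 1).reshape(-1, out_ch)
        self.dw[:] = (dymat.T @ self._cols).reshape(self.w.shape)
        self.db[:] = dymat.sum(axis=0)
        if not need_dx:
            return None
        # d(input): full correlation of dy with the flipped kernel
        kh, kw = self.kh, self.kw
        dyp = np.pad(dy, ((0, 0), (0, 0), (kh - 1, kh - 1),
                          (kw - 1, kw - 1)))
        wflip = self.w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        cols, (_, Hp, Wp) = _im2col(dyp, kh, kw)
        in_ch = wflip.shape[0]
        dxp = (cols @ wflip.reshape(in_ch, -1).T)
        dxp = dxp.reshape(N, Hp, Wp, in_ch).transpose(0, 3, 1, 2)
        return dxp[:, :, self.pt: self.pt + H, self.pl: self.pl + W]

    def parameters(self):
        return [self.w, self.b]

    def gradients(self):
        return [self.dw, self.db]


class BatchNorm2D:
    """Per-channel batch normalization with running statistics."""

    def __init__(self, ch: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(ch)
        self.beta = np.zeros(ch)
        self.run_mean = np.zeros(ch)
        self.run_var = np.ones(ch)
        self.momentum, self.eps = momentum, eps
        self.dgamma = np.zeros(ch)
        self.dbeta = np.zeros(ch)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.run_mean = (self.momentum * self.run_mean
                             + (1 - self.momentum) * mu)
            self.run_var = (self.momentum * self.run_var
                            + (1 - self.momentum) * var)
        else:
            mu, var = self.run_mean, self.run_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std, train,
                       x.shape[0] * x.shape[2] * x.shape[3])
        return (self.gamma[None, :, None, None] * xhat
                + self.beta[None, :, None, None])

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std, train, count = self._cache
        self.dgamma[:] = (dy * xhat).sum(axis=(0, 2, 3))
        self.dbeta[:] = dy.sum(axis=(0, 2, 3))
        g = (self.gamma * inv_std)[None, :, None, None]
        if not train:
            return dy * g
        dxhat = dy * self.gamma[None, :, None, None]
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (inv_std[None, :, None, None] / count
                * (count * dxhat - s1 - xhat * s2))

    def parameters(self):
        return [self.gamma, self.beta]

    def gradients(self):
        return [self.dgamma, self.dbeta]


class ELU:
    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        neg = x < 0
        y = np.where(neg, self.alpha * np.expm1(x), x)
        self._cache = (neg, y)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        neg, y = self._cache
        return dy * np.where(neg, y + self.alpha, 1.0)

    def parameters(self):
        return []

    def gradients(self):
        return []


class MaxPool2D:
    """Non-overlapping max pooling; trailing remainder rows are dropped."""

    def __init__(self, ph: int, pw: int):
        self.ph, self.pw = ph, pw
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        N, C, H, W = x.shape
        Hp, Wp = H // self.ph, W // self.pw
        if Hp == 0 or Wp == 0:
            raise ConfigError(
                f"pool {self.ph}x{self.pw} larger than feature map {H}x{W}")
        xc = x[:, :, : Hp * self.ph, : Wp * self.pw]
        xr = xc.reshape(N, C, Hp, self.ph, Wp, self.pw)
        xr = xr.transpose(0, 1, 2, 4, 3, 5).reshape(N, C, Hp, Wp,
                                                    self.ph * self.pw)
        arg = xr.argmax(axis=-1)
        y = np.take_along_axis(xr, arg[..., None], axis=-1)[..., 0]
        self._cache = (x.shape, arg)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        (N, C, H, W), arg = self._cache
        Hp, Wp = H // self.ph, W // self.pw
        flat = np.zeros((N, C, Hp, Wp, self.ph * self.pw))
        np.put_along_axis(flat, arg[..., None], dy[..., None], axis=-1)
        flat = flat.reshape(N, C, Hp, Wp, self.ph, self.pw)
        flat = flat.transpose(0, 1, 2, 4, 3, 5).reshape(
            N, C, Hp * self.ph, Wp * self.pw)
        dx = np.zeros((N, C, H, W))
        dx[:, :, : Hp * self.ph, : Wp * self.pw] = flat
        return dx

    def parameters(self):
        return []

    def gradients(self):
        return []


class Flatten:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)

    def parameters(self):
        return []

    def gradients(self):
        return []


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._x = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dw[:] = self._x.T @ dy
        self.db[:] = dy.sum(axis=0)
        return dy @ self.w.T

    def parameters(self):
        return [self.w, self.b]

    def gradients(self):
        return [self.dw, self.db]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray,
                  onehot: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient wrt the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-(onehot * np.log(np.clip(p, 1e-12, None))).sum() / n)
    return loss, (p - onehot) / n


class ShallowCNN:
    """Two conv blocks (conv -> batch-norm -> ELU -> max-pool), then a
    dense softmax classification layer.

    ``input_shape`` is (rows, cols) of a single-channel feature map;
    identical specs and seeds construct identical parameters.
    """

    def __init__(
        self,
        input_shape: tuple[int, int],
        n_classes: int,
        conv_kernel: tuple[int, int] = (5, 5),
        filters: tuple[int, int] = (16, 32),
        pool: tuple[int, int] = (2, 2),
        seed: int = 0,
    ):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed),
                                                            0xC44]))
        kh, kw = conv_kernel
        ph, pw = pool
        H, W = input_shape
        self.input_shape = tuple(input_shape)
        self.n_classes = int(n_classes)
        self.layers: list = []
        ch = 1
        for f in filters:
            self.layers += [Conv2D(ch, f, kh, kw, rng), BatchNorm2D(f),
                            ELU(), MaxPool2D(ph, pw)]
            Hn, Wn = H // ph, W // pw
            if Hn == 0 or Wn == 0:
                raise ConfigError(
                    f"pool {ph}x{pw} larger than feature map {H}x{W}")
            H, W, ch = Hn, Wn, f
        self.layers.append(Flatten())
        self.layers.append(Dense(ch * H * W, n_classes, rng))

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Logits for a batch of (N, rows, cols) feature maps."""
        if x.ndim == 3:
            x = x[:, None, :, :]
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dlogits: np.ndarray,
                 need_input_grad: bool = False) -> np.ndarray | None:
        """Backpropagate to every parameter; optionally return d(input).

        The first layer's input gradient is only materialized when
        ``need_input_grad`` is set (training does not use it; the
        sensitivity maps do).
        """
        g = dlogits
        for layer in reversed(self.layers[1:]):
            g = layer.backward(g)
        first = self.layers[0]
        if isinstance(first, Conv2D):
            g = first.backward(g, need_dx=need_input_grad)
        else:  # pragma: no cover - first layer is always a conv block
            g = first.backward(g)
        if g is None:
            return None
        return g[:, 0, :, :]

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, train=False))

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    def gradients(self):
        return [g for layer in self.layers for g in layer.gradients()]

    def get_weights(self) -> list[np.ndarray]:
        weights = [p.copy() for p in self.parameters()]
        for layer in self.layers:
            if isinstance(layer, BatchNorm2D):
                weights += [layer.run_mean.copy(), layer.run_var.copy()]
        return weights

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.parameters()
        for p, w in zip(params, weights[: len(params)]):
            p[...] = w
        extra = iter(weights[len(params):])
        for layer in self.layers:
            if isinstance(layer, BatchNorm2D):
                layer.run_mean[...] = next(extra)
                layer.run_var[...] = next(extra)

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))


class Adam:
    """Adam optimizer over a fixed parameter list."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class EarlyStopper:
    """Stop when validation loss fails to improve for ``patience`` epochs."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.best_epoch = -1
        self.stale = 0

    def update(self, loss: float, epoch: int) -> bool:
        """Record an epoch's validation loss; True means stop now."""
        if loss < self.best - 1e-12:
            self.best = loss
            self.best_epoch = epoch
            self.stale = 0
            return False
        self.stale += 1
        return self.stale >= self.patience
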