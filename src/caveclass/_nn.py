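"""Minimal numpy neural-network core (float32, CPU, deterministic).

Just enough machinery for the two small classifiers in
:mod:`caveclass.deepnets`: dense and 2D convolution layers (im2col), ReLU,
non-overlapping max pooling, a symmetric max over point sets, softmax
cross-entropy with L2 weight decay, and Adam. Everything is seeded through
``numpy.random.Generator`` so training runs are bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


@dataclass
class Param:
    value: np.ndarray
    grad: np.ndarray = field(init=False)
    decay: bool = True  # L2 weight decay applies (kernels yes, biases no)

    def __post_init__(self) -> None:
        self.grad = np.zeros_like(self.value)


class Layer:
    params: list[Param]

    def __init__(self) -> None:
        self.params = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Dense(Layer):
    """Affine map. Accepts (..., n_in); the leading axes are preserved, so the
    same layer acts as a shared per-point transform on (N, P, n_in) input."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.w = Param(he_init(rng, (n_in, n_out), n_in))
        self.b = Param(np.zeros(n_out, dtype=np.float32), decay=False)
        self.params = [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x2 = self._x.reshape(-1, self._x.shape[-1])
        g2 = grad.reshape(-1, grad.shape[-1])
        self.w.grad += x2.T @ g2
        self.b.grad += g2.sum(axis=0)
        return grad @ self.w.value.T


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Conv2D(Layer):
    """3x3 (configurable) convolution, stride 1, zero 'same' padding, im2col."""

    def __init__(self, in_c: int, out_c: int, rng: np.random.Generator, kernel: int = 3):
        super().__init__()
        self.in_c, self.out_c, self.k = in_c, out_c, kernel
        fan_in = in_c * kernel * kernel
        self.w = Param(he_init(rng, (fan_in, out_c), fan_in))
        self.b = Param(np.zeros(out_c, dtype=np.float32), decay=False)
        self.params = [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k = self.k
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        # (N, C, H, W, k, k) windows -> (N, H, W, C*k*k) columns
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h, w, c * k * k)
        self._cols = cols
        self._in_shape = x.shape
        out = cols @ self.w.value + self.b.value  # (N, H, W, out_c)
        return out.transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        k = self.k
        p = k // 2
        g = grad.transpose(0, 2, 3, 1)  # (N, H, W, out_c)
        g2 = g.reshape(-1, self.out_c)
        self.w.grad += self._cols.reshape(-1, c * k * k).T @ g2
        self.b.grad += g2.sum(axis=0)
        gcols = (g @ self.w.value.T).reshape(n, h, w, c, k, k)
        gx = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                gx[:, :, i:i + h, j:j + w] += gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return gx[:, :, p:p + h, p:p + w]


class MaxPool2D(Layer):
    """Non-overlapping max pooling (window == stride); trailing rows/columns
    that do not fill a window are cropped (floor output size)."""

    def __init__(self, window: int = 3):
        super().__init__()
        self.window = window

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        s = self.window
        ho, wo = h // s, w // s
        if ho < 1 or wo < 1:
            raise ValueError(f"input {h}x{w} too small for {s}x{s} pooling")
        xc = x[:, :, : ho * s, : wo * s]
        blocks = xc.reshape(n, c, ho, s, wo, s).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, ho, wo, s * s
        )
        self._argmax = blocks.argmax(axis=-1)
        self._in_shape = x.shape
        return blocks.max(axis=-1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        s = self.window
        ho, wo = h // s, w // s
        flat = np.zeros((n, c, ho, wo, s * s), dtype=np.float32)
        np.put_along_axis(flat, self._argmax[..., None], grad[..., None], axis=-1)
        gx = np.zeros((n, c, h, w), dtype=np.float32)
        gx[:, :, : ho * s, : wo * s] = (
            flat.reshape(n, c, ho, wo, s, s).transpose(0, 1, 2, 4, 3, 5).reshape(
                n, c, ho * s, wo * s
            )
        )
        return gx


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._in_shape)


class MaxOverPoints(Layer):
    """Symmetric aggregation: (N, P, C) -> (N, C) elementwise max over the
    point axis. Exactly permutation invariant, and invariant to duplicating
    points (padding by repetition never changes the max)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._argmax = x.argmax(axis=1)
        self._in_shape = x.shape
        return x.max(axis=1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        gx = np.zeros(self._in_shape, dtype=np.float32)
        np.put_along_axis(gx, self._argmax[:, None, :], grad[:, None, :], axis=1)
        return gx


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    @property
    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, v in zip(self.params, state):
            p.value[...] = v

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params))


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_grad(
    logits: np.ndarray, y: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy of integer labels and its gradient w.r.t. logits."""
    n = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = float(-np.log(np.maximum(p[np.arange(n), y], 1e-12)).mean())
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, (grad / n).astype(np.float32)


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3, l2: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.l2 = lr, l2
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad + (self.l2 * p.value if p.decay else 0.0)
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            mhat = self.m[i] / (1 - self.beta1**self.t)
            vhat = self.v[i] / (1 - self.beta2**self.t)
            p.value -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.value.dtype)


def l2_penalty(params: list[Param], l2: float) -> float:
    if l2 == 0.0:
        return 0.0
    return float(0.5 * l2 * sum(float((p.value.astype(np.float64) ** 2).sum())
                                for p in params if p.decay))


def train_loop(
    net: Sequential,
    X: np.ndarray,
    y: np.ndarray,
    *,
    epochs: int,
    batch_size: int,
    lr: float,
    l2: float,
    rng: np.random.Generator,
    X_val: Optional[np.ndarray] = None,
    y_val: Optional[np.ndarray] = None,
) -> dict:
    """Mini-batch Adam on softmax cross-entropy + L2. Returns a per-epoch
    history and restores the best-on-validation parameters (when a validation
    set is given). Aborts on non-finite loss."""
    opt = Adam(net.params, lr=lr, l2=l2)
    history: dict[str, list[float]] = {"loss": [], "train_acc": [], "val_acc": []}
    best_state, best_val = None, -1.0
    n = X.shape[0]
    for epoch in range(epochs):
        order = rng.permutation(n)
        epoch_loss, seen = 0.0, 0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            net.zero_grad()
            logits = net.forward(X[idx])
            loss, grad = cross_entropy_grad(logits, y[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={loss}; "
                    f"lower the learning rate or the L2 coefficient"
                )
            net.backward(grad)
            opt.step()
            epoch_loss += loss * len(idx)
            seen += len(idx)
        history["loss"].append(epoch_loss / seen + l2_penalty(net.params, l2))
        history["train_acc"].append(float((predict_classes(net, X) == y).mean()))
        if X_val is not None:
            val_acc = float((predict_classes(net, X_val) == y_val).mean())
            history["val_acc"].append(val_acc)
            if val_acc >= best_val:
                best_val, best_state = val_acc, net.state()
    if best_state is not None:
        net.load_state(best_state)
    return history


def predict_classes(net: Sequential, X: np.ndarray, batch_size: int = 64) -> np.ndarray:
    out = []
    for start in range(0, X.shape[0], batch_size):
        out.append(net.forward(X[start:start + batch_size]).argmax(axis=-1))
    return np.concatenate(out) if out else np.empty(0, dtype=int)
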