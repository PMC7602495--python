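"""Minimal numpy neural-network engine used by the classifier module.

Implements exactly the pieces the detection models need -- dense layers,
"same"-padded convolutions, max-pooling, ReLU/sigmoid, inverted dropout,
the RMSProp optimizer, binary cross-entropy training with mini-batches and
validation-based early stopping, and unsupervised autoencoder pre-training
of convolution kernels.  Everything is deterministic given the seed passed
to :class:`Network.fit`; no threading or GPU is involved, so repeated runs
are bitwise reproducible.

Shapes follow a channels-last convention: dense layers take (batch, d),
convolutions take (batch, height, width, channels).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense",
    "Conv2D",
    "MaxPool2D",
    "Flatten",
    "Dropout",
    "Network",
    "pretrain_conv_autoencoder",
]

_RMS_DECAY = 0.9
_RMS_EPS = 1e-8


class Layer:
    params: list

    def __init__(self) -> None:
        self.params = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def init(self, rng: np.random.Generator) -> None:
        pass


class Param:
    """A weight tensor with its gradient and RMSProp accumulator."""

    def __init__(self, value: np.ndarray) -> None:
        self.value = value
        self.grad = np.zeros_like(value)
        self.cache = np.zeros_like(value)

    def step(self, lr: float) -> None:
        self.cache = _RMS_DECAY * self.cache + (1 - _RMS_DECAY) * self.grad**2
        self.value -= lr * self.grad / (np.sqrt(self.cache) + _RMS_EPS)


def _glorot(rng: np.random.Generator, shape: tuple, fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, activation: str = "relu") -> None:
        super().__init__()
        self.d_in, self.d_out = d_in, d_out
        self.activation = activation
        self.W = Param(np.zeros((d_in, d_out)))
        self.b = Param(np.zeros(d_out))
        self.params = [self.W, self.b]

    def init(self, rng: np.random.Generator) -> None:
        self.W.value = _glorot(rng, (self.d_in, self.d_out), self.d_in, self.d_out)
        self.b.value = np.zeros(self.d_out)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        z = x @ self.W.value + self.b.value
        self._out = _activate(z, self.activation)
        return self._out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = grad * _activate_grad(self._out, self.activation)
        self.W.grad = self._x.T @ grad
        self.b.grad = grad.sum(axis=0)
        return grad @ self.W.value.T


def _activate(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return np.maximum(z, 0.0)
    if kind == "sigmoid":
        return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
    if kind == "linear":
        return z
    raise ValueError(f"unknown activation {kind!r}")


def _activate_grad(out: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return (out > 0).astype(out.dtype)
    if kind == "sigmoid":
        return out * (1.0 - out)
    return np.ones_like(out)


class Conv2D(Layer):
    """'Same'-padded 2-D convolution, channels-last, stride 1.

    Implemented as a sum of shifted matrix products, which keeps the
    backward pass simple and fast enough for the small architectures used
    here.  A 1-D convolution along the last spatial axis is the kh=1 case.
    """

    def __init__(self, kh: int, kw: int, c_in: int, c_out: int, activation="relu"):
        super().__init__()
        self.kh, self.kw, self.c_in, self.c_out = kh, kw, c_in, c_out
        self.activation = activation
        self.W = Param(np.zeros((kh, kw, c_in, c_out)))
        self.b = Param(np.zeros(c_out))
        self.params = [self.W, self.b]

    def init(self, rng: np.random.Generator) -> None:
        fan_in = self.kh * self.kw * self.c_in
        self.W.value = _glorot(
            rng, (self.kh, self.kw, self.c_in, self.c_out), fan_in, self.c_out
        )
        self.b.value = np.zeros(self.c_out)

    def _pad(self, x: np.ndarray) -> np.ndarray:
        ph_lo = (self.kh - 1) // 2
        pw_lo = (self.kw - 1) // 2
        return np.pad(
            x,
            (
                (0, 0),
                (ph_lo, self.kh - 1 - ph_lo),
                (pw_lo, self.kw - 1 - pw_lo),
                (0, 0),
            ),
        )

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b, h, w, _ = x.shape
        self._x = x
        xp = self._pad(x)
        z = np.zeros((b, h, w, self.c_out))
        for i in range(self.kh):
            for j in range(self.kw):
                z += xp[:, i : i + h, j : j + w, :] @ self.W.value[i, j]
        z += self.b.value
        self._out = _activate(z, self.activation)
        return self._out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = grad * _activate_grad(self._out, self.activation)
        b, h, w, _ = self._x.shape
        xp = self._pad(self._x)
        gxp = np.zeros_like(xp)
        for i in range(self.kh):
            for j in range(self.kw):
                patch = xp[:, i : i + h, j : j + w, :]
                self.W.grad[i, j] = np.tensordot(patch, grad, axes=([0, 1, 2], [0, 1, 2]))
                gxp[:, i : i + h, j : j + w, :] += grad @ self.W.value[i, j].T
        self.b.grad = grad.sum(axis=(0, 1, 2))
        ph_lo = (self.kh - 1) // 2
        pw_lo = (self.kw - 1) // 2
        return gxp[:, ph_lo : ph_lo + h, pw_lo : pw_lo + w, :]


class MaxPool2D(Layer):
    """Non-overlapping max pooling; trailing remainder is dropped."""

    def __init__(self, ph: int, pw: int) -> None:
        super().__init__()
        self.ph, self.pw = ph, pw

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b, h, w, c = x.shape
        oh, ow = h // self.ph, w // self.pw
        xv = x[:, : oh * self.ph, : ow * self.pw, :].reshape(
            b, oh, self.ph, ow, self.pw, c
        )
        self._x_shape = x.shape
        self._xv = xv
        out = xv.max(axis=(2, 4))
        self._mask = xv == out[:, :, None, :, None, :]
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b, h, w, c = self._x_shape
        oh, ow = h // self.ph, w // self.pw
        g = self._mask * grad[:, :, None, :, None, :]
        out = np.zeros(self._x_shape)
        out[:, : oh * self.ph, : ow * self.pw, :] = g.reshape(
            b, oh * self.ph, ow * self.pw, c
        )
        return out


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout; active only during training."""

    def __init__(self, rate: float = 0.2) -> None:
        super().__init__()
        self.rate = rate
        self.rng: np.random.Generator | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        return grad * self._mask


class Network:
    """A sequential network trained with BCE loss and RMSProp."""

    def __init__(self, layers: list) -> None:
        self.layers = layers

    def init(self, rng: np.random.Generator) -> None:
        for layer in self.layers:
            layer.init(rng)
            if isinstance(layer, Dropout):
                layer.rng = rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def predict(self, x: np.ndarray, batch: int = 512) -> np.ndarray:
        outs = [
            self.forward(x[i : i + batch], train=False)
            for i in range(0, len(x), batch)
        ]
        return np.concatenate(outs, axis=0).ravel()

    def forward_until(self, x: np.ndarray, stop_layer: int) -> np.ndarray:
        """Activations after layer index ``stop_layer`` (inclusive), eval mode."""
        for layer in self.layers[: stop_layer + 1]:
            x = layer.forward(x, train=False)
        return x

    def _params(self) -> list:
        return [p for layer in self.layers for p in layer.params]

    def get_weights(self) -> list:
        return [p.value.copy() for p in self._params()]

    def set_weights(self, weights: list) -> None:
        for p, w in zip(self._params(), weights):
            p.value = w.copy()

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        seed: int,
        x_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
        epochs: int = 50,
        batch_size: int = 50,
        lr: float = 1e-3,
        patience: int = 5,
        init: bool = True,
    ) -> dict:
        """Train with binary cross-entropy; early-stop on validation loss.

        The weights of the best validation epoch are restored at the end.
        Returns a history dict with per-epoch train/val losses and the
        selected epoch.
        """
        rng = np.random.default_rng(seed)
        if init:
            self.init(rng)
        else:
            for layer in self.layers:
                if isinstance(layer, Dropout):
                    layer.rng = rng
        y = np.asarray(y, dtype=float).ravel()
        have_val = x_val is not None and len(x_val) > 0
        best_loss, best_weights, best_epoch, bad = np.inf, None, 0, 0
        history = {"train_loss": [], "val_loss": []}
        for epoch in range(epochs):
            order = rng.permutation(len(x))
            losses = []
            for start in range(0, len(x), batch_size):
                idx = order[start : start + batch_size]
                xb, yb = x[idx], y[idx]
                out = self.forward(xb, train=True).ravel()
                out_c = np.clip(out, 1e-12, 1 - 1e-12)
                losses.append(
                    -np.mean(yb * np.log(out_c) + (1 - yb) * np.log(1 - out_c))
                )
                # d(BCE)/d(pre-sigmoid) = (p - y)/n; expressed through the
                # sigmoid layer's own grad: d(BCE)/d(out)
                grad = ((out_c - yb) / (out_c * (1 - out_c) * len(yb)))[:, None]
                g = grad
                for layer in reversed(self.layers):
                    g = layer.backward(g)
                for p in self._params():
                    p.step(lr)
            history["train_loss"].append(float(np.mean(losses)))
            if have_val:
                val_out = np.clip(self.predict(x_val), 1e-12, 1 - 1e-12)
                yv = np.asarray(y_val, dtype=float).ravel()
                vloss = float(
                    -np.mean(yv * np.log(val_out) + (1 - yv) * np.log(1 - val_out))
                )
            else:
                vloss = history["train_loss"][-1]
            history["val_loss"].append(vloss)
            if vloss < best_loss - 1e-6:
                best_loss, best_weights, best_epoch, bad = (
                    vloss,
                    self.get_weights(),
                    epoch,
                    0,
                )
            else:
                bad += 1
                if bad >= patience:
                    break
        if best_weights is not None:
            self.set_weights(best_weights)
        history["best_epoch"] = best_epoch
        return history

    def fit_mse(
        self,
        x: np.ndarray,
        y: np.ndarray,
        seed: int,
        epochs: int = 10,
        batch_size: int = 50,
        lr: float = 1e-3,
        init: bool = True,
    ) -> None:
        """Mean-squared-error training loop (used for autoencoder pre-training)."""
        rng = np.random.default_rng(seed)
        if init:
            self.init(rng)
        for _ in range(epochs):
            order = rng.permutation(len(x))
            for start in range(0, len(x), batch_size):
                idx = order[start : start + batch_size]
                out = self.forward(x[idx], train=True)
                g = 2.0 * (out - y[idx]) / out.size
                for layer in reversed(self.layers):
                    g = layer.backward(g)
                for p in self._params():
                    p.step(lr)


def pretrain_conv_autoencoder(
    conv: Conv2D, inputs: np.ndarray, seed: int, n_patches: int = 2000, epochs: int = 10
) -> None:
    """Initialize convolution kernels from a 3-layer autoencoder.

    Kernel-shaped patches are sampled from the training inputs and a dense
    input->encoding->decoding autoencoder (ReLU encoder, linear decoder) is
    trained on them with MSE and RMSProp; the encoder weights become the
    convolution kernels.
    """
    rng = np.random.default_rng(seed)
    b, h, w, c = inputs.shape
    kh, kw = conv.kh, conv.kw
    d = kh * kw * c
    patches = np.empty((n_patches, d))
    bi = rng.integers(0, b, n_patches)
    hi = rng.integers(0, max(h - kh + 1, 1), n_patches)
    wi = rng.integers(0, max(w - kw + 1, 1), n_patches)
    for p in range(n_patches):
        patches[p] = inputs[
            bi[p], hi[p] : hi[p] + kh, wi[p] : wi[p] + kw, :
        ].ravel()
    ae = Network(
        [Dense(d, conv.c_out, activation="relu"), Dense(conv.c_out, d, "linear")]
    )
    ae.init(np.random.default_rng(seed))
    ae.fit_mse(patches, patches, seed=seed, epochs=epochs, init=False)
    enc = ae.layers[0]
    conv.W.value = enc.W.value.reshape(kh, kw, c, conv.c_out).copy()
    conv.b.value = enc.b.value.copy()
    # rescale so the pre-activation variance is ~1 on the sampled patches;
    # the autoencoder fixes the kernel directions, not a usable scale
    z = patches @ enc.W.value + enc.b.value
    s = z.std()
    if s > 1e-8:
        conv.W.value /= s
        conv.b.value /= s
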