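"""Supervised window classifiers: random forest, MLP and CNN feature learners.

Four model kinds share one interface:

``rf``       random forest with 100 trees (scikit-learn); scores are the
             fraction of trees voting tremor.
``mlp``      multi-layer perceptron with dense layers of 128, 32 and 1
             units (ReLU, ReLU, sigmoid), trained with binary
             cross-entropy, RMSProp, batch size 50 and 20 % dropout after
             the hidden layers; inputs are z-scored with statistics from
             the training split.
``cnn_raw``  1-D convolution (16 kernels of length 25, "same" padding)
             applied independently along each axis of the raw 3x150
             window, max-pooled by 4, followed by dense layers of
             128/64/32/1 units.
``cnn_tnt``  two 2-D convolutions (32 kernels 3x9, then 16 kernels 3x5)
             over the 9x128 stack of total/tremor/non-tremor spectra of
             the three axes; the second convolution's output is the learned
             feature map, followed by dense layers of 128/32/1 units.

Convolution kernels are initialized from a small patch autoencoder
(encoder weights become the kernels); all other layers use Glorot-uniform
initialization.  The number of training epochs is chosen on a validation
subset (20 % of the training windows) via early stopping.  Everything is
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from . import nn
from .preprocess import N_GRID, WINDOW_SAMPLES

__all__ = ["ClassifierModel", "train_classifier", "train_cnn", "predict_scores", "cnn_features"]

_CNN_RAW_SHAPE = (3, WINDOW_SAMPLES)
_CNN_TNT_SHAPE = (9, N_GRID)


@dataclass
class ClassifierModel:
    """A fitted window classifier with its input contract and metadata."""

    kind: str  # rf | mlp | cnn_raw | cnn_tnt
    model: object
    scaler: tuple | None = None  # (mean, std) for feature z-scoring
    meta: dict = field(default_factory=dict)


def _check_xy(X: np.ndarray, y: np.ndarray) -> tuple:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int).ravel()
    if len(X) != len(y):
        raise ValueError("X and y length mismatch")
    if not np.isfinite(X).all():
        raise ValueError("features contain NaN/Inf")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    return X, y


def _val_split(n: int, y: np.ndarray, seed: int, frac: float = 0.2) -> tuple:
    """Label-stratified train/validation index split, deterministic per seed."""
    rng = np.random.default_rng(seed)
    val = np.zeros(n, dtype=bool)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        k = max(1, int(round(frac * len(idx))))
        val[idx[:k]] = True
    return np.flatnonzero(~val), np.flatnonzero(val)


def train_classifier(
    X: np.ndarray,
    y: np.ndarray,
    kind: str,
    seed: int = 0,
    epochs: int = 50,
    standardize: bool = True,
) -> ClassifierModel:
    """Fit a random forest or MLP on a feature matrix.

    ``standardize`` controls the MLP's input z-scoring; disable it for
    inputs that are already on a homogeneous scale (e.g., frozen CNN
    feature maps, where per-dimension rescaling amplifies inactive units).
    """
    X, y = _check_xy(X, y)
    if kind == "rf":
        clf = RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
        clf.fit(X, y)
        return ClassifierModel(kind="rf", model=clf, meta={"seed": seed})
    if kind != "mlp":
        raise ValueError(f"unknown classifier kind {kind!r}")
    if standardize:
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
    else:
        mu, sd = np.zeros(X.shape[1]), np.ones(X.shape[1])
    Xs = (X - mu) / sd
    tr, va = _val_split(len(Xs), y, seed)
    net = nn.Network(
        [
            nn.Dense(X.shape[1], 128, "relu"),
            nn.Dropout(0.2),
            nn.Dense(128, 32, "relu"),
            nn.Dropout(0.2),
            nn.Dense(32, 1, "sigmoid"),
        ]
    )
    hist = net.fit(
        Xs[tr], y[tr], seed=seed, x_val=Xs[va], y_val=y[va], epochs=epochs,
        batch_size=50, patience=5,
    )
    return ClassifierModel(
        kind="mlp", model=net, scaler=(mu, sd),
        meta={"seed": seed, "epochs": hist["best_epoch"] + 1, "val_frac": 0.2},
    )


def _build_cnn(arch: str, seed: int) -> nn.Network:
    rng = np.random.default_rng(seed)
    if arch == "raw":
        net = nn.Network(
            [
                nn.Conv2D(1, 25, 1, 16, "relu"),  # per-axis 1-D conv, same padding
                nn.MaxPool2D(1, 4),
                nn.Dropout(0.2),
                nn.Flatten(),
                nn.Dense(3 * (WINDOW_SAMPLES // 4) * 16, 128, "relu"),
                nn.Dropout(0.2),
                nn.Dense(128, 64, "relu"),
                nn.Dropout(0.2),
                nn.Dense(64, 32, "relu"),
                nn.Dropout(0.2),
                nn.Dense(32, 1, "sigmoid"),
            ]
        )
    elif arch == "tnt":
        net = nn.Network(
            [
                nn.Conv2D(3, 9, 1, 32, "relu"),
                nn.Conv2D(3, 5, 32, 16, "relu"),  # output = learned feature map
                nn.Dropout(0.2),
                nn.Flatten(),
                nn.Dense(9 * N_GRID * 16, 128, "relu"),
                nn.Dropout(0.2),
                nn.Dense(128, 32, "relu"),
                nn.Dropout(0.2),
                nn.Dense(32, 1, "sigmoid"),
            ]
        )
    else:
        raise ValueError(f"unknown CNN architecture {arch!r}")
    net.init(rng)
    return net


def _cnn_inputs(arch: str, data: np.ndarray) -> np.ndarray:
    data = np.asarray(data, dtype=float)
    want = _CNN_RAW_SHAPE if arch == "raw" else _CNN_TNT_SHAPE
    if data.ndim == 3 and data.shape[1:] == (want[1], want[0]):
        data = np.swapaxes(data, 1, 2)  # accept (n, 150, 3) windows too
    if data.ndim != 3 or data.shape[1:] != want:
        raise ValueError(f"{arch} CNN expects inputs of shape (n, {want[0]}, {want[1]})")
    return data[..., None]  # channels-last


def train_cnn(
    data: np.ndarray,
    y: np.ndarray,
    arch: str,
    seed: int = 0,
    epochs: int = 30,
    pretrain_epochs: int = 10,
) -> ClassifierModel:
    """Fit a CNN feature learner end-to-end on windows (raw) or spectra (tnt).

    ``raw`` takes (n, 3, 150) windows; ``tnt`` takes (n, 9, 128) stacked
    total/tremor/non-tremor spectra.  Convolution kernels are initialized
    by a patch autoencoder before supervised training.
    """
    x = _cnn_inputs(arch, data)
    _, y = _check_xy(x.reshape(len(x), -1), y)
    scale = np.abs(x).mean() or 1.0
    x = x / scale
    net = _build_cnn(arch, seed)
    for layer in net.layers:
        if isinstance(layer, nn.Conv2D):
            inp = x if layer is net.layers[0] else _conv_activations(net, x, layer)
            nn.pretrain_conv_autoencoder(layer, inp, seed=seed, epochs=pretrain_epochs)
    tr, va = _val_split(len(x), y, seed)
    hist = net.fit(
        x[tr], y[tr], seed=seed, x_val=x[va], y_val=y[va], epochs=epochs,
        batch_size=50, patience=5, init=False,
    )
    feat_layer = 1 if arch == "raw" else 1  # maxpool (raw) / 2nd conv (tnt)
    return ClassifierModel(
        kind=f"cnn_{arch}", model=net, scaler=(0.0, scale),
        meta={"seed": seed, "epochs": hist["best_epoch"] + 1, "feature_layer": feat_layer},
    )


def _conv_activations(net: nn.Network, x: np.ndarray, upto_layer: nn.Layer) -> np.ndarray:
    """Activations feeding ``upto_layer``, on a subsample, for AE pre-training."""
    sub = x[: min(len(x), 256)]
    out = sub
    for layer in net.layers:
        if layer is upto_layer:
            return out
        out = layer.forward(out, train=False)
    raise ValueError("layer not found")


def predict_scores(model: ClassifierModel, inputs: np.ndarray) -> np.ndarray:
    """Score windows with a fitted model; returns values in [0, 1]."""
    if model.kind == "rf":
        return model.model.predict_proba(np.asarray(inputs, dtype=float))[:, 1]
    if model.kind == "mlp":
        mu, sd = model.scaler
        X = (np.asarray(inputs, dtype=float) - mu) / sd
        if X.ndim != 2 or X.shape[1] != model.model.layers[0].d_in:
            raise ValueError("feature dimension does not match the fitted MLP")
        return model.model.predict(X)
    arch = model.kind.split("_", 1)[1]
    x = _cnn_inputs(arch, inputs) / model.scaler[1]
    return model.model.predict(x)


def cnn_features(model: ClassifierModel, inputs: np.ndarray) -> np.ndarray:
    """Learned feature vectors (flattened feature-layer activations)."""
    if not model.kind.startswith("cnn_"):
        raise ValueError("cnn_features requires a CNN model")
    arch = model.kind.split("_", 1)[1]
    x = _cnn_inputs(arch, inputs) / model.scaler[1]
    out = model.model.forward_until(x, model.meta["feature_layer"])
    return out.reshape(len(out), -1)
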