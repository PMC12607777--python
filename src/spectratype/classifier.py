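"""Feed-forward subtype classifier on selected enrichment features.

Architecture: a stack of dense layers (default widths 1024, 256, 64, 64),
each followed by SELU activation, batch normalization, and Gaussian dropout
(rate 0.4), capped by a dense softmax head.  Trained with Adam
(learning rate 1e-3, decoupled weight decay 1e-6) on categorical
cross-entropy.  The head defaults to one unit per class; a wider head (e.g.
10 units) is supported, in which case surplus units are trained against
all-zero targets and only the first n_classes units map to labels.

The network is implemented directly on numpy: forward/backward passes for
dense, batch-norm and Gaussian-dropout layers, SELU and softmax, and the
Adam update.  Inference runs batch-norm on running statistics with dropout
off, so prediction is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .balancing import LabeledDataset
from .data_io import EnrichmentMatrix, IncompatibilityError

_SELU_ALPHA = 1.6732632423543772
_SELU_SCALE = 1.0507009873554805
_BN_EPS = 1e-3
_BN_MOMENTUM = 0.99
_ADAM_B1, _ADAM_B2, _ADAM_EPS = 0.9, 0.999, 1e-7


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite during optimization."""


@dataclass
class ModelConfig:
    """Hyperparameters of the subtype network.

    ``output_width=None`` sizes the softmax head to the number of classes;
    an explicit wider value reproduces a fixed-width head.  ``epochs`` and
    ``batch_size`` control Adam mini-batching; ``early_stop_patience`` stops
    when the training loss has not improved for that many epochs (None/0
    disables early stopping).
    """

    hidden_widths: tuple[int, ...] = (1024, 256, 64, 64)
    output_width: int | None = None
    activation: str = "selu"
    dropout_rate: float = 0.4
    learning_rate: float = 0.001
    weight_decay: float = 1e-6
    loss: str = "categorical_cross_entropy"
    epochs: int = 500
    batch_size: int = 64
    seed: int = 0
    early_stop_patience: int | None = 20

    def __post_init__(self) -> None:
        self.hidden_widths = tuple(int(w) for w in self.hidden_widths)
        if any(w < 1 for w in self.hidden_widths):
            raise ValueError("hidden widths must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.activation != "selu":
            raise ValueError("only the SELU activation is supported")
        if self.loss != "categorical_cross_entropy":
            raise ValueError("only categorical cross-entropy loss is supported")


def _selu(z: np.ndarray) -> np.ndarray:
    return _SELU_SCALE * np.where(z > 0, z, _SELU_ALPHA * (np.expm1(z)))


def _selu_grad(z: np.ndarray) -> np.ndarray:
    return _SELU_SCALE * np.where(z > 0, 1.0, _SELU_ALPHA * np.exp(z))


def _softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class _Layers:
    """Parameter store: one dict per hidden block plus the output head."""

    hidden: list[dict[str, np.ndarray]] = field(default_factory=list)
    out: dict[str, np.ndarray] = field(default_factory=dict)

    def trainable(self):
        """(key, layer_dict, param_name) triples for every optimized array."""
        for i, layer in enumerate(self.hidden):
            for name in ("W", "b", "gamma", "beta"):
                yield f"h{i}_{name}", layer, name
        for name in ("W", "b"):
            yield f"out_{name}", self.out, name


def build_model(config: ModelConfig, n_features: int, n_classes: int) -> "TrainedModel":
    """Seeded initialization of the full parameter stack (lecun-normal)."""
    if n_features < 1 or n_classes < 2:
        raise ValueError("need n_features >= 1 and n_classes >= 2")
    out_width = config.output_width if config.output_width is not None else n_classes
    if out_width < n_classes:
        raise ValueError(
            f"output_width {out_width} smaller than n_classes {n_classes}"
        )
    rng = np.random.default_rng(config.seed)
    layers = _Layers()
    fan_in = n_features
    for width in config.hidden_widths:
        layers.hidden.append(
            {
                "W": rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=(fan_in, width)),
                "b": np.zeros(width),
                "gamma": np.ones(width),
                "beta": np.zeros(width),
                "run_mean": np.zeros(width),
                "run_var": np.ones(width),
            }
        )
        fan_in = width
    layers.out = {
        "W": rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=(fan_in, out_width)),
        "b": np.zeros(out_width),
    }
    return TrainedModel(
        layers=layers,
        class_order=[],
        feature_names=[],
        config=config,
        training_log=[],
    )


def _forward_infer(layers: _Layers, X: np.ndarray) -> np.ndarray:
    a = X
    for layer in layers.hidden:
        h = _selu(a @ layer["W"] + layer["b"])
        inv = 1.0 / np.sqrt(layer["run_var"] + _BN_EPS)
        a = layer["gamma"] * (h - layer["run_mean"]) * inv + layer["beta"]
    return _softmax(a @ layers.out["W"] + layers.out["b"])


def _forward_backward(layers: _Layers, X, Y, dropout_rate, rng):
    """One training pass: returns (loss, grads keyed like trainable())."""
    B = X.shape[0]
    caches = []
    a = X
    noise_sd = np.sqrt(dropout_rate / (1.0 - dropout_rate)) if dropout_rate else 0.0
    for layer in layers.hidden:
        z = a @ layer["W"] + layer["b"]
        h = _selu(z)
        mu = h.mean(axis=0)
        var = h.var(axis=0)
        inv = 1.0 / np.sqrt(var + _BN_EPS)
        xhat = (h - mu) * inv
        bn = layer["gamma"] * xhat + layer["beta"]
        layer["run_mean"] = _BN_MOMENTUM * layer["run_mean"] + (1 - _BN_MOMENTUM) * mu
        layer["run_var"] = _BN_MOMENTUM * layer["run_var"] + (1 - _BN_MOMENTUM) * var
        noise = rng.normal(1.0, noise_sd, size=bn.shape) if noise_sd else None
        out = bn * noise if noise is not None else bn
        caches.append((a, z, xhat, inv, noise))
        a = out
    logits = a @ layers.out["W"] + layers.out["b"]
    if not np.all(np.isfinite(logits)):
        return float("nan"), np.full_like(logits, np.nan), {}
    probs = _softmax(logits)
    loss = float(-np.mean(np.sum(Y * np.log(probs + 1e-12), axis=1)))

    grads: dict[str, np.ndarray] = {}
    dlogits = (probs - Y) / B
    grads["out_W"] = a.T @ dlogits
    grads["out_b"] = dlogits.sum(axis=0)
    da = dlogits @ layers.out["W"].T
    for i in range(len(layers.hidden) - 1, -1, -1):
        layer = layers.hidden[i]
        a_in, z, xhat, inv, noise = caches[i]
        if noise is not None:
            da = da * noise
        grads[f"h{i}_gamma"] = np.sum(da * xhat, axis=0)
        grads[f"h{i}_beta"] = np.sum(da, axis=0)
        dxhat = da * layer["gamma"]
        dh = (inv / B) * (
            B * dxhat - dxhat.sum(axis=0) - xhat * np.sum(dxhat * xhat, axis=0)
        )
        dz = dh * _selu_grad(z)
        grads[f"h{i}_W"] = a_in.T @ dz
        grads[f"h{i}_b"] = dz.sum(axis=0)
        da = dz @ layer["W"].T
    return loss, probs, grads


@dataclass
class PredictionResult:
    """Per-sample class probabilities and argmax labels."""

    sample_ids: list[str]
    probabilities: np.ndarray
    predicted_labels: list[str]
    class_order: list[str]


@dataclass
class TrainedModel:
    """Network parameters plus the vocabulary needed to apply them."""

    layers: _Layers
    class_order: list[str]
    feature_names: list[str]
    config: ModelConfig
    training_log: list[tuple[float, float]]

    # -- serialization ------------------------------------------------------
    def to_arrays(self) -> tuple[dict[str, np.ndarray], dict]:
        arrays: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers.hidden):
            for name, arr in layer.items():
                arrays[f"h{i}_{name}"] = arr
        for name, arr in self.layers.out.items():
            arrays[f"out_{name}"] = arr
        meta = {
            "class_order": self.class_order,
            "feature_names": self.feature_names,
            "config": asdict(self.config),
            "n_hidden": len(self.layers.hidden),
            "training_log": self.training_log,
        }
        meta["config"]["hidden_widths"] = list(self.config.hidden_widths)
        return arrays, meta

    @classmethod
    def from_arrays(cls, arrays: dict[str, np.ndarray], meta: dict) -> "TrainedModel":
        cfg = dict(meta["config"])
        cfg["hidden_widths"] = tuple(cfg["hidden_widths"])
        config = ModelConfig(**cfg)
        layers = _Layers()
        for i in range(meta["n_hidden"]):
            layers.hidden.append(
                {
                    name: arrays[f"h{i}_{name}"]
                    for name in ("W", "b", "gamma", "beta", "run_mean", "run_var")
                }
            )
        layers.out = {"W": arrays["out_W"], "b": arrays["out_b"]}
        return cls(
            layers=layers,
            class_order=list(meta["class_order"]),
            feature_names=list(meta["feature_names"]),
            config=config,
            training_log=[tuple(t) for t in meta["training_log"]],
        )


def _one_hot(labels, class_order, out_width) -> np.ndarray:
    code = {c: i for i, c in enumerate(class_order)}
    Y = np.zeros((len(labels), out_width))
    for i, lab in enumerate(labels):
        Y[i, code[lab]] = 1.0
    return Y


def train(model: TrainedModel, data: LabeledDataset, config: ModelConfig) -> TrainedModel:
    """Optimize the network on a balanced, feature-selected training set.

    Deterministic given ``config.seed`` and a fixed thread count; records a
    (loss, accuracy) pair per epoch.  Raises TrainingDivergedError with a
    learning-rate hint on NaN loss.
    """
    if len(set(data.labels)) < 2:
        raise ValueError("training data must contain at least 2 classes")
    X = data.features
    out_width = model.layers.out["b"].shape[0]
    model.class_order = list(data.class_order)
    Y = _one_hot(data.labels, data.class_order, out_width)
    y_idx = np.argmax(Y[:, : len(data.class_order)], axis=1)
    rng = np.random.default_rng(config.seed + 1)

    # Adam state
    state = {
        key: (np.zeros_like(layer[name]), np.zeros_like(layer[name]))
        for key, layer, name in model.layers.trainable()
    }
    t = 0
    log: list[tuple[float, float]] = []
    best_loss = np.inf
    best_params = None
    stall = 0
    n = X.shape[0]
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        correct = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            loss, probs, grads = _forward_backward(
                model.layers, X[idx], Y[idx], config.dropout_rate, rng
            )
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    "loss became non-finite; try a smaller learning_rate"
                )
            epoch_loss += loss * len(idx)
            correct += int(
                np.sum(np.argmax(probs[:, : len(data.class_order)], axis=1) == y_idx[idx])
            )
            t += 1
            lr = config.learning_rate
            b1t = 1.0 - _ADAM_B1**t
            b2t = 1.0 - _ADAM_B2**t
            for key, layer, name in model.layers.trainable():
                g = grads[key]
                m, v = state[key]
                m *= _ADAM_B1
                m += (1 - _ADAM_B1) * g
                v *= _ADAM_B2
                v += (1 - _ADAM_B2) * g * g
                step = lr * (m / b1t) / (np.sqrt(v / b2t) + _ADAM_EPS)
                if config.weight_decay and name == "W":
                    step = step + lr * config.weight_decay * layer[name]
                layer[name] -= step
        epoch_loss /= n
        log.append((epoch_loss, correct / n))
        if config.early_stop_patience:
            if epoch_loss < best_loss - 1e-6:
                best_loss = epoch_loss
                best_params = {
                    key: layer[name].copy()
                    for key, layer, name in model.layers.trainable()
                }
                stall = 0
            else:
                stall += 1
                if stall >= config.early_stop_patience:
                    break
    if best_params is not None:
        for key, layer, name in model.layers.trainable():
            layer[name][...] = best_params[key]
    model.training_log = log
    model.config = config
    return model


def predict(model: TrainedModel, spectra) -> PredictionResult:
    """Apply a trained model; batch-norm/dropout in inference mode.

    ``spectra`` is a reduced EnrichmentMatrix (columns must equal
    model.feature_names) or a raw samples × features array.
    """
    if isinstance(spectra, EnrichmentMatrix):
        if model.feature_names and list(spectra.set_names) != model.feature_names:
            raise IncompatibilityError(
                "spectra columns do not match the model's selected features; "
                "run align_features first"
            )
        X = spectra.scores
        sample_ids = list(spectra.sample_ids)
    else:
        X = np.atleast_2d(np.asarray(spectra, dtype=float))
        sample_ids = [f"s{i}" for i in range(X.shape[0])]
    first = model.layers.hidden[0] if model.layers.hidden else model.layers.out
    if X.shape[1] != first["W"].shape[0]:
        raise IncompatibilityError(
            f"input width {X.shape[1]} != model input width {first['W'].shape[0]}"
        )
    full = _forward_infer(model.layers, X)
    n_classes = len(model.class_order)
    probs = full[:, :n_classes]
    probs = probs / probs.sum(axis=1, keepdims=True)
    pred_idx = np.argmax(probs, axis=1)
    return PredictionResult(
        sample_ids=sample_ids,
        probabilities=probs,
        predicted_labels=[model.class_order[i] for i in pred_idx],
        class_order=list(model.class_order),
    )


class SubtypeClassifier(BaseEstimator, ClassifierMixin):
    """scikit-learn estimator facade over the feed-forward subtype network.

    Parameters mirror ModelConfig; ``fit`` expects an already balanced and
    feature-selected design matrix.

    Attributes
    ----------
    classes_ : ndarray of class labels in sorted order
    model_ : the underlying TrainedModel
    training_log_ : list of per-epoch (loss, accuracy)
    """

    def __init__(
        self,
        hidden_widths: tuple[int, ...] = (1024, 256, 64, 64),
        output_width: int | None = None,
        dropout_rate: float = 0.4,
        learning_rate: float = 0.001,
        weight_decay: float = 1e-6,
        epochs: int = 500,
        batch_size: int = 64,
        random_state: int = 0,
        early_stop_patience: int | None = 20,
    ):
        self.hidden_widths = hidden_widths
        self.output_width = output_width
        self.dropout_rate = dropout_rate
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.epochs = epochs
        self.batch_size = batch_size
        self.random_state = random_state
        self.early_stop_patience = early_stop_patience

    def _config(self) -> ModelConfig:
        return ModelConfig(
            hidden_widths=tuple(self.hidden_widths),
            output_width=self.output_width,
            dropout_rate=self.dropout_rate,
            learning_rate=self.learning_rate,
            weight_decay=self.weight_decay,
            epochs=self.epochs,
            batch_size=self.batch_size,
            seed=self.random_state,
            early_stop_patience=self.early_stop_patience,
        )

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = [str(v) for v in y]
        classes = sorted(set(y))
        config = self._config()
        model = build_model(config, X.shape[1], len(classes))
        model.feature_names = [f"f{i}" for i in range(X.shape[1])]
        data = LabeledDataset(
            sample_ids=[f"s{i}" for i in range(X.shape[0])],
            features=X,
            labels=y,
            class_order=classes,
        )
        if config.epochs > 0:
            train(model, data, config)
        else:
            model.class_order = classes
        self.model_ = model
        self.classes_ = np.asarray(classes, dtype=object)
        self.training_log_ = model.training_log
        return self

    def predict_proba(self, X):
        return predict(self.model_, np.asarray(X, dtype=float)).probabilities

    def predict(self, X):
        result = predict(self.model_, np.asarray(X, dtype=float))
        return np.asarray(result.predicted_labels, dtype=object)
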