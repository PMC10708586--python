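"""Depthwise 1-D CNN classifying 14-channel EEG into the ten digit classes.

The convolution stages slide a length-5 kernel along the time axis only
(kernel 1x5 on the (channel-row, time) grid), so the 14 electrode rows are
treated as a spatial axis shared by every filter; the filter count forms the
leading activation axis.  Three conv stages (leaky rectifier, batch
normalisation, dropout) feed a flatten and a dense chain whose penultimate
layer is the feature vector handed to the saliency generator; the head is a
dense layer with log-softmax outputs trained with cross-entropy under plain
SGD.

Two profiles are provided: ``paper`` (filters 14/10/10, dense 3500/2500,
feature length 2500 — ~122M parameters, forward-pass scale) and ``desk``
(filters 4/4/4, dense 128/64 — minutes-scale training on a CPU).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import nn
from .eeg_io import N_CHANNELS, TARGET_SAMPLES, EEGRecord
from .metrics import classification_metrics, confusion_matrix


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""

    def __init__(self, iteration: int):
        super().__init__(f"non-finite loss at iteration {iteration}")
        self.iteration = iteration


@dataclass
class ClassifierSpec:
    """Architecture description of the EEG classifier.

    ``desk`` only shrinks filter and dense sizes; the three-stage structure
    is identical in both profiles.
    """

    conv_filters: tuple = (14, 10, 10)
    kernel_size: int = 5
    activation_slope: float = 0.1
    dropout_rate: float = 0.2
    dense_sizes: tuple = (3500, 2500)
    n_classes: int = 10
    profile: str = "paper"

    def __post_init__(self):
        if len(self.conv_filters) != 3:
            raise ValueError("exactly three convolution stages are required")
        if len(self.dense_sizes) != 2:
            raise ValueError("exactly two hidden dense layers are required")

    @classmethod
    def desk(cls, n_classes: int = 10) -> "ClassifierSpec":
        return cls(
            conv_filters=(4, 4, 4),
            dense_sizes=(128, 64),
            n_classes=n_classes,
            profile="desk",
        )

    @property
    def feature_length(self) -> int:
        return self.dense_sizes[-1]


@dataclass
class BatchNormState:
    """Batch statistics used by :func:`batch_normalize`."""

    mu_B: np.ndarray
    sigma2_B: np.ndarray
    epsilon: float
    n: int

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if (np.asarray(self.sigma2_B) < 0).any():
            raise ValueError("variances must be non-negative")


def batch_normalize(batch, state: BatchNormState | None = None, eps: float = 1e-5):
    """Normalise a (batch, features) array per feature over the batch.

    Returns ``(normalized, state)``; with no ``state`` given, the batch's
    own mean and (biased) variance are used and returned.
    """
    batch = np.asarray(batch, dtype=float)
    if batch.ndim != 2 or batch.shape[0] < 1:
        raise ValueError("batch must be a non-empty 2-D array")
    if state is None:
        state = BatchNormState(
            mu_B=batch.mean(axis=0),
            sigma2_B=batch.var(axis=0),
            epsilon=eps,
            n=batch.shape[0],
        )
    out = (batch - state.mu_B) / np.sqrt(state.sigma2_B + state.epsilon)
    return out, state


class ClassifierNetwork:
    """A built (possibly trained) classifier with its spec and class labels."""

    def __init__(self, spec: ClassifierSpec, seed: int = 42, dtype=None):
        self.spec = spec
        self.seed = seed
        if dtype is None:
            dtype = np.float32 if spec.profile == "paper" else np.float64
        layers: list[nn.Layer] = []
        for n_filters in spec.conv_filters:
            layers += [
                nn.Conv2d(n_filters, (1, spec.kernel_size), stride=1,
                          padding="same", bias=True),
                nn.LeakyReLU(spec.activation_slope),
                nn.BatchNorm(),
                nn.Dropout(spec.dropout_rate),
            ]
        layers.append(nn.Flatten())
        for units in spec.dense_sizes:
            layers += [nn.Dense(units), nn.LeakyReLU(spec.activation_slope)]
        layers += [nn.Dense(spec.n_classes), nn.LogSoftmax()]
        self.network = nn.Sequential(
            layers, input_shape=(1, N_CHANNELS, TARGET_SAMPLES),
            seed=seed, dtype=dtype,
        )
        # index just past the activation of the last hidden dense layer
        self._feature_cut = len(layers) - 2
        self.class_labels: tuple = tuple(range(spec.n_classes))

    def forward(self, x, training=False):
        return self.network.forward(x, training=training)


def build_classifier(spec: ClassifierSpec, seed: int = 42) -> ClassifierNetwork:
    return ClassifierNetwork(spec, seed=seed)


def _stack_records(records: list[EEGRecord]) -> np.ndarray:
    x = np.stack([r.signal for r in records])
    if x.shape[1:] != (N_CHANNELS, TARGET_SAMPLES):
        raise ValueError(
            f"records must be {N_CHANNELS}x{TARGET_SAMPLES}; got {x.shape[1:]}"
        )
    return x[:, None, :, :]


def classify(model: ClassifierNetwork, record) -> np.ndarray:
    """Log class probabilities for one record or a record list."""
    records = [record] if isinstance(record, EEGRecord) else list(record)
    logp = model.forward(_stack_records(records), training=False)
    return logp[0] if isinstance(record, EEGRecord) else logp


def extract_features(model: ClassifierNetwork, record) -> np.ndarray:
    """The penultimate dense activation (the generator's input vector)."""
    records = [record] if isinstance(record, EEGRecord) else list(record)
    feats = model.network.forward_upto(
        _stack_records(records), model._feature_cut, training=False
    )
    return feats[0] if isinstance(record, EEGRecord) else feats


def predict_labels(model: ClassifierNetwork, records) -> list:
    logp = classify(model, list(records))
    return [model.class_labels[i] for i in np.argmax(logp, axis=1)]


@dataclass
class TrainConfig:
    """Training hyperparameters (SGD with cross-entropy by default)."""

    optimizer: str = "sgd"
    learning_rate: float = 0.001
    weight_decay: float = 5e-5
    momentum: float = 0.0
    batch_size: int = 32
    iterations: int = 300
    seed: int = 42
    eval_every: int = 10


def train_classifier(records, config: TrainConfig | None = None,
                     spec: ClassifierSpec | None = None,
                     test_records=None):
    """Train the classifier; returns (model, history DataFrame).

    ``records`` must already be trimmed and normalised.  The history has one
    row per iteration with the batch loss, and train/test accuracy columns
    filled every ``eval_every`` iterations.  Fully deterministic given
    ``config.seed``.
    """
    config = config or TrainConfig()
    labels = sorted({r.label for r in records})
    if len(labels) < 2:
        raise ValueError("training needs at least two classes")
    spec = spec or ClassifierSpec.desk(n_classes=len(labels))
    if spec.n_classes != len(labels):
        spec = replace(spec, n_classes=len(labels))
    model = ClassifierNetwork(spec, seed=config.seed)
    model.class_labels = tuple(labels)
    label_index = {c: i for i, c in enumerate(labels)}

    x = _stack_records(records)
    y = np.array([label_index[r.label] for r in records])
    x_test = y_test = None
    if test_records:
        x_test = _stack_records(test_records)
        y_test = np.array([label_index[r.label] for r in test_records])

    if config.optimizer.lower() == "sgd":
        opt = nn.SGD(model.network, lr=config.learning_rate,
                     weight_decay=config.weight_decay, momentum=config.momentum)
    elif config.optimizer.lower() == "adam":
        opt = nn.Adam(model.network, lr=config.learning_rate)
    else:
        raise ValueError(f"unknown optimizer {config.optimizer!r}")

    rng = np.random.default_rng(config.seed)
    history = []
    for it in range(config.iterations):
        idx = rng.choice(len(records), size=min(config.batch_size, len(records)),
                         replace=False)
        logp = model.forward(x[idx], training=True)
        loss, grad = nn.nll_loss(logp, y[idx])
        if not np.isfinite(loss):
            raise DivergenceError(it)
        model.network.backward(grad.astype(model.network.dtype))
        opt.step()
        row = {"iteration": it, "loss": loss,
               "train_accuracy": np.nan, "test_accuracy": np.nan}
        if it % config.eval_every == 0 or it == config.iterations - 1:
            row["train_accuracy"] = _accuracy(model, x, y)
            if x_test is not None:
                row["test_accuracy"] = _accuracy(model, x_test, y_test)
        history.append(row)
    return model, pd.DataFrame(history)


def _accuracy(model, x, y) -> float:
    pred = np.argmax(model.forward(x, training=False), axis=1)
    return float((pred == y).mean())


def crossvalidate(records, k: int = 10, config: TrainConfig | None = None,
                  spec: ClassifierSpec | None = None):
    """Stratified k-fold cross-validation; per-fold metric table + summary.

    Returns ``(folds DataFrame, summary DataFrame)`` where the summary rows
    are the mean and standard deviation of each metric over folds.
    """
    config = config or TrainConfig()
    labels = [r.label for r in records]
    counts = pd.Series(labels).value_counts()
    if (counts < k).any():
        small = counts[counts < k]
        raise ValueError(
            f"every class needs >= {k} members for {k}-fold stratification; "
            f"too small: {dict(small)}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=config.seed)
    rows = []
    all_true, all_pred = [], []
    for fold, (train_idx, test_idx) in enumerate(skf.split(records, labels)):
        train = [records[i] for i in train_idx]
        test = [records[i] for i in test_idx]
        model, _ = train_classifier(train, config=config, spec=spec)
        pred = predict_labels(model, test)
        true = [r.label for r in test]
        m = classification_metrics(confusion_matrix(true, pred,
                                                    model.class_labels))
        rows.append({"fold": fold, "accuracy": m["accuracy"],
                     "precision": m["precision"], "recall": m["recall"],
                     "f1": m["f1"], "kappa": m["kappa"]})
        all_true += true
        all_pred += pred
    folds = pd.DataFrame(rows)
    metric_cols = folds.columns.drop("fold")
    summary = pd.DataFrame(
        {"mean": folds[metric_cols].mean(), "sd": folds[metric_cols].std()}
    )
    return folds, summary, (all_true, all_pred)


def count_parameters(network) -> list[dict]:
    """Per-layer trainable-scalar counts (see ``Sequential.count_parameters``)."""
    net = network.network if hasattr(network, "network") else network
    return net.count_parameters()
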