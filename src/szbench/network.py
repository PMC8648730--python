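"""Single-channel 1-D CNN + Bi-LSTM seizure-prediction classifier.

The model consumes one EEG channel at a time: a 1 x L window vector runs
through five convolution blocks (conv k=3 s=1 with same padding, batch
norm, ReLU, max-pool k=2 s=2), whose output — a sequence of L/32 steps
with one feature per conv channel — feeds a single-layer bidirectional
LSTM with 10 hidden units.  The concatenated final hidden states pass
through dropout (0.5) and a fully connected softmax layer over the two
classes (interictal = 0, preictal = 1).  Setting ``use_lstm=False``
removes the recurrent stage and classifies the flattened conv features
directly (the "CNN + FC" ablation).

Because the intended deployment is memory- and power-constrained
implantable hardware, the module also provides closed-form parameter and
forward-FLOP accounting per layer, cross-checked against enumeration of
the instantiated tensors.  One multiply-accumulate counts as 2 FLOPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from ._net import (
    Adam,
    BatchNorm1d,
    BiLstmLast,
    Conv1dSame,
    Dropout,
    Flatten,
    Linear,
    MaxPool1d,
    ReLU,
    Sequential,
    cross_entropy,
    softmax,
)


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters; defaults give the benchmark model."""

    conv_widths: Tuple[int, ...] = (16, 16, 16, 16, 16)
    conv_kernel: int = 3
    conv_stride: int = 1
    pool_kernel: int = 2
    pool_stride: int = 2
    lstm_hidden: int = 10
    lstm_layers: int = 1
    bidirectional: bool = True
    use_lstm: bool = True
    dropout_rate: float = 0.5
    n_classes: int = 2
    input_len: int = 1280

    def __post_init__(self):
        object.__setattr__(self, "conv_widths", tuple(int(w) for w in self.conv_widths))
        if any(w < 1 for w in self.conv_widths) or not self.conv_widths:
            raise ConfigurationError("conv_widths must be positive")
        if self.conv_kernel % 2 != 1 or self.conv_kernel < 1:
            raise ConfigurationError("conv_kernel must be odd and positive")
        if self.conv_stride != 1:
            raise ConfigurationError("only stride-1 convolutions are supported")
        if self.pool_kernel != self.pool_stride or self.pool_kernel < 1:
            raise ConfigurationError("pooling must be non-overlapping")
        if self.lstm_layers != 1:
            raise ConfigurationError("only a single recurrent layer is supported")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ConfigurationError("dropout_rate must be in [0, 1)")
        if self.input_len % (self.pool_stride ** self.n_blocks):
            raise ConfigurationError(
                f"input_len {self.input_len} not divisible by "
                f"{self.pool_stride}^{self.n_blocks}"
            )

    @property
    def n_blocks(self) -> int:
        return len(self.conv_widths)

    @property
    def seq_len(self) -> int:
        """Time steps seen by the LSTM (input_len / pool_stride^blocks)."""
        return self.input_len // (self.pool_stride ** self.n_blocks)

    @property
    def fc_in(self) -> int:
        if self.use_lstm:
            return (2 if self.bidirectional else 1) * self.lstm_hidden
        return self.conv_widths[-1] * self.seq_len


def build_network(config: NetworkConfig, seed: int) -> Sequential:
    """Instantiate the network with weights reproducible from ``seed``."""
    rng = np.random.default_rng(seed)
    layers = []
    c_in = 1
    for w in config.conv_widths:
        layers.append(Conv1dSame(c_in, w, config.conv_kernel, rng))
        layers.append(BatchNorm1d(w))
        layers.append(ReLU())
        layers.append(MaxPool1d(config.pool_kernel))
        c_in = w
    if config.use_lstm:
        layers.append(BiLstmLast(c_in, config.lstm_hidden,
                                 config.bidirectional, rng))
    else:
        layers.append(Flatten())
    layers.append(Dropout(config.dropout_rate, rng))
    layers.append(Linear(config.fc_in, config.n_classes, rng))
    return Sequential(layers)


def forward(model: Sequential, vector: np.ndarray) -> np.ndarray:
    """Inference-mode class probabilities for one 1 x input_len vector."""
    v = np.asarray(vector, dtype=float).reshape(1, 1, -1)
    return softmax(model.forward(v, training=False))[0]


# ---------------------------------------------------------------------------
# budget accounting

@dataclass
class BudgetReport:
    """Parameter and forward-FLOP totals with a per-layer breakdown."""

    n_parameters: int
    n_flops_forward: int
    per_layer: List[Tuple[str, int, int]]  # (name, params, flops)

    def to_text(self) -> str:
        lines = ["layer\tparams\tflops"]
        for name, p, f in self.per_layer:
            lines.append(f"{name}\t{p}\t{f}")
        lines.append(f"total\t{self.n_parameters}\t{self.n_flops_forward}")
        return "\n".join(lines) + "\n"


def _layer_budget(config: NetworkConfig) -> List[Tuple[str, int, int]]:
    """Closed-form per-layer (params, forward FLOPs) for one vector.

    Conventions: MAC = 2 FLOPs; batch-norm at inference is a per-element
    scale and shift (2 FLOPs); ReLU and max-pool cost 1 FLOP per output
    element; LSTM gate non-linearities and state updates cost 10 FLOPs
    per hidden unit per step per direction.
    """
    k = config.conv_kernel
    rows: List[Tuple[str, int, int]] = []
    c_in, L = 1, config.input_len
    for i, c_out in enumerate(config.conv_widths, start=1):
        conv_p = k * c_in * c_out + c_out
        conv_f = 2 * k * c_in * c_out * L
        rows.append((f"conv{i}", conv_p, conv_f))
        rows.append((f"bn{i}", 2 * c_out, 2 * c_out * L))
        rows.append((f"relu{i}", 0, c_out * L))
        L //= config.pool_stride
        rows.append((f"pool{i}", 0, c_out * L))
        c_in = c_out
    if config.use_lstm:
        h = config.lstm_hidden
        d = 2 if config.bidirectional else 1
        per_dir_p = 4 * (h * (c_in + h) + 2 * h)
        # matrix/bias work is 2 FLOPs per parameter per step; elementwise
        # gate math adds 10 FLOPs per hidden unit per step
        lstm_f = d * config.seq_len * (2 * per_dir_p + 10 * h)
        rows.append(("bilstm" if config.bidirectional else "lstm",
                     d * per_dir_p, lstm_f))
    fc_in = config.fc_in
    rows.append(("fc", fc_in * config.n_classes + config.n_classes,
                 2 * fc_in * config.n_classes))
    rows.append(("softmax", 0, 3 * config.n_classes))
    return rows


def count_parameters(config: NetworkConfig) -> int:
    """Closed-form parameter count (conv + BN + LSTM + FC)."""
    return sum(p for _, p, _ in _layer_budget(config))


def count_parameters_by_enumeration(config: NetworkConfig, seed: int = 0) -> int:
    """Independent count: instantiate and sum tensor sizes."""
    model = build_network(config, seed)
    return sum(v.size for v in model.params().values())


def count_flops(config: NetworkConfig) -> int:
    """Analytic forward FLOPs for one single-channel window."""
    return sum(f for _, _, f in _layer_budget(config))


def budget_report(config: NetworkConfig) -> BudgetReport:
    rows = _layer_budget(config)
    report = BudgetReport(
        n_parameters=sum(p for _, p, _ in rows),
        n_flops_forward=sum(f for _, _, f in rows),
        per_layer=rows,
    )
    enumerated = count_parameters_by_enumeration(config)
    if enumerated != report.n_parameters:
        raise AssertionError(
            f"budget mismatch: closed form {report.n_parameters}, "
            f"tensors {enumerated}"
        )
    return report


# ---------------------------------------------------------------------------
# sklearn-style estimator

class CnnBiLstmClassifier(BaseEstimator, ClassifierMixin):
    """Single-channel CNN + Bi-LSTM classifier on window vectors.

    Rows of ``X`` are single-channel window vectors of length
    ``config.input_len``; ``y`` holds 0 (interictal) / 1 (preictal).
    Training uses Adam on softmax cross-entropy with shuffled
    mini-batches; with ``balance=True`` the majority class is randomly
    undersampled to 1:1 before training.  All randomness (init, shuffle,
    dropout, undersampling) derives from ``random_state``, so identical
    inputs and seed give identical weight trajectories.

    Parameters
    ----------
    config : NetworkConfig
        Architecture; ``None`` means the default benchmark model (adjust
        ``input_len`` to the window length in samples).
    epochs, batch_size, learning_rate : training schedule.
    balance : undersample the majority class to 1:1 before training.
    random_state : seed for all stochastic components.
    """

    def __init__(
        self,
        config: Optional[NetworkConfig] = None,
        epochs: int = 20,
        batch_size: int = 32,
        learning_rate: float = 1e-3,
        balance: bool = True,
        random_state: int = 0,
    ):
        self.config = config
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.balance = balance
        self.random_state = random_state

    def _resolved_config(self, n_features: int) -> NetworkConfig:
        cfg = self.config if self.config is not None else NetworkConfig()
        if cfg.input_len != n_features:
            raise ValueError(
                f"X has {n_features} features but config.input_len is "
                f"{cfg.input_len}"
            )
        return cfg

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=np.float64)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError(
                "training data contains a single class; both preictal and "
                "interictal samples are required"
            )
        self.classes_ = classes
        y_idx = np.searchsorted(classes, y)
        cfg = self._resolved_config(X.shape[1])
        rng = np.random.default_rng(self.random_state)
        if self.balance:
            X, y_idx = _undersample(X, y_idx, rng)
        self.net_ = build_network(cfg, seed=int(rng.integers(2 ** 31)))
        opt = Adam(self.net_.params(), lr=self.learning_rate)
        n = X.shape[0]
        self.loss_curve_ = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                xb = X[idx][:, None, :]
                logits = self.net_.forward(xb, training=True)
                loss, dlogits = cross_entropy(logits, y_idx[idx])
                self.net_.backward(dlogits)
                opt.step(self.net_.grads())
                epoch_loss += loss * len(idx)
            self.loss_curve_.append(epoch_loss / n)
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "net_")
        X = check_array(X, dtype=np.float64)
        out = np.empty((X.shape[0], 2))
        for start in range(0, X.shape[0], 256):
            xb = X[start:start + 256][:, None, :]
            out[start:start + xb.shape[0]] = softmax(
                self.net_.forward(xb, training=False)
            )
        return out

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]


def _undersample(X, y_idx, rng):
    counts = np.bincount(y_idx)
    n_keep = counts[counts > 0].min()
    keep = []
    for c in range(counts.size):
        members = np.flatnonzero(y_idx == c)
        if members.size > n_keep:
            members = rng.choice(members, size=n_keep, replace=False)
        keep.append(members)
    keep = np.sort(np.concatenate(keep))
    return X[keep], y_idx[keep]
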