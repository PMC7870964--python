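"""Discretized ordinal regression of burned area with a small dense network.

Burned-area fraction in [0, 1] is discretized into 25 ordered classes — a
zero class [0, 1e-6) plus 24 log-equal intervals over [1e-6, 1] — and a
single-hidden-layer network (12 ELU units, softmax output, dropout 0.05)
is trained by categorical cross-entropy to predict class probabilities.
Continuous burned area is reconstructed as the probability-weighted sum of
per-class representative values B_i (the geometric mean of each class's
bounds; the zero class contributes 0). The log binning is the treatment of
the extreme right-skew of the burned-area distribution: no class
reweighting is applied.

Training uses Adam with minibatches and early stopping on validation
cross-entropy, and is bit-reproducible given the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import Standardizer, feature_columns
from .grid import MonthlyField, GridSpec

logger = logging.getLogger(__name__)


class PartitionError(ValueError):
    pass


class TrainingError(RuntimeError):
    pass


@dataclass(frozen=True)
class ClassPartition:
    """Ordered burned-area bins with per-class representative values.

    ``edges`` has length n_classes + 1 with edges[0] = 0, edges[1] = eps,
    edges[-1] = 1, and edges[1:] log-equally spaced over [eps, 1]. Bins are
    left-closed/right-open; the top bin is closed at 1. ``representatives``
    B_i is the geometric mean of each class's bounds, which for the zero
    class [0, eps) is 0.
    """

    n_classes: int
    eps: float
    edges: np.ndarray
    representatives: np.ndarray

    @property
    def B(self) -> np.ndarray:
        return self.representatives


def build_partition(n_classes: int = 25, eps: float = 1e-6) -> ClassPartition:
    """The default discretization: zero class + (n_classes - 1) log bins."""
    if n_classes < 2:
        raise PartitionError("need at least 2 classes")
    if not 0.0 < eps < 1.0:
        raise PartitionError("eps must lie in (0, 1)")
    log_edges = np.logspace(np.log10(eps), 0.0, n_classes)  # eps ... 1
    edges = np.concatenate([[0.0], log_edges])
    reps = np.empty(n_classes)
    reps[0] = 0.0
    reps[1:] = np.sqrt(edges[1:-1] * edges[2:])
    return ClassPartition(n_classes, eps, edges, reps)


def class_of(ba, partition: ClassPartition):
    """1-based class index of each burned-area fraction.

    Bins are [edge_i, edge_{i+1}); ba = 1 falls in the top class.
    """
    arr = np.asarray(ba, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("burned area must lie in [0, 1]")
    idx = np.searchsorted(partition.edges, arr, side="right")
    idx = np.minimum(idx, partition.n_classes)  # ba = 1 -> top class
    return idx if arr.ndim else int(idx)


def elu(x):
    """Exponential linear unit: x for x > 0, exp(x) - 1 otherwise."""
    x = np.asarray(x, dtype=float)
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))


def _elu_grad(x):
    return np.where(x > 0, 1.0, np.exp(np.minimum(x, 0.0)))


def softmax(logits):
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass
class DiscretizedMLP:
    """Single-hidden-layer ELU network with a softmax class head."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray

    @classmethod
    def init(cls, n_in: int, n_hidden: int, n_out: int, rng) -> "DiscretizedMLP":
        lim1 = np.sqrt(6.0 / (n_in + n_hidden))
        lim2 = np.sqrt(6.0 / (n_hidden + n_out))
        return cls(rng.uniform(-lim1, lim1, (n_in, n_hidden)), np.zeros(n_hidden),
                   rng.uniform(-lim2, lim2, (n_hidden, n_out)), np.zeros(n_out))

    @property
    def n_in(self) -> int:
        return self.W1.shape[0]

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities for a batch (or single row) of features."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.n_in:
            raise ValueError(f"expected {self.n_in} features, got {x.shape[1]}")
        h = elu(x @ self.W1 + self.b1)
        return softmax(h @ self.W2 + self.b2)

    def params(self):
        return [self.W1, self.b1, self.W2, self.b2]


def forward(model: DiscretizedMLP, x) -> np.ndarray:
    return model.forward(x)


def expected_ba(probs: np.ndarray, partition: ClassPartition) -> np.ndarray:
    """Reconstruct burned area as sum_i p_i * B_i."""
    p = np.asarray(probs, dtype=float)
    total = p.sum(axis=-1)
    if np.any(np.abs(total - 1.0) > 1e-6):
        raise ValueError("probabilities must sum to 1 (tolerance 1e-6)")
    return p @ partition.representatives


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters and the data-split rule.

    The test set is all rows whose year falls in ``test_years`` (by default
    years 4-6 of the series, resolved at split time); the remaining rows are
    split 70/30 into train/validation at random. Early stopping monitors
    validation cross-entropy with the given patience and minimum
    improvement; the best-validation parameters are returned.
    """

    hidden: int = 12
    dropout: float = 0.05
    train_fraction: float = 0.70
    test_years: tuple | None = None  # None -> years 4-6 of the series
    learning_rate: float = 1e-3
    lr_decay: float = 1.0  # per-epoch multiplicative decay (1.0 = constant)
    lr_min: float = 1e-4
    batch_size: int = 1024
    max_epochs: int = 200
    patience: int = 20
    min_delta: float = 1e-4
    seed: int = 0
    min_train_rows_per_hidden: int = 50

    def resolve_test_years(self, years: np.ndarray) -> tuple:
        if self.test_years is not None:
            return tuple(self.test_years)
        y0 = int(np.min(years))
        return (y0 + 3, y0 + 4, y0 + 5)


def split_samples(df: pd.DataFrame, config: TrainConfig) -> dict:
    """Exhaustive, disjoint train/validation/test row-index split.

    Test = all rows in the test-year window; remaining rows are permuted by
    the config seed and the first round(70%) become training rows.
    """
    years = df["year"].to_numpy()
    test_years = config.resolve_test_years(years)
    is_test = np.isin(years, list(test_years))
    rest = np.flatnonzero(~is_test)
    if is_test.sum() == 0 or len(rest) == 0:
        raise ValueError(
            f"empty split stratum (test years {test_years}, n={len(df)})")
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(rest)
    n_train = int(round(config.train_fraction * len(rest)))
    return {"train": np.sort(perm[:n_train]),
            "validation": np.sort(perm[n_train:]),
            "test": np.flatnonzero(is_test)}


def _cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(probs[np.arange(len(y)), y], 1e-12, None)
    return float(-np.mean(np.log(p)))


def train(x: np.ndarray, y_class: np.ndarray, config: TrainConfig,
          n_classes: int = 25,
          val: tuple | None = None) -> tuple:
    """Fit the network by minibatch Adam on categorical cross-entropy.

    ``y_class`` holds 0-based class indices. ``val`` is an optional
    (x_val, y_val) pair monitored for early stopping; without it the
    training loss is monitored instead. Returns ``(model, history)`` where
    history records per-epoch train/validation cross-entropy and the best
    epoch. Dropout (inverted scaling) is applied to the hidden layer during
    training only.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y_class, dtype=int)
    n, d = x.shape
    if n < config.min_train_rows_per_hidden * config.hidden:
        raise TrainingError(
            f"{n} training rows < {config.min_train_rows_per_hidden} x "
            f"{config.hidden} hidden units; lower min_train_rows_per_hidden "
            "to override")
    rng = np.random.default_rng(config.seed)
    model = DiscretizedMLP.init(d, config.hidden, n_classes, rng)
    adam_m = [np.zeros_like(p) for p in model.params()]
    adam_v = [np.zeros_like(p) for p in model.params()]
    beta1, beta2, eps_adam = 0.9, 0.999, 1e-8
    step = 0

    best_loss = np.inf
    best_params = [p.copy() for p in model.params()]
    best_epoch = -1
    history = {"train_ce": [], "val_ce": []}
    stale = 0

    lr_epoch = config.learning_rate
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = x[idx], y[idx]
            b = len(idx)
            # forward with dropout on the hidden layer
            z1 = xb @ model.W1 + model.b1
            h = elu(z1)
            if config.dropout > 0:
                keep = rng.random(h.shape) >= config.dropout
                h_used = h * keep / (1.0 - config.dropout)
            else:
                keep = None
                h_used = h
            probs = softmax(h_used @ model.W2 + model.b2)
            # backward
            dlogits = probs
            dlogits[np.arange(b), yb] -= 1.0
            dlogits /= b
            gW2 = h_used.T @ dlogits
            gb2 = dlogits.sum(axis=0)
            dh = dlogits @ model.W2.T
            if keep is not None:
                dh = dh * keep / (1.0 - config.dropout)
            dz1 = dh * _elu_grad(z1)
            gW1 = xb.T @ dz1
            gb1 = dz1.sum(axis=0)
            grads = [gW1, gb1, gW2, gb2]
            step += 1
            lr_t = lr_epoch * (
                np.sqrt(1 - beta2 ** step) / (1 - beta1 ** step))
            for p, g, m, v in zip(model.params(), grads, adam_m, adam_v):
                m *= beta1
                m += (1 - beta1) * g
                v *= beta2
                v += (1 - beta2) * g * g
                p -= lr_t * m / (np.sqrt(v) + eps_adam)

        lr_epoch = max(lr_epoch * config.lr_decay, config.lr_min)
        train_ce = _cross_entropy(model.forward(x), y)
        if val is not None:
            monitor = _cross_entropy(model.forward(val[0]), np.asarray(val[1], int))
            history["val_ce"].append(monitor)
        else:
            monitor = train_ce
        history["train_ce"].append(train_ce)
        if not np.isfinite(monitor):
            raise TrainingError(
                f"non-finite loss at epoch {epoch} (train_ce={train_ce})")
        if monitor < best_loss - config.min_delta:
            best_loss = monitor
            best_params = [p.copy() for p in model.params()]
            best_epoch = epoch
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break

    model.W1, model.b1, model.W2, model.b2 = best_params
    history["best_epoch"] = best_epoch
    history["best_loss"] = best_loss
    return model, history


@dataclass
class BurnedAreaModel:
    """A trained model bundle: network, partition, scaling, and features.

    This is the unit that the selection and sensitivity stages pass around:
    it knows how to go from a raw (untransformed-except-log) feature matrix
    to predicted burned-area fractions.
    """

    mlp: DiscretizedMLP
    partition: ClassPartition
    standardizer: Standardizer
    feature_names: list
    region: str = ""
    history: dict = field(default_factory=dict)

    def predict_probs(self, df: pd.DataFrame) -> np.ndarray:
        z = self.standardizer.transform(df[self.feature_names])
        return self.mlp.forward(z.to_numpy(dtype=float))

    def predict_ba(self, df: pd.DataFrame) -> np.ndarray:
        return expected_ba(self.predict_probs(df), self.partition)

    def save(self, path) -> None:
        payload = {
            "schema": "emberfire-model-v1",
            "feature_names": list(self.feature_names),
            "region": self.region,
            "partition": {"n_classes": self.partition.n_classes,
                          "eps": self.partition.eps},
            "standardizer": self.standardizer.to_dict(),
            "weights": {k: getattr(self.mlp, k).tolist()
                        for k in ("W1", "b1", "W2", "b2")},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "BurnedAreaModel":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("schema") != "emberfire-model-v1":
            raise ValueError(f"unrecognized model schema in {path}")
        mlp = DiscretizedMLP(**{k: np.asarray(v, dtype=float)
                                for k, v in payload["weights"].items()})
        part = build_partition(**payload["partition"])
        return cls(mlp, part, Standardizer.from_dict(payload["standardizer"]),
                   payload["feature_names"], payload.get("region", ""))


def fit_burned_area_model(df: pd.DataFrame, split: dict, config: TrainConfig,
                          partition: ClassPartition | None = None,
                          features: list | None = None,
                          region: str = "") -> BurnedAreaModel:
    """Standardize, discretize the target, and train on the given split."""
    partition = partition or build_partition()
    features = list(features or feature_columns(df))
    std = Standardizer().fit(df.iloc[split["train"]], features)
    z = std.transform(df[features]).to_numpy(dtype=float)
    y = np.asarray(class_of(df["ba"].to_numpy(), partition)) - 1  # 0-based
    mlp, history = train(
        z[split["train"]], y[split["train"]], config,
        n_classes=partition.n_classes,
        val=(z[split["validation"]], y[split["validation"]]))
    return BurnedAreaModel(mlp, partition, std, features, region, history)


def predict_field(model: BurnedAreaModel, df: pd.DataFrame,
                  grid: GridSpec, years: np.ndarray,
                  months: np.ndarray) -> MonthlyField:
    """Scatter per-sample predictions back onto the grid.

    Cell-months with no sample stay missing.
    """
    values = np.full((len(years), grid.n_lat, grid.n_lon), np.nan)
    pred = model.predict_ba(df)
    values[df["time_idx"].to_numpy(), df["ilat"].to_numpy(),
           df["ilon"].to_numpy()] = pred
    return MonthlyField(grid, values, years, months, "ba_pred", "fraction")
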