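"""Sequence models over one-hot SMILES and their cross-validated training.

Three architectures are provided, all reading a ``(max_len, vocab)``
one-hot matrix per SMILES variant:

* ``rnn1`` — one recurrent layer (GRU or LSTM), mean-pooled over time,
  linear readout;
* ``rnn2`` — two stacked recurrent layers, same readout;
* ``cnn_rnn`` — a 1-D convolution over the character sequence feeding the
  recurrent layer, then mean pooling, a ReLU dense layer with dropout and
  a linear head.

Training uses Adam with minibatches, an internal validation split for
early stopping and checkpointing, learning-rate decay on validation-loss
plateau, and k-fold cross-validation that partitions *parent molecules*
— every augmented variant of a molecule lands in the same fold, so no
near-duplicate of a test molecule can leak into training. Reported
metrics are computed at molecule level after averaging the scores of a
molecule's variants.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, TrainingError
from .nn.autodiff import Tensor, bce_with_logits_loss, mse_loss
from .nn.layers import Conv1D, Dense, GRULayer, LSTMLayer
from .nn.optim import Adam
from .vectorize import EncodedSample, EncodingSpec

_GRAD_CLIP = 5.0  # global-norm clip; recurrent nets occasionally spike


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``conv_*`` fields are used only by the ``cnn_rnn`` variant.
    """

    variant: str = "cnn_rnn"
    gate: str = "gru"
    conv_kernel: int = 4
    conv_channels: int = 64
    conv_padding: str = "same"
    rnn_hidden: int = 128
    dense_units: int = 128
    dropout_rate: float = 0.2

    def __post_init__(self):
        if self.variant not in ("rnn1", "rnn2", "cnn_rnn"):
            raise ConfigError(f"unknown model variant {self.variant!r}")
        if self.gate not in ("gru", "lstm"):
            raise ConfigError(f"unknown gate {self.gate!r}")
        if min(self.conv_kernel, self.conv_channels, self.rnn_hidden, self.dense_units) <= 0:
            raise ConfigError("all layer sizes must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise ConfigError("dropout_rate must be in [0, 1)")


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol: epochs, batching, optimization and CV layout."""

    epochs: int = 200
    batch_size: int = 64
    learning_rate: float = 1e-3
    lr_decay: float = 0.5  # multiplier applied on validation plateau; 0 disables
    lr_decay_patience: int = 10
    n_folds: int = 5
    early_stopping_patience: int = 20
    val_fraction: float = 0.1
    seed: int = 0
    task: str = "regression"
    aggregate_variants: bool = True  # average all test variants vs canonical-only

    def __post_init__(self):
        if self.n_folds < 2:
            raise ConfigError("n_folds must be >= 2")
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")
        if self.task not in ("regression", "classification"):
            raise ConfigError(f"unknown task {self.task!r}")


@dataclass
class EncodedDataset:
    """Dense tensor view of an encoded (augmented) dataset."""

    X: np.ndarray  # (n_samples, max_len, vocab)
    y: np.ndarray  # (n_samples, n_outputs), NaN = missing
    parent_ids: np.ndarray  # (n_samples,)
    variant_index: np.ndarray  # (n_samples,)
    label_names: list[str]

    @classmethod
    def from_samples(cls, samples: list[EncodedSample]) -> "EncodedDataset":
        if not samples:
            raise ConfigError("empty sample list")
        label_names = sorted(samples[0].labels)
        return cls(
            X=np.stack([s.matrix for s in samples]).astype(np.float64),
            y=np.array([[s.labels[n] for n in label_names] for s in samples]),
            parent_ids=np.array([s.parent_id for s in samples]),
            variant_index=np.array([s.variant_index for s in samples]),
            label_names=label_names,
        )

    def subset(self, mask: np.ndarray) -> "EncodedDataset":
        return EncodedDataset(
            self.X[mask], self.y[mask], self.parent_ids[mask],
            self.variant_index[mask], self.label_names,
        )


class SequenceNet:
    """An untrained network; predictions are a pure function of weights and input."""

    def __init__(
        self,
        config: ModelConfig,
        input_shape: tuple[int, int],
        n_outputs: int,
        task: str,
        seed: int = 0,
    ):
        if n_outputs < 1:
            raise ConfigError("n_outputs must be >= 1")
        self.config = config
        self.input_shape = input_shape
        self.n_outputs = n_outputs
        self.task = task
        rng = np.random.default_rng([seed, 0x5EED])
        max_len, vocab = input_shape
        gate_cls = GRULayer if config.gate == "gru" else LSTMLayer

        self.conv = None
        rnn_in = vocab
        if config.variant == "cnn_rnn":
            self.conv = Conv1D(rng, vocab, config.conv_channels,
                               config.conv_kernel, config.conv_padding)
            rnn_in = config.conv_channels
        self.rnn_layers = [gate_cls(rng, rnn_in, config.rnn_hidden)]
        if config.variant == "rnn2":
            self.rnn_layers.append(gate_cls(rng, config.rnn_hidden, config.rnn_hidden))
        self.dense = None
        head_in = config.rnn_hidden
        if config.variant == "cnn_rnn":
            self.dense = Dense(rng, config.rnn_hidden, config.dense_units)
            head_in = config.dense_units
        self.head = Dense(rng, head_in, n_outputs)

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        if self.conv is not None:
            params += self.conv.parameters()
        for layer in self.rnn_layers:
            params += layer.parameters()
        if self.dense is not None:
            params += self.dense.parameters()
        params += self.head.parameters()
        return params

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def forward(
        self,
        X: np.ndarray,
        train: bool = False,
        dropout_rng: np.random.Generator | None = None,
    ) -> Tensor:
        """Logits (regression: raw outputs) of shape (n_batch, n_outputs)."""
        x = Tensor(X)
        if self.conv is not None:
            x = self.conv(x).relu()
        first = self.rnn_layers[0]
        projected = first.project_inputs(x)
        t_steps = projected.data.shape[1]
        states = [layer.initial_state(X.shape[0]) for layer in self.rnn_layers]
        pooled_sum = None
        for t in range(t_steps):
            h, states[0] = first.step(projected[:, t, :], states[0])
            for i, layer in enumerate(self.rnn_layers[1:], start=1):
                xp_t = h @ layer.w_in + layer.bias
                h, states[i] = layer.step(xp_t, states[i])
            pooled_sum = h if pooled_sum is None else pooled_sum + h
        pooled = pooled_sum * (1.0 / t_steps)
        if self.dense is not None:
            pooled = self.dense(pooled).relu()
            if train and self.config.dropout_rate > 0:
                if dropout_rng is None:
                    raise TrainingError("dropout requires a random generator in training mode")
                keep = 1.0 - self.config.dropout_rate
                mask = (dropout_rng.random(pooled.data.shape) < keep) / keep
                pooled = pooled * mask
        return self.head(pooled)

    def get_weights(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.parameters(), weights, strict=True):
            p.data[...] = w


def build_model(
    model_config: ModelConfig,
    input_shape: tuple[int, int],
    n_outputs: int,
    task: str,
    seed: int = 0,
) -> SequenceNet:
    """Construct an untrained network for the given encoding shape."""
    return SequenceNet(model_config, input_shape, n_outputs, task, seed)


@dataclass
class TrainedModel:
    """Checkpointed weights plus everything needed to reproduce predictions."""

    weights: list[np.ndarray]
    model_config: ModelConfig
    task: str
    n_outputs: int
    input_shape: tuple[int, int]
    y_mean: np.ndarray
    y_scale: np.ndarray
    encoding_spec: EncodingSpec | None = None
    history: pd.DataFrame | None = None

    def _net(self) -> SequenceNet:
        net = SequenceNet(self.model_config, self.input_shape, self.n_outputs, self.task)
        net.set_weights(self.weights)
        return net


def predict(model: TrainedModel, samples: "EncodedDataset | list[EncodedSample] | np.ndarray",
            batch_size: int = 256) -> np.ndarray:
    """Per-sample scores: probabilities in [0, 1] for classification,
    label-scale values for regression."""
    if isinstance(samples, EncodedDataset):
        X = samples.X
    elif isinstance(samples, np.ndarray):
        X = samples
    else:
        X = np.stack([s.matrix for s in samples]).astype(np.float64)
    if X.shape[1:] != model.input_shape:
        raise ConfigError(
            f"input shape {X.shape[1:]} does not match the model's encoding "
            f"spec {model.input_shape}"
        )
    net = model._net()
    chunks = []
    for start in range(0, X.shape[0], batch_size):
        out = net.forward(X[start : start + batch_size]).data
        chunks.append(out)
    raw = np.concatenate(chunks)
    if model.task == "classification":
        return 1.0 / (1.0 + np.exp(-raw))
    return model.y_mean + model.y_scale * raw


def aggregate_by_molecule(
    parent_ids: np.ndarray, scores: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Mean score over each molecule's variants.

    Returns (sorted unique parent ids, per-molecule mean scores).
    """
    parent_ids = np.asarray(parent_ids)
    scores = np.asarray(scores)
    if parent_ids.size == 0:
        raise ConfigError("aggregate_by_molecule called with no samples")
    frame = pd.DataFrame(scores.reshape(scores.shape[0], -1))
    frame["parent_id"] = parent_ids
    grouped = frame.groupby("parent_id", sort=True).mean()
    return grouped.index.to_numpy(), grouped.to_numpy()


def _clip_gradients(params: list[Tensor]) -> None:
    total = math.sqrt(sum(float((p.grad**2).sum()) for p in params if p.grad is not None))
    if total > _GRAD_CLIP:
        scale = _GRAD_CLIP / total
        for p in params:
            if p.grad is not None:
                p.grad *= scale


def _fit_one(
    net: SequenceNet,
    train: EncodedDataset,
    val: EncodedDataset,
    config: TrainConfig,
    rng: np.random.Generator,
) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Minibatch Adam with early stopping; returns best weights + history."""
    params = net.parameters()
    optimizer = Adam(params, config.learning_rate)
    loss_fn = mse_loss if config.task == "regression" else bce_with_logits_loss
    best_val = math.inf
    best_weights = net.get_weights()
    since_best = 0
    since_decay = 0
    history = []
    n = train.X.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            y = train.y[idx]
            mask = ~np.isnan(y)
            if not mask.any():
                continue
            logits = net.forward(train.X[idx], train=True, dropout_rng=rng)
            loss = loss_fn(logits, np.nan_to_num(y), mask)
            if not math.isfinite(loss.data):
                raise TrainingError(
                    f"non-finite training loss at epoch {epoch}: {loss.data}"
                )
            optimizer.zero_grad()
            loss.backward()
            _clip_gradients(params)
            optimizer.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        val_mask = ~np.isnan(val.y)
        val_logits = net.forward(val.X).data
        val_loss = float(
            loss_fn(Tensor(val_logits), np.nan_to_num(val.y), val_mask).data
        )
        if not math.isfinite(val_loss):
            raise TrainingError(f"non-finite validation loss at epoch {epoch}")
        history.append(
            {"epoch": epoch, "train_loss": epoch_loss / max(n_batches, 1),
             "val_loss": val_loss, "learning_rate": optimizer.learning_rate}
        )
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_weights = net.get_weights()
            since_best = 0
            since_decay = 0
        else:
            since_best += 1
            since_decay += 1
            if config.lr_decay > 0 and since_decay >= config.lr_decay_patience:
                optimizer.learning_rate *= config.lr_decay
                since_decay = 0
            if since_best >= config.early_stopping_patience:
                break
    return best_weights, pd.DataFrame(history)


def make_folds(
    parent_ids: np.ndarray, n_folds: int, seed: int
) -> list[np.ndarray]:
    """Partition unique parent molecules into shuffled folds."""
    parents = np.unique(parent_ids)
    if parents.size < n_folds:
        raise ConfigError(
            f"{parents.size} distinct molecules cannot fill {n_folds} folds"
        )
    rng = np.random.default_rng([seed, 0xF01D])
    return np.array_split(rng.permutation(parents), n_folds)


@dataclass
class FoldRun:
    """Everything produced by one CV fold."""

    fold_index: int
    model: TrainedModel
    metrics: dict[str, float]
    n_test_molecules: int
    test_parent_ids: np.ndarray
    test_scores: np.ndarray  # per-molecule, aggregated
    test_targets: np.ndarray  # per-molecule


def train_cv(
    dataset: EncodedDataset,
    model_config: ModelConfig,
    train_config: TrainConfig,
    encoding_spec: EncodingSpec | None = None,
) -> list[FoldRun]:
    """K-fold cross-validation grouped by parent molecule.

    Within each fold the held-in parents are further split into a
    training part and an internal validation part used for early
    stopping/checkpointing; the checkpointed best-validation weights are
    restored before scoring the test fold. Metrics are molecule-level:
    test variant scores are averaged per molecule first (or only the
    canonical variant is scored when ``aggregate_variants`` is off).
    """
    from . import evaluate  # local import to avoid a cycle

    folds = make_folds(dataset.parent_ids, train_config.n_folds, train_config.seed)
    runs: list[FoldRun] = []
    for fold_index, test_parents in enumerate(folds):
        rng = np.random.default_rng([train_config.seed, 0xC5, fold_index])
        test_mask = np.isin(dataset.parent_ids, test_parents)
        held_in = np.unique(dataset.parent_ids[~test_mask])
        held_in = rng.permutation(held_in)
        n_val = max(1, int(round(train_config.val_fraction * held_in.size)))
        if held_in.size - n_val < 1:
            raise ConfigError("not enough molecules for a train/validation split")
        val_parents, train_parents = held_in[:n_val], held_in[n_val:]
        train_set = dataset.subset(np.isin(dataset.parent_ids, train_parents))
        val_set = dataset.subset(np.isin(dataset.parent_ids, val_parents))
        test_set = dataset.subset(test_mask)

        y_mean = np.zeros(dataset.y.shape[1])
        y_scale = np.ones(dataset.y.shape[1])
        if train_config.task == "regression":
            y_mean = np.nanmean(train_set.y, axis=0)
            y_scale = np.nanstd(train_set.y, axis=0)
            y_scale[y_scale == 0] = 1.0
        train_scaled = EncodedDataset(
            train_set.X, (train_set.y - y_mean) / y_scale,
            train_set.parent_ids, train_set.variant_index, train_set.label_names,
        )
        val_scaled = EncodedDataset(
            val_set.X, (val_set.y - y_mean) / y_scale,
            val_set.parent_ids, val_set.variant_index, val_set.label_names,
        )

        net = SequenceNet(
            model_config, dataset.X.shape[1:], dataset.y.shape[1],
            train_config.task, seed=train_config.seed * 1000 + fold_index,
        )
        weights, history = _fit_one(net, train_scaled, val_scaled, train_config, rng)
        trained = TrainedModel(
            weights=weights, model_config=model_config, task=train_config.task,
            n_outputs=dataset.y.shape[1], input_shape=dataset.X.shape[1:],
            y_mean=y_mean, y_scale=y_scale, encoding_spec=encoding_spec,
            history=history,
        )

        if not train_config.aggregate_variants:
            test_set = test_set.subset(test_set.variant_index == 0)
        scores = predict(trained, test_set)
        parents, mol_scores = aggregate_by_molecule(test_set.parent_ids, scores)
        _, mol_targets = aggregate_by_molecule(test_set.parent_ids, test_set.y)
        metrics = evaluate.compute_metrics(
            mol_targets, mol_scores, train_config.task
        )
        runs.append(
            FoldRun(
                fold_index=fold_index, model=trained, metrics=metrics,
                n_test_molecules=parents.size, test_parent_ids=parents,
                test_scores=mol_scores, test_targets=mol_targets,
            )
        )
    return runs


def save_model(model: TrainedModel, directory: str | Path) -> None:
    """Serialize weights (npz) plus model/encoding JSON sidecars."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "weights.npz", *model.weights)
    meta = {
        "model_config": asdict(model.model_config),
        "task": model.task,
        "n_outputs": model.n_outputs,
        "input_shape": list(model.input_shape),
        "y_mean": model.y_mean.tolist(),
        "y_scale": model.y_scale.tolist(),
    }
    (directory / "model.json").write_text(json.dumps(meta, indent=2))
    if model.encoding_spec is not None:
        (directory / "encoding.json").write_text(model.encoding_spec.to_json())
    if model.history is not None:
        model.history.to_csv(directory / "history.csv", index=False)


def load_model(directory: str | Path) -> TrainedModel:
    directory = Path(directory)
    meta = json.loads((directory / "model.json").read_text())
    archive = np.load(directory / "weights.npz")
    weights = [archive[k] for k in archive.files]
    spec_path = directory / "encoding.json"
    history_path = directory / "history.csv"
    return TrainedModel(
        weights=weights,
        model_config=ModelConfig(**meta["model_config"]),
        task=meta["task"],
        n_outputs=meta["n_outputs"],
        input_shape=tuple(meta["input_shape"]),
        y_mean=np.array(meta["y_mean"]),
        y_scale=np.array(meta["y_scale"]),
        encoding_spec=EncodingSpec.from_json(spec_path.read_text()) if spec_path.exists() else None,
        history=pd.read_csv(history_path) if history_path.exists() else None,
    )
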