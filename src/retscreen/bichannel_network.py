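"""The bichannel convolutional classifier for referable retinopathy.

Two parallel convolutional stacks — one per preprocessed input (the
unit-scaled entropy image of the UM-sharpened gray level, and of the
UM-sharpened green component) — each built from four blocks of

    conv 5x5 (same) -> ReLU -> max-pool 2x2 -> dropout 0.3

with 32, 64, 64 and 128 filters by default.  The two stacks are flattened,
concatenated and fed through a hidden dense layer to a single sigmoid unit;
training minimizes binary cross-entropy with Adam (default learning rate
1e-4).  A single-branch configuration (``branches=("green",)``) gives the
single-channel ablations.

Kaggle-scale defaults are kept for fidelity; the synthetic phantom
benchmark in this package runs a narrower configuration (see
``benchmark_config``) sized for a single CPU core.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn
from .errors import ConfigError, DataError

__all__ = [
    "ModelConfig",
    "TrainedModel",
    "build_model",
    "train",
    "predict",
    "evaluate_loss",
    "save_model",
    "load_model",
    "benchmark_config",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training hyperparameters.

    input_side : side of the square single-plane inputs (pixels).
    conv_filters : filters per conv block in each stack.
    kernel_side : conv kernel side (5).
    dropout : dropout rate after every pool stage and the hidden dense layer.
    dense_units : hidden dense widths before the sigmoid output unit.
    branches : names of the input stacks, e.g. ("gray", "green").
    """

    input_side: int = 100
    conv_filters: tuple[int, ...] = (32, 64, 64, 128)
    kernel_side: int = 5
    dropout: float = 0.3
    dense_units: tuple[int, ...] = (128,)
    learning_rate: float = 1e-4
    batch_size: int = 64
    epochs: int = 50
    seed: int = 0
    branches: tuple[str, ...] = ("gray", "green")

    def __post_init__(self) -> None:
        if not self.conv_filters:
            raise ConfigError("need at least one conv block")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigError(f"dropout must be in [0, 1), got {self.dropout}")
        if self.learning_rate <= 0:
            raise ConfigError("learning rate must be > 0")
        if not self.branches:
            raise ConfigError("need at least one branch")
        if self.input_side < 2 ** len(self.conv_filters):
            raise ConfigError(
                f"input side {self.input_side} too small for "
                f"{len(self.conv_filters)} pooling stages"
            )

    @property
    def feature_side(self) -> int:
        side = self.input_side
        for _ in self.conv_filters:
            side //= 2
        return side

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for key in ("conv_filters", "dense_units", "branches"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def benchmark_config(branches=("gray", "green"), seed: int = 0, epochs: int = 15,
                     input_side: int = 50) -> ModelConfig:
    """Narrow configuration used for the synthetic phantom benchmark.

    Same architecture shape as the default (four conv 5x5 / ReLU / max-pool
    blocks per stack) with fewer filters, 2x2-mean-pooled 50x50 inputs, no
    dropout and a higher learning rate — a capacity and schedule sized for a
    2,000-image corpus and minutes of single-core training, where the
    regularization the full-scale configuration needs would only slow
    convergence.  The hidden dense width scales with the number of input
    stacks so the fused model's head is not bottlenecked relative to the
    single-channel ablations.
    """
    return ModelConfig(
        input_side=input_side,
        conv_filters=(4, 8, 8, 16),
        dense_units=(32 * len(branches),),
        dropout=0.0,
        learning_rate=2e-3,
        batch_size=32,
        epochs=epochs,
        seed=seed,
        branches=tuple(branches),
    )


class TrainedModel:
    """Parameter store + config snapshot + per-epoch training history."""

    def __init__(self, config: ModelConfig):
        self.config = config
        init_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
        self._train_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
        k = config.kernel_side
        self.stacks: list[nn.Sequential] = []
        for _ in config.branches:
            layers: list[nn.Layer] = []
            c_in = 1
            for i, c_out in enumerate(config.conv_filters):
                layers += [
                    nn.Conv2dSame(c_in, c_out, k, init_rng, input_layer=(i == 0)),
                    nn.ReLU(),
                    nn.MaxPool2(),
                    nn.Dropout(config.dropout, self._train_rng),
                ]
                c_in = c_out
            layers.append(nn.Flatten())
            self.stacks.append(nn.Sequential(layers))

        feat = config.conv_filters[-1] * config.feature_side**2 * len(config.branches)
        head_layers: list[nn.Layer] = []
        for units in config.dense_units:
            head_layers += [
                nn.Dense(feat, units, init_rng),
                nn.ReLU(),
                nn.Dropout(config.dropout, self._train_rng),
            ]
            feat = units
        head_layers.append(nn.Dense(feat, 1, init_rng, relu_follows=False))
        self.head = nn.Sequential(head_layers)
        self.history: list[dict] = []

    # -- parameter plumbing -------------------------------------------------
    def parameters(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for stack in self.stacks:
            out.extend(stack.parameters())
        out.extend(self.head.parameters())
        return out

    def gradients(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for stack in self.stacks:
            out.extend(stack.gradients())
        out.extend(self.head.gradients())
        return out

    # -- forward/backward ---------------------------------------------------
    def _check_inputs(self, inputs: list[np.ndarray]) -> list[np.ndarray]:
        if len(inputs) != len(self.config.branches):
            raise DataError(
                f"model has {len(self.config.branches)} input branches, "
                f"got {len(inputs)} arrays"
            )
        side = self.config.input_side
        arrays = []
        n = None
        for name, arr in zip(self.config.branches, inputs):
            arr = np.asarray(arr, dtype=np.float32)
            if arr.ndim == 3:
                arr = arr[:, :, :, None]  # single plane -> channels-last
            if arr.ndim != 4 or arr.shape[3] != 1 or arr.shape[1:3] != (side, side):
                raise DataError(
                    f"branch {name!r}: expected (N, {side}, {side}) inputs, "
                    f"got shape {arr.shape}"
                )
            if n is None:
                n = arr.shape[0]
            elif arr.shape[0] != n:
                raise DataError("branches disagree on batch size")
            arrays.append(arr)
        return arrays

    def forward_logits(self, inputs: list[np.ndarray], train: bool = False) -> np.ndarray:
        arrays = self._check_inputs(inputs)
        feats = [
            stack.forward(arr, train) for stack, arr in zip(self.stacks, arrays)
        ]
        self._feat_widths = [f.shape[1] for f in feats]
        return self.head.forward(np.concatenate(feats, axis=1), train)

    def backward(self, dlogits: np.ndarray) -> None:
        dfeat = self.head.backward(dlogits)
        offset = 0
        for stack, width in zip(self.stacks, self._feat_widths):
            stack.backward(dfeat[:, offset : offset + width])
            offset += width


def build_model(config: ModelConfig) -> TrainedModel:
    """Seeded, untrained model; identical seeds give bit-identical parameters."""
    return TrainedModel(config)


def _as_labels(labels) -> np.ndarray:
    y = np.asarray(labels).astype(np.float64).ravel()
    if y.size and not np.isin(y, (0.0, 1.0)).all():
        raise DataError("labels must be binary 0/1")
    return y


def evaluate_loss(model: TrainedModel, inputs: list[np.ndarray], labels) -> tuple[float, float]:
    """Mean BCE loss and accuracy at threshold 0.5, in evaluation mode."""
    y = _as_labels(labels)
    probs = predict(model, inputs)
    eps = 1e-12
    loss = float(-np.mean(y * np.log(probs + eps) + (1 - y) * np.log(1 - probs + eps)))
    acc = float(np.mean((probs >= 0.5) == (y == 1.0)))
    return loss, acc


def train(
    model: TrainedModel,
    inputs: list[np.ndarray],
    labels,
    epochs: int | None = None,
    validation: tuple[list[np.ndarray], np.ndarray] | None = None,
    verbose: bool = False,
) -> TrainedModel:
    """Minimize binary cross-entropy with Adam; one history row per epoch.

    ``inputs`` is one ``(N, side, side)`` array per branch, unit-scaled;
    ``labels`` the binary referable flags.  Deterministic given the config
    seed (and a fixed BLAS thread count).
    """
    arrays = model._check_inputs(inputs)
    y = _as_labels(labels)
    n = arrays[0].shape[0]
    if y.size != n:
        raise DataError(f"{n} input pairs but {y.size} labels")
    n_epochs = model.config.epochs if epochs is None else epochs
    if n_epochs == 0:
        return model

    opt = model._opt if getattr(model, "_opt", None) else nn.Adam(
        model.parameters(), lr=model.config.learning_rate
    )
    model._opt = opt
    bs = model.config.batch_size
    rng = model._train_rng

    for epoch in range(n_epochs):
        order = rng.permutation(n)
        losses = []
        correct = 0
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            batch = [arr[idx] for arr in arrays]
            logits = model.forward_logits(batch, train=True)
            loss, dlogits = nn.bce_with_logits(logits, y[idx])
            model.backward(dlogits)
            opt.step(model.gradients())
            losses.append(loss * idx.size)
            correct += int(((logits.ravel() >= 0) == (y[idx] == 1.0)).sum())
        row = {
            "epoch": len(model.history) + 1,
            "loss": float(np.sum(losses) / n),
            "acc": correct / n,
        }
        if validation is not None:
            val_loss, val_acc = evaluate_loss(model, validation[0], validation[1])
            row["val_loss"], row["val_acc"] = val_loss, val_acc
        model.history.append(row)
        if verbose:
            print(
                "epoch {epoch}: loss={loss:.4f} acc={acc:.4f}".format(**row)
                + (f" val_acc={row['val_acc']:.4f}" if "val_acc" in row else "")
            )
    return model


def predict(model: TrainedModel, inputs: list[np.ndarray], batch_size: int = 256) -> np.ndarray:
    """Referable probability per input pair (evaluation mode, dropout off)."""
    arrays = model._check_inputs(inputs)
    n = arrays[0].shape[0]
    probs = np.empty(n, dtype=np.float64)
    for start in range(0, n, batch_size):
        batch = [arr[start : start + batch_size] for arr in arrays]
        logits = model.forward_logits(batch, train=False)
        probs[start : start + batch_size] = nn.sigmoid(logits.ravel())
    return probs


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Checkpoint: parameters as an .npz archive, config + history as JSON."""
    arrays = {f"param_{i}": p for i, p in enumerate(model.parameters())}
    arrays["config_json"] = np.frombuffer(
        json.dumps({"config": model.config.to_dict(), "history": model.history}).encode(),
        dtype=np.uint8,
    )
    np.savez(Path(path), **arrays)


def load_model(path: str | Path) -> TrainedModel:
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["config_json"].tobytes()).decode())
        model = build_model(ModelConfig.from_dict(meta["config"]))
        model.history = meta["history"]
        for i, p in enumerate(model.parameters()):
            p[...] = data[f"param_{i}"]
    return model


def history_to_csv(model: TrainedModel, path: str | Path) -> None:
    import csv

    keys = ["epoch", "loss", "acc", "val_loss", "val_acc"]
    with open(Path(path), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(keys)
        for row in model.history:
            writer.writerow([row.get(k, "") for k in keys])
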