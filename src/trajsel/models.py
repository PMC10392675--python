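"""Network architectures, training regimes and evaluation.

Four fixed layer stacks are provided, each with its published training
regime (optimizer, learning rate, epochs, batch size, loss):

=================  ==========================================================
cnn1d              Conv1D(16, k7) > MaxPool(5) > Conv1D(16, k7) >
                   GlobalMaxPool > Dense(1, sigmoid); RMSprop 1e-4,
                   10 epochs, batch 8, binary cross-entropy.
cnn2d              Conv2D(8, 1x5) > MaxPool(1x3) > Dropout(0.3) >
                   Conv2D(4, 1x5) > MaxPool(1x3) > Flatten >
                   Dense(1, sigmoid); RMSprop 1e-4, 20 epochs, batch 16.
                   The height-1 kernels never mix descriptor channels.
cnn2d_cam          Conv2D(3x3: 128, 64, 32, 16), each followed by
                   MaxPool(2x2), then Flatten > Dense(256) >
                   Dense(1, sigmoid); RMSprop 1e-4, 20 epochs, batch 1.
lstm_forecaster    LSTM(16, tanh) > LSTM(8, tanh) > Dense(1, linear);
                   Adam 0.01, 5 epochs, batch 128, mean squared error.
=================  ==========================================================

All convolutions are valid (no padding); with the default input sizes the
intermediate lengths are 1000>994>198>192>16 (cnn1d), time widths
996>332>328>109 with flatten length 6,540 (cnn2d), and spatial sizes
318>159>157>78>76>38>36>18 with a final 18x18x16 feature map (cnn2d_cam).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import json

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .data import DatasetBundle, ForecastWindowSet, to_signal_batch, to_matrix_image_batch
from .errors import ConfigurationError
from .featurize import Normalizer
from .nn import (
    DTYPE,
    Conv1D,
    Conv2D,
    Dense,
    Dropout,
    Flatten,
    GlobalMaxPool1D,
    LSTM,
    MaxPool1D,
    MaxPool2D,
    Sequential,
    Sigmoid,
    binary_cross_entropy,
    make_optimizer,
)

_REGIMES = {
    "cnn1d": dict(optimizer="rmsprop", lr=1e-4, epochs=10, batch_size=8, loss="bce"),
    "cnn2d": dict(optimizer="rmsprop", lr=1e-4, epochs=20, batch_size=16, loss="bce"),
    "cnn2d_cam": dict(optimizer="rmsprop", lr=1e-4, epochs=20, batch_size=1, loss="bce"),
    "lstm_forecaster": dict(optimizer="adam", lr=0.01, epochs=5, batch_size=128, loss="mse"),
    "baseline": dict(optimizer="rmsprop", lr=0.0, epochs=0, batch_size=128, loss="mse"),
    "linear": dict(optimizer="adam", lr=0.01, epochs=5, batch_size=128, loss="mse"),
    "dense": dict(optimizer="adam", lr=0.01, epochs=5, batch_size=128, loss="mse"),
    "cnn1d_forecaster": dict(optimizer="adam", lr=0.01, epochs=5, batch_size=128, loss="mse"),
    "embedding_classifier": dict(optimizer="rmsprop", lr=1e-3, epochs=20, batch_size=32, loss="bce"),
}


@dataclass
class ArchitectureSpec:
    """Architecture id plus its training configuration."""

    arch: str
    optimizer: str
    lr: float
    epochs: int
    batch_size: int
    loss: str
    seed: int = 0
    threshold: float = 0.5

    @classmethod
    def default(cls, arch: str, seed: int = 0, **overrides) -> "ArchitectureSpec":
        if arch not in _REGIMES:
            raise ConfigurationError(f"unknown architecture {arch!r}")
        params = dict(_REGIMES[arch])
        params.update(overrides)
        return cls(arch=arch, seed=seed, **params)


@dataclass
class TrainedModel:
    spec: ArchitectureSpec
    model: Sequential
    history: dict
    normalizer: Normalizer | None = None

    def predict_proba(self, x) -> np.ndarray:
        return self.model.predict(x)[:, 0]

    def predict_label(self, x) -> np.ndarray:
        return (self.predict_proba(x) >= self.spec.threshold).astype(np.int8)


@dataclass
class EvalReport:
    accuracy: float
    roc_auc: float
    loss: float
    confusion: dict
    per_ligand: pd.DataFrame  # misclassified counts per ligand, split by true class
    n: int

    def to_json(self) -> str:
        d = {
            "accuracy": self.accuracy,
            "roc_auc": self.roc_auc,
            "loss": self.loss,
            "confusion": self.confusion,
            "n": self.n,
            "per_ligand": self.per_ligand.to_dict(orient="list"),
        }
        return json.dumps(d, indent=2)


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------


def build_cnn1d(n_frames: int = 1000, n_channels: int = 15, seed: int = 0) -> Sequential:
    """Binary classifier over the (T, D) multichannel signal."""
    model = Sequential(
        [
            Conv1D(16, 7, activation="relu"),
            MaxPool1D(5),
            Conv1D(16, 7, activation="relu"),
            GlobalMaxPool1D(),
            Dense(1, activation=None),
            Sigmoid(),
        ]
    )
    return model.build((n_frames, n_channels), seed=seed)


def build_cnn2d(n_frames: int = 1000, n_channels: int = 15, seed: int = 0) -> Sequential:
    """Binary classifier over the (D, T, 1) matrix image; kernels never mix channels."""
    model = Sequential(
        [
            Conv2D(8, (1, 5), activation="relu"),
            MaxPool2D((1, 3)),
            Dropout(0.3),
            Conv2D(4, (1, 5), activation="relu"),
            MaxPool2D((1, 3)),
            Flatten(),
            Dense(1, activation=None),
            Sigmoid(),
        ]
    )
    return model.build((n_channels, n_frames, 1), seed=seed)


def build_cnn2d_cam(input_size: int = 320, seed: int = 0) -> Sequential:
    """Overparameterised image classifier used for class-activation mapping."""
    model = Sequential(
        [
            Conv2D(128, (3, 3), activation="relu"),
            MaxPool2D((2, 2)),
            Conv2D(64, (3, 3), activation="relu"),
            MaxPool2D((2, 2)),
            Conv2D(32, (3, 3), activation="relu"),
            MaxPool2D((2, 2)),
            Conv2D(16, (3, 3), activation="relu"),
            MaxPool2D((2, 2)),
            Flatten(),
            Dense(256, activation="relu"),
            Dense(1, activation=None),
            Sigmoid(),
        ]
    )
    return model.build((input_size, input_size, 1), seed=seed)


def build_lstm_forecaster(window: int = 50, n_channels: int = 15, seed: int = 0) -> Sequential:
    """Next-step regressor; the second LSTM's final state is the 8-d window embedding."""
    model = Sequential(
        [
            LSTM(16, return_sequences=True),
            LSTM(8, return_sequences=False),
            Dense(1, activation=None),
        ]
    )
    return model.build((window, n_channels), seed=seed)


class LastValueBaseline:
    """Persistence forecaster: predict the query channel's last observed value."""

    def __init__(self, query_channel: int):
        self.query_channel = query_channel

    def fit(self, *args, **kwargs):
        return {"loss": []}

    def predict(self, x, batch_size=None) -> np.ndarray:
        return np.asarray(x)[:, -1, self.query_channel][:, None]


def build_forecast_baselines(
    window: int = 50, n_channels: int = 15, query_channel: int = 3, seed: int = 0
) -> dict:
    """Reference forecasters: persistence, affine, one-hidden-layer, temporal conv."""
    linear = Sequential([Flatten(), Dense(1, activation=None)]).build(
        (window, n_channels), seed=seed
    )
    dense = Sequential(
        [Flatten(), Dense(64, activation="relu"), Dense(1, activation=None)]
    ).build((window, n_channels), seed=seed + 1)
    cnn = Sequential(
        [Conv1D(16, 7, activation="relu"), GlobalMaxPool1D(), Dense(1, activation=None)]
    ).build((window, n_channels), seed=seed + 2)
    return {
        "baseline": LastValueBaseline(query_channel),
        "linear": linear,
        "dense": dense,
        "cnn1d_forecaster": cnn,
    }


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _classifier_inputs(bundle: DatasetBundle, arch: str, split: str):
    if arch == "cnn2d":
        return to_matrix_image_batch(bundle, split)
    return to_signal_batch(bundle, split)


def train_classifier(
    model: Sequential,
    bundle: DatasetBundle,
    spec: ArchitectureSpec,
    channels: list[int] | None = None,
    verbose: int = 0,
) -> TrainedModel:
    """Train a classifier on the training split; validation is never touched.

    ``channels`` restricts the input to a channel subset (used by the
    single-channel ablation protocol).
    """
    if bundle.normalizer is None:
        bundle.fit_normalizer()
    x = _classifier_inputs(bundle, spec.arch, "train")
    if channels is not None:
        x = x[:, :, channels] if spec.arch != "cnn2d" else x[:, channels]
    y = bundle.labels[bundle.indices("train")]
    history = model.fit(
        x.astype(DTYPE),
        y,
        epochs=spec.epochs,
        batch_size=spec.batch_size,
        loss=spec.loss,
        optimizer=make_optimizer(spec.optimizer, spec.lr),
        seed=spec.seed,
        verbose=verbose,
    )
    return TrainedModel(spec=spec, model=model, history=history, normalizer=bundle.normalizer)


def train_forecaster(
    model: Sequential, windows: ForecastWindowSet, spec: ArchitectureSpec, verbose: int = 0
) -> TrainedModel:
    """Train a next-step forecaster on a window set (MSE loss)."""
    if isinstance(model, LastValueBaseline):
        return TrainedModel(spec=spec, model=model, history={"loss": []})
    if model.input_shape != windows.inputs.shape[1:]:
        raise ConfigurationError(
            f"window shape {windows.inputs.shape[1:]} does not match model "
            f"input {model.input_shape}"
        )
    history = model.fit(
        windows.inputs,
        windows.targets,
        epochs=spec.epochs,
        batch_size=spec.batch_size,
        loss="mse",
        optimizer=make_optimizer(spec.optimizer, spec.lr),
        seed=spec.seed,
        verbose=verbose,
    )
    return TrainedModel(spec=spec, model=model, history=history)


def forecast_mse(model, windows: ForecastWindowSet) -> float:
    pred = model.predict(windows.inputs)[:, 0]
    return float(np.mean((pred - windows.targets) ** 2))


def embed_windows(trained: TrainedModel, windows: ForecastWindowSet) -> np.ndarray:
    """8-d embedding per window: final-step state of the second LSTM layer."""
    return trained.model.forward_to(windows.inputs, 1)


def trajectory_embeddings(
    trained: TrainedModel, windows: ForecastWindowSet
) -> tuple[np.ndarray, np.ndarray]:
    """Mean per-trajectory embedding and the matching labels."""
    emb = embed_windows(trained, windows)
    traj = windows.traj_index
    uniq = np.unique(traj)
    out = np.stack([emb[traj == u].mean(axis=0) for u in uniq])
    labels = np.array([windows.labels[traj == u][0] for u in uniq])
    return out, labels


def classify_from_embeddings(
    embeddings: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    validation_data: tuple | None = None,
    **overrides,
) -> tuple[TrainedModel, dict]:
    """Single dense sigmoid head on fixed embeddings (binary cross-entropy).

    Returns the trained head and a report with loss/accuracy on the training
    embeddings and, if given, on held-out ``validation_data``.
    """
    embeddings = np.asarray(embeddings, dtype=DTYPE)
    labels = np.asarray(labels)
    if len(embeddings) != len(labels):
        raise ConfigurationError("label/embedding count mismatch")
    spec = ArchitectureSpec.default("embedding_classifier", seed=seed, **overrides)
    model = Sequential([Dense(1, activation=None), Sigmoid()]).build(
        (embeddings.shape[1],), seed=seed
    )
    history = model.fit(
        embeddings,
        labels,
        epochs=spec.epochs,
        batch_size=spec.batch_size,
        loss="bce",
        optimizer=make_optimizer(spec.optimizer, spec.lr),
        seed=seed,
        validation_data=validation_data,
    )
    trained = TrainedModel(spec=spec, model=model, history=history)
    p = trained.predict_proba(embeddings)
    report = {
        "loss": binary_cross_entropy(p[:, None], labels.reshape(-1, 1).astype(DTYPE)),
        "accuracy": float(np.mean((p >= 0.5) == (labels > 0))),
    }
    if validation_data is not None:
        xv, yv = validation_data
        pv = trained.predict_proba(np.asarray(xv, dtype=DTYPE))
        yv = np.asarray(yv)
        report["val_loss"] = binary_cross_entropy(
            pv[:, None], yv.reshape(-1, 1).astype(DTYPE)
        )
        report["val_accuracy"] = float(np.mean((pv >= 0.5) == (yv > 0)))
    return trained, report


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def evaluate(
    trained: TrainedModel,
    bundle: DatasetBundle,
    split: str = "validation",
    channels: list[int] | None = None,
) -> EvalReport:
    """Accuracy, ROC-AUC, confusion counts and per-ligand misclassification."""
    idx = bundle.indices(split)
    if idx.size == 0:
        raise ConfigurationError(f"split {split!r} is empty")
    x = _classifier_inputs(bundle, trained.spec.arch, split)
    if channels is not None:
        x = x[:, :, channels] if trained.spec.arch != "cnn2d" else x[:, channels]
    y = bundle.labels[idx]
    ligands = bundle.ligand_ids[idx]
    probs = trained.predict_proba(x.astype(DTYPE))
    preds = (probs >= trained.spec.threshold).astype(np.int8)
    accuracy = float(np.mean(preds == y))
    if len(np.unique(y)) == 2:
        auc = float(roc_auc_score(y, probs))
    else:
        auc = float("nan")
    loss = binary_cross_entropy(probs[:, None], y.reshape(-1, 1).astype(DTYPE))
    confusion = {
        "tp": int(np.sum((preds == 1) & (y == 1))),
        "tn": int(np.sum((preds == 0) & (y == 0))),
        "fp": int(np.sum((preds == 1) & (y == 0))),
        "fn": int(np.sum((preds == 0) & (y == 1))),
    }
    rows = []
    for lig in np.unique(ligands):
        m = ligands == lig
        rows.append(
            {
                "ligand_id": int(lig),
                "misclassified_reactive": int(np.sum(m & (y == 1) & (preds == 0))),
                "misclassified_nonreactive": int(np.sum(m & (y == 0) & (preds == 1))),
                "n": int(m.sum()),
            }
        )
    per_ligand = pd.DataFrame(rows)
    total_err = confusion["fp"] + confusion["fn"]
    assert (
        per_ligand.misclassified_reactive.sum()
        + per_ligand.misclassified_nonreactive.sum()
        == total_err
    )
    return EvalReport(
        accuracy=accuracy,
        roc_auc=auc,
        loss=loss,
        confusion=confusion,
        per_ligand=per_ligand,
        n=int(idx.size),
    )


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

_BUILDERS = {
    "cnn1d": lambda shape, seed: build_cnn1d(shape[0], shape[1], seed),
    "cnn2d": lambda shape, seed: build_cnn2d(shape[1], shape[0], seed),
    "cnn2d_cam": lambda shape, seed: build_cnn2d_cam(shape[0], seed),
    "lstm_forecaster": lambda shape, seed: build_lstm_forecaster(shape[0], shape[1], seed),
}


def save_trained(path, trained: TrainedModel):
    """One-archive checkpoint: spec + input shape + weights + normalizer."""
    manifest = {
        "spec": asdict(trained.spec),
        "input_shape": list(trained.model.input_shape),
        "history": trained.history,
        "normalizer": trained.normalizer.to_dict() if trained.normalizer else None,
    }
    arrays = {}
    for i, layer in enumerate(trained.model.layers):
        for k, v in layer.params.items():
            arrays[f"{i}.{k}"] = v
    np.savez(path, manifest=json.dumps(manifest), **arrays)


def load_trained(path) -> TrainedModel:
    with np.load(path, allow_pickle=False) as data:
        manifest = json.loads(str(data["manifest"]))
        spec = ArchitectureSpec(**manifest["spec"])
        if spec.arch not in _BUILDERS:
            raise ConfigurationError(f"cannot rebuild architecture {spec.arch!r}")
        model = _BUILDERS[spec.arch](manifest["input_shape"], spec.seed)
        for i, layer in enumerate(model.layers):
            for k in layer.params:
                layer.params[k] = data[f"{i}.{k}"].astype(DTYPE)
    norm = manifest.get("normalizer")
    return TrainedModel(
        spec=spec,
        model=model,
        history=manifest.get("history", {}),
        normalizer=Normalizer.from_dict(norm) if norm else None,
    )
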