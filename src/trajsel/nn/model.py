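"""Sequential model container: build, fit, predict, introspection, (de)serialization.

Training is plain minibatch SGD-style backprop with a seeded shuffle; the
history records per-epoch loss (and accuracy for binary cross-entropy).
Runs are bit-reproducible for a fixed seed under single-threaded BLAS.
"""

from __future__ import annotations

import io
import json

import numpy as np

from .layers import DTYPE, Layer, Sigmoid
from .optim import Optimizer, make_optimizer

_EPS = 1e-7


def binary_cross_entropy(p, y):
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def mean_squared_error(pred, y):
    return float(np.mean((pred - y) ** 2))


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = layers
        self.built = False
        self.input_shape = None
        self.output_shape = None
        self.layer_shapes: list[tuple] = []

    # -- construction -----------------------------------------------------
    def build(self, input_shape, seed=0):
        rng = np.random.default_rng(seed)
        shape = tuple(input_shape)
        self.input_shape = shape
        self.layer_shapes = []
        for layer in self.layers:
            shape = tuple(layer.build(shape, rng))
            self.layer_shapes.append(shape)
        self.output_shape = shape
        self.built = True
        return self

    # -- inference --------------------------------------------------------
    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def predict(self, x, batch_size=256):
        outs = []
        for i in range(0, len(x), batch_size):
            outs.append(self.forward(np.asarray(x[i : i + batch_size], dtype=DTYPE)))
        return np.concatenate(outs, axis=0)

    def forward_to(self, x, layer_index, batch_size=256):
        """Output of ``layers[:layer_index + 1]`` (e.g. embeddings, feature maps)."""
        outs = []
        for i in range(0, len(x), batch_size):
            h = np.asarray(x[i : i + batch_size], dtype=DTYPE)
            for layer in self.layers[: layer_index + 1]:
                h = layer.forward(h, training=False)
            outs.append(h)
        return np.concatenate(outs, axis=0)

    def score_gradients(self, x, wrt_index):
        """Gradient of the summed pre-sigmoid score w.r.t. ``layers[wrt_index]`` output.

        Requires the final layer to be a :class:`Sigmoid`. Also returns the
        forward output of the target layer.
        """
        if not isinstance(self.layers[-1], Sigmoid):
            raise ValueError("score_gradients requires a sigmoid output head")
        x = np.asarray(x, dtype=DTYPE)
        acts = []
        h = x
        for layer in self.layers:
            h = layer.forward(h, training=False)
            acts.append(h)
        logits = acts[-2]
        delta = np.ones_like(logits)
        for layer in reversed(self.layers[wrt_index + 1 : -1]):
            delta = layer.backward(delta)
        return acts[wrt_index], delta

    # -- training ---------------------------------------------------------
    def fit(
        self,
        x,
        y,
        *,
        epochs,
        batch_size,
        loss,
        optimizer,
        seed=0,
        validation_data=None,
        verbose=0,
    ):
        """Train and return a history dict (per-epoch lists).

        ``loss`` is ``"bce"`` (requires a trailing Sigmoid layer) or ``"mse"``.
        """
        if not self.built:
            raise RuntimeError("call build() before fit()")
        if isinstance(optimizer, str):
            optimizer = make_optimizer(optimizer, 1e-3)
        assert isinstance(optimizer, Optimizer)
        x = np.asarray(x, dtype=DTYPE)
        y = np.asarray(y, dtype=DTYPE).reshape(len(x), -1)
        if loss == "bce" and not isinstance(self.layers[-1], Sigmoid):
            raise ValueError("bce loss expects a Sigmoid output layer")
        rng = np.random.default_rng(seed)
        history: dict[str, list[float]] = {"loss": []}
        if loss == "bce":
            history["accuracy"] = []
        if validation_data is not None:
            history["val_loss"] = []
            if loss == "bce":
                history["val_accuracy"] = []
        n = len(x)
        for epoch in range(epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            correct = 0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                xb, yb = x[idx], y[idx]
                out = self.forward(xb, training=True)
                if loss == "bce":
                    batch_loss = binary_cross_entropy(out, yb)
                    delta = ((out - yb) / len(xb)).astype(DTYPE)
                    back_layers = self.layers[:-1]  # fused sigmoid + BCE gradient
                    correct += int(((out >= 0.5) == (yb >= 0.5)).sum())
                else:
                    batch_loss = mean_squared_error(out, yb)
                    delta = (2.0 * (out - yb) / out.size).astype(DTYPE)
                    back_layers = self.layers
                if not np.isfinite(batch_loss):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}, batch offset {start}"
                    )
                for layer in reversed(back_layers):
                    delta = layer.backward(delta)
                optimizer.step(self.layers)
                epoch_loss += batch_loss * len(xb)
            history["loss"].append(epoch_loss / n)
            if loss == "bce":
                history["accuracy"].append(correct / n)
            if validation_data is not None:
                xv, yv = validation_data
                pv = self.predict(xv)
                yv2 = np.asarray(yv, dtype=DTYPE).reshape(len(xv), -1)
                if loss == "bce":
                    history["val_loss"].append(binary_cross_entropy(pv, yv2))
                    history["val_accuracy"].append(
                        float(np.mean((pv >= 0.5) == (yv2 >= 0.5)))
                    )
                else:
                    history["val_loss"].append(mean_squared_error(pv, yv2))
            if verbose:
                msg = f"epoch {epoch + 1}/{epochs} loss={history['loss'][-1]:.4f}"
                if loss == "bce":
                    msg += f" acc={history['accuracy'][-1]:.4f}"
                if validation_data is not None:
                    msg += f" val_loss={history['val_loss'][-1]:.4f}"
                print(msg)
        return history

    # -- weights ----------------------------------------------------------
    def get_weights(self):
        return [
            {k: v.copy() for k, v in layer.params.items()} for layer in self.layers
        ]

    def set_weights(self, weights):
        if len(weights) != len(self.layers):
            raise ValueError("weight list length mismatch")
        for layer, wdict in zip(self.layers, weights):
            for k, v in wdict.items():
                if layer.params[k].shape != v.shape:
                    raise ValueError(f"shape mismatch for {k}")
                layer.params[k] = np.asarray(v, dtype=DTYPE).copy()

    def weights_to_bytes(self) -> bytes:
        arrays = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.params.items():
                arrays[f"{i}.{k}"] = v
        buf = io.BytesIO()
        np.savez(buf, **arrays)
        return buf.getvalue()

    def weights_from_bytes(self, blob: bytes):
        with np.load(io.BytesIO(blob)) as data:
            for i, layer in enumerate(self.layers):
                for k in layer.params:
                    layer.params[k] = data[f"{i}.{k}"].astype(DTYPE)

    def summary(self) -> str:
        lines = [f"input: {self.input_shape}"]
        for layer, shape in zip(self.layers, self.layer_shapes):
            n_par = sum(int(np.prod(p.shape)) for p in layer.params.values())
            lines.append(f"{type(layer).__name__:<16} -> {shape}  params={n_par}")
        return "\n".join(lines)


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration object."""
    import hashlib

    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
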