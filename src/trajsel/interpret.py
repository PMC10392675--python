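"""Explaining trained classifiers.

Four complementary views:

* **Channel ablation** — 15 independent single-channel classifiers (5 seeds
  each) plus an all-channel reference quantify each descriptor's standalone
  discriminative power.
* **1-D CAM** — the 1-D classifier ends in GlobalMaxPool > Dense(1), the exact
  structure classic class-activation mapping requires, so the saliency of
  filter *f* is its final-conv feature map scaled by the output weight for
  *f*, clipped at zero and upsampled back to frame resolution. A raw
  (unweighted) per-filter mode is also available.
* **2-D Grad-CAM** — the image classifier has hidden dense layers after
  Flatten, which breaks classic CAM's structural requirement, so
  gradient-weighted CAM on the final 16-channel feature map is used instead
  (channel weights = spatially averaged score gradients, weighted sum, ReLU,
  bilinear upsampling to the input image).
* **Latent space** — t-SNE (perplexity 30) of the 16-d penultimate embeddings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import DatasetBundle
from .errors import ConfigurationError, UnsupportedArchitectureError
from .models import (
    ArchitectureSpec,
    TrainedModel,
    build_cnn1d,
    evaluate,
    train_classifier,
)
from .nn import Conv1D, Dense, GlobalMaxPool1D, MaxPool1D, Sigmoid


@dataclass
class AblationResult:
    """Per-channel single-input accuracies (mean ± sd over replicas) plus reference."""

    table: pd.DataFrame  # columns: channel, name, mean_accuracy, sd_accuracy
    reference_mean: float
    reference_sd: float
    replicas: int

    def top_channel(self) -> int:
        return int(self.table.loc[self.table.mean_accuracy.idxmax(), "channel"])


@dataclass
class SaliencyMap:
    """Non-negative activation map aligned back to the input resolution."""

    activations: np.ndarray  # (filters, T) for 1-D; (H, W) for 2-D
    upsampling_factor: int
    source: str
    meta: dict


@dataclass
class MaxActivationRecord:
    """Descriptor values at the time of a filter's maximum activation."""

    table: pd.DataFrame  # columns: trajectory, time, class, d1..dD
    filter_id: int


# ---------------------------------------------------------------------------
# ablation
# ---------------------------------------------------------------------------


def ablation_study(
    bundle: DatasetBundle,
    replicas: int = 5,
    seed: int = 0,
    spec_overrides: dict | None = None,
    channels: list[int] | None = None,
) -> AblationResult:
    """Train one classifier per channel per replica on the single-channel slice.

    Every model is trained from scratch with the standard regime on the
    training split and scored on the held-out-ligand validation split; the
    all-channel reference uses the same ``replicas`` seeds. Deterministic for
    a fixed ``seed``.
    """
    if replicas < 2:
        raise ConfigurationError("need >= 2 replicas for a standard deviation")
    channels = list(range(bundle.n_channels)) if channels is None else list(channels)
    for c in channels:
        if not 0 <= c < bundle.n_channels:
            raise ConfigurationError(f"channel index {c} out of range")
    overrides = spec_overrides or {}
    if bundle.normalizer is None:
        bundle.fit_normalizer()

    def _accuracy(channel_subset, rep_seed):
        spec = ArchitectureSpec.default("cnn1d", seed=rep_seed, **overrides)
        model = build_cnn1d(bundle.n_frames, len(channel_subset), seed=rep_seed)
        trained = train_classifier(model, bundle, spec, channels=channel_subset)
        return evaluate(trained, bundle, "validation", channels=channel_subset).accuracy

    ref = np.array([_accuracy(channels, seed + r) for r in range(replicas)])
    rows = []
    for c in channels:
        accs = np.array([_accuracy([c], seed + 1000 * (c + 1) + r) for r in range(replicas)])
        rows.append(
            {
                "channel": c,
                "name": bundle.descriptor_names[c],
                "mean_accuracy": float(accs.mean()),
                "sd_accuracy": float(accs.std(ddof=1)),
            }
        )
    return AblationResult(
        table=pd.DataFrame(rows),
        reference_mean=float(ref.mean()),
        reference_sd=float(ref.std(ddof=1)),
        replicas=replicas,
    )


# ---------------------------------------------------------------------------
# 1-D CAM
# ---------------------------------------------------------------------------


def _check_cnn1d_structure(model):
    layers = model.layers
    ok = (
        len(layers) == 6
        and isinstance(layers[2], Conv1D)
        and isinstance(layers[3], GlobalMaxPool1D)
        and isinstance(layers[4], Dense)
        and isinstance(layers[5], Sigmoid)
        and isinstance(layers[1], MaxPool1D)
    )
    if not ok:
        raise UnsupportedArchitectureError(
            "1-D CAM needs Conv>Pool>Conv>GlobalMaxPool>Dense(1)>Sigmoid"
        )


def cam_receptive_field(j: int, pool: int = 5, kernel: int = 7) -> tuple[int, int]:
    """Inclusive input-frame range seen by final-conv output position ``j``."""
    first = pool * j
    last = pool * (j + kernel - 1) + (pool - 1) + (kernel - 1)
    return first, last


def compute_cam_1d(
    trained: TrainedModel, tensor: np.ndarray, mode: str = "weighted"
) -> SaliencyMap:
    """Class-activation map of the 1-D classifier for one normalized (T, D) tensor.

    ``weighted`` scales each filter's final-conv feature map by its output
    weight and clips negatives (classic CAM); ``raw`` returns the plain
    post-ReLU feature maps. The map is upsampled by nearest-neighbour repeat
    with the pooling factor (5) — keeping the saliency piecewise-constant —
    centred on the frame axis, with edge frames carrying the nearest value.
    """
    model = trained.model
    _check_cnn1d_structure(model)
    if mode not in ("weighted", "raw"):
        raise ConfigurationError(f"unknown CAM mode {mode!r}")
    tensor = np.asarray(tensor, dtype=np.float32)
    single = tensor.ndim == 2
    batch = tensor[None] if single else tensor
    t = batch.shape[1]
    fmap = model.forward_to(batch, 2)  # (n, L, F) post-ReLU
    if mode == "weighted":
        w = model.layers[4].params["W"][:, 0]  # (F,)
        cam = np.maximum(fmap * w[None, None, :], 0.0)
    else:
        cam = fmap
    pool = model.layers[1].pool_size
    up = np.repeat(cam, pool, axis=1)  # (n, L*pool, F)
    full = np.empty((cam.shape[0], t, cam.shape[2]), dtype=cam.dtype)
    offset = (t - up.shape[1]) // 2
    full[:, offset : offset + up.shape[1]] = up
    full[:, :offset] = up[:, :1]
    full[:, offset + up.shape[1] :] = up[:, -1:]
    act = full.transpose(0, 2, 1)  # (n, F, T): y-axis filter, x-axis time
    return SaliencyMap(
        activations=act[0] if single else act,
        upsampling_factor=pool,
        source="cnn1d/conv2",
        meta={"mode": mode, "offset": offset, "fmap_length": cam.shape[1]},
    )


def strongest_filter(trained: TrainedModel) -> int:
    """Filter with the largest absolute output weight (most class-relevant).

    A fixed filter index can land on a dead filter for a given seed; reports
    default to the strongest one.
    """
    _check_cnn1d_structure(trained.model)
    return int(np.abs(trained.model.layers[4].params["W"][:, 0]).argmax())


def extract_max_activation_values(
    trained: TrainedModel, bundle: DatasetBundle, filter_id: int = 4, split: str | None = None
) -> MaxActivationRecord:
    """Per trajectory: argmax time of one filter's CAM and all descriptor values there.

    Ties in the saliency break to the earliest frame. Values are reported on
    the normalized scale the network saw.
    """
    x = bundle.normalized(split)
    labels = bundle.labels[bundle.indices(split)]
    n_filters = trained.model.layers[2].filters
    if not 0 <= filter_id < n_filters:
        raise ConfigurationError(f"filter id {filter_id} out of range (0..{n_filters - 1})")
    sal = compute_cam_1d(trained, x)
    acts = sal.activations[:, filter_id, :]  # (n, T)
    tmax = acts.argmax(axis=1)  # argmax takes the earliest maximum
    rows = {
        "trajectory": np.arange(len(x)),
        "time": tmax,
        "class": np.where(labels == 1, "reactive", "non-reactive"),
    }
    vals = x[np.arange(len(x)), tmax]  # (n, D)
    for d, name in enumerate(bundle.descriptor_names):
        rows[name] = vals[:, d]
    return MaxActivationRecord(table=pd.DataFrame(rows), filter_id=filter_id)


# ---------------------------------------------------------------------------
# 2-D Grad-CAM
# ---------------------------------------------------------------------------


def _gradcam_combine(fmaps: np.ndarray, grads: np.ndarray) -> np.ndarray:
    """ReLU of the gradient-weighted feature-map sum (one image, HWC arrays)."""
    alpha = grads.mean(axis=(0, 1))  # (C,)
    return np.maximum(np.tensordot(fmaps, alpha, axes=([2], [0])), 0.0)


def compute_gradcam_2d(trained: TrainedModel, image: np.ndarray) -> SaliencyMap:
    """Grad-CAM of the image classifier on one (H, W, 1) input.

    Classic CAM is structurally impossible here (hidden dense layers follow
    the Flatten), so channel weights are the spatial means of the score
    gradient at the final pooled feature map; the weighted sum is rectified
    and bilinearly upsampled to the input size.
    """
    from scipy.ndimage import zoom

    model = trained.model
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 3:
        raise ConfigurationError("expected one (H, W, 1) image")
    target = 7  # index of the last MaxPool2D in the fixed cam stack
    from .nn import MaxPool2D as _MP

    if len(model.layers) <= target or not isinstance(model.layers[target], _MP):
        raise UnsupportedArchitectureError("model does not match the CAM image stack")
    fmap, grad = model.score_gradients(image[None], target)
    cam = _gradcam_combine(fmap[0], grad[0])
    h, w = image.shape[:2]
    factors = (h / cam.shape[0], w / cam.shape[1])
    up = zoom(cam, factors, order=1, grid_mode=True, mode="nearest")
    return SaliencyMap(
        activations=up,
        upsampling_factor=int(round(factors[0])),
        source="cnn2d_cam/gradcam(pool4)",
        meta={"method": "grad-cam", "fmap_shape": cam.shape},
    )


# ---------------------------------------------------------------------------
# latent space
# ---------------------------------------------------------------------------


def project_latent_space(
    trained: TrainedModel,
    bundle: DatasetBundle,
    split: str = "validation",
    perplexity: float = 30.0,
    seed: int = 0,
) -> pd.DataFrame:
    """t-SNE of the 16-d penultimate (GlobalMaxPool) embeddings of one split."""
    from sklearn.manifold import TSNE

    x = bundle.normalized(split)
    labels = bundle.labels[bundle.indices(split)]
    if len(x) <= perplexity:
        raise ConfigurationError(
            f"{len(x)} points are too few for perplexity {perplexity}"
        )
    emb = trained.model.forward_to(x.astype(np.float32), 3)  # (n, 16)
    ts = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed, init="pca"
    ).fit_transform(emb)
    return pd.DataFrame(
        {
            "x": ts[:, 0],
            "y": ts[:, 1],
            "label": labels,
            "class": np.where(labels == 1, "reactive", "non-reactive"),
            "ligand_id": bundle.ligand_ids[bundle.indices(split)],
        }
    )
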