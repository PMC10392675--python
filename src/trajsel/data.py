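"""Dataset assembly: labels, ligand-held-out splits and network input encodings.

A :class:`DatasetBundle` stacks all trajectories of a study into one
``(N, T, D)`` array plus per-trajectory metadata. The same normalized tensors
feed four encodings: the multichannel 1-D signal, the D x T x 1 matrix image,
a rendered square grayscale image of the channel traces, and sliding windows
for next-step forecasting.

The split is by ligand identity, never random: every trajectory of a ligand
lives entirely in one split, so validation accuracy measures generalization
to unseen compounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, LabelingError
from .featurize import Normalizer, TrajectoryTensor

logger = logging.getLogger(__name__)

REACTIVE, NON_REACTIVE = "reactive", "non-reactive"


@dataclass
class DatasetBundle:
    """Stacked trajectory tensors with labels, ligand ids and an optional split."""

    tensors: np.ndarray  # (N, T, D)
    labels: np.ndarray  # (N,) int8, 1 = reactive
    ligand_ids: np.ndarray  # (N,) int
    enantiomers: np.ndarray  # (N,) 'S' / 'R'
    descriptor_names: list[str]
    units: list[str]
    dt: float = 0.02
    train_idx: np.ndarray | None = None
    val_idx: np.ndarray | None = None
    normalizer: Normalizer | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.tensors = np.asarray(self.tensors)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.ligand_ids = np.asarray(self.ligand_ids)
        self.enantiomers = np.asarray(self.enantiomers)
        n = len(self.tensors)
        if not (len(self.labels) == len(self.ligand_ids) == len(self.enantiomers) == n):
            raise ValueError("metadata arrays must match the number of trajectories")

    @property
    def n_trajectories(self) -> int:
        return len(self.tensors)

    @property
    def n_frames(self) -> int:
        return self.tensors.shape[1]

    @property
    def n_channels(self) -> int:
        return self.tensors.shape[2]

    def indices(self, split: str | None) -> np.ndarray:
        if split is None or split == "all":
            return np.arange(self.n_trajectories)
        if split == "train":
            if self.train_idx is None:
                raise ConfigurationError("bundle has no split; call split_by_ligand")
            return self.train_idx
        if split == "validation":
            if self.val_idx is None:
                raise ConfigurationError("bundle has no split; call split_by_ligand")
            return self.val_idx
        raise ConfigurationError(f"unknown split {split!r}")

    def fit_normalizer(self) -> Normalizer:
        """Fit the min-max normalizer on the training split only."""
        self.normalizer = Normalizer.fit(self.tensors[self.indices("train")])
        return self.normalizer

    def normalized(self, split: str | None = None) -> np.ndarray:
        """Normalized (n, T, D) stack for a split (requires a fitted normalizer)."""
        if self.normalizer is None:
            raise ConfigurationError("no normalizer fitted; call fit_normalizer()")
        return self.normalizer.apply(self.tensors[self.indices(split)])


# ---------------------------------------------------------------------------
# labels and splits
# ---------------------------------------------------------------------------


def assign_class_labels(
    tensors: list[TrajectoryTensor], preferred_enantiomer: dict[int, str]
) -> list[TrajectoryTensor]:
    """Label each trajectory reactive iff its enantiomer is the ligand's preferred one."""
    for t in tensors:
        if t.ligand_id not in preferred_enantiomer:
            raise LabelingError(f"no preferred enantiomer for ligand {t.ligand_id}")
        pref = preferred_enantiomer[t.ligand_id]
        if pref not in ("S", "R"):
            raise LabelingError(f"bad enantiomer tag {pref!r}")
        t.class_label = REACTIVE if t.enantiomer == pref else NON_REACTIVE
    return tensors


def split_by_ligand(bundle: DatasetBundle, train_ligands, val_ligands) -> DatasetBundle:
    """Assign every trajectory to train or validation by its ligand id (in place)."""
    train_set, val_set = set(train_ligands), set(val_ligands)
    if train_set & val_set:
        raise ConfigurationError(f"overlapping ligand sets: {sorted(train_set & val_set)}")
    present = set(np.unique(bundle.ligand_ids).tolist())
    uncovered = present - train_set - val_set
    if uncovered:
        raise ConfigurationError(f"ligands not assigned to any split: {sorted(uncovered)}")
    in_train = np.isin(bundle.ligand_ids, sorted(train_set))
    bundle.train_idx = np.where(in_train)[0]
    bundle.val_idx = np.where(~in_train)[0]
    if bundle.val_idx.size == 0:
        logger.warning("validation split is empty")
    assert not set(bundle.ligand_ids[bundle.train_idx]) & set(
        bundle.ligand_ids[bundle.val_idx]
    ), "ligand leakage between splits"
    return bundle


def default_split(bundle: DatasetBundle, train_fraction: float = 0.8) -> DatasetBundle:
    """Ligand-ordered 80/20 split (first ligands train, remainder validation)."""
    ligands = np.unique(bundle.ligand_ids)
    n_train = int(round(train_fraction * len(ligands)))
    return split_by_ligand(bundle, ligands[:n_train], ligands[n_train:])


# ---------------------------------------------------------------------------
# network input encodings
# ---------------------------------------------------------------------------


def to_signal_batch(bundle: DatasetBundle, split: str | None = None) -> np.ndarray:
    """Normalized (n, T, D) stack: the 1-D multichannel signal encoding."""
    return bundle.normalized(split)


def to_matrix_image_batch(bundle: DatasetBundle, split: str | None = None) -> np.ndarray:
    """Normalized (n, D, T, 1) stack: the one-channel matrix-image encoding."""
    sig = bundle.normalized(split)
    return sig.transpose(0, 2, 1)[..., None]


def render_trajectory_image(
    tensor: np.ndarray, size: int = 320, gap: int = 4
) -> np.ndarray:
    """Rasterize a normalized (T, D) tensor as a (size, size, 1) grayscale image.

    Each channel is drawn as a dark polyline (value 0) on a light background
    (value 1) inside its own horizontal band of ``floor(size / D)`` rows; the
    top ``gap`` rows of every band stay blank so bands never touch, and any
    remainder rows pad the bottom. Rasterization is per-column with vertical
    joins and no anti-aliasing, so the image is a deterministic function of
    the tensor.
    """
    arr = np.asarray(tensor, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError("tensor must be (T, D)")
    t, d = arr.shape
    band = size // d
    if band <= gap:
        raise ConfigurationError(
            f"{d} channels do not fit {size} rows with band gap {gap}"
        )
    if np.nanmin(arr) < -1e-9 or np.nanmax(arr) > 1 + 1e-9:
        raise ValueError("render expects normalized values in [0, 1]")
    trace_h = band - gap
    img = np.ones((size, size), dtype=np.float32)
    xs = np.linspace(0.0, t - 1.0, size)
    base = np.arange(t, dtype=np.float64)
    for c in range(d):
        vals = np.interp(xs, base, arr[:, c])
        rows = c * band + gap + np.rint((1.0 - vals) * (trace_h - 1)).astype(int)
        img[rows, np.arange(size)] = 0.0
        for x in range(1, size):  # vertical joins between adjacent columns
            lo, hi = sorted((rows[x - 1], rows[x]))
            img[lo : hi + 1, x] = 0.0
    return img[:, :, None]


def band_masks(size: int, n_channels: int, gap: int = 4):
    """Boolean (trace-band rows, inter-band/padding rows) masks of the rendering."""
    band = size // n_channels
    trace = np.zeros(size, dtype=bool)
    for c in range(n_channels):
        trace[c * band + gap : (c + 1) * band] = True
    return trace, ~trace


# ---------------------------------------------------------------------------
# forecast windows
# ---------------------------------------------------------------------------


@dataclass
class ForecastWindowSet:
    """Sliding windows for next-step forecasting of one query channel."""

    inputs: np.ndarray  # (M, window, D)
    targets: np.ndarray  # (M,)
    traj_index: np.ndarray  # (M,) index into the source split
    start_frame: np.ndarray  # (M,) start frame in the (possibly lagged) series
    query_channel: int
    labels: np.ndarray | None = None  # per-window class label of the source trajectory

    def __len__(self) -> int:
        return len(self.inputs)


def make_forecast_windows(
    bundle: DatasetBundle,
    query_channel: int = 3,
    window: int = 50,
    stride: int = 19,
    split: str | None = None,
    lag: int = 1,
) -> ForecastWindowSet:
    """Cut normalized trajectories into (window, D) inputs with next-step targets.

    Windows never cross trajectory boundaries. ``lag`` > 1 first decimates each
    series to every ``lag``-th frame. The default stride of 19 yields 50
    windows per 1,000-frame trajectory (490,000 for the full-size study).
    """
    if stride < 1:
        raise ConfigurationError("stride must be >= 1")
    if lag < 1:
        raise ConfigurationError("lag must be >= 1")
    data = bundle.normalized(split)
    n, t_full, d = data.shape
    if not 0 <= query_channel < d:
        raise ConfigurationError(f"query channel {query_channel} out of range")
    data = data[:, ::lag, :]
    t = data.shape[1]
    if t < window + 1:
        raise ConfigurationError(
            f"series length {t} after lag {lag} is shorter than window+1={window + 1}"
        )
    starts = np.arange(0, t - window, stride)
    labels = bundle.labels[bundle.indices(split)]
    inputs = np.empty((n * len(starts), window, d), dtype=np.float32)
    targets = np.empty(n * len(starts), dtype=np.float32)
    traj_index = np.repeat(np.arange(n), len(starts))
    start_frame = np.tile(starts, n)
    k = 0
    for i in range(n):
        for s in starts:
            inputs[k] = data[i, s : s + window]
            targets[k] = data[i, s + window, query_channel]
            k += 1
    return ForecastWindowSet(
        inputs=inputs,
        targets=targets,
        traj_index=traj_index,
        start_frame=start_frame,
        query_channel=query_channel,
        labels=np.repeat(labels, len(starts)),
    )


def make_lagged_windows(
    bundle: DatasetBundle, lag: int, query_channel: int = 3, window: int = 50,
    stride: int = 19, split: str | None = None,
) -> ForecastWindowSet:
    """Windows over every ``lag``-th frame (time-lagged forecasting input)."""
    return make_forecast_windows(
        bundle, query_channel=query_channel, window=window, stride=stride,
        split=split, lag=lag,
    )
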