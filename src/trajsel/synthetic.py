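"""Synthetic descriptor-trajectory generator with class-matched marginals.

The generator emulates the statistical structure of short (20 ps) MD
trajectories of enzyme–ligand complexes reduced to 15 geometric descriptors:
49 ligands, 100 trajectories per class per ligand, 1,000 frames each. Its
defining property mirrors the real data: the per-channel value distributions
of the two classes are identical by construction, so class information lives
only in *temporal* patterns or *cross-channel* phase relationships — exactly
the kind of signal a convolutional network must find and a per-channel
histogram cannot.

Two class-signal mechanisms are provided:

``temporal`` (default)
    Informative channels oscillate in a fast frequency band for the reactive
    class and in the slow background band for the non-reactive class. The
    pooled value distribution of a random-phase sinusoid is the arcsine law
    regardless of frequency, so per-channel marginals are identical across
    classes by construction, while the local frame-to-frame dynamics carry
    the class — shuffling frame order destroys the signal exactly.

``coupling``
    A designated channel subset shares one oscillation frequency; the
    reactive class locks fixed phase offsets between those channels while the
    non-reactive class randomizes the phase ordering. The joint instantaneous
    configuration carries the class, so the signal survives frame shuffling.

The slow χ1-like dihedral channel is a reflected (bounded) random walk around
-90° in *both* classes: complexes start docked in the catalytic orientation
and mostly retain it over such short trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import NON_REACTIVE, REACTIVE, DatasetBundle
from .errors import ConfigurationError, LabelingError
from .featurize import DEFAULT_CHANNEL_KINDS

_SCALES = {"distance": 0.5, "angle": 8.0, "dihedral": 15.0}  # physical units per z-unit
_BASELINE_RANGES = {"distance": (3.5, 4.5), "angle": (85.0, 105.0), "dihedral": (-40.0, 40.0)}


def channel_kinds(n_channels: int) -> tuple[str, ...]:
    """Kind of each channel: the documented 15-channel layout, cycled if needed."""
    reps = -(-n_channels // len(DEFAULT_CHANNEL_KINDS))
    return (DEFAULT_CHANNEL_KINDS * reps)[:n_channels]


def channel_units(n_channels: int) -> list[str]:
    return ["angstrom" if k == "distance" else "degrees" for k in channel_kinds(n_channels)]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the synthetic dataset.

    Defaults reproduce the full-size study: 49 ligands x 2 classes x 100
    trajectories of 1,000 frames (20 ps, so 0.02 ps per frame) x 15 channels.
    """

    n_ligands: int = 49
    n_per_class: int = 100
    n_frames: int = 1000
    n_channels: int = 15
    dt: float = 0.02  # ps per frame
    slow_channel: int = 2  # 0-based index of the χ1-like dihedral (d3)
    noise_sd: float = 0.2  # frame noise, dimensionless z-units
    master_seed: int = 0
    signal_mode: str = "temporal"  # temporal | coupling | none
    informative_channels: tuple[int, ...] = (3, 4, 10)  # d4, d5, d11 analogues
    informative_weights: tuple[float, ...] = (1.0, 0.6, 0.6)
    osc_amplitude: float = 1.0
    coupling_amplitude: float = 2.5  # oscillation amplitude of coupled channels
    fast_freq_band: tuple[float, float] = (5.0, 8.0)  # cycles per 100 frames
    slow_freq_band: tuple[float, float] = (0.8, 1.6)  # cycles per 100 frames
    slow_drift_band: float = 12.0  # degrees around -90
    slow_step_sd: float = 1.0  # degrees per frame
    hard_ligand_fraction: float = 0.15
    hard_attenuation: float = 0.6
    fraction_r_preferring: float = 0.1
    marginal_ks_threshold: float = 0.05

    def __post_init__(self):
        if min(self.n_ligands, self.n_per_class, self.n_channels) < 1:
            raise ConfigurationError("counts must be positive")
        if self.n_frames < 51:
            raise ConfigurationError("n_frames must be >= 51 (window + next step)")
        if self.signal_mode not in ("temporal", "coupling", "none"):
            raise ConfigurationError(f"unknown signal mode {self.signal_mode!r}")
        if not 0 <= self.slow_channel < self.n_channels:
            raise ConfigurationError("slow_channel out of range")
        if len(self.informative_channels) != len(self.informative_weights):
            raise ConfigurationError("informative channels/weights length mismatch")
        if any(not 0 <= c < self.n_channels for c in self.informative_channels):
            raise ConfigurationError("informative channel index out of range")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if self.fast_freq_band[0] <= self.slow_freq_band[1]:
            raise ConfigurationError("fast and slow frequency bands must not overlap")

    @property
    def kinds(self) -> tuple[str, ...]:
        return channel_kinds(self.n_channels)

    @property
    def units(self) -> list[str]:
        return channel_units(self.n_channels)


@dataclass(frozen=True)
class LigandProfile:
    """Per-ligand statistical identity: baselines, spreads and motif/coupling parameters."""

    ligand_id: int
    preferred_enantiomer: str
    channel_baselines: np.ndarray  # physical units per channel
    channel_spreads: np.ndarray  # physical units per z-unit, strictly positive
    pattern_params: dict
    seed: int
    config: GeneratorConfig

    def __post_init__(self):
        if not np.all(self.channel_spreads > 0):
            raise ConfigurationError("channel spreads must be strictly positive")


def make_ligand_profiles(config: GeneratorConfig) -> list[LigandProfile]:
    """Deterministically derive one profile per ligand from the master seed.

    Baselines are drawn per ligand so a ligand-held-out split is a genuine
    generalization test; a small fraction of ligands gets attenuated signal
    strength (intrinsically hard ligands).
    """
    profiles = []
    kinds = config.kinds
    for lig in range(1, config.n_ligands + 1):
        rng = np.random.default_rng(
            np.random.SeedSequence(config.master_seed, spawn_key=(1, lig))
        )
        baselines = np.empty(config.n_channels)
        for c, kind in enumerate(kinds):
            lo, hi = _BASELINE_RANGES[kind]
            baselines[c] = rng.uniform(lo, hi)
        baselines[config.slow_channel] = -90.0  # catalytic orientation
        spreads = np.array([_SCALES[k] for k in kinds], dtype=float)
        hard = rng.random() < config.hard_ligand_fraction
        preferred = "R" if rng.random() < config.fraction_r_preferring else "S"
        pattern = {
            "hard": hard,
            "signal_gain": config.hard_attenuation if hard else 1.0,
            "coupling_freq": rng.uniform(*config.slow_freq_band),  # cycles / 100 frames
        }
        profiles.append(
            LigandProfile(
                ligand_id=lig,
                preferred_enantiomer=preferred,
                channel_baselines=baselines,
                channel_spreads=spreads,
                pattern_params=pattern,
                seed=int(rng.integers(2**31)),
                config=config,
            )
        )
    return profiles


def _fold(x: np.ndarray, band: float) -> np.ndarray:
    """Reflect an unbounded walk into [-band, band] (exact triangular fold)."""
    p = np.mod(x + band, 4.0 * band)
    return np.where(p < 2.0 * band, p - band, 3.0 * band - p)


def _wrap_dihedral(x: np.ndarray) -> np.ndarray:
    return np.mod(x + 180.0, 360.0) - 180.0


def generate_trajectory(
    profile: LigandProfile, class_label: str, replicate: int
) -> np.ndarray:
    """One (n_frames, n_channels) descriptor matrix in physical units.

    Deterministic in (master seed, ligand, class, replicate). Both classes
    share every marginal ingredient; only oscillation frequency (temporal
    mode) or phase ordering (coupling mode) differs on informative channels.
    """
    if class_label not in (REACTIVE, NON_REACTIVE):
        raise LabelingError(f"unknown class tag {class_label!r}")
    cfg = profile.config
    reactive = class_label == REACTIVE
    rng = np.random.default_rng(
        np.random.SeedSequence(
            cfg.master_seed, spawn_key=(2, profile.ligand_id, int(reactive), replicate)
        )
    )
    t = np.arange(cfg.n_frames) / 100.0  # frequency bands are cycles / 100 frames
    z = np.empty((cfg.n_frames, cfg.n_channels))
    info = dict(zip(cfg.informative_channels, cfg.informative_weights))
    gain = profile.pattern_params["signal_gain"]
    phi0 = rng.uniform(0.0, 2 * np.pi)
    for c in range(cfg.n_channels):
        if c == cfg.slow_channel:
            z[:, c] = 0.0  # filled below in physical units
            continue
        f_bg = rng.uniform(*cfg.slow_freq_band)
        ph_bg = rng.uniform(0.0, 2 * np.pi)
        if cfg.signal_mode == "temporal" and c in info:
            # class-dependent frequency band, class-independent marginal
            f_cls = rng.uniform(*cfg.fast_freq_band) if reactive else rng.uniform(
                *cfg.slow_freq_band
            )
            ph_cls = rng.uniform(0.0, 2 * np.pi)
            w = info[c] * gain
            sig = w * np.sin(2 * np.pi * f_cls * t + ph_cls) + (1.0 - w) * np.sin(
                2 * np.pi * f_bg * t + ph_bg
            )
        elif cfg.signal_mode == "coupling" and c in info:
            # reactive: coupled channels phase-locked (in phase); non-reactive:
            # independent random phases -> identical marginals either way
            freq = profile.pattern_params["coupling_freq"]
            phase = phi0 if reactive else rng.uniform(0.0, 2 * np.pi)
            boost = cfg.coupling_amplitude / max(cfg.osc_amplitude, 1e-12)
            sig = boost * np.sin(2 * np.pi * freq * t + phase)
        else:
            sig = np.sin(2 * np.pi * f_bg * t + ph_bg)
        z[:, c] = cfg.osc_amplitude * sig
    z += rng.normal(0.0, cfg.noise_sd, size=z.shape)

    x = profile.channel_baselines[None, :] + profile.channel_spreads[None, :] * z
    # the slow dihedral: reflected random walk around the catalytic orientation.
    # Seeded by (ligand, replicate) only, so paired replicates of the two
    # classes share the identical path: this channel carries no class signal
    # and its class marginals match exactly.
    walk_rng = np.random.default_rng(
        np.random.SeedSequence(cfg.master_seed, spawn_key=(4, profile.ligand_id, replicate))
    )
    steps = walk_rng.normal(0.0, cfg.slow_step_sd, size=cfg.n_frames)
    steps[0] = 0.0
    x[:, cfg.slow_channel] = profile.channel_baselines[cfg.slow_channel] + _fold(
        np.cumsum(steps), cfg.slow_drift_band
    )
    for c, kind in enumerate(cfg.kinds):
        if kind == "angle":
            x[:, c] = np.clip(x[:, c], 0.0, 180.0)
        elif kind == "dihedral":
            x[:, c] = _wrap_dihedral(x[:, c])
        else:
            x[:, c] = np.maximum(x[:, c], 0.05)
    return x


def generate_dataset(config: GeneratorConfig) -> DatasetBundle:
    """Full labelled dataset: n_ligands x 2 classes x n_per_class trajectories."""
    profiles = make_ligand_profiles(config)
    n = config.n_ligands * 2 * config.n_per_class
    tensors = np.empty((n, config.n_frames, config.n_channels), dtype=np.float32)
    labels = np.empty(n, dtype=np.int8)
    ligand_ids = np.empty(n, dtype=np.int64)
    enantiomers = np.empty(n, dtype="U1")
    i = 0
    for prof in profiles:
        other = "R" if prof.preferred_enantiomer == "S" else "S"
        for label, cls in ((1, REACTIVE), (0, NON_REACTIVE)):
            for rep in range(config.n_per_class):
                tensors[i] = generate_trajectory(prof, cls, rep)
                labels[i] = label
                ligand_ids[i] = prof.ligand_id
                enantiomers[i] = prof.preferred_enantiomer if label else other
                i += 1
    return DatasetBundle(
        tensors=tensors,
        labels=labels,
        ligand_ids=ligand_ids,
        enantiomers=enantiomers,
        descriptor_names=[f"d{c + 1}" for c in range(config.n_channels)],
        units=config.units,
        dt=config.dt,
        meta={
            "generator": "trajsel.synthetic",
            "master_seed": config.master_seed,
            "signal_mode": config.signal_mode,
            "null": False,
        },
    )


def generate_null_dataset(config: GeneratorConfig) -> DatasetBundle:
    """Same trajectories, but labels permuted within each ligand (no class signal)."""
    bundle = generate_dataset(config)
    rng = np.random.default_rng(np.random.SeedSequence(config.master_seed, spawn_key=(3,)))
    labels = bundle.labels.copy()
    for lig in np.unique(bundle.ligand_ids):
        idx = np.where(bundle.ligand_ids == lig)[0]
        labels[idx] = labels[rng.permutation(idx)]
    bundle.labels = labels
    bundle.meta["null"] = True
    return bundle


def shuffle_frames(bundle: DatasetBundle, seed: int = 0) -> DatasetBundle:
    """Independently permute the frame order of every trajectory.

    Destroys temporal patterns while preserving each frame's joint
    cross-channel values (and hence all marginals).
    """
    rng = np.random.default_rng(seed)
    shuffled = bundle.tensors.copy()
    for i in range(len(shuffled)):
        shuffled[i] = shuffled[i, rng.permutation(bundle.n_frames)]
    out = replace_tensors(bundle, shuffled)
    out.meta = dict(bundle.meta, frame_shuffled=True)
    return out


def replace_tensors(bundle: DatasetBundle, tensors: np.ndarray) -> DatasetBundle:
    out = DatasetBundle(
        tensors=tensors,
        labels=bundle.labels.copy(),
        ligand_ids=bundle.ligand_ids.copy(),
        enantiomers=bundle.enantiomers.copy(),
        descriptor_names=list(bundle.descriptor_names),
        units=list(bundle.units),
        dt=bundle.dt,
        train_idx=None if bundle.train_idx is None else bundle.train_idx.copy(),
        val_idx=None if bundle.val_idx is None else bundle.val_idx.copy(),
        normalizer=bundle.normalizer,
        meta=dict(bundle.meta),
    )
    return out


def marginal_ks_statistics(bundle: DatasetBundle, max_samples: int = 20000, seed: int = 0):
    """Two-sample KS statistic per channel between pooled class distributions."""
    from scipy.stats import ks_2samp

    rng = np.random.default_rng(seed)
    stats = np.empty(bundle.n_channels)
    pos = bundle.tensors[bundle.labels == 1].reshape(-1, bundle.n_channels)
    neg = bundle.tensors[bundle.labels == 0].reshape(-1, bundle.n_channels)
    for c in range(bundle.n_channels):
        a, b = pos[:, c], neg[:, c]
        if len(a) > max_samples:
            a = a[rng.choice(len(a), max_samples, replace=False)]
        if len(b) > max_samples:
            b = b[rng.choice(len(b), max_samples, replace=False)]
        stats[c] = ks_2samp(a, b).statistic
    return stats


__all__ = [
    "GeneratorConfig",
    "LigandProfile",
    "make_ligand_profiles",
    "generate_trajectory",
    "generate_dataset",
    "generate_null_dataset",
    "shuffle_frames",
    "marginal_ks_statistics",
    "channel_kinds",
    "channel_units",
]
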