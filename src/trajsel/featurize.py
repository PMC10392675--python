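"""Geometric featurization of trajectory coordinates.

Each trajectory frame is reduced to a fixed vector of geometric descriptors —
interatomic distances (Å), bond/pseudo-bond angles (degrees, [0, 180]) and
signed dihedrals (degrees, [-180, 180), IUPAC convention) — defined by tuples
of atom indices. The resulting T x D matrix is the sole input representation
used by all downstream networks.

Channels are brought to a common scale with a min-max normalizer fitted on the
training split only; values outside the fitted range are clipped (and counted
via the ``logging`` channel) so that unseen ligands cannot silently shift the
input scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import FeaturizationError

logger = logging.getLogger(__name__)

_KIND_ARITY = {"distance": 2, "angle": 3, "dihedral": 4}
_KIND_UNITS = {"distance": "angstrom", "angle": "degrees", "dihedral": "degrees"}
_DEGENERACY_TOL = 1e-10


@dataclass(frozen=True)
class DescriptorDefinition:
    """One geometric observable: a named distance, angle or dihedral.

    ``atoms`` are 0-based indices into the topology; 1-based serial numbers
    from external files must be converted at the reader boundary.
    """

    name: str
    kind: str
    atoms: tuple[int, ...]
    units: str = ""

    def __post_init__(self):
        if self.kind not in _KIND_ARITY:
            raise FeaturizationError(f"unknown descriptor kind {self.kind!r}")
        arity = _KIND_ARITY[self.kind]
        if len(self.atoms) != arity:
            raise FeaturizationError(
                f"{self.name}: {self.kind} needs {arity} atoms, got {len(self.atoms)}"
            )
        if len(set(self.atoms)) != len(self.atoms):
            raise FeaturizationError(f"{self.name}: atom indices must be distinct")
        if any(a < 0 for a in self.atoms):
            raise FeaturizationError(f"{self.name}: negative atom index")
        if not self.units:
            object.__setattr__(self, "units", _KIND_UNITS[self.kind])


@dataclass
class TrajectoryTensor:
    """T x D descriptor matrix for one trajectory plus its metadata."""

    values: np.ndarray
    descriptor_names: list[str]
    units: list[str]
    ligand_id: int = 0
    enantiomer: str = "S"
    class_label: str | None = None
    dt: float = 0.02  # ps per frame

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("values must be a T x D matrix")
        if self.values.shape[1] != len(self.descriptor_names):
            raise ValueError("descriptor_names length must match D")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# geometry primitives (vectorized over frames)
# ---------------------------------------------------------------------------


def _frames_array(coords):
    arr = np.asarray(coords, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3 or arr.shape[-1] != 3:
        raise FeaturizationError("coordinates must be (n_atoms, 3) or (T, n_atoms, 3)")
    return arr


def _check_indices(indices, n_atoms):
    for a in indices:
        if not 0 <= a < n_atoms:
            raise FeaturizationError(f"atom index {a} out of range (n_atoms={n_atoms})")


def compute_distance(coords, pair) -> float | np.ndarray:
    """Euclidean distance in Å between two atoms; vectorized over frames."""
    frames = _frames_array(coords)
    _check_indices(pair, frames.shape[1])
    i, j = pair
    d = np.linalg.norm(frames[:, j] - frames[:, i], axis=-1)
    return float(d[0]) if np.asarray(coords).ndim == 2 else d


def compute_angle(coords, triple) -> float | np.ndarray:
    """Angle A-B-C at vertex B, in degrees within [0, 180]."""
    frames = _frames_array(coords)
    _check_indices(triple, frames.shape[1])
    a, b, c = triple
    v1 = frames[:, a] - frames[:, b]
    v2 = frames[:, c] - frames[:, b]
    n1 = np.linalg.norm(v1, axis=-1)
    n2 = np.linalg.norm(v2, axis=-1)
    bad = np.where((n1 < _DEGENERACY_TOL) | (n2 < _DEGENERACY_TOL))[0]
    if bad.size:
        raise FeaturizationError(f"coincident atoms in angle at frame {bad[0]}")
    cosang = np.einsum("ij,ij->i", v1, v2) / (n1 * n2)
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return float(ang[0]) if np.asarray(coords).ndim == 2 else ang


def compute_dihedral(coords, quad) -> float | np.ndarray:
    """Signed dihedral A-B-C-D in degrees, IUPAC convention, in [-180, 180).

    0 for a cis (eclipsed) arrangement; +180 maps to -180.
    """
    frames = _frames_array(coords)
    _check_indices(quad, frames.shape[1])
    p0, p1, p2, p3 = (frames[:, k] for k in quad)
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.linalg.norm(n1, axis=-1)
    m2 = np.linalg.norm(n2, axis=-1)
    bad = np.where((m1 < _DEGENERACY_TOL) | (m2 < _DEGENERACY_TOL))[0]
    if bad.size:
        raise FeaturizationError(
            f"collinear atoms in dihedral at frame {bad[0]}"
        )
    b1u = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    x = np.einsum("ij,ij->i", n1, n2)
    y = np.einsum("ij,ij->i", np.cross(n1, b1u), n2)
    ang = np.degrees(np.arctan2(y, x))
    ang = np.where(ang >= 180.0, ang - 360.0, ang)  # map +180 -> -180
    return float(ang[0]) if np.asarray(coords).ndim == 2 else ang


_KIND_FUNC = {
    "distance": compute_distance,
    "angle": compute_angle,
    "dihedral": compute_dihedral,
}


def featurize_trajectory(
    frames, definitions: list[DescriptorDefinition], **meta
) -> TrajectoryTensor:
    """Reduce (T, n_atoms, 3) coordinates to a T x D descriptor tensor.

    Columns follow the definition order; geometry errors carry the offending
    frame index.
    """
    arr = _frames_array(frames)
    if arr.shape[0] < 1:
        raise FeaturizationError("need at least one frame")
    cols = [np.asarray(_KIND_FUNC[d.kind](arr, d.atoms), dtype=np.float64) for d in definitions]
    values = np.stack(cols, axis=1)
    return TrajectoryTensor(
        values=values,
        descriptor_names=[d.name for d in definitions],
        units=[d.units for d in definitions],
        **meta,
    )


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


@dataclass
class Normalizer:
    """Per-channel min-max scaling to [0, 1], fitted on the training split only."""

    offset: np.ndarray = field(default_factory=lambda: np.zeros(0))
    scale: np.ndarray = field(default_factory=lambda: np.ones(0))
    method: str = "minmax"

    @classmethod
    def fit(cls, train_stack: np.ndarray) -> "Normalizer":
        """Fit on a (N, T, D) or (T, D) stack of training tensors."""
        arr = np.asarray(train_stack, dtype=np.float64)
        if arr.ndim == 2:
            arr = arr[None]
        lo = arr.min(axis=(0, 1))
        hi = arr.max(axis=(0, 1))
        scale = hi - lo
        flat = scale <= 0
        if flat.any():
            logger.warning(
                "constant channel(s) %s: scale set to 1", np.where(flat)[0].tolist()
            )
            scale = np.where(flat, 1.0, scale)
        return cls(offset=lo, scale=scale)

    def apply(self, x: np.ndarray, clip: bool = True) -> np.ndarray:
        z = (np.asarray(x, dtype=np.float64) - self.offset) / self.scale
        if clip:
            n_out = int(np.sum((z < 0) | (z > 1)))
            if n_out:
                logger.info("clipped %d values outside the training range", n_out)
            z = np.clip(z, 0.0, 1.0)
        return z

    def invert(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(z, dtype=np.float64) * self.scale + self.offset

    def to_dict(self) -> dict:
        return {
            "offset": self.offset.tolist(),
            "scale": self.scale.tolist(),
            "method": self.method,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Normalizer":
        return cls(
            offset=np.asarray(d["offset"], dtype=np.float64),
            scale=np.asarray(d["scale"], dtype=np.float64),
            method=d.get("method", "minmax"),
        )


# ---------------------------------------------------------------------------
# descriptor-definition files and the default 15-descriptor layout
# ---------------------------------------------------------------------------


def read_descriptor_definitions(path) -> list[DescriptorDefinition]:
    """Read a columnar text file: ``name kind i,j[,k[,l]] [units]`` per row."""
    defs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 3:
                raise FeaturizationError(f"{path}:{lineno}: expected 'name kind atoms'")
            name, kind, atoms = parts[0], parts[1], parts[2]
            units = parts[3] if len(parts) > 3 else ""
            defs.append(
                DescriptorDefinition(
                    name=name,
                    kind=kind,
                    atoms=tuple(int(a) for a in atoms.split(",")),
                    units=units,
                )
            )
    return defs


def write_descriptor_definitions(path, definitions: list[DescriptorDefinition]):
    with open(path, "w") as fh:
        fh.write("# name kind atom_indices(0-based,comma-separated) units\n")
        for d in definitions:
            fh.write(f"{d.name} {d.kind} {','.join(map(str, d.atoms))} {d.units}\n")


#: kind of each of the 15 default channels (0-based index -> kind).
#: d1, d2 and d11..d15 are distances; d4..d8 angles; d3, d9, d10 dihedrals.
#: d3 is the slow χ1-like dihedral that distinguishes catalytic (-90°) from
#: non-catalytic (+90°) ligand orientations.
DEFAULT_CHANNEL_KINDS: tuple[str, ...] = (
    "distance",  # d1  Hα–Nz distance (proton to abstract -> attacking atom)
    "distance",  # d2
    "dihedral",  # d3  χ1 (slow ligand-orientation dihedral)
    "angle",     # d4  Hα–Nz–CE
    "angle",     # d5  Hα–Nz–Hz1
    "angle",     # d6  Hα–Nz–Hz2
    "angle",     # d7
    "angle",     # d8
    "dihedral",  # d9
    "dihedral",  # d10
    "distance",  # d11 water – Lys-NH2
    "distance",  # d12 water – Thr-OH oxygen
    "distance",  # d13
    "distance",  # d14
    "distance",  # d15 Nz–Cα
)


def default_descriptor_set(atom_indices: dict[str, tuple[int, ...]] | None = None):
    """The default d1..d15 layout (kinds/units fixed, atom tuples configurable).

    Only a subset of the fifteen descriptors has a fixed chemical identity
    (d1, d3, d4, d5, d6, d11, d12, d15); the remaining tuples are stand-ins
    that the user is expected to override for a real topology via
    ``atom_indices`` or a definitions file.
    """
    defs = []
    counter = 0
    for i, kind in enumerate(DEFAULT_CHANNEL_KINDS):
        name = f"d{i + 1}"
        arity = _KIND_ARITY[kind]
        if atom_indices and name in atom_indices:
            atoms = tuple(atom_indices[name])
        else:
            atoms = tuple(range(counter, counter + arity))
        counter += arity
        defs.append(DescriptorDefinition(name=name, kind=kind, atoms=atoms))
    return defs


# ---------------------------------------------------------------------------
# coordinate input
# ---------------------------------------------------------------------------


def read_pdb_frames(path) -> np.ndarray:
    """Read a multi-model PDB (MODEL/ENDMDL records) into (T, n_atoms, 3) Å.

    This is the built-in frame source; binary trajectory formats can be
    plugged in through any reader that yields the same array layout.
    """
    import biotite.structure.io.pdb as pdb

    pdb_file = pdb.PDBFile.read(str(path))
    stack = pdb_file.get_structure(model=None)
    coords = np.asarray(stack.coord, dtype=np.float64)
    if coords.ndim == 2:
        coords = coords[None]
    return coords
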