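"""Ligand pose encoding and torsion-tree kinematics.

A flexible-ligand pose is a fixed-length real vector: a rigid-body translation
(3 genes, Å), a rigid-body orientation (4 genes, unit quaternion ``w,x,y,z``)
and one torsion angle per rotatable bond (degrees, wrapped to ``[-180, 180)``).
Given a :class:`LigandTopology` — the rigid root set plus a rooted tree of
rotatable branches — :func:`decode_pose` turns that vector into Cartesian atom
coordinates: torsions are applied branch-by-branch from the root outward, then
the whole ligand is rotated about the root-set centroid and translated.

The module also provides the plain (atom-order-matched, no superposition)
RMSD used throughout docking evaluation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Atom",
    "Branch",
    "LigandTopology",
    "PoseGenome",
    "GeneBounds",
    "GenomeSpace",
    "TopologyError",
    "decode_pose",
    "rmsd",
    "heavy_atom_rmsd",
    "wrap_degrees",
    "quat_to_matrix",
    "axis_angle_matrix",
    "random_unit_quaternion",
    "docking_space",
]

IDENTITY_QUAT = np.array([1.0, 0.0, 0.0, 0.0])


class TopologyError(ValueError):
    """A ligand topology or genome violates its structural contract."""


@dataclass(frozen=True)
class Atom:
    """One ligand atom: identity, typing and reference coordinates (Å)."""

    serial: int
    name: str
    element: str
    ad_type: str
    charge: float
    coords: tuple[float, float, float]


@dataclass(frozen=True)
class Branch:
    """A rotatable bond and the atom set it moves.

    ``bond`` is ``(anchor_serial, distal_serial)``; the rotation axis runs from
    the anchor atom to the distal atom, and ``moving`` contains every atom
    distal to the bond (the distal bond atom itself lies on the axis and is
    included by convention).  ``parent`` is the index of the enclosing branch
    in the topology's depth-first branch list, or ``None`` for branches
    attached directly to the root.
    """

    bond: tuple[int, int]
    moving: frozenset[int]
    parent: int | None = None


@dataclass
class LigandTopology:
    """Atoms, bonds and the rooted torsion tree of a flexible ligand.

    Branches are stored in depth-first order (each branch after its parent),
    which is also the order torsion genes are assigned.
    """

    atoms: list[Atom]
    bonds: list[tuple[int, int]]
    root: frozenset[int]
    branches: list[Branch]
    torsdof: int

    # derived, built once in __post_init__
    _row: dict[int, int] = field(init=False, repr=False)
    _ref: np.ndarray = field(init=False, repr=False)
    _root_rows: np.ndarray = field(init=False, repr=False)
    _branch_rows: list[np.ndarray] = field(init=False, repr=False)
    _branch_axis_rows: list[tuple[int, int]] = field(init=False, repr=False)
    _heavy_rows: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise TopologyError("duplicate atom serials")
        if self.torsdof != len(self.branches):
            raise TopologyError(
                f"torsdof {self.torsdof} != number of branches {len(self.branches)}"
            )
        if not self.root:
            raise TopologyError("empty root set")
        known = set(serials)
        if not self.root <= known:
            raise TopologyError("root references unknown atoms")
        for i, br in enumerate(self.branches):
            a, b = br.bond
            if br.moving & self.root:
                raise TopologyError(f"branch {i} moving set overlaps the root set")
            if b not in br.moving or a in br.moving:
                raise TopologyError(
                    f"branch {i}: distal bond atom must move, anchor must not"
                )
            if not br.moving <= known:
                raise TopologyError(f"branch {i} references unknown atoms")
            if br.parent is not None:
                if not (0 <= br.parent < i):
                    raise TopologyError(f"branch {i} parent out of order (not acyclic)")
                if not br.moving <= self.branches[br.parent].moving:
                    raise TopologyError(
                        f"branch {i} moving set escapes its parent branch"
                    )
        self._row = {s: i for i, s in enumerate(serials)}
        self._ref = np.array([a.coords for a in self.atoms], dtype=float)
        self._root_rows = np.array(sorted(self._row[s] for s in self.root), dtype=int)
        self._branch_rows = [
            np.array(sorted(self._row[s] for s in br.moving), dtype=int)
            for br in self.branches
        ]
        self._branch_axis_rows = [
            (self._row[br.bond[0]], self._row[br.bond[1]]) for br in self.branches
        ]
        self._heavy_rows = np.array(
            [i for i, a in enumerate(self.atoms) if a.element.upper() != "H"],
            dtype=int,
        )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def ref_coords(self) -> np.ndarray:
        """Reference (input) coordinates, shape ``(n_atoms, 3)``."""
        return self._ref.copy()

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    @property
    def atom_types(self) -> list[str]:
        return [a.ad_type for a in self.atoms]

    def row_of(self, serial: int) -> int:
        return self._row[serial]


def wrap_degrees(angles: np.ndarray | float) -> np.ndarray | float:
    """Wrap angle(s) to the half-open interval ``[-180, 180)``."""
    return (np.asarray(angles) + 180.0) % 360.0 - 180.0


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix of a quaternion ``(w, x, y, z)`` (normalized here)."""
    w, x, y, z = np.asarray(q, dtype=float) / np.linalg.norm(q)
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def axis_angle_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix about ``axis`` by ``angle_rad``."""
    ux, uy, uz = (float(v) for v in axis)
    n = math.sqrt(ux * ux + uy * uy + uz * uz)
    if n < 1e-12:
        raise ValueError("degenerate rotation axis")
    ux, uy, uz = ux / n, uy / n, uz / n
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    t = 1.0 - c
    return np.array([
        [c + ux * ux * t, ux * uy * t - uz * s, ux * uz * t + uy * s],
        [uy * ux * t + uz * s, c + uy * uy * t, uy * uz * t - ux * s],
        [uz * ux * t - uy * s, uz * uy * t + ux * s, c + uz * uz * t],
    ])


def random_unit_quaternion(rng: np.random.Generator) -> np.ndarray:
    """Uniformly distributed unit quaternion (4 normal deviates, normalized)."""
    q = rng.normal(size=4)
    n = np.linalg.norm(q)
    if n < 1e-12:  # pragma: no cover - measure-zero
        return IDENTITY_QUAT.copy()
    q = q / n
    return q if q[0] >= 0 else -q


@dataclass
class PoseGenome:
    """The docking search variable: translation, orientation, torsions."""

    translation: np.ndarray  # (3,) Å
    orientation: np.ndarray  # (4,) unit quaternion w,x,y,z
    torsions: np.ndarray  # (n,) degrees in [-180, 180)

    def __post_init__(self) -> None:
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.orientation = np.asarray(self.orientation, dtype=float).reshape(4)
        self.torsions = np.asarray(self.torsions, dtype=float).reshape(-1)

    @classmethod
    def identity(cls, n_torsions: int) -> "PoseGenome":
        return cls(np.zeros(3), IDENTITY_QUAT.copy(), np.zeros(n_torsions))

    @classmethod
    def from_vector(cls, vec: np.ndarray) -> "PoseGenome":
        vec = np.asarray(vec, dtype=float)
        if vec.size < 7:
            raise TopologyError("pose vector needs at least 7 genes")
        return cls(vec[:3], vec[3:7], vec[7:])

    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.translation, self.orientation, self.torsions])

    def normalized(self) -> "PoseGenome":
        """Copy with unit quaternion and wrapped torsions."""
        q = self.orientation
        n = np.linalg.norm(q)
        q = IDENTITY_QUAT.copy() if n < 1e-12 else q / n
        return PoseGenome(self.translation.copy(), q, wrap_degrees(self.torsions))


@dataclass
class GeneBounds:
    """Per-gene search limits (box extents, quaternion cube, torsion range)."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float).reshape(-1)
        self.upper = np.asarray(self.upper, dtype=float).reshape(-1)
        if self.lower.shape != self.upper.shape:
            raise ValueError("bounds shape mismatch")
        if not np.all(self.lower < self.upper):
            raise ValueError("every lower bound must be < its upper bound")

    @property
    def n_genes(self) -> int:
        return self.lower.size

    @property
    def widths(self) -> np.ndarray:
        return self.upper - self.lower

    def clip(self, vec: np.ndarray) -> np.ndarray:
        return np.minimum(np.maximum(vec, self.lower), self.upper)

    def contains(self, vec: np.ndarray, atol: float = 0.0) -> bool:
        v = np.asarray(vec, dtype=float)
        return bool(
            np.all(v >= self.lower - atol) and np.all(v <= self.upper + atol)
        )

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(self.lower, self.upper)


@dataclass
class GenomeSpace:
    """A bounded real search space, optionally with pose structure.

    ``quaternion`` / ``torsions`` mark gene slices that need renormalization /
    angular wrapping after any stochastic operator; plain benchmark landscapes
    leave both ``None`` and repair reduces to clipping.
    """

    bounds: GeneBounds
    quaternion: slice | None = None
    torsions: slice | None = None

    @property
    def n_genes(self) -> int:
        return self.bounds.n_genes

    def repair(self, vec: np.ndarray) -> np.ndarray:
        """Return a copy satisfying all genome invariants."""
        v = np.asarray(vec, dtype=float).copy()
        if self.torsions is not None:
            v[self.torsions] = wrap_degrees(v[self.torsions])
        v = self.bounds.clip(v)
        if self.quaternion is not None:
            q = v[self.quaternion]
            n = np.linalg.norm(q)
            v[self.quaternion] = IDENTITY_QUAT if n < 1e-12 else q / n
        return v

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        return self.repair(self.bounds.sample(rng))


def docking_space(topo: LigandTopology, translation_halfwidth: float,
                  center: np.ndarray | None = None) -> GenomeSpace:
    """Standard pose space: translations within ``center ± halfwidth`` per axis,
    quaternion components in ``[-1, 1]``, torsions in ``[-180, 180)``."""
    c = np.zeros(3) if center is None else np.asarray(center, dtype=float)
    lo = np.concatenate([c - translation_halfwidth, -np.ones(4),
                         np.full(topo.torsdof, -180.0)])
    hi = np.concatenate([c + translation_halfwidth, np.ones(4),
                         np.full(topo.torsdof, 180.0)])
    return GenomeSpace(GeneBounds(lo, hi), quaternion=slice(3, 7),
                       torsions=slice(7, 7 + topo.torsdof))


def decode_pose(genome: PoseGenome | np.ndarray, topo: LigandTopology) -> np.ndarray:
    """Cartesian coordinates (Å, shape ``(n_atoms, 3)``) of a pose.

    Torsion rotations are applied depth-first from the root outward about the
    current positions of each rotatable bond, then the whole ligand is rotated
    about the root-set centroid by the genome quaternion and translated.
    """
    if not isinstance(genome, PoseGenome):
        genome = PoseGenome.from_vector(np.asarray(genome))
    if genome.torsions.size != topo.torsdof:
        raise TopologyError(
            f"genome has {genome.torsions.size} torsions, topology expects "
            f"{topo.torsdof}"
        )
    coords = topo._ref.copy()
    for tau, rows, (ra, rb) in zip(
        genome.torsions, topo._branch_rows, topo._branch_axis_rows
    ):
        a = coords[ra]
        axis = coords[rb] - a
        rot = axis_angle_matrix(axis, math.radians(float(tau)))
        coords[rows] = (coords[rows] - a) @ rot.T + a
    center = coords[topo._root_rows].mean(axis=0)
    rot = quat_to_matrix(genome.orientation)
    return (coords - center) @ rot.T + center + genome.translation


def rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Plain atom-order-matched RMSD (Å); no superposition is performed.

    Both coordinate sets are assumed to live in the same (receptor) frame,
    the docking convention for comparing a docked pose to the crystal pose.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"coordinate shape mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("empty coordinate sets")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))


def heavy_atom_rmsd(topo: LigandTopology, coords_a: np.ndarray,
                    coords_b: np.ndarray) -> float:
    """RMSD over non-hydrogen atoms (the default docking success metric)."""
    rows = topo._heavy_rows
    if rows.size == 0:
        raise ValueError("topology has no heavy atoms")
    return rmsd(np.asarray(coords_a)[rows], np.asarray(coords_b)[rows])
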