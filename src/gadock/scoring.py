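"""Objective functions for the docking search.

Three families are provided behind one callable contract (vector in, energy
out, evaluation counter on the side):

* :func:`grid_score` — AutoDock-style precomputed affinity grid maps: each
  atom looks up its atom-type map by trilinear interpolation, plus
  charge-weighted electrostatic interpolation and a torsional entropy penalty
  ``W_tors * torsdof``.
* :func:`toy_pairwise_energy` — a desk-scale explicit receptor: 12-6
  Lennard-Jones plus Coulomb with a distance-dependent dielectric 4r.
* :func:`benchmark_landscape` — analytic multimodal test surfaces (sphere,
  rastrigin-like, double-funnel) operating directly on raw genome vectors so
  operator and archive behavior can be studied without any molecular fixture.

Poses that leave the grid box receive a large finite penalty (1e5 plus the
squared distance back to the box) instead of raising, so stochastic search
operators stay total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .genome import (
    GeneBounds,
    GenomeSpace,
    LigandTopology,
    PoseGenome,
    decode_pose,
)

__all__ = [
    "GridMapSet",
    "ObjectiveFunction",
    "ReceptorAtom",
    "trilinear_interpolate",
    "grid_score",
    "toy_pairwise_energy",
    "benchmark_landscape",
    "make_grid_objective",
    "OUT_OF_BOX_PENALTY",
    "DEFAULT_W_TORS",
    "COULOMB_CONSTANT",
]

OUT_OF_BOX_PENALTY = 1.0e5
#: AutoDock 4 torsional free-energy weight, kcal/mol per active torsion.
DEFAULT_W_TORS = 0.2983
#: Electrostatic conversion factor, kcal/mol per (e^2/Å).
COULOMB_CONSTANT = 332.06
#: Floor on interatomic distance in the Coulomb term (Å).
MIN_COULOMB_DISTANCE = 0.5


@dataclass
class GridMapSet:
    """Per-atom-type 3-D affinity lattices sharing one box geometry.

    ``npts`` are points per axis (odd, AutoDock convention of NELEMENTS+1);
    each lattice is indexed ``[ix, iy, iz]`` with x the fastest-varying axis
    in the on-disk format.
    """

    center: np.ndarray  # (3,) Å
    spacing: float  # Å
    npts: tuple[int, int, int]
    maps: dict[str, np.ndarray]
    electrostatics: np.ndarray | None = None

    _flat_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def flat_rows(self, types: tuple[str, ...]) -> tuple[np.ndarray, np.ndarray]:
        """Flattened lattices stacked per unique atom type, plus the per-atom
        row index into that stack (cached; used by the vectorized scorer)."""
        key = types
        hit = self._flat_cache.get(key)
        if hit is None:
            unique = sorted(set(types))
            missing = [t for t in unique if t not in self.maps]
            if missing:
                raise KeyError(f"no affinity map for atom type {missing[0]!r}")
            stack = np.stack([self.maps[t].reshape(-1) for t in unique])
            rows = np.array([unique.index(t) for t in types])
            hit = (stack, rows)
            self._flat_cache[key] = hit
        return hit

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        self.npts = tuple(int(n) for n in self.npts)
        if any(n < 2 or n % 2 == 0 for n in self.npts):
            raise ValueError("points per axis must be odd and >= 3")
        for name, lat in self.maps.items():
            if lat.shape != self.npts:
                raise ValueError(
                    f"map {name!r} shape {lat.shape} != points-per-axis {self.npts}"
                )
        if self.electrostatics is not None and self.electrostatics.shape != self.npts:
            raise ValueError("electrostatic map shape mismatch")

    @property
    def origin(self) -> np.ndarray:
        """Lower corner of the box (Å)."""
        return self.center - self.spacing * (np.array(self.npts) - 1) / 2.0

    @property
    def upper(self) -> np.ndarray:
        return self.center + self.spacing * (np.array(self.npts) - 1) / 2.0

    def out_of_box_sq(self, points: np.ndarray) -> np.ndarray:
        """Squared distance of each point to the box (0 inside)."""
        pts = np.atleast_2d(points)
        d = np.maximum(self.origin - pts, 0.0) + np.maximum(pts - self.upper, 0.0)
        return np.sum(d * d, axis=1)


def trilinear_interpolate(lattice: np.ndarray, point: np.ndarray,
                          origin: np.ndarray, spacing: float) -> float:
    """Standard 8-corner trilinear blend of one lattice at one point (Å).

    Points outside the lattice return the out-of-box penalty
    ``OUT_OF_BOX_PENALTY + squared distance to the box`` rather than raising.
    """
    lattice = np.asarray(lattice)
    p = (np.asarray(point, dtype=float) - np.asarray(origin, dtype=float)) / spacing
    hi = np.array(lattice.shape) - 1
    if np.any(p < 0) or np.any(p > hi):
        d = np.maximum(-p, 0.0) + np.maximum(p - hi, 0.0)
        return OUT_OF_BOX_PENALTY + float(np.sum((d * spacing) ** 2))
    i = np.minimum(p.astype(int), hi - 1)
    f = p - i
    ix, iy, iz = i
    fx, fy, fz = f
    c = lattice[ix : ix + 2, iy : iy + 2, iz : iz + 2]
    wx = np.array([1 - fx, fx])
    wy = np.array([1 - fy, fy])
    wz = np.array([1 - fz, fz])
    return float(np.einsum("i,j,k,ijk->", wx, wy, wz, c))


def _interpolate_weights(maps: GridMapSet, points: np.ndarray):
    """Shared corner indices/weights for all points; assumes all inside."""
    p = (points - maps.origin) / maps.spacing
    hi = np.array(maps.npts) - 1
    i = np.minimum(p.astype(int), hi - 1)
    f = p - i
    return i, f


def grid_score(genome: PoseGenome | np.ndarray, topo: LigandTopology,
               maps: GridMapSet, w_tors: float = DEFAULT_W_TORS) -> float:
    """Grid-map docking energy of a pose (kcal/mol).

    Sum over atoms of the atom-type map interpolation plus charge times the
    electrostatic-map interpolation, plus ``w_tors * torsdof``.  Atoms outside
    the box contribute the out-of-box penalty instead.
    """
    coords = decode_pose(genome, topo)
    outside = maps.out_of_box_sq(coords)
    energy = w_tors * topo.torsdof
    charges = topo.charges
    types = topo.atom_types
    inside = outside == 0.0
    if not np.all(inside):
        energy += float(np.sum(OUT_OF_BOX_PENALTY + outside[~inside]))
    if np.any(inside):
        idx = np.nonzero(inside)[0]
        i, f = _interpolate_weights(maps, coords[idx])
        # 8-corner weights, vectorized over atoms: (n, 8)
        wx = np.stack([1 - f[:, 0], f[:, 0]], axis=1)
        wy = np.stack([1 - f[:, 1], f[:, 1]], axis=1)
        wz = np.stack([1 - f[:, 2], f[:, 2]], axis=1)
        w = (wx[:, :, None, None] * wy[:, None, :, None]
             * wz[:, None, None, :]).reshape(len(idx), 8)
        # flat lattice indices of the 8 corners per atom: (n, 8)
        ny, nz = maps.npts[1], maps.npts[2]
        base = (i[:, 0] * ny + i[:, 1]) * nz + i[:, 2]
        offs = np.array([(dx * ny + dy) * nz + dz
                         for dx in (0, 1) for dy in (0, 1) for dz in (0, 1)])
        flat_idx = base[:, None] + offs[None, :]
        stack, rows = maps.flat_rows(tuple(types))
        vals = stack[rows[idx][:, None], flat_idx]
        energy += float(np.sum(w * vals))
        if maps.electrostatics is not None and np.any(charges[idx]):
            evals_ = maps.electrostatics.reshape(-1)[flat_idx]
            energy += float(np.sum(charges[idx] * np.sum(w * evals_, axis=1)))
    return energy


@dataclass(frozen=True)
class ReceptorAtom:
    """Explicit receptor atom for the toy pairwise objective."""

    coords: tuple[float, float, float]
    r_eq: float  # Å, pair equilibrium distance
    epsilon: float  # kcal/mol, pair well depth
    charge: float = 0.0


def toy_pairwise_energy(genome: PoseGenome | np.ndarray, topo: LigandTopology,
                        receptor_atoms: list[ReceptorAtom]) -> float:
    """Explicit-pair 12-6 Lennard-Jones + screened Coulomb energy (kcal/mol).

    Pair LJ parameters come from the receptor atom; ligand atoms contribute
    position and partial charge.  The Coulomb term uses the distance-dependent
    dielectric ``eps(r) = 4r`` with ``r`` floored at 0.5 Å so coincident
    fixture atoms stay finite.
    """
    coords = decode_pose(genome, topo)
    qlig = topo.charges
    rx = np.array([a.coords for a in receptor_atoms], dtype=float)
    req = np.array([a.r_eq for a in receptor_atoms])
    eps = np.array([a.epsilon for a in receptor_atoms])
    qrec = np.array([a.charge for a in receptor_atoms])
    d = np.linalg.norm(coords[:, None, :] - rx[None, :, :], axis=2)
    d = np.maximum(d, 1e-12)
    s6 = (req[None, :] / np.maximum(d, 1e-3)) ** 6
    lj = eps[None, :] * (s6 * s6 - 2.0 * s6)
    rc = np.maximum(d, MIN_COULOMB_DISTANCE)
    coul = COULOMB_CONSTANT * qlig[:, None] * qrec[None, :] / (4.0 * rc * rc)
    return float(np.sum(lj + coul))


class ObjectiveFunction:
    """A counted, bounded objective: ``genome vector -> energy``.

    Deterministic for a fixed input; the counter increments by exactly one
    per call, which the engine audits against its evaluation budget.
    """

    def __init__(self, fn: Callable[[np.ndarray], float], space: GenomeSpace,
                 name: str = "objective",
                 optimum_point: np.ndarray | None = None,
                 optimum_value: float | None = None):
        self._fn = fn
        self.space = space
        self.name = name
        self.optimum_point = None if optimum_point is None else np.asarray(
            optimum_point, dtype=float)
        self.optimum_value = optimum_value
        self.n_evals = 0

    @property
    def bounds(self) -> GeneBounds:
        return self.space.bounds

    def __call__(self, vec: np.ndarray) -> float:
        self.n_evals += 1
        return float(self._fn(np.asarray(vec, dtype=float)))

    def reset_counter(self) -> None:
        self.n_evals = 0

    def fresh(self) -> "ObjectiveFunction":
        """Copy with a zeroed counter (for independent batch runs)."""
        out = ObjectiveFunction(self._fn, self.space, self.name,
                                self.optimum_point, self.optimum_value)
        return out


def make_grid_objective(topo: LigandTopology, maps: GridMapSet,
                        space: GenomeSpace,
                        w_tors: float = DEFAULT_W_TORS) -> ObjectiveFunction:
    """Wrap :func:`grid_score` for a fixed ligand/map pair as an objective."""
    return ObjectiveFunction(
        lambda v: grid_score(v, topo, maps, w_tors=w_tors),
        space,
        name="grid",
    )


_DOUBLE_FUNNEL = {
    # (center offset along each axis, curvature, depth)
    "broad": (2.5, 0.5, 1.0),
    "narrow": (-2.5, 8.0, 2.0),
}


def benchmark_landscape(name: str, dimension: int) -> ObjectiveFunction:
    """Analytic test landscape with a known global optimum.

    ``sphere``          convex bowl, optimum 0 at the origin.
    ``rastrigin-like``  ``10 d + sum(x^2 - 10 cos(2 pi x))``: a regular lattice
                        of local minima, optimum 0 at the origin.
    ``double-funnel``   two quadratic funnels: a broad shallow one (depth -1)
                        and a narrow deep one (depth -2); the volume of the
                        global basin is small, so undirected sampling tends to
                        land in the wrong funnel.
    """
    if dimension < 1:
        raise ValueError("dimension must be >= 1")
    d = dimension
    if name == "sphere":
        bounds = GeneBounds(np.full(d, -5.12), np.full(d, 5.12))
        return ObjectiveFunction(
            lambda x: float(np.dot(x, x)), GenomeSpace(bounds),
            name="sphere", optimum_point=np.zeros(d), optimum_value=0.0)
    if name == "rastrigin-like":
        bounds = GeneBounds(np.full(d, -5.12), np.full(d, 5.12))
        two_pi = 2.0 * math.pi

        def rastrigin(x: np.ndarray) -> float:
            # scalar loop: an order of magnitude faster than ufuncs at d ~ 10
            total = 10.0 * d
            for v in x.tolist():
                total += v * v - 10.0 * math.cos(two_pi * v)
            return total

        return ObjectiveFunction(
            rastrigin, GenomeSpace(bounds),
            name="rastrigin-like", optimum_point=np.zeros(d), optimum_value=0.0)
    if name == "double-funnel":
        (o1, k1, d1) = _DOUBLE_FUNNEL["broad"]
        (o2, k2, d2) = _DOUBLE_FUNNEL["narrow"]
        c1 = np.full(d, o1)
        c2 = np.full(d, o2)

        def fn(x: np.ndarray) -> float:
            f1 = k1 * float(np.sum((x - c1) ** 2)) - d1
            f2 = k2 * float(np.sum((x - c2) ** 2)) - d2
            return min(f1, f2)

        obj = ObjectiveFunction(
            fn, GenomeSpace(GeneBounds(np.full(d, -5.0), np.full(d, 5.0))),
            name="double-funnel", optimum_point=c2, optimum_value=-d2)
        obj.funnel_centers = (c1, c2)  # type: ignore[attr-defined]
        obj.funnel_depths = (-d1, -d2)  # type: ignore[attr-defined]
        return obj
    raise ValueError(f"unknown landscape {name!r}")
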