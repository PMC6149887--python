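"""Deterministic synthetic fixtures: toy flexible ligands, grid maps with a
known global optimum, and the analytic landscape suite.

``make_toy_complex`` emulates a redocking experiment with known ground truth:
a compact helical chain ligand with a chosen number of rotatable bonds, and
one Gaussian-well affinity map per atom, each centered on that atom's
position in a randomly drawn target pose.  The grid energy is minimized
exactly when every atom sits at its target position, so the global-optimum
genome (and the reference pose coordinates) are known by construction —
something real receptor grids cannot provide.  What these fixtures do *not*
emulate: force-field ruggedness, inter-atom clash terms, pose symmetry.

Everything is bit-reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import (
    Atom,
    Branch,
    GenomeSpace,
    LigandTopology,
    PoseGenome,
    decode_pose,
    docking_space,
    random_unit_quaternion,
)
from .scoring import GridMapSet, ObjectiveFunction, benchmark_landscape, grid_score

__all__ = ["ToyComplex", "make_toy_complex", "make_landscape_suite",
           "make_chain_ligand"]

#: Helix geometry of the chain ligand (Å / degrees): compact enough that any
#: in-bounds pose keeps all atoms inside the grid box.
_HELIX_RADIUS = 1.5
_HELIX_RISE = 0.6
_HELIX_TURN_DEG = 100.0


def make_chain_ligand(n_torsions: int) -> LigandTopology:
    """Helical chain of ``n_torsions + 3`` atoms with ``n_torsions`` rotatable
    bonds: the first two atoms anchor the rigid root (all three when the
    ligand is rigid), and each bond ``(k+2, k+3)`` for ``k = 0..n-1`` rotates
    every atom distal to it.  Every atom gets its own
    synthetic AutoDock-style type (``T0``, ``T1``, ...) so each one can carry
    its own affinity map."""
    if not 0 <= n_torsions <= 15:
        raise ValueError("n_torsions must lie in 0..15")
    n_atoms = n_torsions + 3
    idx = np.arange(n_atoms)
    theta = np.radians(_HELIX_TURN_DEG) * idx
    xyz = np.stack([
        _HELIX_RADIUS * np.cos(theta),
        _HELIX_RADIUS * np.sin(theta),
        _HELIX_RISE * idx,
    ], axis=1)
    xyz -= xyz.mean(axis=0)
    atoms = [
        Atom(serial=i + 1, name=f"C{i + 1}", element="C", ad_type=f"T{i}",
             charge=0.0, coords=tuple(np.round(xyz[i], 3)))
        for i in range(n_atoms)
    ]
    bonds = [(i + 1, i + 2) for i in range(n_atoms - 1)]
    branches = [
        Branch(bond=(k + 2, k + 3),
               moving=frozenset(range(k + 3, n_atoms + 1)),
               parent=None if k == 0 else k - 1)
        for k in range(n_torsions)
    ]
    root = frozenset({1, 2, 3}) if n_torsions == 0 else frozenset({1, 2})
    return LigandTopology(atoms=atoms, bonds=bonds, root=root,
                          branches=branches, torsdof=n_torsions)


@dataclass
class ToyComplex:
    """A synthetic redocking problem with known ground truth."""

    topology: LigandTopology
    maps: GridMapSet
    space: GenomeSpace
    optimum_genome: PoseGenome
    optimum_coords: np.ndarray
    optimum_energy: float
    well_depth: float
    well_sigma: float
    seed: int

    def objective(self) -> ObjectiveFunction:
        """Fresh counted grid-score objective for this complex."""
        topo, maps = self.topology, self.maps
        return ObjectiveFunction(
            lambda v: grid_score(v, topo, maps, w_tors=0.0),
            self.space, name=f"toy-complex-{self.seed}",
            optimum_point=self.optimum_genome.to_vector(),
            optimum_value=self.optimum_energy)


def make_toy_complex(n_torsions: int, seed: int,
                     spacing: float = 0.5, npts: int = 41,
                     well_depth: float = 1.0, well_sigma: float = 2.0,
                     translation_halfwidth: float = 3.5) -> ToyComplex:
    """Build a chain ligand plus per-atom Gaussian-well grid maps.

    A target pose is drawn from the seed: uniform random orientation and
    torsions, with the translation centering the resulting conformer in the
    box (plus a ±1.5 Å jitter, clipped to the search bounds).  Random
    torsions can stretch the chain into an extended conformer, so draws are
    rejected until every atom sits at least 1.5 Å inside the box — the
    reference pose is always fully scoreable.  Atom ``a``'s map holds
    ``-well_depth * exp(-|g - t_a|^2 / (2 sigma^2))`` at each grid node
    ``g``, where ``t_a`` is the atom's target position.  The grid score of
    the target genome is stored (and self-checked) as the construction's
    optimum energy; each map has a single basin, so no deeper basin exists.
    """
    rng = np.random.default_rng(seed)
    topo = make_chain_ligand(n_torsions)
    space = docking_space(topo, translation_halfwidth)

    box_half = spacing * (npts - 1) / 2.0
    t_lo = space.bounds.lower[:3]
    t_hi = space.bounds.upper[:3]
    for _ in range(200):
        probe = PoseGenome(
            translation=np.zeros(3),
            orientation=random_unit_quaternion(rng),
            torsions=rng.uniform(-180.0, 180.0, size=n_torsions),
        )
        conformer = decode_pose(probe, topo)
        jitter = rng.uniform(-1.5, 1.5, size=3)
        translation = np.clip(-conformer.mean(axis=0) + jitter, t_lo, t_hi)
        coords = conformer + translation
        if np.abs(coords).max() <= box_half - 1.5:
            target = PoseGenome(translation, probe.orientation,
                                probe.torsions)
            target_coords = coords
            break
    else:  # pragma: no cover - generous box, compact ligand
        raise RuntimeError("could not place the target pose inside the box")

    center = np.zeros(3)
    axes = [center[d] + spacing * (np.arange(npts) - (npts - 1) / 2)
            for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    maps = {}
    for a, atom in enumerate(topo.atoms):
        tx, ty, tz = target_coords[a]
        d2 = (gx - tx) ** 2 + (gy - ty) ** 2 + (gz - tz) ** 2
        maps[atom.ad_type] = -well_depth * np.exp(-d2 / (2.0 * well_sigma ** 2))
    grid = GridMapSet(center=center, spacing=spacing, npts=(npts,) * 3,
                      maps=maps, electrostatics=np.zeros((npts,) * 3))

    optimum_energy = grid_score(target, topo, grid, w_tors=0.0)
    # construction self-check: no rival *basin* undercuts the target pose.
    # Poses in the target basin can dip ~1% below the stored value (trilinear
    # interpolation flattens the node-sampled well peak), so the margin is
    # basin-scale, not epsilon-scale.
    margin = 0.05 * well_depth * topo.n_atoms
    for _ in range(8):
        rival = grid_score(space.sample(rng), topo, grid, w_tors=0.0)
        if rival < optimum_energy - margin:  # pragma: no cover
            raise AssertionError("fixture self-check: deeper rival basin found")
    return ToyComplex(
        topology=topo, maps=grid, space=space,
        optimum_genome=target, optimum_coords=target_coords,
        optimum_energy=optimum_energy, well_depth=well_depth,
        well_sigma=well_sigma, seed=seed)


def make_landscape_suite(seed: int, dimension: int = 10
                         ) -> dict[str, ObjectiveFunction]:
    """The named analytic landscapes with recorded optima and bounds.

    The surfaces themselves are deterministic; the seed is recorded on each
    objective (``suite_seed``) so downstream runs can derive per-run seeds.
    """
    suite = {
        name: benchmark_landscape(name, dimension)
        for name in ("sphere", "rastrigin-like", "double-funnel")
    }
    for obj in suite.values():
        obj.suite_seed = seed  # type: ignore[attr-defined]
    return suite
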