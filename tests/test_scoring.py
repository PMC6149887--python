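"""Objective functions: interpolation, grid scoring, pairwise toy energy,
benchmark landscapes."""

import math

import numpy as np
import pytest

from gadock.fixtures import make_chain_ligand
from gadock.genome import Atom, LigandTopology, PoseGenome, decode_pose, docking_space
from gadock.scoring import (
    OUT_OF_BOX_PENALTY,
    COULOMB_CONSTANT,
    GridMapSet,
    ObjectiveFunction,
    ReceptorAtom,
    benchmark_landscape,
    grid_score,
    toy_pairwise_energy,
    trilinear_interpolate,
)


def brute_force_trilinear(lattice, point, origin, spacing):
    """Independent 8-term sum over corners with explicit weights."""
    p = (np.asarray(point) - np.asarray(origin)) / spacing
    i = np.minimum(p.astype(int), np.array(lattice.shape) - 2)
    f = p - i
    total = 0.0
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = ((f[0] if dx else 1 - f[0])
                     * (f[1] if dy else 1 - f[1])
                     * (f[2] if dz else 1 - f[2]))
                total += w * lattice[i[0] + dx, i[1] + dy, i[2] + dz]
    return total


class TestTrilinear:
    def test_grid_node_returns_stored_value(self, rng):
        lat = rng.normal(size=(5, 5, 5))
        origin = np.array([-1.0, -1.0, -1.0])
        assert trilinear_interpolate(lat, [-1 + 2 * 0.5, -1.0, -1 + 4 * 0.5],
                                     origin, 0.5) == pytest.approx(lat[2, 0, 4])

    def test_edge_midpoint_blends_half(self):
        lat = np.zeros((3, 3, 3))
        lat[1, 0, 0] = 1.0
        val = trilinear_interpolate(lat, [0.25, 0.0, 0.0], np.zeros(3), 0.5)
        assert val == pytest.approx(0.5)

    def test_random_interior_points_match_explicit_sum(self, rng):
        lat = rng.normal(size=(7, 6, 5))
        origin = np.array([1.0, -2.0, 0.5])
        spacing = 0.375
        upper = origin + spacing * (np.array(lat.shape) - 1)
        for _ in range(50):
            p = rng.uniform(origin, upper)
            got = trilinear_interpolate(lat, p, origin, spacing)
            want = brute_force_trilinear(lat, p, origin, spacing)
            assert got == pytest.approx(want, abs=1e-12)

    def test_outside_point_gets_finite_penalty(self):
        lat = np.zeros((3, 3, 3))
        val = trilinear_interpolate(lat, [10.0, 0.0, 0.0], np.zeros(3), 0.5)
        assert val >= OUT_OF_BOX_PENALTY
        assert np.isfinite(val)


def _single_atom_topology(charge=0.0):
    return LigandTopology(
        atoms=[Atom(1, "C1", "C", "T0", charge, (0.0, 0.0, 0.0))],
        bonds=[], root=frozenset({1}), branches=[], torsdof=0)


class TestGridScore:
    def test_zero_maps_zero_wtors_scores_zero(self, rng):
        topo = make_chain_ligand(2)
        space = docking_space(topo, 1.0)  # keep all atoms inside the 8 A box
        maps = GridMapSet(np.zeros(3), 0.5, (17, 17, 17),
                          {a.ad_type: np.zeros((17, 17, 17))
                           for a in topo.atoms})
        for _ in range(5):
            assert grid_score(space.sample(rng), topo, maps,
                              w_tors=0.0) == 0.0

    def test_single_atom_on_node_reduces_to_lookup(self):
        topo = _single_atom_topology()
        lat = np.zeros((5, 5, 5))
        lat[3, 2, 1] = -1.3
        maps = GridMapSet(np.zeros(3), 0.5, (5, 5, 5), {"T0": lat})
        # node (3,2,1) sits at origin + 0.5*(3,2,1) with origin = -1
        g = PoseGenome(np.array([0.5, 0.0, -0.5]), [1, 0, 0, 0], [])
        assert grid_score(g, topo, maps, w_tors=0.0) == pytest.approx(-1.3)

    def test_torsional_penalty_added_per_active_torsion(self):
        topo = make_chain_ligand(3)
        maps = GridMapSet(np.zeros(3), 0.5, (21, 21, 21),
                          {a.ad_type: np.zeros((21, 21, 21))
                           for a in topo.atoms})
        assert grid_score(PoseGenome.identity(3), topo, maps,
                          w_tors=0.3) == pytest.approx(0.9)

    def test_rigid_two_atom_pose_matches_trilinear_oracle(self, rng):
        topo = make_chain_ligand(0)
        space = docking_space(topo, 2.0)
        maps = GridMapSet(np.zeros(3), 0.5, (17, 17, 17),
                          {a.ad_type: rng.normal(size=(17, 17, 17))
                           for a in topo.atoms})
        for _ in range(10):
            v = space.sample(rng)
            coords = decode_pose(PoseGenome.from_vector(v), topo)
            want = sum(
                brute_force_trilinear(maps.maps[a.ad_type], coords[k],
                                      maps.origin, maps.spacing)
                for k, a in enumerate(topo.atoms))
            got = grid_score(v, topo, maps, w_tors=0.0)
            assert got == pytest.approx(want, abs=1e-9)

    def test_electrostatic_term_scales_with_charge(self):
        topo = _single_atom_topology(charge=0.5)
        lat = np.zeros((5, 5, 5))
        elec = np.full((5, 5, 5), 2.0)
        maps = GridMapSet(np.zeros(3), 0.5, (5, 5, 5), {"T0": lat},
                          electrostatics=elec)
        g = PoseGenome(np.zeros(3), [1, 0, 0, 0], [])
        assert grid_score(g, topo, maps, w_tors=0.0) == pytest.approx(1.0)

    def test_missing_atom_type_names_the_type(self):
        topo = _single_atom_topology()
        maps = GridMapSet(np.zeros(3), 0.5, (5, 5, 5),
                          {"XX": np.zeros((5, 5, 5))})
        with pytest.raises(KeyError, match="T0"):
            grid_score(PoseGenome(np.zeros(3), [1, 0, 0, 0], []), topo, maps)

    def test_out_of_box_pose_penalized_not_raised(self):
        topo = _single_atom_topology()
        maps = GridMapSet(np.zeros(3), 0.5, (5, 5, 5),
                          {"T0": np.zeros((5, 5, 5))})
        g = PoseGenome(np.array([50.0, 0.0, 0.0]), [1, 0, 0, 0], [])
        e = grid_score(g, topo, maps, w_tors=0.0)
        assert e >= OUT_OF_BOX_PENALTY and np.isfinite(e)

    def test_translation_covariance_with_shifted_map(self, rng):
        """Shifting pose and map content by whole grid cells together leaves
        the energy unchanged."""
        topo = _single_atom_topology()
        lat = rng.normal(size=(9, 9, 9))
        maps = GridMapSet(np.zeros(3), 0.5, (9, 9, 9), {"T0": lat})
        shifted = GridMapSet(np.zeros(3), 0.5, (9, 9, 9),
                             {"T0": np.roll(lat, 2, axis=0)})
        g = PoseGenome(np.array([-0.8, 0.3, 0.1]), [1, 0, 0, 0], [])
        g_shift = PoseGenome(g.translation + [2 * 0.5, 0, 0], [1, 0, 0, 0], [])
        e0 = grid_score(g, topo, maps, w_tors=0.0)
        e1 = grid_score(g_shift, topo, shifted, w_tors=0.0)
        assert e0 == pytest.approx(e1, abs=1e-9)


class TestToyPairwise:
    def test_lj_minimum_at_equilibrium_distance(self):
        topo = _single_atom_topology()
        rec = [ReceptorAtom((3.2, 0.0, 0.0), r_eq=3.2, epsilon=0.7)]
        e = toy_pairwise_energy(PoseGenome(np.zeros(3), [1, 0, 0, 0], []),
                                topo, rec)
        assert e == pytest.approx(-0.7)

    def test_asymptotic_decay(self):
        topo = _single_atom_topology()
        rec = [ReceptorAtom((32.0, 0.0, 0.0), r_eq=3.2, epsilon=0.7)]
        e = toy_pairwise_energy(PoseGenome(np.zeros(3), [1, 0, 0, 0], []),
                                topo, rec)
        assert abs(e) < 1e-5 * 0.7

    def test_multi_atom_system_matches_pair_loop_oracle(self, rng):
        topo = make_chain_ligand(0)  # 3 atoms, neutral
        atoms = [Atom(a.serial, a.name, a.element, a.ad_type, 0.2 * a.serial,
                      a.coords) for a in topo.atoms]
        topo = LigandTopology(atoms=atoms, bonds=topo.bonds, root=topo.root,
                              branches=[], torsdof=0)
        rec = [ReceptorAtom((4.0, 1.0, 0.0), 3.0, 0.5, charge=-0.3),
               ReceptorAtom((-2.0, 3.0, 1.0), 3.5, 0.2, charge=0.1)]
        g = PoseGenome(np.array([0.5, -0.2, 0.3]), [1, 0, 0, 0], [])
        coords = decode_pose(g, topo)
        want = 0.0
        for k, la in enumerate(topo.atoms):
            for ra in rec:
                r = math.dist(coords[k], ra.coords)
                s = ra.r_eq / r
                want += ra.epsilon * (s ** 12 - 2 * s ** 6)
                rc = max(r, 0.5)
                want += COULOMB_CONSTANT * la.charge * ra.charge / (4 * rc * rc)
        got = toy_pairwise_energy(g, topo, rec)
        assert got == pytest.approx(want, abs=1e-10)

    def test_monotone_decay_beyond_equilibrium_for_neutral_pair(self):
        topo = _single_atom_topology()
        energies = []
        for x in np.linspace(9.6, 30.0, 15):  # beyond 3 * r_eq
            rec = [ReceptorAtom((x, 0.0, 0.0), r_eq=3.2, epsilon=0.7)]
            energies.append(
                toy_pairwise_energy(PoseGenome(np.zeros(3), [1, 0, 0, 0], []),
                                    topo, rec))
        assert all(e1 < e2 <= 0 for e1, e2 in zip(energies, energies[1:]))


class TestLandscapes:
    @pytest.mark.parametrize("name", ["sphere", "rastrigin-like"])
    def test_known_optimum_is_zero_at_origin(self, name):
        obj = benchmark_landscape(name, 4)
        assert obj(np.zeros(4)) == pytest.approx(0.0)
        assert obj.optimum_value == 0.0

    def test_double_funnel_depths_at_centers(self):
        obj = benchmark_landscape("double-funnel", 3)
        c1, c2 = obj.funnel_centers
        d1, d2 = obj.funnel_depths
        assert obj(c1) == pytest.approx(d1)
        assert obj(c2) == pytest.approx(d2)
        assert obj.optimum_value == d2 < d1

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            benchmark_landscape("himmelblau", 2)

    def test_counter_increments_once_per_call(self, rng):
        obj = benchmark_landscape("sphere", 3)
        for k in range(5):
            obj(rng.normal(size=3))
        assert obj.n_evals == 5
        assert obj.fresh().n_evals == 0

    def test_deterministic_for_fixed_genome(self, rng):
        obj = benchmark_landscape("rastrigin-like", 6)
        v = rng.normal(size=6)
        assert obj(v) == obj(v)
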