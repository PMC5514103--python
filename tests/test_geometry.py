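"""SASA engine against closed forms, neighbor search against brute force,
Kabsch superposition and rotation-angle extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from interfab.fixtures import _rotation_about_axis, make_sphere_cluster
from interfab.geometry import (
    analytic_two_sphere_sasa,
    kabsch,
    neighbor_pairs,
    rotation_angle,
    shrake_rupley_sasa,
    sphere_lattice,
)
from interfab.model import StructureError
from interfab.testing import brute_force_pairs, sampled_two_sphere_area


def two_atom_model(d: float, radius: float = 1.9):
    model, _ = make_sphere_cluster(2, seed=0, radius=radius)
    atoms = [a for _, a in model.atoms()]
    atoms[0].coords = np.zeros(3)
    atoms[1].coords = np.array([d, 0.0, 0.0])
    return model


class TestNeighborPairs:
    def test_cutoff_inclusion_and_exclusion(self):
        assert len(neighbor_pairs(two_atom_model(3.0), 3.5)) == 1
        assert len(neighbor_pairs(two_atom_model(3.0), 2.9)) == 0

    def test_matches_brute_force_on_random_cluster(self):
        model, _ = make_sphere_cluster(500, box=40.0, seed=7)
        fast = {
            (min(a, b), max(a, b)) for a, b, _ in neighbor_pairs(model, 5.0)
        }
        assert fast == brute_force_pairs(model, 5.0)

    def test_reported_distances_correct(self):
        model, truth = make_sphere_cluster(50, box=20.0, seed=1)
        truth_map = {(i, j): d for i, j, d in truth}
        for (ka, _), (kb, _), d in neighbor_pairs(model, 6.0):
            i, j = sorted((ka.seq_num, kb.seq_num))
            assert d == pytest.approx(truth_map[(i, j)], abs=1e-9)


class TestSphereLattice:
    def test_points_on_unit_sphere_and_deterministic(self):
        pts = sphere_lattice(960)
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
        np.testing.assert_array_equal(pts, sphere_lattice(960))


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        model, _ = make_sphere_cluster(1, radius=1.9)
        result = shrake_rupley_sasa(model, probe=1.4, n_points=960)
        assert result.total == pytest.approx(4 * np.pi * 3.3**2, rel=1e-12)

    def test_distant_atoms_are_isolated(self):
        result = shrake_rupley_sasa(two_atom_model(100.0), n_points=960)
        isolated = 4 * np.pi * 3.3**2
        for area in result.per_atom.values():
            assert area == pytest.approx(isolated, rel=1e-12)

    def test_two_sphere_matches_cap_formula(self):
        result = shrake_rupley_sasa(two_atom_model(3.0), probe=1.4, n_points=960)
        exact, _ = analytic_two_sphere_sasa(1.9, 1.9, 3.0, probe=1.4)
        for area in result.per_atom.values():
            assert abs(area - exact) / exact < 0.005

    def test_rigid_motion_invariance(self):
        # the 0.1% band needs a finer lattice than the 960-point default;
        # discretization noise at 7680 points is a few 0.01%
        model, _ = make_sphere_cluster(40, box=15.0, seed=5)
        base = shrake_rupley_sasa(model, n_points=7680).total
        rot = _rotation_about_axis(np.array([1.0, -2.0, 0.5]), 63.0)
        moved = model.transformed(rot, np.array([11.0, -4.0, 2.0]))
        assert abs(shrake_rupley_sasa(moved, n_points=7680).total - base) / base < 1e-3

    def test_monotonic_on_approach(self):
        # per-atom area can only shrink as two spheres come together
        areas = [
            shrake_rupley_sasa(two_atom_model(d), n_points=960).per_atom
            for d in (8.0, 6.0, 5.0, 4.0, 3.0, 2.0)
        ]
        totals = [sum(a.values()) for a in areas]
        assert all(t0 >= t1 - 1e-6 for t0, t1 in zip(totals, totals[1:]))

    def test_agrees_with_independent_library_implementation(self):
        # dual route: our engine vs biotite's SASA on the same coordinates,
        # same radii, same probe
        import io

        import biotite.structure as struc
        import biotite.structure.io.pdb as pdb_io

        from interfab.fixtures import PlantedContact, make_toy_complex
        from interfab.structure_io import assign_radii, write_pdb

        model, _ = make_toy_complex(
            [PlantedContact("hydrogen_bond"), PlantedContact("salt_bridge"),
             PlantedContact("vdw")]
        )
        assign_radii(model)
        mine = shrake_rupley_sasa(model, probe=1.4, n_points=960)

        pdb_file = pdb_io.PDBFile.read(io.StringIO(write_pdb(model)))
        atoms = pdb_io.get_structure(pdb_file, model=1)
        radii = np.array([a.radius for _, a in model.atoms()])
        theirs = struc.sasa(atoms, probe_radius=1.4, vdw_radii=radii, point_number=960)
        assert np.nansum(theirs) == pytest.approx(mine.total, rel=0.01)

    def test_missing_radius_raises(self):
        model, _ = make_sphere_cluster(1)
        next(iter(model.residues())).atoms[0].radius = None
        with pytest.raises(StructureError):
            shrake_rupley_sasa(model)


class TestAnalyticTwoSphere:
    def test_separated_full_areas(self):
        a1, a2 = analytic_two_sphere_sasa(1.9, 1.9, 100.0, probe=1.4)
        assert a1 == pytest.approx(4 * np.pi * 3.3**2)
        assert a2 == pytest.approx(a1)

    def test_coincident_equal_spheres_halve(self):
        # cap formula limit d -> 0: each sphere keeps exactly half its surface
        a1, a2 = analytic_two_sphere_sasa(1.9, 1.9, 1e-9, probe=1.4)
        assert a1 == pytest.approx(2 * np.pi * 3.3**2, rel=1e-6)
        assert a2 == pytest.approx(a1)

    def test_contained_sphere_is_buried(self):
        a1, a2 = analytic_two_sphere_sasa(3.0, 0.5, 0.2, probe=1.4)
        assert a2 == 0.0
        assert a1 == pytest.approx(4 * np.pi * 4.4**2)

    def test_against_dense_surface_sampling(self):
        exact = analytic_two_sphere_sasa(1.9, 1.9, 3.3, probe=1.4)
        sampled = sampled_two_sphere_area(1.9, 1.9, 3.3, probe=1.4, n_points=100_000)
        for e, s in zip(exact, sampled):
            assert abs(e - s) / e < 2e-3


class TestKabsch:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(20, 3))
        sup = kabsch(pts, pts)
        np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(sup.translation, 0.0, atol=1e-10)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-10)

    def test_recovers_known_rotation(self):
        pts = np.random.default_rng(1).normal(size=(30, 3))
        rot = _rotation_about_axis(np.array([0.0, 0.0, 1.0]), 37.0)
        sup = kabsch(pts, pts @ rot.T + np.array([1.0, 2.0, 3.0]))
        assert rotation_angle(sup.rotation) == pytest.approx(37.0, abs=1e-6)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_noisy_fit_beats_coarse_rotation_grid(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(50, 3))
        rot = _rotation_about_axis(np.array([1.0, 1.0, 0.0]), 25.0)
        b = a @ rot.T + rng.normal(scale=0.5, size=(50, 3))
        best = kabsch(a, b).rmsd
        # exhaustive search over a coarse rotation mesh can only do worse
        ca, cb = a - a.mean(0), b - b.mean(0)
        grid_best = np.inf
        for ax in ([1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 0], [1, 1, 1]):
            for angle in range(0, 360, 5):
                r = _rotation_about_axis(np.array(ax, dtype=float), angle)
                grid_best = min(
                    grid_best, np.sqrt(np.mean(np.sum((ca @ r.T - cb) ** 2, axis=1)))
                )
        assert best <= grid_best + 1e-9
        assert best == pytest.approx(0.5 * np.sqrt(3), rel=0.3)  # sampling expectation

    def test_degenerate_inputs_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(StructureError):
            kabsch(line, line)
        with pytest.raises(StructureError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_rmsd_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(10, 3))
        b = rng.normal(size=(10, 3))
        assert kabsch(a, b).rmsd == pytest.approx(kabsch(b, a).rmsd, abs=1e-9)


class TestRotationAngle:
    @pytest.mark.parametrize(
        "angles,expected",
        [((0.0,), 0.0), ((30.0,), 30.0), ((20.0, 15.0), 35.0)],
    )
    def test_known_angles_about_one_axis(self, angles, expected):
        axis = np.array([0.3, -1.2, 0.5])
        r = np.eye(3)
        for a in angles:
            r = _rotation_about_axis(axis, a) @ r
        assert rotation_angle(r) == pytest.approx(expected, abs=1e-9)

    def test_non_orthogonal_rejected(self):
        with pytest.raises(ValueError):
            rotation_angle(np.eye(3) * 2.0)
        with pytest.raises(ValueError):
            rotation_angle(np.diag([1.0, 1.0, -1.0]))  # reflection
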