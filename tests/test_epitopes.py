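"""Region maps, epitope set algebra, loop deviations, elbow swing, ASU counts."""

import numpy as np
import pytest

from interfab.epitopes import (
    EpitopeSet,
    RegionMap,
    asu_copy_count,
    default_pdl1_region_map,
    elbow_swing,
    epitope_overlap,
    epitope_set,
    loop_deviation,
    superpose_on_antigen,
)
from interfab.fixtures import (
    PlantedContact,
    _rotation_about_axis,
    make_hinged_fab,
    make_toy_complex,
)
from interfab.model import (
    ROLE_ANTIGEN,
    ROLE_HEAVY,
    AtomRecord,
    Residue,
    ResidueKey,
    Selection,
    StructureError,
    StructureModel,
)
from interfab.structure_io import assign_radii


def ca_chain(chain_id, coords, role=ROLE_ANTIGEN, start=1):
    residues = []
    for i, xyz in enumerate(coords):
        atom = AtomRecord(serial=i + 1, name="CA", element="C", coords=np.asarray(xyz, float))
        residues.append(Residue(ResidueKey(chain_id, start + i, "", "GLY"), [atom]))
    return StructureModel({chain_id: residues}, {chain_id: role})


def zigzag(n, start=1, chain="A", role=ROLE_ANTIGEN):
    coords = [(3.0 * i, 0.8 * (i % 2), 0.3 * (i % 3)) for i in range(n)]
    return ca_chain(chain, coords, role=role, start=start)


class TestRegionMap:
    def test_pdl1_map_assigns_canonical_regions(self):
        regions = default_pdl1_region_map()
        assert regions.classify(45) == "BC-loop"
        assert regions.classify(58) == "C"
        assert regions.classify(61) == "CC'-loop"
        assert regions.classify(69) == "C'C''-loop"
        assert regions.classify(113) == "F"
        assert regions.classify(119) == "FG-loop"
        assert regions.classify(123) == "G"
        assert regions.classify(35) == "B"
        assert regions.classify(999) == "unassigned"

    def test_overlapping_ranges_rejected(self):
        with pytest.raises(ValueError):
            RegionMap("x", {"a": ((1, 5),), "b": ((5, 9),)})


class TestEpitopeSet:
    def test_contacting_residues_with_region_labels(self):
        model, inventory = make_toy_complex(
            [PlantedContact("hydrogen_bond"), PlantedContact("salt_bridge")]
        )
        assign_radii(model)
        regions = RegionMap("toy", {"front": ((1, 1),), "back": ((2, 9),)})
        epi = epitope_set(model, binder_id="toy-ab", region_map=regions)
        assert {k.seq_num for k in epi.residues} == {1, 2}
        assert epi.region_labels[next(k for k in epi.residues if k.seq_num == 1)] == "front"
        assert epi.regions_engaged() == {"front", "back"}

    def test_missing_region_map_warns_unassigned(self, caplog):
        model, _ = make_toy_complex([PlantedContact("vdw")])
        assign_radii(model)
        epi = epitope_set(model, binder_id="x")
        assert set(epi.region_labels.values()) == {"unassigned"}


class TestEpitopeOverlap:
    def _set(self, nums, binder="ab"):
        keys = {ResidueKey("A", n, "", "GLY") for n in nums}
        return EpitopeSet(binder_id=binder, residues=keys)

    def test_identical_sets_jaccard_one(self):
        out = epitope_overlap([self._set({1, 2, 3}, "x"), self._set({1, 2, 3}, "y")])
        assert out["jaccard"][("x", "y")] == 1.0
        assert len(out["intersection"]) == 3

    def test_disjoint_sets_jaccard_zero(self):
        out = epitope_overlap([self._set({1, 2}, "x"), self._set({5, 6}, "y")])
        assert out["jaccard"][("x", "y")] == 0.0
        assert out["intersection"] == []

    def test_order_invariant(self):
        a, b, c = self._set({1, 2, 4}, "a"), self._set({2, 4, 9}, "b"), self._set({2, 7}, "c")
        out1 = epitope_overlap([a, b, c])
        out2 = epitope_overlap([c, a, b])
        assert out1["intersection"] == out2["intersection"]
        assert out1["union"] == out2["union"]

    def test_different_antigens_rejected(self):
        x = EpitopeSet("x", {ResidueKey("A", 5, "", "GLY")})
        y = EpitopeSet("y", {ResidueKey("B", 5, "", "TRP")})
        with pytest.raises(StructureError):
            epitope_overlap([x, y])


class TestSuperposeOnAntigen:
    def test_same_complex_rmsd_zero(self):
        model = zigzag(10)
        (m0, s0), (m1, s1) = superpose_on_antigen([model, model.copy()])
        assert s1.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rotated_copy_recovered(self):
        from interfab.geometry import rotation_angle

        model = zigzag(10)
        rot = _rotation_about_axis(np.array([0.0, 0.0, 1.0]), 90.0)
        moved = model.transformed(rot, np.array([4.0, 5.0, 6.0]))
        (_, _), (m1, s1) = superpose_on_antigen([model, moved])
        assert s1.rmsd == pytest.approx(0.0, abs=1e-9)
        assert rotation_angle(s1.rotation) == pytest.approx(90.0, abs=1e-6)
        np.testing.assert_allclose(m1.coords_array(), model.coords_array(), atol=1e-9)

    def test_too_few_common_residues_rejected(self):
        with pytest.raises(StructureError):
            superpose_on_antigen([zigzag(10), zigzag(10, start=100)])


class TestLoopDeviation:
    regions = RegionMap("toy", {"core": ((1, 20),), "loop": ((21, 25),)})

    def test_identical_models_zero(self):
        model = zigzag(25)
        out = loop_deviation(model, model.copy(), "loop", self.regions)
        assert out["max_A"] == pytest.approx(0.0, abs=1e-9)

    def test_planted_rigid_shift_recovered(self):
        model = zigzag(25)
        shifted = model.copy()
        for res in shifted.chains["A"]:
            if 21 <= res.key.seq_num <= 25:
                for atom in res.atoms:
                    atom.coords = atom.coords + np.array([0.0, 0.0, 2.0])
        out = loop_deviation(model, shifted, "loop", self.regions)
        assert out["max_A"] == pytest.approx(2.0, abs=1e-9)
        assert out["mean_A"] == pytest.approx(2.0, abs=1e-9)
        assert out["core_rmsd_A"] == pytest.approx(0.0, abs=1e-9)

    def test_absent_region_rejected(self):
        model = zigzag(10)  # no residues 21-25
        with pytest.raises(StructureError):
            loop_deviation(model, model.copy(), "loop", self.regions)


class TestElbowSwing:
    v = Selection.by_range("F", 1, 30)
    c = Selection.by_range("F", 31, 60)

    def test_identical_copies_zero(self):
        base, _ = make_hinged_fab(20.0, seed=1)
        out = elbow_swing([base, base.copy()], self.v, self.c)
        # arccos amplifies roundoff near 0 degrees; 1e-4 deg is still far
        # below any physically meaningful angle
        assert out["max_deg"] == pytest.approx(0.0, abs=1e-4)

    @pytest.mark.parametrize("angle", [5.0, 25.0, 30.0])
    def test_constructed_hinge_recovered(self, angle):
        base, swung = make_hinged_fab(angle, seed=2)
        out = elbow_swing([base, swung], self.v, self.c)
        assert out["max_deg"] == pytest.approx(angle, abs=0.1)

    def test_invariant_to_global_motion_and_pair_order(self):
        base, swung = make_hinged_fab(30.0, seed=3)
        rot = _rotation_about_axis(np.array([2.0, 1.0, 1.0]), 50.0)
        moved = swung.transformed(rot, np.array([7.0, -3.0, 1.0]))
        forward = elbow_swing([base, moved], self.v, self.c)["max_deg"]
        backward = elbow_swing([moved, base], self.v, self.c)["max_deg"]
        assert forward == pytest.approx(30.0, abs=0.1)
        assert forward == pytest.approx(backward, abs=1e-9)

    def test_dict_regions_across_roles(self):
        base, swung = make_hinged_fab(18.0, seed=4)
        out = elbow_swing([base, swung], {"F": (1, 30)}, {"F": (31, 60)})
        assert out["max_deg"] == pytest.approx(18.0, abs=0.1)

    def test_max_over_multiple_copies(self):
        base, swung10 = make_hinged_fab(10.0, seed=5)
        _, swung40 = make_hinged_fab(40.0, seed=5)
        out = elbow_swing([base, swung10, swung40], self.v, self.c)
        assert out["max_deg"] == pytest.approx(40.0, abs=0.1)
        assert out["max_pair"] == (0, 2)


class TestAsuCopyCount:
    def test_counts_antigen_chains(self):
        m1 = zigzag(5, chain="A")
        m2 = zigzag(5, chain="B")
        m1.chains["B"] = m2.chains["B"]
        m1.role_map["B"] = ROLE_ANTIGEN
        assert asu_copy_count(m1) == 2

    def test_single_copy_and_none(self):
        assert asu_copy_count(zigzag(5)) == 1
        assert asu_copy_count(zigzag(5, role=ROLE_HEAVY)) == 0
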