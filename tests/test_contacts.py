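"""Buried-area bookkeeping and the typed contact detectors."""

import numpy as np
import pytest

from interfab.contacts import (
    InterfaceCriteria,
    buried_area,
    chain_contribution,
    contact_table,
    detect_hbonds,
    detect_salt_bridges,
    detect_vdw_contacts,
    detect_water_bridges,
    distinct_bridging_waters,
    interface_residues,
)
from interfab.fixtures import PlantedContact, _rotation_about_axis, make_sphere_cluster, make_toy_complex
from interfab.geometry import analytic_two_sphere_sasa
from interfab.model import ROLE_ANTIGEN, ROLE_HEAVY, Selection, StructureError
from interfab.structure_io import assign_radii
from interfab.testing import brute_force_pairs
from conftest import random_planted_spec

A = Selection.by_role(ROLE_ANTIGEN)
B = Selection.by_role(ROLE_HEAVY)


def recovered_inventory(model, criteria=None):
    """Detector output reduced to (category, seq_a, seq_b) triples."""
    criteria = criteria or InterfaceCriteria()
    triples = set()
    for rec in detect_salt_bridges(model, A, B, criteria.salt_max):
        triples.add(("salt_bridge", rec.residue_a.seq_num, rec.residue_b.seq_num))
    for rec in detect_hbonds(model, A, B, criteria.hbond_max, criteria.salt_max):
        triples.add(("hydrogen_bond", rec.residue_a.seq_num, rec.residue_b.seq_num))
    for rec in detect_vdw_contacts(model, A, B, criteria.vdw_max, criteria):
        triples.add(("vdw", rec.residue_a.seq_num, rec.residue_b.seq_num))
    for rec in detect_water_bridges(model, A, B, criteria.water_max):
        triples.add(("water_bridge", rec.residue_a.seq_num, rec.residue_b.seq_num))
    return triples


class TestBuriedArea:
    def test_distant_chains_bury_nothing(self):
        model, _ = make_toy_complex([])  # chains 10 A apart
        assign_radii(model)
        summary = buried_area(model, A, B)
        assert summary.bsa_total == pytest.approx(0.0, abs=0.5)

    def test_two_sphere_interface_matches_cap_loss(self):
        from interfab.model import Residue, ResidueKey

        model, _ = make_sphere_cluster(2, radius=1.9)
        atoms = [a for _, a in model.atoms()]
        atoms[0].coords = np.zeros(3)
        atoms[1].coords = np.array([3.0, 0.0, 0.0])
        moved = model.chains["A"].pop()
        model.chains["B"] = [Residue(ResidueKey("B", 1, "", "UNK"), moved.atoms)]
        model.role_map["B"] = ROLE_HEAVY
        summary = buried_area(model, A, B)
        isolated = 4 * np.pi * 3.3**2
        a1, a2 = analytic_two_sphere_sasa(1.9, 1.9, 3.0, probe=1.4)
        expected = (isolated - a1) + (isolated - a2)
        assert summary.bsa_total == pytest.approx(expected, rel=0.005)

    def test_symmetric_in_side_order(self, full_toy):
        model, _ = full_toy
        assert buried_area(model, A, B).bsa_total == pytest.approx(
            buried_area(model, B, A).bsa_total, abs=1e-9
        )

    def test_rigid_motion_invariance(self, full_toy):
        model, _ = full_toy
        base = buried_area(model, A, B).bsa_total
        rot = _rotation_about_axis(np.array([1.0, 0.7, -0.2]), 41.0)
        moved = model.transformed(rot, np.array([3.0, -8.0, 5.0]))
        assert buried_area(moved, A, B).bsa_total == pytest.approx(base, rel=0.02)

    def test_overlapping_sides_rejected(self, full_toy):
        model, _ = full_toy
        with pytest.raises(StructureError):
            buried_area(model, A, Selection())  # B-side matches everything


class TestChainContribution:
    def test_single_chain_binder_is_unity(self, full_toy):
        model, _ = full_toy
        summary = buried_area(model, A, B)
        assert chain_contribution(summary, "b") == {"B": pytest.approx(1.0)}

    def test_symmetric_two_chain_binder_splits_evenly(self):
        # one antigen sphere flanked by two binder spheres at mirror positions:
        # the split is 50/50 by symmetry
        from interfab.model import AtomRecord, Residue, ResidueKey, StructureModel

        def sphere(chain, xyz):
            atom = AtomRecord(serial=1, name="C", element="C", coords=np.array(xyz))
            atom.radius = 1.9
            return Residue(ResidueKey(chain, 1, "", "UNK"), [atom])

        model = StructureModel(
            chains={
                "M": [sphere("M", [0.0, 0.0, 0.0])],
                "B": [sphere("B", [0.0, 3.8, 0.0])],
                "L": [sphere("L", [0.0, -3.8, 0.0])],
            },
            role_map={"M": ROLE_ANTIGEN, "B": ROLE_HEAVY, "L": "light"},
        )
        both = Selection.by_role(ROLE_HEAVY, "light")
        summary = buried_area(model, A, both)
        contrib = chain_contribution(summary, "b")
        assert contrib["B"] == pytest.approx(0.5, abs=0.01)
        assert sum(contrib.values()) == pytest.approx(1.0, abs=1e-9)

    def test_zero_burial_is_undefined(self):
        model, _ = make_toy_complex([])
        assign_radii(model)
        summary = buried_area(model, A, B)
        with pytest.raises(StructureError):
            chain_contribution(summary, "b")


class TestInterfaceResidues:
    def test_non_touching_chains_give_empty_sets(self):
        model, _ = make_toy_complex([])
        assign_radii(model)
        res_a, res_b = interface_residues(model, A, B)
        assert res_a == set() and res_b == set()

    def test_planted_contacts_recovered(self, full_toy):
        model, inventory = full_toy
        res_a, _ = interface_residues(model, A, B)
        contact_slots = {a for cat, a, _ in inventory if cat != "water_bridge"}
        assert {k.seq_num for k in res_a} >= contact_slots

    def test_every_contact_residue_is_interface_residue(self, full_toy):
        model, _ = full_toy
        res_a, res_b = interface_residues(model, A, B)
        for detector in (detect_hbonds, detect_salt_bridges, detect_vdw_contacts):
            for rec in detector(model, A, B):
                assert rec.residue_a in res_a
                assert rec.residue_b in res_b


class TestDetectors:
    def test_planted_inventory_recovered_exactly(self, full_toy):
        model, inventory = full_toy
        assert recovered_inventory(model) == set(inventory)

    def test_hbond_distance_window(self):
        near, _ = make_toy_complex([PlantedContact("hydrogen_bond", 2.8)])
        far, _ = make_toy_complex([PlantedContact("hydrogen_bond", 3.8)])
        assert len(detect_hbonds(near, A, B)) == 1
        assert len(detect_hbonds(far, A, B)) == 0
        # ... but the 3.8 A donor/acceptor pair is still a vdW contact
        assert ("vdw", 1, 1) in recovered_inventory(far)

    def test_nonpolar_atoms_never_hbond(self):
        model, _ = make_toy_complex([PlantedContact("vdw", 2.8)])
        assert len(detect_hbonds(model, A, B)) == 0

    def test_bidentate_salt_bridge_two_records(self):
        model, _ = make_toy_complex([PlantedContact("salt_bridge_bidentate", 3.5)])
        records = detect_salt_bridges(model, A, B)
        assert len(records) == 2
        assert {(r.atom_a, r.atom_b) for r in records} == {("NH1", "OE1"), ("NH2", "OE2")}

    def test_salt_bridge_beyond_cutoff_ignored(self):
        model, _ = make_toy_complex([PlantedContact("salt_bridge", 4.5)])
        assert detect_salt_bridges(model, A, B) == []

    def test_salt_bridge_pairs_excluded_from_hbonds_and_vdw(self):
        model, _ = make_toy_complex([PlantedContact("salt_bridge", 3.4)])
        salt = detect_salt_bridges(model, A, B)
        assert len(salt) == 1
        pair = (salt[0].residue_a, salt[0].atom_a, salt[0].residue_b, salt[0].atom_b)
        for rec in detect_hbonds(model, A, B) + detect_vdw_contacts(model, A, B):
            assert (rec.residue_a, rec.atom_a, rec.residue_b, rec.atom_b) != pair

    def test_vdw_equals_brute_force_on_random_cluster(self):
        from interfab.model import Residue, ResidueKey

        model, _ = make_sphere_cluster(200, box=30.0, seed=11)
        # split into two "chains" to create cross-side pairs
        residues = model.chains.pop("A")
        model.chains["A"] = residues[:100]
        model.chains["B"] = [
            Residue(ResidueKey("B", r.key.seq_num, "", r.key.res_name), r.atoms)
            for r in residues[100:]
        ]
        model.role_map = {"A": ROLE_ANTIGEN, "B": ROLE_HEAVY}
        fast = {
            frozenset([(r.residue_a, r.atom_a), (r.residue_b, r.atom_b)])
            for r in detect_vdw_contacts(model, A, B, 4.0)
        }
        seqs_a = {r.key for r in model.chains["A"]}
        oracle = {
            frozenset([ka, kb])
            for ka, kb in brute_force_pairs(model, 4.0)
            if (ka[0] in seqs_a) != (kb[0] in seqs_a)  # cross-side only
        }
        assert fast == oracle

    def test_water_bridge_requires_both_sides(self):
        bridged, _ = make_toy_complex([PlantedContact("water_bridge", water_gaps=(2.8, 2.9))])
        records = detect_water_bridges(bridged, A, B)
        assert len(distinct_bridging_waters(records)) == 1
        # pull the side-b partner out of range: water now touches one side only
        lonely, _ = make_toy_complex([PlantedContact("water_bridge", water_gaps=(2.8, 3.4))])
        for res in lonely.chains["B"]:
            for atom in res.atoms:
                atom.coords = atom.coords + np.array([0.0, 50.0, 0.0])
        assert detect_water_bridges(lonely, A, B) == []


class TestCategoryPartition:
    @pytest.mark.parametrize("seed", range(8))
    def test_atom_pair_in_exactly_one_category(self, seed):
        rng = np.random.default_rng(seed)
        model, _ = make_toy_complex(random_planted_spec(rng), seed=seed)
        seen = {}
        for detector, cutoff in (
            (detect_salt_bridges, 4.0),
            (detect_hbonds, 3.5),
            (detect_vdw_contacts, 4.0),
        ):
            for rec in detector(model, A, B):
                key = (rec.residue_a, rec.atom_a, rec.residue_b, rec.atom_b)
                assert key not in seen, f"{key} typed as both {seen[key]} and {rec.category}"
                seen[key] = rec.category

    @pytest.mark.parametrize("seed", range(8))
    def test_random_planted_specs_recovered(self, seed):
        rng = np.random.default_rng(100 + seed)
        planted = random_planted_spec(rng)
        model, inventory = make_toy_complex(planted, seed=seed)
        assert recovered_inventory(model) == set(inventory)


class TestContactTable:
    def test_counts_by_category(self, full_toy):
        model, _ = full_toy
        table, counts = contact_table(model, A, B)
        assert counts == {
            "hydrogen_bond": 1,
            "salt_bridge": 2,  # residue pairs: one monodentate + one bidentate
            "vdw": 1,
            "water_bridge": 1,
        }
        assert set(table.columns) == {
            "residue_a", "residue_b", "atom_a", "atom_b", "distance_A", "category", "water_id",
        }

    def test_labels_use_entity_names(self, full_toy):
        model, _ = full_toy
        table, _ = contact_table(model, A, B, entity_a="PD-L1")
        assert table["residue_a"].str.startswith("PD-L1_").all()

    def test_empty_interface_empty_table(self):
        model, _ = make_toy_complex([])
        assign_radii(model)
        table, counts = contact_table(model, A, B)
        assert len(table) == 0
        assert all(v == 0 for v in counts.values())
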