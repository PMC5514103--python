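"""Cross-complex epitope comparison in a common antigen frame.

Several complexes of the same antigen (receptor-bound, different antibodies,
crystallographically independent copies) are compared by superposing each
antigen onto a reference with a least-squares rigid fit over shared C-alpha
atoms, then doing set algebra on the antigen residues each binder engages.
Residue correspondence across complexes is by author numbering, which all
deposited PD-L1 complexes share.

Also here: the Fab elbow swing (residual rotation of the constant module
after the variable modules are aligned), per-region loop deviations after a
core fit, and the antigen copy count of an asymmetric unit.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .contacts import InterfaceCriteria, interface_residues
from .geometry import SuperpositionResult, kabsch, rotation_angle
from .model import (
    ROLE_ANTIGEN,
    ROLE_HEAVY,
    ROLE_LIGHT,
    ResidueKey,
    Selection,
    StructureError,
    StructureModel,
    residues_in,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RegionMap",
    "EpitopeSet",
    "default_pdl1_region_map",
    "superpose_on_antigen",
    "epitope_set",
    "epitope_overlap",
    "loop_deviation",
    "elbow_swing",
    "asu_copy_count",
]


# ---------------------------------------------------------------------------
# regions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionMap:
    """Named residue ranges (author numbering) on the antigen, e.g. the
    strands and loops of an immunoglobulin V-set domain."""

    antigen: str
    regions: dict[str, tuple[tuple[int, int], ...]]

    def __post_init__(self) -> None:
        seen: dict[int, str] = {}
        for name, ranges in self.regions.items():
            for lo, hi in ranges:
                for n in range(lo, hi + 1):
                    if n in seen:
                        raise ValueError(
                            f"region ranges overlap at residue {n}: {seen[n]} and {name}"
                        )
                    seen[n] = name

    def classify(self, seq_num: int) -> str:
        for name, ranges in self.regions.items():
            if any(lo <= seq_num <= hi for lo, hi in ranges):
                return name
        return "unassigned"

    def residues_of(self, name: str) -> list[int]:
        if name not in self.regions:
            raise KeyError(f"unknown region {name!r}; have {sorted(self.regions)}")
        return [n for lo, hi in self.regions[name] for n in range(lo, hi + 1)]

    @classmethod
    def from_yaml(cls, source: str | Path) -> "RegionMap":
        data = yaml.safe_load(Path(source).read_text())
        return cls(
            antigen=data.get("antigen", ""),
            regions={
                str(name): tuple((int(lo), int(hi)) for lo, hi in ranges)
                for name, ranges in data["regions"].items()
            },
        )


def default_pdl1_region_map() -> RegionMap:
    """Strand/loop designations of the PD-L1 IgSF V-set domain (aa 18-134)."""
    with resources.as_file(resources.files("interfab.data") / "regions_pdl1.yaml") as path:
        return RegionMap.from_yaml(path)


@dataclass
class EpitopeSet:
    binder_id: str
    residues: set[ResidueKey]
    region_labels: dict[ResidueKey, str] = field(default_factory=dict)

    def numbering(self) -> set[tuple[int, str]]:
        """Residue identities independent of the chain id, for cross-complex algebra."""
        return {(k.seq_num, k.icode) for k in self.residues}

    def by_number(self) -> dict[tuple[int, str], ResidueKey]:
        return {(k.seq_num, k.icode): k for k in self.residues}

    def regions_engaged(self) -> set[str]:
        return set(self.region_labels.values())


# ---------------------------------------------------------------------------
# superposition across complexes
# ---------------------------------------------------------------------------

def _antigen_ca(
    model: StructureModel,
    antigen: Selection,
    atom_set: str = "CA",
    exclude: set[int] | None = None,
) -> dict[tuple[int, str, str], np.ndarray]:
    names = ("CA",) if atom_set == "CA" else ("N", "CA", "C", "O")
    out = {}
    for res in residues_in(model, antigen):
        if exclude and res.key.seq_num in exclude:
            continue
        for name in names:
            atom = res.atom(name)
            if atom is not None:
                out[(res.key.seq_num, res.key.icode, name)] = atom.coords
    return out


def superpose_on_antigen(
    complexes: list[StructureModel],
    reference: int = 0,
    antigen: Selection | None = None,
    atom_set: str = "CA",
) -> list[tuple[StructureModel, SuperpositionResult]]:
    """Rigidly place every complex so its antigen best fits the reference's.

    The fit uses the intersection of antigen residue numbers present in each
    pair; RMSD is reported over that common set.
    """
    antigen = antigen or Selection.by_role(ROLE_ANTIGEN)
    ref_map = _antigen_ca(complexes[reference], antigen, atom_set)
    results = []
    for idx, model in enumerate(complexes):
        mov_map = _antigen_ca(model, antigen, atom_set)
        common = sorted(set(ref_map) & set(mov_map))
        if len(common) < 3:
            raise StructureError(
                f"complex {idx}: only {len(common)} antigen atoms shared with the reference"
            )
        mov = np.array([mov_map[k] for k in common])
        ref = np.array([ref_map[k] for k in common])
        sup = kabsch(mov, ref)
        results.append((model.transformed(sup.rotation, sup.translation), sup))
    return results


# ---------------------------------------------------------------------------
# epitopes
# ---------------------------------------------------------------------------

def epitope_set(
    model: StructureModel,
    binder_id: str = "",
    antigen: Selection | None = None,
    binder: Selection | None = None,
    criteria: InterfaceCriteria | None = None,
    region_map: RegionMap | None = None,
) -> EpitopeSet:
    """Antigen residues engaged by the binder, labelled by antigen region."""
    antigen = antigen or Selection.by_role(ROLE_ANTIGEN)
    binder = binder or Selection.by_role(ROLE_HEAVY, ROLE_LIGHT)
    residues, _ = interface_residues(model, antigen, binder, criteria)
    if region_map is None:
        logger.warning("no region map supplied; epitope regions left 'unassigned'")
        labels = {k: "unassigned" for k in residues}
    else:
        labels = {k: region_map.classify(k.seq_num) for k in residues}
    return EpitopeSet(binder_id=binder_id or model.source_id, residues=residues,
                      region_labels=labels)


def epitope_overlap(sets: list[EpitopeSet]) -> dict:
    """Intersection, union and pairwise Jaccard of epitopes on one antigen.

    Residue identity is (seq_num, icode); a shared number mapping to two
    different residue types means the sets come from different antigens and
    is rejected.
    """
    if len(sets) < 2:
        raise ValueError("need at least two epitope sets to compare")
    named: dict[tuple[int, str], str] = {}
    for es in sets:
        for key in es.residues:
            ident = (key.seq_num, key.icode)
            if named.setdefault(ident, key.res_name) != key.res_name:
                raise StructureError(
                    f"residue {ident} is {named[ident]} in one set and {key.res_name} "
                    "in another: epitopes are not on the same antigen"
                )
    numberings = [es.numbering() for es in sets]
    inter = set.intersection(*numberings)
    union = set.union(*numberings)
    jaccard = {}
    for (i, si), (j, sj) in itertools.combinations(enumerate(numberings), 2):
        u = len(si | sj)
        jaccard[(sets[i].binder_id, sets[j].binder_id)] = (len(si & sj) / u) if u else 1.0
    label_of = {}
    for es in sets:
        label_of.update({(k.seq_num, k.icode): k for k in es.residues})
    return {
        "intersection": sorted(inter),
        "intersection_labels": sorted(str(label_of[i]) for i in inter),
        "union": sorted(union),
        "jaccard": jaccard,
    }


# ---------------------------------------------------------------------------
# plasticity
# ---------------------------------------------------------------------------

def loop_deviation(
    model_a: StructureModel,
    model_b: StructureModel,
    region: str,
    region_map: RegionMap,
    antigen: Selection | None = None,
) -> dict[str, float]:
    """Per-residue C-alpha displacement over a region after a core fit.

    The two antigens are superposed on all shared C-alphas *excluding* the
    region, then the region's displacements are measured, so a genuinely
    mobile loop is not averaged into the fit.
    """
    antigen = antigen or Selection.by_role(ROLE_ANTIGEN)
    region_nums = set(region_map.residues_of(region))

    core_a = _antigen_ca(model_a, antigen, "CA", exclude=region_nums)
    core_b = _antigen_ca(model_b, antigen, "CA", exclude=region_nums)
    common = sorted(set(core_a) & set(core_b))
    if len(common) < 3:
        raise StructureError("fewer than 3 shared core residues for the superposition")
    sup = kabsch(
        np.array([core_b[k] for k in common]),
        np.array([core_a[k] for k in common]),
    )

    loop_a = _antigen_ca(model_a, antigen, "CA")
    loop_b = _antigen_ca(model_b, antigen, "CA")
    displacements = []
    for key in sorted(set(loop_a) & set(loop_b)):
        if key[0] not in region_nums:
            continue
        moved = sup.rotation @ loop_b[key] + sup.translation
        displacements.append(float(np.linalg.norm(moved - loop_a[key])))
    if not displacements:
        raise StructureError(f"region {region!r} absent from one of the models")
    return {
        "region": region,
        "n_residues": len(displacements),
        "mean_A": float(np.mean(displacements)),
        "max_A": float(np.max(displacements)),
        "core_rmsd_A": sup.rmsd,
    }


def _selection_ca(
    model: StructureModel, sel: "Selection | dict[str, tuple[int, int]]"
) -> dict[tuple[str, int, str], np.ndarray]:
    if isinstance(sel, dict):
        out = {}
        for chain, (lo, hi) in sel.items():
            for res in model.chains.get(chain, []):
                atom = res.atom("CA")
                if atom is not None and lo <= res.key.seq_num <= hi:
                    out[(chain, res.key.seq_num, res.key.icode)] = atom.coords
        return out
    out = {}
    for res in residues_in(model, sel):
        atom = res.atom("CA")
        if atom is not None:
            out[(res.key.chain_id, res.key.seq_num, res.key.icode)] = atom.coords
    return out


def elbow_swing(
    fab_copies: list[StructureModel],
    v_region: "Selection | dict[str, tuple[int, int]]",
    c_region: "Selection | dict[str, tuple[int, int]]",
) -> dict:
    """Max pairwise rotation of the Fab constant module between copies.

    For each pair of copies the variable modules are least-squares aligned;
    the rotation that then still separates the constant modules is the elbow
    swing. Invariant to any global rigid motion of either copy.
    """
    if len(fab_copies) < 2:
        raise ValueError("need at least two Fab copies")
    v_sets = [_selection_ca(m, v_region) for m in fab_copies]
    c_sets = [_selection_ca(m, c_region) for m in fab_copies]
    for idx, (v, c) in enumerate(zip(v_sets, c_sets)):
        if len(v) < 3 or len(c) < 3:
            raise StructureError(f"copy {idx}: variable/constant ranges select fewer than 3 CAs")
    angles = {}
    for i, j in itertools.combinations(range(len(fab_copies)), 2):
        vkeys = sorted(set(v_sets[i]) & set(v_sets[j]))
        ckeys = sorted(set(c_sets[i]) & set(c_sets[j]))
        if len(vkeys) < 3 or len(ckeys) < 3:
            raise StructureError(f"copies {i},{j}: fewer than 3 shared CAs")
        sup_v = kabsch(
            np.array([v_sets[j][k] for k in vkeys]),
            np.array([v_sets[i][k] for k in vkeys]),
        )
        moved_c = np.array([sup_v.rotation @ c_sets[j][k] + sup_v.translation for k in ckeys])
        ref_c = np.array([c_sets[i][k] for k in ckeys])
        sup_c = kabsch(moved_c, ref_c)
        angles[(i, j)] = rotation_angle(sup_c.rotation)
    return {
        "pairwise_deg": angles,
        "max_deg": max(angles.values()),
        "max_pair": max(angles, key=angles.get),
    }


def asu_copy_count(model: StructureModel, antigen_role: str = ROLE_ANTIGEN) -> int:
    """Number of antigen chain instances in the (deposited) asymmetric unit."""
    count = len(model.chains_with_role(antigen_role))
    if count == 0:
        logger.warning("no chains with role %r in %s", antigen_role, model.source_id)
    return count
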