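"""Hierarchical coordinate model: chains of residues of atoms, with entity roles.

The model is deliberately small: structures arrive through :mod:`interfab.structure_io`
(backed by gemmi) and everything downstream (SASA, contacts, superposition) works
on these plain containers plus numpy views extracted on demand.

Roles tag what each chain *is* in an antigen/antibody complex: ``antigen``,
``heavy``, ``light``, ``water`` or ``other``. Water residues (HOH) always carry
role ``water`` regardless of the chain they were deposited in.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

ROLE_ANTIGEN = "antigen"
ROLE_HEAVY = "heavy"
ROLE_LIGHT = "light"
ROLE_WATER = "water"
ROLE_OTHER = "other"
ROLES = (ROLE_ANTIGEN, ROLE_HEAVY, ROLE_LIGHT, ROLE_WATER, ROLE_OTHER)

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


class StructureError(Exception):
    """Base class for coordinate-model errors."""


class ParseError(StructureError):
    pass


class ConfigurationError(StructureError):
    pass


class SelectionError(StructureError):
    pass


@dataclass(frozen=True, order=True)
class ResidueKey:
    """Identity of one residue in author (PDB) numbering."""

    chain_id: str
    seq_num: int
    icode: str = ""
    res_name: str = ""

    def __str__(self) -> str:  # e.g. A:GLU58
        return f"{self.chain_id}:{self.res_name}{self.seq_num}{self.icode}"

    @property
    def one_letter(self) -> str:
        return AA3_TO_1.get(self.res_name, "X")

    def label(self, entity: str | None = None) -> str:
        """Residue label in the field's shorthand, e.g. ``PD-L1_E58``."""
        prefix = entity if entity is not None else self.chain_id
        return f"{prefix}_{self.one_letter}{self.seq_num}{self.icode}"


@dataclass
class AtomRecord:
    serial: int
    name: str
    element: str
    coords: np.ndarray          # (3,) float, Angstrom
    occupancy: float = 1.0
    altloc: str = ""
    b_factor: float = 0.0
    radius: float | None = None  # assigned by assign_radii

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.name}: coords must be 3 finite numbers")
        if not 0.0 <= self.occupancy <= 1.0:
            raise StructureError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Residue:
    key: ResidueKey
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def is_water(self) -> bool:
        return self.key.res_name in WATER_NAMES

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def side_chain_atoms(self) -> list[AtomRecord]:
        backbone = {"N", "CA", "C", "O", "OXT"}
        return [a for a in self.atoms if a.name not in backbone]


@dataclass
class StructureModel:
    """Ordered chains of residues of atoms plus a chain-role map."""

    chains: dict[str, list[Residue]] = field(default_factory=dict)
    role_map: dict[str, str] = field(default_factory=dict)
    source_id: str = ""

    # -- iteration helpers -------------------------------------------------
    def residues(self) -> Iterator[Residue]:
        for residues in self.chains.values():
            yield from residues

    def atoms(self) -> Iterator[tuple[Residue, AtomRecord]]:
        for res in self.residues():
            for atom in res.atoms:
                yield res, atom

    def role_of(self, residue: Residue) -> str:
        if residue.is_water:
            return ROLE_WATER
        return self.role_map.get(residue.key.chain_id, ROLE_OTHER)

    def chain_ids(self) -> list[str]:
        return list(self.chains.keys())

    def chains_with_role(self, role: str) -> list[str]:
        return [c for c, r in self.role_map.items() if r == role]

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())

    @property
    def n_residues(self) -> int:
        return sum(len(rs) for rs in self.chains.values())

    def coords_array(self) -> np.ndarray:
        if self.n_atoms == 0:
            return np.zeros((0, 3))
        return np.array([a.coords for _, a in self.atoms()])

    def radii_array(self) -> np.ndarray:
        radii = []
        missing = []
        for res, atom in self.atoms():
            if atom.radius is None:
                missing.append(f"{res.key}/{atom.name}")
            else:
                radii.append(atom.radius)
        if missing:
            raise StructureError(
                "atoms without assigned radii (run assign_radii first): "
                + ", ".join(missing[:8])
            )
        return np.array(radii)

    def find_residue(self, key: ResidueKey) -> Residue | None:
        for res in self.chains.get(key.chain_id, []):
            if (res.key.seq_num, res.key.icode) == (key.seq_num, key.icode):
                return res
        return None

    def copy(self) -> "StructureModel":
        new_chains = {
            cid: [Residue(res.key, [replace(a, coords=a.coords.copy()) for a in res.atoms])
                  for res in residues]
            for cid, residues in self.chains.items()
        }
        return StructureModel(new_chains, dict(self.role_map), self.source_id)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Return a copy with every atom mapped through x -> R x + t."""
        out = self.copy()
        rotation = np.asarray(rotation, float)
        translation = np.asarray(translation, float)
        for _, atom in out.atoms():
            atom.coords = rotation @ atom.coords + translation
        return out


@dataclass(frozen=True)
class Selection:
    """Substructure filter by role, chain and residue range.

    Empty criteria match everything of that kind; criteria combine with AND.
    Waters are excluded unless ``include_water`` is set or role ``water`` is
    requested explicitly.
    """

    roles: frozenset[str] = frozenset()
    chains: frozenset[str] = frozenset()
    residue_ranges: tuple[tuple[int, int], ...] = ()
    include_water: bool = False

    @classmethod
    def by_role(cls, *roles: str) -> "Selection":
        return cls(roles=frozenset(roles), include_water=ROLE_WATER in roles)

    @classmethod
    def by_chain(cls, *chains: str) -> "Selection":
        return cls(chains=frozenset(chains))

    @classmethod
    def by_range(cls, chain: str, start: int, end: int) -> "Selection":
        return cls(chains=frozenset({chain}), residue_ranges=((start, end),))

    def matches(self, model: StructureModel, residue: Residue) -> bool:
        role = model.role_of(residue)
        if role == ROLE_WATER and not (self.include_water or ROLE_WATER in self.roles):
            return False
        if self.roles and role not in self.roles:
            return False
        if self.chains and residue.key.chain_id not in self.chains:
            return False
        if self.residue_ranges:
            n = residue.key.seq_num
            if not any(lo <= n <= hi for lo, hi in self.residue_ranges):
                return False
        return True


def residues_in(model: StructureModel, selection: Selection) -> list[Residue]:
    return [r for r in model.residues() if selection.matches(model, r)]
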