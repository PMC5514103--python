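"""Reading and writing macromolecular coordinates.

gemmi does the heavy lifting for both PDB and mmCIF; this module turns its
hierarchy into the package's plain :class:`~interfab.model.StructureModel`,
applying the conventions used throughout:

* hydrogens (and deuteriums) are dropped on parse — every downstream criterion
  is heavy-atom based;
* alternate locations are resolved to the highest-occupancy conformer, ties
  broken by altloc letter;
* only one model of a multi-model file is kept (the first by default);
* waters are retained and always carry role ``water``;
* author (PDB) residue numbering is preserved, so residue labels used in the
  literature (E58, R113, ...) map directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import gemmi
import numpy as np
import yaml

from .model import (
    ROLE_OTHER,
    ROLE_WATER,
    ROLES,
    STANDARD_AA,
    AtomRecord,
    ConfigurationError,
    ParseError,
    Residue,
    ResidueKey,
    Selection,
    SelectionError,
    StructureError,
    StructureModel,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# radii
# ---------------------------------------------------------------------------

@dataclass
class RadiiTable:
    """(res_name, atom_name) -> radius with element-level fallback."""

    name: str
    elements: dict[str, float]
    residue_atoms: dict[str, dict[str, float]] = field(default_factory=dict)
    probe_radius: float = 1.4

    def __post_init__(self) -> None:
        for radius in list(self.elements.values()) + [
            r for d in self.residue_atoms.values() for r in d.values()
        ]:
            if not 0.5 <= radius <= 3.0:
                raise ConfigurationError(f"radius {radius} outside the plausible 0.5-3.0 A")
        for el in ("C", "N", "O", "S"):
            if el not in self.elements:
                raise ConfigurationError(f"radii table must provide a fallback for element {el}")

    def lookup(self, res_name: str, atom_name: str, element: str) -> float:
        # the "*" entry covers the shared backbone atoms of amino acids only;
        # a ligand atom that happens to be named "C" falls back to its element
        keys = (res_name, "*") if res_name in STANDARD_AA else (res_name,)
        for key in keys:
            value = self.residue_atoms.get(key, {}).get(atom_name)
            if value is not None:
                return value
        element = element.upper()
        if element in self.elements:
            return self.elements[element]
        raise StructureError(f"no radius for element {element!r} (atom {res_name}/{atom_name})")

    @classmethod
    def from_yaml(cls, source: str | Path) -> "RadiiTable":
        data = yaml.safe_load(Path(source).read_text())
        return cls(
            name=data["name"],
            elements={str(k): float(v) for k, v in data["elements"].items()},
            residue_atoms={
                str(res): {str(a): float(r) for a, r in atoms.items()}
                for res, atoms in data.get("residue_atoms", {}).items()
            },
            probe_radius=float(data.get("probe_radius", 1.4)),
        )


def default_radii_table() -> RadiiTable:
    """The packaged Chothia-class radii (probe 1.4 A)."""
    with resources.as_file(resources.files("interfab.data") / "radii.yaml") as path:
        return RadiiTable.from_yaml(path)


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _read_gemmi(source: str | Path, fmt: str) -> gemmi.Structure:
    text: str | None = None
    path: Path | None = None
    if isinstance(source, Path):
        path = source
    elif "\n" in source:
        text = source
    else:
        path = Path(source)

    if path is not None:
        if not path.exists():
            raise ParseError(f"no such coordinate file: {path}")
        text = path.read_text()

    assert text is not None
    if fmt == "auto":
        stripped = text.lstrip()
        fmt = "mmcif" if stripped.startswith(("data_", "#")) else "pdb"

    try:
        if fmt == "pdb":
            structure = gemmi.read_pdb_string(text)
        elif fmt == "mmcif":
            block = gemmi.cif.read_string(text).sole_block()
            structure = gemmi.make_structure_from_block(block)
        else:
            raise ParseError(f"unknown coordinate format {fmt!r} (expected pdb or mmcif)")
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"could not parse {fmt} input: {exc}") from exc
    structure.setup_entities()
    return structure


def _resolve_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one conformer per atom name: highest occupancy, ties by letter."""
    by_name: dict[str, AtomRecord] = {}
    order: list[str] = []
    for atom in atoms:
        if atom.name not in by_name:
            by_name[atom.name] = atom
            order.append(atom.name)
        else:
            held = by_name[atom.name]
            if (atom.occupancy, -ord(atom.altloc or "A")) > (held.occupancy, -ord(held.altloc or "A")):
                by_name[atom.name] = atom
    for atom in by_name.values():
        atom.altloc = ""
    return [by_name[name] for name in order]


def parse_structure(
    source: str | Path,
    fmt: str = "auto",
    model_index: int = 0,
    source_id: str | None = None,
) -> StructureModel:
    """Parse a PDB or mmCIF file (or raw text) into a :class:`StructureModel`.

    Parameters
    ----------
    source:
        Path to a coordinate file, or the file content itself (detected by the
        presence of newlines).
    fmt:
        ``pdb``, ``mmcif`` or ``auto``.
    model_index:
        Which model of a multi-model file to keep (default: the first).
    """
    structure = _read_gemmi(source, fmt)
    if len(structure) == 0:
        raise ParseError("coordinate input contains no models")
    if not 0 <= model_index < len(structure):
        raise ParseError(f"model index {model_index} out of range (file has {len(structure)})")
    gmodel = structure[model_index]

    chains: dict[str, list[Residue]] = {}
    n_atoms = 0
    for gchain in gmodel:
        residues = chains.setdefault(gchain.name, [])
        for gres in gchain:
            atoms: list[AtomRecord] = []
            for gatom in gres:
                if gatom.element.name in ("H", "D"):
                    continue
                atoms.append(
                    AtomRecord(
                        serial=gatom.serial,
                        name=gatom.name,
                        element=gatom.element.name,
                        coords=np.array([gatom.pos.x, gatom.pos.y, gatom.pos.z]),
                        occupancy=float(min(max(gatom.occ, 0.0), 1.0)),
                        altloc=gatom.altloc if gatom.altloc else "",
                        b_factor=float(gatom.b_iso),
                    )
                )
            if not atoms:
                continue
            atoms = _resolve_altlocs(atoms)
            key = ResidueKey(
                chain_id=gchain.name,
                seq_num=gres.seqid.num,
                icode=gres.seqid.icode.strip(),
                res_name=gres.name,
            )
            residues.append(Residue(key, atoms))
            n_atoms += len(atoms)
    chains = {c: rs for c, rs in chains.items() if rs}
    if n_atoms == 0:
        raise ParseError("coordinate input contains no (heavy) atoms")

    model = StructureModel(
        chains=chains,
        role_map={c: ROLE_OTHER for c in chains},
        source_id=source_id or structure.name or (str(source) if isinstance(source, Path) else ""),
    )
    # chains that are pure solvent are water by construction
    for cid, residues in chains.items():
        if all(r.is_water for r in residues):
            model.role_map[cid] = ROLE_WATER
    return model


# ---------------------------------------------------------------------------
# roles, radii, selection
# ---------------------------------------------------------------------------

def assign_roles(model: StructureModel, role_spec: dict[str, str]) -> StructureModel:
    """Set chain roles; unlisted chains become ``other`` (with a warning)."""
    for chain_id, role in role_spec.items():
        if chain_id not in model.chains:
            raise ConfigurationError(
                f"role spec names chain {chain_id!r} absent from {sorted(model.chains)}"
            )
        if role not in ROLES:
            raise ConfigurationError(f"unknown role {role!r}; expected one of {ROLES}")
    out = model.copy()
    for chain_id in out.chains:
        if chain_id in role_spec:
            out.role_map[chain_id] = role_spec[chain_id]
        else:
            if not all(r.is_water for r in out.chains[chain_id]):
                logger.warning("chain %s not in role spec; assigned role 'other'", chain_id)
                out.role_map[chain_id] = ROLE_OTHER
            else:
                out.role_map[chain_id] = ROLE_WATER
    return out


def assign_radii(model: StructureModel, table: RadiiTable | None = None) -> StructureModel:
    """Assign a van der Waals radius to every heavy atom (idempotent)."""
    table = table or default_radii_table()
    failures = []
    for res, atom in model.atoms():
        try:
            atom.radius = table.lookup(res.key.res_name, atom.name, atom.element)
        except StructureError:
            failures.append(f"{res.key}/{atom.name}({atom.element})")
    if failures:
        raise StructureError("cannot assign radii to: " + ", ".join(failures[:10]))
    return model


def select(model: StructureModel, selection: Selection) -> StructureModel:
    """Extract a sub-model; keys, roles and radii are preserved."""
    chains: dict[str, list[Residue]] = {}
    for cid, residues in model.chains.items():
        kept = [res for res in residues if selection.matches(model, res)]
        if kept:
            chains[cid] = [Residue(r.key, list(r.atoms)) for r in kept]
    if not chains:
        raise SelectionError(f"selection {selection} matches nothing in {model.source_id or 'model'}")
    return StructureModel(
        chains=chains,
        role_map={c: model.role_map.get(c, ROLE_OTHER) for c in chains},
        source_id=model.source_id,
    )


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_pdb(model: StructureModel) -> str:
    """Serialize the model as fixed-column PDB text (round-trips through parse)."""
    if model.n_atoms == 0:
        raise StructureError("refusing to write an empty model")
    structure = gemmi.Structure()
    structure.name = model.source_id or "interfab"
    gmodel = gemmi.Model("1")
    serial = 0
    for cid, residues in model.chains.items():
        if len(cid) != 1:
            raise StructureError(f"PDB format needs 1-character chain ids, got {cid!r}")
        gchain = gemmi.Chain(cid)
        for res in residues:
            gres = gemmi.Residue()
            gres.name = res.key.res_name
            gres.seqid = gemmi.SeqId(res.key.seq_num, res.key.icode or " ")
            gres.het_flag = "H" if res.is_water else "A"
            for atom in res.atoms:
                serial += 1
                gatom = gemmi.Atom()
                gatom.name = atom.name
                gatom.element = gemmi.Element(atom.element)
                gatom.pos = gemmi.Position(*atom.coords)
                gatom.occ = atom.occupancy
                gatom.b_iso = atom.b_factor
                gatom.serial = serial
                gres.add_atom(gatom)
            gchain.add_residue(gres)
        gmodel.add_chain(gchain)
    structure.add_model(gmodel)
    structure.setup_entities()
    return structure.make_pdb_string()
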