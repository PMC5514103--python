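"""Synthetic coordinate fixtures with analytically known ground truth.

Every analysis stage in the package is testable without downloading any
crystal structure: these generators build small coordinate models whose
correct answer is known by construction —

* sphere clusters (SASA against closed forms, neighbor-search oracles);
* two-chain toy complexes with planted hydrogen bonds, salt bridges, van der
  Waals contacts and water bridges at exact distances, isolated in slots far
  enough apart that no unplanned cross-chain contact can occur;
* hinged two-domain chains with a known inter-domain rotation (Fab elbow
  test bed);
* antigen/homolog pairs where one small residue is replaced by a bulky
  tryptophan positioned to overlap a partner chain by a stated margin
  (cross-reactivity clash test bed).

Fixtures use real residue and atom names so the donor/acceptor and radii
tables are exercised, but the backbone geometry is idealized: they are
geometric test instruments, not physically realistic folds. All randomized
placement flows through one seeded RNG per fixture, so a fixed seed yields
byte-identical PDB output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import (
    ROLE_ANTIGEN,
    ROLE_HEAVY,
    ROLE_LIGHT,
    AtomRecord,
    Residue,
    ResidueKey,
    StructureModel,
)

__all__ = [
    "PlantedContact",
    "make_sphere_cluster",
    "make_toy_complex",
    "make_hinged_fab",
    "make_homolog_pair",
]

_SLOT_SPACING = 15.0  # A between planted-contact slots; >> any contact cutoff


def _atom(serial: int, name: str, element: str, xyz) -> AtomRecord:
    return AtomRecord(serial=serial, name=name, element=element, coords=np.asarray(xyz, float))


# ---------------------------------------------------------------------------
# sphere clusters
# ---------------------------------------------------------------------------

def make_sphere_cluster(
    n: int, box: float = 40.0, seed: int = 0, radius: float = 1.9
) -> tuple[StructureModel, list[tuple[int, int, float]]]:
    """n pseudo-atoms uniformly placed in a cube, with the all-pairs distances.

    Each pseudo-atom is its own UNK residue with a single carbon whose radius
    is set directly (no table lookup), so SASA can be compared against the
    closed forms at an exactly known radius.
    """
    if n < 1:
        raise ValueError("need at least one atom")
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0.0, box, size=(n, 3))
    residues = []
    for i in range(n):
        atom = _atom(i + 1, "C", "C", coords[i])
        atom.radius = radius
        residues.append(Residue(ResidueKey("A", i + 1, "", "UNK"), [atom]))
    model = StructureModel({"A": residues}, {"A": ROLE_ANTIGEN}, source_id=f"sphere_cluster_seed{seed}")
    truth = [
        (i + 1, j + 1, float(np.linalg.norm(coords[i] - coords[j])))
        for i in range(n)
        for j in range(i + 1, n)
    ]
    return model, truth


# ---------------------------------------------------------------------------
# toy complexes with planted contacts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedContact:
    """One contact to realize between the two chains of a toy complex.

    category: hydrogen_bond | salt_bridge | salt_bridge_bidentate | vdw |
    water_bridge. ``distance`` is the tip-atom separation (for a water bridge,
    the two water-to-tip gaps are ``water_gaps``).
    """

    category: str
    distance: float = 0.0
    water_gaps: tuple[float, float] = (2.8, 2.9)

    def effective_distance(self) -> float:
        if self.distance:
            return self.distance
        return {"hydrogen_bond": 2.9, "salt_bridge": 3.5,
                "salt_bridge_bidentate": 3.5, "vdw": 3.8,
                "water_bridge": sum(self.water_gaps)}[self.category]


# residue templates in a local frame: tip atom at the origin, stalk receding
# along -y (mirrored for the opposite chain). (name, element, x, y, z)
_TEMPLATES: dict[str, list[tuple[str, str, float, float, float]]] = {
    "SER": [
        ("OG", "O", 0.0, 0.0, 0.0), ("CB", "C", 0.0, -1.43, 0.0),
        ("CA", "C", 0.0, -2.93, 0.0), ("N", "N", -1.20, -3.63, 0.30),
        ("C", "C", 1.20, -3.63, 0.0), ("O", "O", 1.30, -4.83, 0.40),
    ],
    "ARG": [
        ("NH1", "N", 0.0, 0.0, 0.0), ("NH2", "N", 2.20, 0.0, 1.40),
        ("CZ", "C", 0.0, -1.33, 0.0), ("NE", "N", 0.0, -2.63, 0.0),
        ("CD", "C", 0.0, -3.93, 0.0), ("CG", "C", 0.0, -5.23, 0.0),
        ("CB", "C", 0.0, -6.53, 0.0), ("CA", "C", 0.0, -7.93, 0.0),
        ("N", "N", -1.20, -8.63, 0.30), ("C", "C", 1.20, -8.63, 0.0),
        ("O", "O", 1.30, -9.83, 0.40),
    ],
    "ARG_BIDENTATE": [
        ("NH1", "N", 0.0, 0.0, 0.0), ("NH2", "N", 2.20, 0.0, 0.0),
        ("CZ", "C", 1.10, -1.10, 0.0), ("NE", "N", 1.10, -2.40, 0.0),
        ("CD", "C", 1.10, -3.70, 0.0), ("CG", "C", 1.10, -5.00, 0.0),
        ("CB", "C", 1.10, -6.30, 0.0), ("CA", "C", 1.10, -7.70, 0.0),
        ("N", "N", -0.10, -8.40, 0.30), ("C", "C", 2.30, -8.40, 0.0),
        ("O", "O", 2.40, -9.60, 0.40),
    ],
    "GLU": [
        ("OE1", "O", 0.0, 0.0, 0.0), ("OE2", "O", 2.20, 0.0, -1.40),
        ("CD", "C", 0.0, -1.25, 0.0), ("CG", "C", 0.0, -2.75, 0.0),
        ("CB", "C", 0.0, -4.25, 0.0), ("CA", "C", 0.0, -5.75, 0.0),
        ("N", "N", -1.20, -6.45, 0.30), ("C", "C", 1.20, -6.45, 0.0),
        ("O", "O", 1.30, -7.65, 0.40),
    ],
    "GLU_BIDENTATE": [
        ("OE1", "O", 0.0, 0.0, 0.0), ("OE2", "O", 2.20, 0.0, 0.0),
        ("CD", "C", 1.10, -1.10, 0.0), ("CG", "C", 1.10, -2.60, 0.0),
        ("CB", "C", 1.10, -4.10, 0.0), ("CA", "C", 1.10, -5.60, 0.0),
        ("N", "N", -0.10, -6.30, 0.30), ("C", "C", 2.30, -6.30, 0.0),
        ("O", "O", 2.40, -7.50, 0.40),
    ],
    "LEU": [
        ("CD1", "C", 0.0, 0.0, 0.0), ("CD2", "C", 1.40, -0.80, 1.00),
        ("CG", "C", 0.0, -1.40, 0.0), ("CB", "C", 0.0, -2.90, 0.0),
        ("CA", "C", 0.0, -4.40, 0.0), ("N", "N", -1.20, -5.10, 0.30),
        ("C", "C", 1.20, -5.10, 0.0), ("O", "O", 1.30, -6.30, 0.40),
    ],
    "ALA": [
        ("CB", "C", 0.0, 0.0, 0.0), ("CA", "C", 0.0, -1.50, 0.0),
        ("N", "N", -1.20, -2.20, 0.30), ("C", "C", 1.20, -2.20, 0.0),
        ("O", "O", 1.30, -3.40, 0.40),
    ],
}

# which residue pair realizes each planted category (side a, side b)
_PAIRINGS = {
    "hydrogen_bond": ("SER", "SER"),
    "salt_bridge": ("ARG", "GLU"),
    "salt_bridge_bidentate": ("ARG_BIDENTATE", "GLU_BIDENTATE"),
    "vdw": ("LEU", "ALA"),
    "water_bridge": ("SER", "SER"),
}

_HBOND_MAX, _SALT_MAX, _VDW_MAX, _WATER_MAX = 3.5, 4.0, 4.0, 3.5


def _intended_category(planted: PlantedContact) -> str | None:
    """What the default distance criteria make of this planted geometry.

    Derived directly from the planted distances and the published defaults —
    a deliberate re-statement of the classification rules, independent of the
    detector code path, so recovery tests are two-route.
    """
    d = planted.effective_distance()
    if planted.category == "water_bridge":
        return "water_bridge" if max(planted.water_gaps) <= _WATER_MAX else None
    if planted.category == "hydrogen_bond":
        if d <= _HBOND_MAX:
            return "hydrogen_bond"
        return "vdw" if d <= _VDW_MAX else None
    if planted.category in ("salt_bridge", "salt_bridge_bidentate"):
        return "salt_bridge" if d <= _SALT_MAX else None
    if planted.category == "vdw":
        return "vdw" if d <= _VDW_MAX else None
    raise ValueError(f"unknown planted category {planted.category!r}")


def _place(template: str, tip: np.ndarray, side: str, serial_start: int,
           chain: str, seq: int) -> tuple[Residue, int]:
    sign = -1.0 if side == "b" else 1.0  # side b stalks recede toward +y
    atoms = []
    serial = serial_start
    res_name = template.split("_")[0]
    for name, element, x, y, z in _TEMPLATES[template]:
        serial += 1
        atoms.append(_atom(serial, name, element, tip + np.array([x, sign * y, z])))
    return Residue(ResidueKey(chain, seq, "", res_name), atoms), serial


def make_toy_complex(
    planted: list[PlantedContact], seed: int = 0
) -> tuple[StructureModel, list[tuple[str, int, int]]]:
    """Two peptide-like chains realizing each planted contact in its own slot.

    Returns the model (chains A and B, waters in chain W) and the ground-truth
    inventory as (category, residue_a seq, residue_b seq) triples, already
    expressed in terms of the default criteria (a "hydrogen bond" planted
    beyond 3.5 A appears as vdw, etc.). Chain A is tagged antigen and chain B
    heavy, so role-based selections work out of the box.
    """
    chain_a: list[Residue] = []
    chain_b: list[Residue] = []
    waters: list[Residue] = []
    inventory: list[tuple[str, int, int]] = []
    serial = 0
    for contact in planted:
        if contact.category == "water_bridge":
            if not all(1.0 <= g <= 4.0 for g in contact.water_gaps):
                raise ValueError(
                    f"planted water gaps {contact.water_gaps} outside the satisfiable 1.0-4.0 A"
                )
            continue
        d = contact.effective_distance()
        if not 1.0 <= d <= 6.0:
            raise ValueError(
                f"planted {contact.category} at {d:.2f} A is geometrically unsatisfiable "
                "in this construction (supported range 1.0-6.0 A)"
            )
    for slot, contact in enumerate(planted):
        x = slot * _SLOT_SPACING
        tmpl_a, tmpl_b = _PAIRINGS[contact.category]
        if contact.category == "water_bridge":
            ga, gb = contact.water_gaps
            tip_a = np.array([x, 0.0, 0.0])
            tip_b = np.array([x, ga + gb, 0.0])
            serial += 1
            waters.append(
                Residue(
                    ResidueKey("W", len(waters) + 1, "", "HOH"),
                    [_atom(serial, "O", "O", [x, ga, 0.0])],
                )
            )
        else:
            tip_a = np.array([x, 0.0, 0.0])
            tip_b = np.array([x, contact.effective_distance(), 0.0])
        res_a, serial = _place(tmpl_a, tip_a, "a", serial, "A", slot + 1)
        res_b, serial = _place(tmpl_b, tip_b, "b", serial, "B", slot + 1)
        chain_a.append(res_a)
        chain_b.append(res_b)
        category = _intended_category(contact)
        if category is not None:
            inventory.append((category, slot + 1, slot + 1))

    if not planted:
        # an empty spec still yields a valid, simply non-contacting, complex
        res_a, serial = _place("SER", np.array([0.0, 0.0, 0.0]), "a", serial, "A", 1)
        res_b, serial = _place("SER", np.array([0.0, 10.0, 0.0]), "b", serial, "B", 1)
        chain_a.append(res_a)
        chain_b.append(res_b)

    chains: dict[str, list[Residue]] = {"A": chain_a, "B": chain_b}
    if waters:
        chains["W"] = waters
    model = StructureModel(
        chains,
        {"A": ROLE_ANTIGEN, "B": ROLE_HEAVY, **({"W": "water"} if waters else {})},
        source_id=f"toy_complex_seed{seed}",
    )
    return model, inventory


# ---------------------------------------------------------------------------
# hinged two-domain chains
# ---------------------------------------------------------------------------

def _rotation_about_axis(axis: np.ndarray, degrees: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    theta = np.radians(degrees)
    k = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    return np.eye(3) + np.sin(theta) * k + (1 - np.cos(theta)) * (k @ k)


def make_hinged_fab(
    angle: float, seed: int = 0, n_per_domain: int = 30
) -> tuple[StructureModel, StructureModel]:
    """Two copies of a two-domain CA chain; copy 2's 'constant' domain is
    rotated by ``angle`` degrees about a hinge axis (z through the elbow).

    Residues 1..n are the variable module, n+1..2n the constant module.
    """
    if not 0 <= angle <= 180:
        raise ValueError("angle must be in [0, 180] degrees")
    rng = np.random.default_rng(seed)

    def _blob(center: np.ndarray) -> np.ndarray:
        pts = rng.normal(size=(n_per_domain, 3))
        pts *= (8.0 * rng.uniform(0.3, 1.0, size=(n_per_domain, 1))) / np.linalg.norm(
            pts, axis=1, keepdims=True
        )
        return center + pts

    v_pts = _blob(np.array([0.0, 0.0, 0.0]))
    c_pts = _blob(np.array([25.0, 0.0, 0.0]))
    hinge = np.array([12.5, 0.0, 0.0])
    rot = _rotation_about_axis(np.array([0.0, 0.0, 1.0]), angle)
    c_rotated = (c_pts - hinge) @ rot.T + hinge

    def _chain(v: np.ndarray, c: np.ndarray, tag: str) -> StructureModel:
        residues = []
        serial = 0
        for i, xyz in enumerate(np.vstack([v, c])):
            serial += 1
            residues.append(
                Residue(ResidueKey("F", i + 1, "", "GLY"), [_atom(serial, "CA", "C", xyz)])
            )
        return StructureModel({"F": residues}, {"F": ROLE_HEAVY}, source_id=tag)

    base = _chain(v_pts, c_pts, f"hinged_fab_seed{seed}_base")
    swung = _chain(v_pts, c_rotated, f"hinged_fab_seed{seed}_swung{angle:g}")
    return base, swung


# ---------------------------------------------------------------------------
# homolog pairs with a planted bulky substitution
# ---------------------------------------------------------------------------

_TRP_SIDE = [  # idealized indole reaching +y from CA; tip CZ2 at y=5.0
    ("CB", "C", 0.0, 1.50, 0.0), ("CG", "C", 0.0, 2.90, 0.0),
    ("CD1", "C", -1.15, 3.70, 0.0), ("CD2", "C", 0.75, 3.90, 0.0),
    ("NE1", "N", -0.90, 4.95, 0.0), ("CE2", "C", 0.40, 5.05, 0.0),
    ("CE3", "C", 1.60, 3.30, 0.0), ("CZ2", "C", 0.0, 5.00, 0.9),
    ("CZ3", "C", 2.40, 4.20, 0.0), ("CH2", "C", 1.90, 5.20, 0.0),
]
_TRP_TIP_Y = 5.0
_C_RING_RADIUS = 1.76   # trigonal carbon in the packaged table
_C_ALIPHATIC_RADIUS = 1.87


def make_homolog_pair(
    margin: float,
    position: int = 5,
    n_residues: int = 9,
    substitute: bool = True,
) -> tuple[StructureModel, StructureModel, ResidueKey, bool]:
    """An antigen/partner complex plus a homolog with a bulky substitution.

    The antigen (chain A) is a zig-zag of alanines; a partner atom (chain B)
    sits above residue ``position``. The homolog has identical coordinates
    except that residue ``position`` is a tryptophan whose ring tip overlaps
    the partner atom by ``margin`` Angstrom of van der Waals radius (negative
    margin: no overlap). With ``substitute=False`` the homolog is identical
    (self-graft control).

    Returns (complex model, homolog, target residue key, expected clash flag
    at the default 0.4 A overlap threshold).
    """
    if not 1 <= position <= n_residues:
        raise ValueError("position outside the chain")

    def _ala(chain: str, seq: int, serial: int, base: np.ndarray,
             flip: bool = False) -> tuple[Residue, int]:
        sign = -1.0 if flip else 1.0  # flipped: CB points -y (down toward the interface)
        atoms = []
        for name, element, dx, dy, dz in [
            ("N", "N", -1.2, -0.7, 0.3), ("CA", "C", 0.0, 0.0, 0.0),
            ("C", "C", 1.2, -0.7, 0.0), ("O", "O", 1.3, -1.9, 0.4),
            ("CB", "C", 0.0, 1.50, 0.0),
        ]:
            serial += 1
            atoms.append(_atom(serial, name, element, base + np.array([dx, sign * dy, dz])))
        return Residue(ResidueKey(chain, seq, "", "ALA"), atoms), serial

    serial = 0
    antigen: list[Residue] = []
    bases = []
    for i in range(n_residues):
        base = np.array([3.0 * i, 0.0, 0.8 * (i % 2)])  # zig-zag: never collinear
        bases.append(base)
        res, serial = _ala("A", i + 1, serial, base)
        antigen.append(res)

    # clash target distance: ring tip (trigonal C) vs partner CB (aliphatic C)
    target_d = _C_RING_RADIUS + _C_ALIPHATIC_RADIUS - margin
    tip = bases[position - 1] + np.array([0.0, _TRP_TIP_Y, 0.9])
    # flipped partner: its CB sits at base - (0, 1.5, 0), backbone recedes upward
    partner_base = tip + np.array([0.0, target_d + 1.5, 0.0])
    partner_res, serial = _ala("B", 1, serial, partner_base, flip=True)

    complex_model = StructureModel(
        {"A": antigen, "B": [partner_res]},
        {"A": ROLE_ANTIGEN, "B": ROLE_HEAVY},
        source_id="homolog_pair_complex",
    )

    homolog_res: list[Residue] = []
    serial_h = 0
    for i in range(n_residues):
        if substitute and i + 1 == position:
            atoms = []
            for name, element, dx, dy, dz in [
                ("N", "N", -1.2, -0.7, 0.3), ("CA", "C", 0.0, 0.0, 0.0),
                ("C", "C", 1.2, -0.7, 0.0), ("O", "O", 1.3, -1.9, 0.4),
            ] + _TRP_SIDE:
                serial_h += 1
                atoms.append(_atom(serial_h, name, element, bases[i] + np.array([dx, dy, dz])))
            homolog_res.append(Residue(ResidueKey("A", i + 1, "", "TRP"), atoms))
        else:
            res, serial_h = _ala("A", i + 1, serial_h, bases[i])
            homolog_res.append(res)
    homolog = StructureModel({"A": homolog_res}, {"A": ROLE_ANTIGEN}, source_id="homolog_pair_homolog")

    target_key = homolog_res[position - 1].key
    expected_clash = substitute and margin > 0.4
    return complex_model, homolog, target_key, expected_clash
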