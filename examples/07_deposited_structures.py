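"""The full pipeline on the deposited PD-L1 complexes (needs the cache).

Recomputes, from the deposited coordinates, the interface numbers of the
PD-L1 complexes with atezolizumab (5X8L), durvalumab (5X8M) and the PD-1
receptor (4ZQK): buried areas, heavy-chain share, interface residue counts,
contact inventories, ASU copy counts, the Fab elbow swing and the shared
epitope. The coordinate files are not redistributable here; populate the
cache first (network required):

    interfab fetch --accession 5X8L --accession 5X8M --accession 4ZQK --accession 3BOV
"""

from importlib import resources
from pathlib import Path

import interfab as ifb
from interfab.crossreact import read_fasta
from interfab.model import Selection
from interfab.report import _canonical_copy, infer_complex_copies
from interfab.structure_io import assign_radii, assign_roles, parse_structure

CACHE = Path(__file__).resolve().parents[1] / "data" / "structures"
ANTIGEN = Selection.by_role("antigen")
BINDER = Selection.by_role("heavy", "light")


def pdl1_v_domain() -> str:
    text = (resources.files("interfab.data") / "pdl1_human.fasta").read_text()
    return next(iter(read_fasta(text).values()))[17:134]


def load(accession: str):
    for suffix in (".cif", ".pdb"):
        path = CACHE / f"{accession.lower()}{suffix}"
        if path.exists():
            return parse_structure(path, source_id=accession)
    raise SystemExit(
        f"{accession} not in {CACHE}/ — run `interfab fetch --accession {accession}` "
        "on a networked machine first"
    )


for accession, name in (("5x8l", "atezolizumab"), ("5x8m", "durvalumab")):
    model = load(accession)
    roles, copies = infer_complex_copies(model, pdl1_v_domain())
    model = assign_roles(model, roles)
    assign_radii(model)
    print(f"{name} ({accession.upper()}): {ifb.asu_copy_count(model)} complex copies in the ASU")
    for i, copy in enumerate(copies):
        sub = _canonical_copy(model, copy)
        summary = ifb.buried_area(sub, ANTIGEN, BINDER)
        residues, _ = ifb.interface_residues(sub, ANTIGEN, BINDER, summary=summary)
        _, counts = ifb.contact_table(sub, ANTIGEN, BINDER)
        contrib = ifb.chain_contribution(summary, "b")
        print(
            f"  copy {i}: BSA {summary.bsa_total:7.1f} A^2 | heavy share "
            f"{contrib.get('heavy', 0) * 100:4.1f}% | {len(residues)} antigen residues | "
            f"H-bonds {counts['hydrogen_bond']}, salt bridges {counts['salt_bridge']}, "
            f"bridging waters {counts['water_bridge']}"
        )
    print()

model = load("4zqk")
roles, _ = infer_complex_copies(model, pdl1_v_domain(), fallback_binder_role="heavy")
model = assign_roles(model, roles)
assign_radii(model)
bsa = ifb.buried_area(model, ANTIGEN, Selection.by_role("heavy")).bsa_total
print(f"PD-1/PD-L1 receptor interface (4ZQK): BSA {bsa:.1f} A^2")
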