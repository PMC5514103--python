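"""End-to-end interface report: from a config naming structures to a bundle.

A run config lists one or more antigen/antibody (or antigen/receptor)
complexes — local coordinate files or accessions resolved against a local
cache directory (this package never downloads implicitly; see the ``fetch``
subcommand) — with a chain-role map per input. The pipeline computes, per
complex copy: buried surface area, per-chain contributions, interface residue
sets, the typed contact inventory; across complexes: epitope overlap and
per-region loop deviations; optionally the Fab elbow swing over ASU copies,
a homolog cross-reactivity clash scan and a glycosylation-site report.

Every stage failure is caught and recorded with its stage name; partial
results are preserved. All numeric fields carry units in the key name.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .contacts import InterfaceCriteria, buried_area, chain_contribution, contact_table, interface_residues
from .crossreact import find_sequons, glyco_epitope_distance, graft_clash_scan, read_fasta, structural_alignment
from .epitopes import (
    RegionMap,
    asu_copy_count,
    default_pdl1_region_map,
    elbow_swing,
    epitope_overlap,
    epitope_set,
    loop_deviation,
    superpose_on_antigen,
)
from .model import ROLE_ANTIGEN, ROLE_HEAVY, ROLE_LIGHT, Selection, StructureError, StructureModel
from .structure_io import assign_radii, assign_roles, parse_structure, select

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "ComplexSpec",
    "run_interface_report",
    "resolve_structure_path",
    "chain_sequence",
    "infer_complex_copies",
]

# Constant-region sequence signatures used to tell Fab heavy from light chains:
# the N-terminus of the human IgG1 CH1 domain and of the human kappa CL domain.
HEAVY_CH1_MOTIF = "ASTKGPSVFPLAP"
KAPPA_CL_MOTIF = "TVAAPSVFIFPP"


def resolve_structure_path(name: str, cache_dir: Path) -> Path:
    """Resolve a path or accession against the local structure cache."""
    p = Path(name)
    if p.exists():
        return p
    for candidate in (
        cache_dir / f"{name.lower()}.cif",
        cache_dir / f"{name.upper()}.cif",
        cache_dir / f"{name.lower()}.pdb",
        cache_dir / f"{name.upper()}.pdb",
    ):
        if candidate.exists():
            return candidate
    raise FileNotFoundError(
        f"structure {name!r} not found as a file nor in the cache {cache_dir}/ "
        "(populate it with `interfab fetch` where network access is available)"
    )


@dataclass
class ComplexSpec:
    id: str
    source: str                       # path or accession
    roles: dict[str, str]             # chain -> role
    antigen_label: str = "antigen"
    # each ASU copy: {"antigen": chain, "heavy": chain, "light": chain}
    copies: list[dict[str, str]] = field(default_factory=list)


@dataclass
class RunConfig:
    complexes: list[ComplexSpec]
    cache_dir: Path = Path("data/structures")
    criteria: InterfaceCriteria = field(default_factory=InterfaceCriteria)
    region_map: RegionMap | None = None
    elbow: dict | None = None         # {"complex": id, "v_ranges": {...}, "c_ranges": {...}}
    homolog: dict | None = None       # {"source":, "chain":, "target_residue":, "against": [ids]}
    glyco: dict | None = None         # {"sequence": path|"pdl1", "positions": [...], "against": id}
    out_dir: Path | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        criteria = InterfaceCriteria(**raw.get("criteria", {}))
        region_map = raw.get("region_map")
        if region_map == "pdl1":
            region_map = default_pdl1_region_map()
        elif region_map:
            region_map = RegionMap.from_yaml(region_map)
        complexes = [
            ComplexSpec(
                id=c["id"],
                source=str(c.get("path") or c.get("accession")),
                roles={str(k): str(v) for k, v in c["roles"].items()},
                antigen_label=c.get("antigen_label", "antigen"),
                copies=c.get("copies", []),
            )
            for c in raw["complexes"]
        ]
        return cls(
            complexes=complexes,
            cache_dir=Path(raw.get("cache_dir", "data/structures")),
            criteria=criteria,
            region_map=region_map,
            elbow=raw.get("elbow"),
            homolog=raw.get("homolog"),
            glyco=raw.get("glyco"),
            out_dir=Path(raw["out_dir"]) if raw.get("out_dir") else None,
        )


def chain_sequence(model: StructureModel, chain_id: str) -> str:
    """One-letter sequence of a chain's polymer residues (waters skipped)."""
    return "".join(
        r.key.one_letter for r in model.chains.get(chain_id, []) if not r.is_water
    )


def _sequence_identity(a: str, b: str) -> float:
    from .crossreact import needleman_wunsch

    if not a or not b:
        return 0.0
    aln = needleman_wunsch(a, b)
    matches = sum(1 for x, y in zip(aln.aligned_a, aln.aligned_b) if x == y and x != "-")
    return matches / min(len(a), len(b))


def infer_complex_copies(
    model: StructureModel,
    antigen_seq: str,
    min_identity: float = 0.5,
    fallback_binder_role: str | None = None,
) -> tuple[dict[str, str], list[dict[str, str]]]:
    """Assign chain roles by sequence and group chains into complex copies.

    Antigen chains are recognized by sequence identity to ``antigen_seq``;
    Fab heavy/light chains by their constant-domain signatures. A remaining
    protein chain becomes ``fallback_binder_role`` if given (e.g. a receptor
    treated as the binder), else ``other``. Each antigen chain is paired with
    the spatially nearest heavy and light chains to form one copy.
    """
    roles: dict[str, str] = {}
    for cid in model.chains:
        seq = chain_sequence(model, cid)
        if not seq:
            roles[cid] = "water"
        elif HEAVY_CH1_MOTIF in seq:
            roles[cid] = ROLE_HEAVY
        elif KAPPA_CL_MOTIF in seq:
            roles[cid] = ROLE_LIGHT
        elif _sequence_identity(seq, antigen_seq) >= min_identity:
            roles[cid] = ROLE_ANTIGEN
        else:
            roles[cid] = fallback_binder_role or "other"

    import numpy as np

    def _ca_coords(cid: str):
        pts = [r.atom("CA").coords for r in model.chains[cid]
               if not r.is_water and r.atom("CA") is not None]
        return np.array(pts) if pts else np.zeros((0, 3))

    def _min_dist(c1: str, c2: str) -> float:
        a, b = _ca_coords(c1), _ca_coords(c2)
        if not len(a) or not len(b):
            return float("inf")
        return float(np.min(np.linalg.norm(a[:, None] - b[None], axis=2)))

    copies = []
    for cid, role in roles.items():
        if role != ROLE_ANTIGEN:
            continue
        copy = {"antigen": cid}
        for part in (ROLE_HEAVY, ROLE_LIGHT):
            candidates = [c for c, r in roles.items() if r == part]
            if candidates:
                copy[part] = min(candidates, key=lambda c: _min_dist(cid, c))
        copies.append(copy)
    return roles, copies


def _load_complex(spec: ComplexSpec, cache_dir: Path) -> StructureModel:
    path = resolve_structure_path(spec.source, cache_dir)
    model = parse_structure(path, source_id=spec.id)
    model = assign_roles(model, spec.roles)
    assign_radii(model)
    return model


def _copy_model(model: StructureModel, copy_roles: dict[str, str]) -> StructureModel:
    """Extract one ASU copy (a chain-per-role mapping) as its own complex."""
    chains = list(copy_roles.values())
    sub = select(model, Selection.by_chain(*chains))
    sub = assign_roles(sub, {chain: role for role, chain in copy_roles.items()})
    # keep waters that belong to the file for water-bridge analysis
    water_chains = [c for c in model.chains if model.role_map.get(c) == "water" and c not in sub.chains]
    for wc in water_chains:
        sub.chains[wc] = [r for r in model.chains[wc]]
        sub.role_map[wc] = "water"
    return sub


def _analyze_one(model: StructureModel, spec: ComplexSpec, criteria: InterfaceCriteria,
                 region_map: RegionMap | None) -> dict:
    antigen = Selection.by_role(ROLE_ANTIGEN)
    binder = Selection.by_role(ROLE_HEAVY, ROLE_LIGHT)
    summary = buried_area(model, antigen, binder, criteria)
    res_a, res_b = interface_residues(model, antigen, binder, criteria, summary)
    table, counts = contact_table(model, antigen, binder, criteria,
                                  entity_a=spec.antigen_label)
    contribution = chain_contribution(summary, side="b")
    role_contrib: dict[str, float] = {}
    for chain, frac in contribution.items():
        role = model.role_map.get(chain, chain)
        role_contrib[role] = role_contrib.get(role, 0.0) + frac
    epi = epitope_set(model, binder_id=spec.id, criteria=criteria, region_map=region_map)
    return {
        "bsa_A2": round(summary.bsa_total, 1),
        "binder_contribution_by_chain": {c: round(f, 4) for c, f in contribution.items()},
        "binder_contribution_by_role": {r: round(f, 4) for r, f in role_contrib.items()},
        "n_antigen_interface_residues": len(res_a),
        "n_binder_interface_residues": len(res_b),
        "antigen_interface_residues": sorted(str(k) for k in res_a),
        "contact_counts": counts,
        "epitope_regions": sorted(epi.regions_engaged()),
        "criteria": criteria.as_dict(),
        "_epitope": epi,       # kept for cross-complex stages; stripped on dump
        "_table": table,
    }


def run_interface_report(config: RunConfig) -> dict:
    """Run the full pipeline; returns the report bundle (JSON-serializable
    after the private keys are stripped) and writes JSON/TSV when an output
    directory is configured."""
    bundle: dict = {"complexes": {}, "errors": []}

    loaded: dict[str, StructureModel] = {}
    per_complex_first_copy: dict[str, dict] = {}
    for spec in config.complexes:
        try:
            model = _load_complex(spec, config.cache_dir)
            loaded[spec.id] = model
        except Exception as exc:  # noqa: BLE001 - stage isolation is the contract
            bundle["errors"].append({"stage": "load", "input": spec.id, "error": str(exc)})
            continue
        entry: dict = {"source": spec.source, "asu_antigen_copies": asu_copy_count(model)}
        copies = spec.copies or [None]
        entry["copies"] = []
        for i, copy_roles in enumerate(copies):
            try:
                sub = _copy_model(model, copy_roles) if copy_roles else model
                result = _analyze_one(sub, spec, config.criteria, config.region_map)
                entry["copies"].append(result)
                if spec.id not in per_complex_first_copy:
                    per_complex_first_copy[spec.id] = result
            except Exception as exc:  # noqa: BLE001
                bundle["errors"].append(
                    {"stage": "interface", "input": f"{spec.id}[copy {i}]", "error": str(exc)}
                )
        if entry["copies"]:
            bsas = [c["bsa_A2"] for c in entry["copies"]]
            entry["bsa_mean_A2"] = round(sum(bsas) / len(bsas), 1)
            entry["bsa_spread_A2"] = round(max(bsas) - min(bsas), 1)
        bundle["complexes"][spec.id] = entry

    if len(per_complex_first_copy) >= 2:
        try:
            sets = [entry["_epitope"] for entry in per_complex_first_copy.values()]
            overlap = epitope_overlap(sets)
            bundle["epitope_overlap"] = {
                "intersection_labels": overlap["intersection_labels"],
                "n_intersection": len(overlap["intersection"]),
                "n_union": len(overlap["union"]),
                "jaccard": {f"{a}|{b}": round(v, 3) for (a, b), v in overlap["jaccard"].items()},
            }
        except Exception as exc:  # noqa: BLE001
            bundle["errors"].append({"stage": "epitope_overlap", "input": "*", "error": str(exc)})

    if config.region_map is not None and len(loaded) >= 2:
        try:
            ids = list(loaded)
            ref_id = ids[0]
            deviations = {}
            loop_names = [n for n in config.region_map.regions if n.endswith("loop")]
            for other_id in ids[1:]:
                per_region = {}
                for region in loop_names:
                    try:
                        per_region[region] = loop_deviation(
                            loaded[ref_id], loaded[other_id], region, config.region_map
                        )
                    except StructureError as exc:
                        per_region[region] = {"error": str(exc)}
                deviations[f"{ref_id}|{other_id}"] = per_region
            bundle["loop_deviations"] = deviations
        except Exception as exc:  # noqa: BLE001
            bundle["errors"].append({"stage": "loop_deviation", "input": "*", "error": str(exc)})

    if config.elbow:
        try:
            bundle["elbow"] = _elbow_stage(config, loaded)
        except Exception as exc:  # noqa: BLE001
            bundle["errors"].append({"stage": "elbow", "input": str(config.elbow.get("complex")), "error": str(exc)})

    if config.homolog:
        try:
            bundle["crossreact"] = _homolog_stage(config, loaded, per_complex_first_copy)
        except Exception as exc:  # noqa: BLE001
            bundle["errors"].append({"stage": "crossreact", "input": str(config.homolog.get("source")), "error": str(exc)})

    if config.glyco:
        try:
            bundle["glycosylation"] = _glyco_stage(config, loaded, per_complex_first_copy)
        except Exception as exc:  # noqa: BLE001
            bundle["errors"].append({"stage": "glyco", "input": "glyco", "error": str(exc)})

    if config.out_dir is not None:
        _write_bundle(bundle, config)
    return bundle


def _canonical_copy(model: StructureModel, copy_roles: dict[str, str]) -> StructureModel:
    """One ASU copy with its chains renamed to the role names, so several
    copies of the same complex share chain ids and residue numbering."""
    from .model import Residue, ResidueKey

    chains: dict[str, list[Residue]] = {}
    roles: dict[str, str] = {}
    for role, chain in copy_roles.items():
        if chain not in model.chains:
            raise StructureError(f"ASU copy names chain {chain!r} absent from {model.source_id}")
        chains[role] = [
            Residue(
                ResidueKey(role, r.key.seq_num, r.key.icode, r.key.res_name),
                list(r.atoms),
            )
            for r in model.chains[chain]
        ]
        roles[role] = role if role in ("antigen", "heavy", "light") else "other"
    return StructureModel(chains, roles, source_id=model.source_id)


def _elbow_stage(config: RunConfig, loaded: dict[str, StructureModel]) -> dict:
    spec = config.elbow
    model = loaded[spec["complex"]]
    cx = next(c for c in config.complexes if c.id == spec["complex"])
    if not cx.copies or len(cx.copies) < 2:
        raise StructureError("elbow analysis needs >= 2 ASU copies configured")
    copies = [_canonical_copy(model, roles) for roles in cx.copies]
    v_region = {role: (int(lo), int(hi)) for role, (lo, hi) in spec["v_ranges"].items()}
    c_region = {role: (int(lo), int(hi)) for role, (lo, hi) in spec["c_ranges"].items()}
    result = elbow_swing(copies, v_region, c_region)
    return {
        "pairwise_deg": {f"{i}|{j}": round(a, 2) for (i, j), a in result["pairwise_deg"].items()},
        "max_deg": round(result["max_deg"], 2),
        "max_pair": list(result["max_pair"]),
    }


def _homolog_stage(config: RunConfig, loaded: dict[str, StructureModel],
                   first_copies: dict[str, dict]) -> dict:
    spec = config.homolog
    path = resolve_structure_path(spec["source"], config.cache_dir)
    homolog = parse_structure(path, source_id=str(spec["source"]))
    if spec.get("chain"):
        homolog = select(homolog, Selection.by_chain(spec["chain"]))
    homolog = assign_roles(homolog, {c: ROLE_ANTIGEN for c in homolog.chains
                                     if any(not r.is_water for r in homolog.chains[c])})
    assign_radii(homolog)
    out = {}
    against = spec.get("against") or list(loaded)
    for cid in against:
        model = loaded[cid]
        aln, sup = structural_alignment(
            homolog, model,
            sel_b=Selection.by_role(ROLE_ANTIGEN),
            pair_cutoff=float(spec.get("pair_cutoff", 3.5)),
        )
        target_num = int(spec["target_residue"])
        target = next(
            (r.key for r in homolog.residues() if r.key.seq_num == target_num and not r.is_water),
            None,
        )
        if target is None:
            raise StructureError(f"target residue {target_num} absent from the homolog")
        partner = aln.partner_of(target)
        report = graft_clash_scan(
            model, homolog, sup, target,
            partner=Selection.by_role(ROLE_HEAVY, ROLE_LIGHT),
            overlap_min=float(spec.get("overlap_min", 0.4)),
        )
        out[cid] = {
            "aligned_pairs": len(aln.matched()),
            "alignment_rmsd_A": round(sup.rmsd, 2),
            "target": str(target),
            "target_pairs_with": str(partner) if partner else None,
            "clash_count": report.count,
            "max_overlap_A": round(report.max_overlap, 2),
            "clashing_partner_residues": sorted(str(k) for k in report.partner_residues),
        }
    return out


def _glyco_stage(config: RunConfig, loaded: dict[str, StructureModel],
                 first_copies: dict[str, dict]) -> dict:
    spec = config.glyco
    source = spec.get("sequence", "pdl1")
    if source == "pdl1":
        text = (resources.files("interfab.data") / "pdl1_human.fasta").read_text()
    else:
        text = Path(source).read_text()
    sequence = next(iter(read_fasta(text).values()))
    offset = int(spec.get("numbering_offset", 0))
    sequons = find_sequons(sequence, offset)
    positions = spec.get("positions") or [h.position for h in sequons]
    result: dict = {
        "sequons": [{"position": h.position, "triplet": h.triplet} for h in sequons],
        "sites": {},
    }
    threshold = float(spec.get("independence_threshold", 10.0))
    for cid in spec.get("against") or list(first_copies):
        epi = first_copies[cid]["_epitope"]
        dists = glyco_epitope_distance(loaded[cid], positions, epi,
                                       independence_threshold=threshold)
        result["sites"][cid] = {
            str(pos): {
                "present_in_construct": info["present"],
                "independent": info["independent"],
                "min_distance_A": (round(info["min_distance_A"], 1)
                                   if info["min_distance_A"] is not None else None),
            }
            for pos, info in dists.items()
        }
    return result


def _strip_private(obj):
    if isinstance(obj, dict):
        return {k: _strip_private(v) for k, v in obj.items() if not str(k).startswith("_")}
    if isinstance(obj, list):
        return [_strip_private(v) for v in obj]
    return obj


def _write_bundle(bundle: dict, config: RunConfig) -> None:
    out_dir = config.out_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "report.json").write_text(
        json.dumps(_strip_private(bundle), indent=2, sort_keys=True) + "\n"
    )
    for cid, entry in bundle["complexes"].items():
        for i, copy in enumerate(entry.get("copies", [])):
            table = copy.get("_table")
            if table is not None:
                table.to_csv(out_dir / f"contacts_{cid}_{i}.tsv", sep="\t", index=False)
    lines = ["interface report", "================", ""]
    for cid, entry in bundle["complexes"].items():
        lines.append(f"{cid}: antigen copies in ASU = {entry.get('asu_antigen_copies')}")
        for i, copy in enumerate(entry.get("copies", [])):
            lines.append(
                f"  copy {i}: BSA {copy['bsa_A2']} A^2, "
                f"{copy['n_antigen_interface_residues']} antigen interface residues, "
                f"contacts {copy['contact_counts']}"
            )
    if "epitope_overlap" in bundle:
        lines.append(f"shared epitope: {bundle['epitope_overlap']['intersection_labels']}")
    for err in bundle["errors"]:
        lines.append(f"ERROR [{err['stage']}] {err['input']}: {err['error']}")
    (out_dir / "summary.txt").write_text("\n".join(lines) + "\n")
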