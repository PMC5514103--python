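"""Homolog cross-reactivity and glycosylation-site analysis.

Why an anti-PD-L1 antibody spares the paralog PD-L2 is a structural question:
after a structure-based alignment of the two ligands, does any PD-L2 side
chain, carried into the antibody complex by the superposition, collide with
the antibody? The classic case is the bulky PD-L2 Trp110 occupying the spot
of PD-L1 Ala121 inside the epitope. This module provides the pieces:

* a linear-gap Needleman-Wunsch global alignment (the seed pairing);
* an iterative structural alignment (Kabsch fit <-> re-pairing of nearby
  C-alphas, sequence order preserved);
* a graft clash scan: van der Waals overlap of one superposed homolog side
  chain against the partner chains of the complex;
* an N-glycosylation sequon scan (N-X-S/T, X != P) and the distance from each
  glycosylation site to an epitope, flagging sites far enough away (or outside
  the crystallized construct) that binding is glycosylation-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .epitopes import EpitopeSet
from .geometry import SuperpositionResult, kabsch
from .model import (
    AA3_TO_1,
    ResidueKey,
    Selection,
    StructureError,
    StructureModel,
    residues_in,
)

__all__ = [
    "SequenceAlignment",
    "ResiduePairAlignment",
    "ClashReport",
    "SequonHit",
    "needleman_wunsch",
    "structural_alignment",
    "graft_clash_scan",
    "find_sequons",
    "glyco_epitope_distance",
    "read_fasta",
]

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")


def read_fasta(source: str) -> dict[str, str]:
    """Minimal FASTA reader for sequence input (text, not a path)."""
    sequences: dict[str, str] = {}
    name = None
    for line in source.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            name = line[1:].split()[0]
            sequences[name] = ""
        elif name is not None:
            sequences[name] += line.upper()
    return sequences


# ---------------------------------------------------------------------------
# sequence alignment
# ---------------------------------------------------------------------------

@dataclass
class SequenceAlignment:
    pairs: list[tuple[int | None, int | None]]  # 0-based indices; None = gap
    score: float
    aligned_a: str
    aligned_b: str


def needleman_wunsch(
    seq_a: str,
    seq_b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> SequenceAlignment:
    """Optimal global alignment under a linear gap penalty.

    Tie-breaking in the traceback is deterministic: diagonal first, then up
    (gap in ``seq_b``), then left.
    """
    for seq in (seq_a, seq_b):
        bad = set(seq.upper()) - _AA_ALPHABET
        if bad:
            raise ValueError(f"illegal sequence characters: {sorted(bad)}")
    a, b = seq_a.upper(), seq_b.upper()
    n, m = len(a), len(b)
    score = np.zeros((n + 1, m + 1))
    score[:, 0] = gap * np.arange(n + 1)
    score[0, :] = gap * np.arange(m + 1)
    for i in range(1, n + 1):
        sub = np.where(np.frombuffer(b.encode(), dtype="S1") == a[i - 1].encode(), match, mismatch)
        for j in range(1, m + 1):
            score[i, j] = max(
                score[i - 1, j - 1] + sub[j - 1],
                score[i - 1, j] + gap,
                score[i, j - 1] + gap,
            )
    pairs: list[tuple[int | None, int | None]] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and np.isclose(
            score[i, j], score[i - 1, j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
        ):
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif i > 0 and np.isclose(score[i, j], score[i - 1, j] + gap):
            pairs.append((i - 1, None))
            i -= 1
        else:
            pairs.append((None, j - 1))
            j -= 1
    pairs.reverse()
    aligned_a = "".join(a[p] if p is not None else "-" for p, _ in pairs)
    aligned_b = "".join(b[q] if q is not None else "-" for _, q in pairs)
    return SequenceAlignment(pairs=pairs, score=float(score[n, m]),
                             aligned_a=aligned_a, aligned_b=aligned_b)


# ---------------------------------------------------------------------------
# structural alignment
# ---------------------------------------------------------------------------

@dataclass
class ResiduePairAlignment:
    pairs: list[tuple[ResidueKey | None, ResidueKey | None]]
    method: str                                   # "sequence" | "structural"
    ca_distances: dict[tuple[ResidueKey, ResidueKey], float] = field(default_factory=dict)

    def matched(self) -> list[tuple[ResidueKey, ResidueKey]]:
        return [(ka, kb) for ka, kb in self.pairs if ka is not None and kb is not None]

    def partner_of(self, key_a: ResidueKey) -> ResidueKey | None:
        for ka, kb in self.pairs:
            if ka is not None and (ka.chain_id, ka.seq_num, ka.icode) == (
                key_a.chain_id, key_a.seq_num, key_a.icode
            ):
                return kb
        return None


def _ca_list(model: StructureModel, sel: Selection) -> tuple[list[ResidueKey], np.ndarray]:
    keys, coords = [], []
    for res in residues_in(model, sel):
        atom = res.atom("CA")
        if atom is not None:
            keys.append(res.key)
            coords.append(atom.coords)
    return keys, np.array(coords) if coords else np.zeros((0, 3))


def _monotonic_pairing(dist: np.ndarray, cutoff: float) -> list[tuple[int, int]]:
    """Sequence-order-preserving pairing maximizing total (cutoff - distance).

    A dynamic program over the distance matrix; only pairs closer than the
    cutoff score, so topology-violating pairings on a beta-sandwich cannot
    occur and remote residues stay unpaired.
    """
    n, m = dist.shape
    gain = np.where(dist <= cutoff, cutoff - dist, -np.inf)
    best = np.zeros((n + 1, m + 1))
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            pair = best[i - 1, j - 1] + gain[i - 1, j - 1] if np.isfinite(gain[i - 1, j - 1]) else -np.inf
            best[i, j] = max(pair, best[i - 1, j], best[i, j - 1])
    pairs = []
    i, j = n, m
    while i > 0 and j > 0:
        if np.isfinite(gain[i - 1, j - 1]) and np.isclose(
            best[i, j], best[i - 1, j - 1] + gain[i - 1, j - 1]
        ) and best[i, j] > max(best[i - 1, j], best[i, j - 1]) - 1e-12:
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif best[i - 1, j] >= best[i, j - 1]:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    return pairs


def structural_alignment(
    model_a: StructureModel,
    model_b: StructureModel,
    sel_a: Selection | None = None,
    sel_b: Selection | None = None,
    seed: ResiduePairAlignment | None = None,
    pair_cutoff: float = 3.5,
    max_iter: int = 20,
) -> tuple[ResiduePairAlignment, SuperpositionResult]:
    """Iterative structure-based residue pairing of two homologous chains.

    Alternates a Kabsch fit of ``model_b`` onto ``model_a`` over the current
    C-alpha pairs with re-pairing of close C-alphas (monotonic in sequence,
    <= ``pair_cutoff`` after the fit) until the pair set is stable. The seed
    pairing defaults to a Needleman-Wunsch alignment of the one-letter
    sequences.
    """
    sel_a = sel_a or Selection()
    sel_b = sel_b or Selection()
    keys_a, ca_a = _ca_list(model_a, sel_a)
    keys_b, ca_b = _ca_list(model_b, sel_b)
    if len(keys_a) < 3 or len(keys_b) < 3:
        raise StructureError("structural alignment needs >= 3 C-alphas on each side")

    if seed is not None:
        index_a = {(k.chain_id, k.seq_num, k.icode): i for i, k in enumerate(keys_a)}
        index_b = {(k.chain_id, k.seq_num, k.icode): i for i, k in enumerate(keys_b)}
        current = [
            (index_a[(ka.chain_id, ka.seq_num, ka.icode)], index_b[(kb.chain_id, kb.seq_num, kb.icode)])
            for ka, kb in seed.matched()
            if (ka.chain_id, ka.seq_num, ka.icode) in index_a
            and (kb.chain_id, kb.seq_num, kb.icode) in index_b
        ]
    else:
        seq_a = "".join(AA3_TO_1.get(k.res_name, "A") for k in keys_a)
        seq_b = "".join(AA3_TO_1.get(k.res_name, "A") for k in keys_b)
        nw = needleman_wunsch(seq_a, seq_b)
        current = [(p, q) for p, q in nw.pairs if p is not None and q is not None]
    if len(current) < 3:
        raise StructureError("seed pairing has fewer than 3 pairs")

    sup: SuperpositionResult | None = None
    for _ in range(max_iter):
        ia = [p for p, _ in current]
        ib = [q for _, q in current]
        sup = kabsch(ca_b[ib], ca_a[ia])
        moved_b = sup.apply(ca_b)
        dist = np.linalg.norm(ca_a[:, None, :] - moved_b[None, :, :], axis=2)
        new_pairs = _monotonic_pairing(dist, pair_cutoff)
        if len(new_pairs) < 3:
            raise StructureError(
                f"structural alignment collapsed to {len(new_pairs)} pairs at cutoff {pair_cutoff} A"
            )
        if new_pairs == current:
            break
        current = new_pairs
    else:
        raise StructureError(f"structural alignment did not stabilize in {max_iter} iterations")

    assert sup is not None
    moved_b = sup.apply(ca_b)
    pairs: list[tuple[ResidueKey | None, ResidueKey | None]] = []
    matched_a = {p for p, _ in current}
    matched_b = {q for _, q in current}
    dists = {}
    pi = {p: q for p, q in current}
    for i, key in enumerate(keys_a):
        if i in matched_a:
            j = pi[i]
            pairs.append((key, keys_b[j]))
            dists[(key, keys_b[j])] = float(np.linalg.norm(ca_a[i] - moved_b[j]))
        else:
            pairs.append((key, None))
    for j, key in enumerate(keys_b):
        if j not in matched_b:
            pairs.append((None, key))
    return ResiduePairAlignment(pairs=pairs, method="structural", ca_distances=dists), sup


# ---------------------------------------------------------------------------
# graft clash scan
# ---------------------------------------------------------------------------

@dataclass
class ClashReport:
    grafted_residue: ResidueKey
    clashes: list[tuple[str, str, float, float]]  # (graft atom, partner atom label, distance, overlap)
    count: int
    max_overlap: float
    partner_residues: set[ResidueKey] = field(default_factory=set)


def graft_clash_scan(
    complex_model: StructureModel,
    homolog: StructureModel,
    alignment_sup: SuperpositionResult,
    target_residue: ResidueKey,
    partner: Selection,
    overlap_min: float = 0.4,
) -> ClashReport:
    """Steric clashes of one homolog side chain inside an existing complex.

    The homolog is carried into the complex frame by the structural-alignment
    transform (its own side-chain coordinates, no rotamer rebuilding, the way
    overlay figures are made); a clash is a heavy-atom pair whose distance is
    below ``r_i + r_j - overlap_min``. Radii must be assigned on both models.
    """
    target = homolog.find_residue(target_residue)
    if target is None:
        raise StructureError(f"target residue {target_residue} not found in the homolog")
    side_chain = target.side_chain_atoms()
    if not side_chain:
        raise StructureError(f"target residue {target_residue} has no side-chain atoms")

    partner_atoms = [
        (res, atom)
        for res in residues_in(complex_model, partner)
        if not res.is_water
        for atom in res.atoms
    ]
    clashes = []
    partner_res: set[ResidueKey] = set()
    for atom in side_chain:
        if atom.radius is None:
            raise StructureError("homolog radii not assigned; run assign_radii first")
        moved = alignment_sup.rotation @ atom.coords + alignment_sup.translation
        for res, patom in partner_atoms:
            if patom.radius is None:
                raise StructureError("complex radii not assigned; run assign_radii first")
            d = float(np.linalg.norm(moved - patom.coords))
            overlap = atom.radius + patom.radius - d
            if overlap > overlap_min:
                clashes.append((atom.name, f"{res.key}/{patom.name}", d, overlap))
                partner_res.add(res.key)
    return ClashReport(
        grafted_residue=target.key,
        clashes=clashes,
        count=len(clashes),
        max_overlap=max((c[3] for c in clashes), default=0.0),
        partner_residues=partner_res,
    )


# ---------------------------------------------------------------------------
# glycosylation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequonHit:
    position: int        # author numbering of the Asn
    triplet: str
    min_epitope_distance: float | None = None


def find_sequons(sequence: str, numbering_offset: int = 0) -> list[SequonHit]:
    """All N-X-[S/T] motifs (X != P), positions in author numbering."""
    seq = sequence.upper()
    hits = []
    for i in range(len(seq) - 2):
        if seq[i] == "N" and seq[i + 1] != "P" and seq[i + 2] in ("S", "T"):
            hits.append(SequonHit(position=i + 1 + numbering_offset, triplet=seq[i:i + 3]))
    return hits


def glyco_epitope_distance(
    model: StructureModel,
    glyco_positions: list[int],
    epitope: EpitopeSet,
    antigen: Selection | None = None,
    independence_threshold: float = 10.0,
) -> dict[int, dict]:
    """Distance from each glycosylation Asn side chain to the epitope.

    A site is flagged ``independent`` when its minimum heavy-atom distance to
    any epitope residue exceeds the threshold, or when it lies outside the
    crystallized construct altogether (reported ``present: False``).
    """
    antigen = antigen or Selection.by_role("antigen")
    antigen_residues = {r.key.seq_num: r for r in residues_in(model, antigen)}
    epitope_atoms = []
    for key in epitope.residues:
        res = model.find_residue(key)
        if res is not None:
            epitope_atoms.extend(a.coords for a in res.atoms)
    epitope_coords = np.array(epitope_atoms) if epitope_atoms else np.zeros((0, 3))

    out: dict[int, dict] = {}
    for pos in glyco_positions:
        res = antigen_residues.get(pos)
        if res is None:
            out[pos] = {"present": False, "independent": True, "min_distance_A": None}
            continue
        side = res.side_chain_atoms() or res.atoms
        coords = np.array([a.coords for a in side])
        if epitope_coords.size == 0:
            raise StructureError("epitope residues not resolvable in the model")
        dmin = float(
            np.min(np.linalg.norm(coords[:, None, :] - epitope_coords[None, :, :], axis=2))
        )
        out[pos] = {
            "present": True,
            "independent": dmin > independence_threshold,
            "min_distance_A": dmin,
        }
    return out
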