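"""Independent oracles used to validate the fast implementations.

Everything here is deliberately naive — quadratic scans, exponential
recursions, dense surface sampling — so that agreement with the optimized
code paths is meaningful evidence, not a tautology.
"""

from __future__ import annotations

import numpy as np

from .geometry import sphere_lattice
from .model import StructureModel

__all__ = [
    "brute_force_pairs",
    "sampled_two_sphere_area",
    "exhaustive_alignment_score",
]


def brute_force_pairs(model: StructureModel, cutoff: float) -> set[tuple]:
    """All-pairs O(n^2) neighbor search over the full distance matrix."""
    keys = [(res.key, atom.name) for res, atom in model.atoms()]
    coords = model.coords_array()
    if len(keys) < 2:
        return set()
    dist = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    out = set()
    for i, j in zip(*np.nonzero(np.triu(dist <= cutoff, k=1))):
        key_i, key_j = keys[i], keys[j]
        out.add((min(key_i, key_j), max(key_i, key_j)))
    return out


def sampled_two_sphere_area(
    r1: float, r2: float, d: float, probe: float = 1.4, n_points: int = 100_000
) -> tuple[float, float]:
    """Two-sphere SASA by dense deterministic surface sampling (no cap formula)."""
    R1, R2 = r1 + probe, r2 + probe
    c1 = np.array([0.0, 0.0, 0.0])
    c2 = np.array([d, 0.0, 0.0])
    lattice = sphere_lattice(n_points)

    def _area(center, R, other_center, other_R):
        pts = center + R * lattice
        keep = np.sum((pts - other_center) ** 2, axis=1) >= other_R**2
        return keep.sum() / n_points * 4.0 * np.pi * R**2

    return _area(c1, R1, c2, R2), _area(c2, R2, c1, R1)


def exhaustive_alignment_score(
    a: str, b: str, match: float = 1.0, mismatch: float = -1.0, gap: float = -2.0
) -> float:
    """Optimal global alignment score by plain exponential recursion.

    No memoization — the full alignment tree is explored, so this is an
    independent check of the dynamic program for short sequences only.
    """

    def rec(i: int, j: int) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            options.append(s + rec(i + 1, j + 1))
        if i < len(a):
            options.append(gap + rec(i + 1, j))
        if j < len(b):
            options.append(gap + rec(i, j + 1))
        return max(options)

    return rec(0, 0)
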