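"""Independent oracles used by the test suite and the acceptance script.

These deliberately avoid the code paths they check: the alignment oracle is a
three-state affine dynamic program written directly from the recurrences, and
the ion-pair/disulfide oracles are unaccelerated all-pairs scans over the raw
atom lists.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

NEG_INF = float("-inf")


def dp_align_score(a: str, b: str, gap_open: float = 10.0, gap_extend: float = 0.5) -> float:
    """Optimal global affine-gap alignment score (gap of length L costs
    open + (L-1)*extend), computed with an explicit three-state DP."""
    n, m = len(a), len(b)
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    Iy = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        Ix[i][0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Iy[0][j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = float(_BLOSUM62[a[i - 1], b[j - 1]])
            M[i][j] = s + max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            Ix[i][j] = max(M[i - 1][j] - gap_open,
                           Ix[i - 1][j] - gap_extend,
                           Iy[i - 1][j] - gap_open)
            Iy[i][j] = max(M[i][j - 1] - gap_open,
                           Iy[i][j - 1] - gap_extend,
                           Ix[i][j - 1] - gap_open)
    return max(M[n][m], Ix[n][m], Iy[n][m])


def brute_force_ion_pairs(model, cutoff: float = 3.2, include_his: bool = False):
    """All-pairs residue-level ion-pair scan; returns {(refA, refB): min_dist}
    keyed by unordered (sorted) residue-ref pairs."""
    from lyase_profile.bridge_analysis import ACIDIC_ATOMS, BASIC_ATOMS, HIS_ATOMS

    basic_table = dict(BASIC_ATOMS)
    if include_his:
        basic_table.update(HIS_ATOMS)
    acid, base = [], []
    for res in model.iter_residues():
        if res.name in ACIDIC_ATOMS:
            for a in res.atoms:
                if a.name in ACIDIC_ATOMS[res.name]:
                    acid.append((res.ref, a.position))
        if res.name in basic_table:
            for a in res.atoms:
                if a.name in basic_table[res.name]:
                    base.append((res.ref, a.position))
    found = {}
    for ra, pa in acid:
        for rb, pb in base:
            d = float(np.linalg.norm(pa - pb))
            if d <= cutoff:
                key = tuple(sorted(
                    [(ra.chain_id, ra.residue_number, ra.insertion_code),
                     (rb.chain_id, rb.residue_number, rb.insertion_code)]))
                found[key] = min(d, found.get(key, np.inf))
    return found


def brute_force_disulfides(model, cutoff: float = 6.0):
    """All-pairs Cys SG-SG scan (strict < cutoff)."""
    thiols = []
    for res in model.iter_residues():
        if res.name == "CYS":
            atom = res.atom("SG") or res.atom("CB")
            if atom is not None:
                thiols.append((res.ref, atom.position))
    found = {}
    for (ra, pa), (rb, pb) in combinations(thiols, 2):
        d = float(np.linalg.norm(pa - pb))
        if d < cutoff:
            key = tuple(sorted(
                [(ra.chain_id, ra.residue_number, ra.insertion_code),
                 (rb.chain_id, rb.residue_number, rb.insertion_code)]))
            found[key] = d
    return found


def pair_key_set(pairs):
    """Normalise detected IonPair/DisulfidePair lists to unordered key sets."""
    keys = set()
    for p in pairs:
        refs = (p.acidic, p.basic) if hasattr(p, "acidic") else (p.cys_a, p.cys_b)
        keys.add(tuple(sorted(
            [(r.chain_id, r.residue_number, r.insertion_code) for r in refs])))
    return keys


def spherical_cap_sasa(r1: float, r2: float, d: float) -> float:
    """Closed-form accessible area of sphere 1 partially occluded by sphere 2.

    ``r1``/``r2`` are probe-expanded radii and ``d`` the centre distance,
    with |r1 - r2| < d < r1 + r2.
    """
    x = (d * d + r1 * r1 - r2 * r2) / (2.0 * d)
    cap_height = r1 - x
    return 4.0 * np.pi * r1 * r1 - 2.0 * np.pi * r1 * cap_height
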