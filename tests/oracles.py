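"""Independent brute-force oracles used to validate the fast implementations.

These deliberately avoid the algorithms they check: alignment scores come
from exhaustive enumeration of all global alignments (no dynamic
programming), optimal rotations from a dense SO(3) grid search with local
refinement (no SVD), and permutation-test p-values from exhaustive subset
enumeration.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from Bio.Align import substitution_matrices
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def brute_force_alignment_score(seq_a: str, seq_b: str,
                                matrix: str = "BLOSUM62",
                                gap_open: float = 10.0,
                                gap_extend: float = 0.5) -> float:
    """Best global alignment score by enumerating every alignment.

    A gap of length L costs gap_open + L*gap_extend.  Exponential in the
    sequence lengths; intended for sequences of length <= 8.
    """
    sub = substitution_matrices.load(matrix)
    first = gap_open + gap_extend
    n, m = len(seq_a), len(seq_b)

    def recurse(i: int, j: int, prev: str) -> float:
        if i == n and j == m:
            return 0.0
        best = -math.inf
        if i < n and j < m:
            best = max(best, sub[seq_a[i], seq_b[j]]
                       + recurse(i + 1, j + 1, "M"))
        if i < n:  # seq_a residue against a gap
            cost = gap_extend if prev == "B" else first
            best = max(best, -cost + recurse(i + 1, j, "B"))
        if j < m:  # seq_b residue against a gap
            cost = gap_extend if prev == "A" else first
            best = max(best, -cost + recurse(i, j + 1, "A"))
        return best

    return recurse(0, 0, "M")


def grid_search_rmsd(coords_a: np.ndarray, coords_b: np.ndarray,
                     coarse_step_deg: float = 12.0) -> float:
    """Minimum RMSD over rigid motions by rotation grid search + refinement.

    Centers both sets, scans Euler angles on a coarse grid, then polishes
    the best candidates with Nelder-Mead on the rotation vector.  No
    closed-form superposition is used.
    """
    a = np.asarray(coords_a, float)
    b = np.asarray(coords_b, float)
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)

    def rmsd_of(rotvec):
        rot = Rotation.from_rotvec(rotvec).as_matrix()
        return float(np.sqrt(np.mean(np.sum((a0 @ rot.T - b0) ** 2, axis=1))))

    grid = np.deg2rad(np.arange(0.0, 360.0, coarse_step_deg))
    half = np.deg2rad(np.arange(-90.0, 90.1, coarse_step_deg))
    candidates = []
    for ex in half:
        for ey in half:
            for ez in grid:
                rv = Rotation.from_euler("xyz", [ex, ey, ez]).as_rotvec()
                candidates.append((rmsd_of(rv), tuple(rv)))
    candidates.sort(key=lambda t: t[0])
    best = candidates[0][0]
    for _, rv in candidates[:5]:
        res = minimize(rmsd_of, np.array(rv), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12,
                                "maxiter": 5000})
        best = min(best, float(res.fun))
    return best


def exhaustive_patch_p(model, residue_set, statistic) -> float:
    """Exact permutation p-value by enumerating all same-size subsets.

    ``statistic(model, subset)`` must be the same function the permutation
    test uses.  p = #{subsets with stat <= observed} / #subsets.
    """
    residues = model.residue_numbers()
    k = len(set(residue_set))
    observed = statistic(model, sorted(set(residue_set)))
    hits = total = 0
    for subset in itertools.combinations(residues, k):
        total += 1
        if statistic(model, subset) <= observed + 1e-12:
            hits += 1
    return hits / total
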