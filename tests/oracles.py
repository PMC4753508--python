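"""Independent brute-force oracles used by the tests.

These stay deliberately naive: exhaustive recursion over every global
alignment, and literal permutation enumeration for the rank-sum test.
They are never imported by the package.
"""

from __future__ import annotations

import itertools
from math import inf

import numpy as np
from Bio.Align import substitution_matrices
from scipy import stats

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def exhaustive_alignment_score(
    a: str, b: str, gap_open: float = 10.0, gap_extend: float = 0.5
) -> float:
    """Best global alignment score by enumerating every alignment path.

    Affine gaps: a gap of length L costs gap_open + gap_extend*(L-1).
    Exponential — only for sequences of length <= 8.
    """

    def rec(i: int, j: int, prev: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        best = -inf
        if i < len(a) and j < len(b):
            best = max(best, _BLOSUM62[a[i], b[j]] + rec(i + 1, j + 1, "D"))
        if i < len(a):
            cost = gap_extend if prev == "U" else gap_open
            best = max(best, -cost + rec(i + 1, j, "U"))
        if j < len(b):
            cost = gap_extend if prev == "L" else gap_open
            best = max(best, -cost + rec(i, j + 1, "L"))
        return best

    return rec(0, 0, "")


def permutation_rank_sum_p(x, y) -> float:
    """Two-sided rank-sum p by literal enumeration of group assignments."""
    x = list(x)
    y = list(y)
    pooled = np.asarray(x + y, dtype=float)
    ranks = stats.rankdata(pooled)
    n = len(x)
    w_obs = ranks[:n].sum()
    n_le = n_ge = total = 0
    for subset in itertools.combinations(range(len(pooled)), n):
        w = ranks[list(subset)].sum()
        total += 1
        if w <= w_obs + 1e-12:
            n_le += 1
        if w >= w_obs - 1e-12:
            n_ge += 1
    return min(1.0, 2.0 * min(n_le, n_ge) / total)
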