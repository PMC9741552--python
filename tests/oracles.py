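"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths (and, where feasible, the
libraries) they are used to check.
"""

from __future__ import annotations

import math
from functools import lru_cache

from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def fisher_p_bruteforce(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact hypergeometric enumeration with integer
    binomials (math.comb)."""
    n = a + b + c + d
    r, m = a + b, a + c
    denom = math.comb(n, m)
    k_min, k_max = max(0, r + m - n), min(r, m)
    probs = {
        k: math.comb(r, k) * math.comb(n - r, m - k) / denom
        for k in range(k_min, k_max + 1)
    }
    p_obs = probs[a]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-7)))


def global_affine_score(
    seq_a: str,
    seq_b: str,
    open_pen: float = 10.0,
    extend_pen: float = 1.0,
) -> float:
    """Optimal global alignment score with affine gaps, by exhaustive
    memoized recursion over (position, position, previous move).

    Gap cost for a run of length L is open_pen + (L - 1) * extend_pen,
    matching an aligner parameterised with open = -open_pen and
    extend = -extend_pen applied per gap column (first column charged the
    open score)."""

    @lru_cache(maxsize=None)
    def best(i: int, j: int, prev: str) -> float:
        if i == len(seq_a) and j == len(seq_b):
            return 0.0
        options = []
        if i < len(seq_a) and j < len(seq_b):
            s = float(_BLOSUM62[seq_a[i]][seq_b[j]])
            options.append(s + best(i + 1, j + 1, "M"))
        if i < len(seq_a):  # seq_a residue against a gap
            cost = extend_pen if prev == "A" else open_pen
            options.append(-cost + best(i + 1, j, "A"))
        if j < len(seq_b):
            cost = extend_pen if prev == "B" else open_pen
            options.append(-cost + best(i, j + 1, "B"))
        return max(options)

    return best(0, 0, "M")


def enumerate_alignment_scores(seq_a: str, seq_b: str, open_pen=10.0, extend_pen=1.0):
    """Literal enumeration of every global alignment (for tiny sequences),
    yielding each alignment's affine-gap score.  Used to validate the
    memoized oracle itself."""
    results = []

    def rec(i, j, cols):
        if i == len(seq_a) and j == len(seq_b):
            score = 0.0
            prev = None
            for x, y in cols:
                if x == "-" or y == "-":
                    kind = "A" if y == "-" else "B"
                    score -= extend_pen if prev == kind else open_pen
                    prev = kind
                else:
                    score += float(_BLOSUM62[x][y])
                    prev = "M"
            results.append(score)
            return
        if i < len(seq_a) and j < len(seq_b):
            rec(i + 1, j + 1, cols + [(seq_a[i], seq_b[j])])
        if i < len(seq_a):
            rec(i + 1, j, cols + [(seq_a[i], "-")])
        if j < len(seq_b):
            rec(i, j + 1, cols + [("-", seq_b[j])])

    rec(0, 0, [])
    return results


def tryptic_peptides_bruteforce(protein: str, max_missed: int, min_len: int):
    """Digest by enumerating every (start, end) substring and checking the
    tryptic-boundary and missed-cleavage conditions directly."""
    def is_site(i):  # cleavage after position i (0-based)
        return protein[i] in "KR" and (i + 1 >= len(protein) or protein[i + 1] != "P")

    out = set()
    n = len(protein)
    for s in range(n):
        for e in range(s + 1, n + 1):
            if e - s < min_len:
                continue
            left_ok = s == 0 or is_site(s - 1)
            right_ok = e == n or is_site(e - 1)
            internal = sum(1 for i in range(s, e - 1) if is_site(i))
            if left_ok and right_ok and internal <= max_missed:
                out.add(protein[s:e])
    return out
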