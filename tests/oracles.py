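"""Independent reference implementations used only to check famvote.

These deliberately re-derive results from first principles (plain
Python recursion/enumeration) and never call the code paths they
verify.
"""

from __future__ import annotations

import itertools


def local_affine_score_dp(
    a: str, b: str, score: dict, gap_open: int, gap_extend: int
) -> int:
    """Optimal local affine-gap score by a plain three-state Gotoh DP.

    A gap of length L costs gap_open + L * gap_extend.
    """
    NEG = -(10**9)
    n, m = len(a), len(b)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(
                H[i][j - 1] - gap_open - gap_extend, E[i][j - 1] - gap_extend
            )
            F[i][j] = max(
                H[i - 1][j] - gap_open - gap_extend, F[i - 1][j] - gap_extend
            )
            diag = max(H[i - 1][j - 1], E[i - 1][j - 1], F[i - 1][j - 1])
            H[i][j] = max(0, diag + score[(a[i - 1], b[j - 1])])
            best = max(best, H[i][j], E[i][j], F[i][j])
    return best


def local_affine_score_enum(
    a: str, b: str, score: dict, gap_open: int, gap_extend: int
) -> int:
    """Exhaustive enumeration of every local alignment path (tiny inputs).

    Every alignment is a start cell plus a sequence of moves in
    {match, gap-in-a, gap-in-b}; affine costs depend on the previous
    move.  Exponential: use only for len <= 6.
    """
    n, m = len(a), len(b)
    best = 0

    def extend(i: int, j: int, acc: int, last: str) -> None:
        nonlocal best
        best = max(best, acc)
        if i < n and j < m:
            extend(i + 1, j + 1, acc + score[(a[i], b[j])], "M")
        if j < m:
            cost = gap_extend if last == "E" else gap_open + gap_extend
            extend(i, j + 1, acc - cost, "E")
        if i < n:
            cost = gap_extend if last == "F" else gap_open + gap_extend
            extend(i + 1, j, acc - cost, "F")

    for i in range(n):
        for j in range(m):
            extend(i + 1, j + 1, score[(a[i], b[j])], "M")
    return best


def profile_best_window_score(log_odds, residue_indices) -> float:
    """Brute-force best placement of an ungapped profile along a sequence."""
    W = len(log_odds)
    L = len(residue_indices)
    best = None
    if L >= W:
        for start in range(L - W + 1):
            s = sum(
                log_odds[i][residue_indices[start + i]] for i in range(W)
            )
            best = s if best is None else max(best, s)
    else:
        for offset in range(W - L + 1):
            s = sum(
                log_odds[offset + i][residue_indices[i]] for i in range(L)
            )
            best = s if best is None else max(best, s)
    return best


def majority_probability_enum(p1: float, p2: float, p3: float) -> float:
    """P(>= 2 of 3 independent Bernoulli fire) by enumerating outcomes."""
    total = 0.0
    for o1, o2, o3 in itertools.product((0, 1), repeat=3):
        if o1 + o2 + o3 >= 2:
            pr = 1.0
            for o, p in ((o1, p1), (o2, p2), (o3, p3)):
                pr *= p if o else (1.0 - p)
            total += pr
    return total


def auc_concordance(scores, labels) -> float:
    """Mann-Whitney AUC: concordant pairs / (n_pos * n_neg), ties 0.5."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    num = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                num += 1.0
            elif sp == sn:
                num += 0.5
    return num / (len(pos) * len(neg))
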