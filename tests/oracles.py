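"""Independent reference implementations used only to check the package.

Each oracle recomputes a quantity by direct definition (exhaustive
enumeration, closed forms, hand arithmetic) without sharing code with the
implementation under test.
"""

from __future__ import annotations

import itertools
from functools import lru_cache
from math import comb, inf

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def local_alignment_score_enumerated(
    a: str, b: str, open_cost: float = 11.0, extend_cost: float = 1.0
) -> float:
    """Best local-alignment score by enumerating every pair of substrings
    and every alignment path between them (affine gaps: a length-L gap
    costs open + (L-1)*extend).  Feasible for sequences of length <= 6."""
    best = 0.0
    for i0, i1 in itertools.combinations(range(len(a) + 1), 2):
        for j0, j1 in itertools.combinations(range(len(b) + 1), 2):
            best = max(best, _align_exhaustive(a[i0:i1], b[j0:j1], open_cost, extend_cost))
    return best


def _align_exhaustive(a: str, b: str, open_cost: float, extend_cost: float) -> float:
    @lru_cache(maxsize=None)
    def rec(i: int, j: int, state: int) -> float:
        # state: 0 = last move was a match, 1 = gap in b, 2 = gap in a
        if i == len(a) and j == len(b):
            return 0.0
        best = -inf
        if i < len(a) and j < len(b):
            best = max(best, _BLOSUM62[a[i], b[j]] + rec(i + 1, j + 1, 0))
        if i < len(a):
            best = max(best, -(extend_cost if state == 1 else open_cost) + rec(i + 1, j, 1))
        if j < len(b):
            best = max(best, -(extend_cost if state == 2 else open_cost) + rec(i, j + 1, 2))
        return best

    return rec(0, 0, 0)


def auc_pairwise(scores, y) -> float:
    """AUC as the probability a random positive outranks a random negative,
    ties counting one half."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    pos = scores[y == 1]
    neg = scores[y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def mcc_pearson(tp: int, tn: int, fp: int, fn: int) -> float:
    """MCC as the Pearson correlation of +/-1-encoded true and predicted
    labels reconstructed from a confusion table."""
    y_true = [1] * tp + [1] * fn + [0] * tn + [0] * fp
    y_pred = [1] * tp + [0] * fn + [0] * tn + [1] * fp
    t = np.asarray(y_true) * 2 - 1
    p = np.asarray(y_pred) * 2 - 1
    if t.std() == 0 or p.std() == 0:
        return 0.0
    return float(np.corrcoef(t, p)[0, 1])


def hypergeom_tail(a: int, n_cand: int, n_term: int, n_bg: int) -> float:
    """P(X >= a) where X ~ Hypergeometric(N=n_bg, K=n_term, n=n_cand):
    the one-sided Fisher overrepresentation p-value by tail summation."""
    total = 0.0
    for k in range(a, min(n_cand, n_term) + 1):
        total += comb(n_term, k) * comb(n_bg - n_term, n_cand - k)
    return total / comb(n_bg, n_cand)


def mannwhitney_exact_enumeration(x, y) -> tuple[float, float]:
    """Two-sided exact Mann-Whitney p by enumerating all assignments of the
    pooled ranks (no ties allowed)."""
    x = list(x)
    y = list(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "enumeration oracle assumes no ties"

    def u_stat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b)

    u_obs = u_stat(x, y)
    n, m = len(x), len(y)
    mean_u = n * m / 2.0
    count = 0
    total = 0
    for combo in itertools.combinations(range(n + m), n):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(n + m) if i not in combo]
        u = u_stat(xs, ys)
        total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u):
            count += 1
    return float(u_obs), count / total
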