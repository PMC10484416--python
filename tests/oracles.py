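"""Brute-force reference implementations used only to verify the package.

Each oracle is deliberately written from first principles (enumeration or
the textbook definition), independent of the code paths it checks, and is
only feasible at tiny problem sizes.
"""

import itertools
import math

import numpy as np


def exact_wilcoxon_p(x, y):
    """Two-sided rank-sum p by exhaustive enumeration of group assignments.

    Assumes no ties across the pooled sample. p = P(|U - mu| >= |u_obs - mu|)
    under uniform reassignment of the pooled values to the two groups.
    """
    pooled = list(x) + list(y)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    n1 = len(x)
    ranks = {v: r + 1 for r, v in enumerate(sorted(pooled))}

    def u_of(group):
        r1 = sum(ranks[v] for v in group)
        return r1 - n1 * (n1 + 1) / 2

    mu = n1 * len(y) / 2
    u_obs = u_of(x)
    hits = total = 0
    for combo in itertools.combinations(pooled, n1):
        total += 1
        if abs(u_of(combo) - mu) >= abs(u_obs - mu) - 1e-9:
            hits += 1
    return hits / total


def bh_stepup(pvals):
    """Benjamini-Hochberg by the step-up definition: adj_i = min over j>=i
    of p_(j) * n / j, computed without vectorized shortcuts."""
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    adjusted = [None] * n
    for pos, i in enumerate(order):
        candidates = [
            pvals[order[j]] * n / (j + 1) for j in range(pos, n)
        ]
        adjusted[i] = min(1.0, min(candidates))
    return adjusted


def fisher_one_sided_p(table, side="greater"):
    """One-sided Fisher p by enumerating all tables with fixed margins."""
    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d

    def prob(a_val):
        b_val, c_val = row1 - a_val, col1 - a_val
        d_val = n - row1 - c_val
        if min(b_val, c_val, d_val) < 0:
            return 0.0
        return (
            math.comb(row1, a_val)
            * math.comb(n - row1, c_val)
            / math.comb(n, col1)
        )

    values = range(0, min(row1, col1) + 1)
    if side == "greater":
        return sum(prob(v) for v in values if v >= a)
    return sum(prob(v) for v in values if v <= a)


def windowed_mean(matrix, half_window):
    """Truncated-window moving average along axis 0, by direct loops."""
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    out = np.empty_like(matrix)
    for i in range(n):
        lo = max(0, i - half_window)
        hi = min(n - 1, i + half_window)
        out[i] = matrix[lo : hi + 1].mean(axis=0)
    return out


def best_local_score(rna, dna, pairs, match=1.0, mismatch=-1.0,
                     gap_open=-2.0, gap_extend=-1.0):
    """Best local alignment score by enumerating every substring pair and
    globally aligning it; ``pairs`` is the set of matching (rna, dna) bases.

    Substitute alphabet trick: map each rna/dna base pair to equal symbols
    iff it is a triplex contact, by scoring via membership in ``pairs``.
    """
    best = 0.0
    # encode via a match table consulted inside the NW recursion
    for i1 in range(len(rna)):
        for i2 in range(i1 + 1, len(rna) + 1):
            sub_r = rna[i1:i2]
            for j1 in range(len(dna)):
                for j2 in range(j1 + 1, len(dna) + 1):
                    sub_d = dna[j1:j2]
                    score = _nw_pairs(sub_r, sub_d, pairs, match, mismatch,
                                      gap_open, gap_extend)
                    if score > best:
                        best = score
    return best


def _nw_pairs(a, b, pairs, match, mismatch, gap_open, gap_extend):
    NEG = float("-inf")
    n, m = len(a), len(b)
    H = [[NEG] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    H[0][0] = 0.0
    for j in range(1, m + 1):
        E[0][j] = max(H[0][j - 1] + gap_open, E[0][j - 1] + gap_extend)
        H[0][j] = E[0][j]
    for i in range(1, n + 1):
        F[i][0] = max(H[i - 1][0] + gap_open, F[i - 1][0] + gap_extend)
        H[i][0] = F[i][0]
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            s = match if (a[i - 1], b[j - 1]) in pairs else mismatch
            H[i][j] = max(H[i - 1][j - 1] + s, E[i][j], F[i][j])
    return H[n][m]
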