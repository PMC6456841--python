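"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code with the package: the rank-sum oracle
enumerates every group assignment, the BH oracle is the textbook step-up
formula, and the silhouette oracle evaluates the definition cell by cell.
"""

from itertools import combinations

import numpy as np


def exact_rank_sum_pvalue(a, b):
    """Two-sided exact Wilcoxon rank-sum p by exhaustive enumeration.

    Enumerates all C(nA+nB, nA) assignments of the pooled (tie-free) values
    to group A, computes the Mann-Whitney U for each, and doubles the
    smaller tail (capped at 1).
    """
    a = list(a)
    b = list(b)
    pooled = a + b
    n = len(pooled)
    nA = len(a)

    def u_stat(groupA, groupB):
        return sum(1 for x in groupA for y in groupB if x > y)

    u_obs = u_stat(a, b)
    us = []
    for idx in combinations(range(n), nA):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(n) if i not in idx]
        us.append(u_stat(ga, gb))
    us = np.array(us)
    total = len(us)
    p = 2 * min((us <= u_obs).sum(), (us >= u_obs).sum()) / total
    return min(1.0, p)


def bh_stepup(pvals):
    """Textbook Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adjusted[i] = running_min
    return np.minimum(adjusted, 1.0)


def brute_silhouette(coords, labels):
    """Silhouette widths straight from the definition, cell by cell."""
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    n = len(labels)
    widths = np.zeros(n)
    for i in range(n):
        same = [j for j in range(n) if j != i and labels[j] == labels[i]]
        if not same:
            continue  # singleton cluster
        a = np.mean([np.linalg.norm(coords[i] - coords[j]) for j in same])
        b = np.inf
        for other in set(labels) - {labels[i]}:
            members = [j for j in range(n) if labels[j] == other]
            b = min(
                b,
                np.mean([np.linalg.norm(coords[i] - coords[j]) for j in members]),
            )
        denom = max(a, b)
        widths[i] = 0.0 if denom == 0 else (b - a) / denom
    return widths
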