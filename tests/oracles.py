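"""Independent brute-force oracles used by the test suite.

These recompute quantities by direct enumeration / two-pass summation and
stay deliberately independent of the library's vectorised implementations.
"""

import numpy as np

from commtrees.tree import enumerate_level_sets


def two_pass_ss(rows: np.ndarray) -> float:
    """Within-node SS by explicit per-column two-pass summation."""
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    total = 0.0
    for j in range(rows.shape[1]):
        col = rows[:, j]
        mean = col.sum() / len(col)
        total += sum((x - mean) ** 2 for x in col)
    return total


def brute_force_best_split(Y, columns, min_node=1):
    """Exhaustive search over every variable, cutpoint and level-set.

    ``columns`` is a list of (name, kind, values, levels); ordered variables
    pass their integer level codes as values.  Returns (name, kind, payload,
    improvement) where payload is a threshold or a frozenset, or None.
    Tie-break: earlier variable, then smaller threshold / lexicographically
    smallest level-set.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != len(columns[0][2]):
        Y = Y.T
    parent = two_pass_ss(Y)
    best = None
    for name, kind, values, levels in columns:
        values = np.asarray(values)
        if kind in ("numeric", "ordered"):
            distinct = np.unique(values[~np.isnan(values.astype(float))])
            for lo, hi in zip(distinct[:-1], distinct[1:]):
                thr = 0.5 * (lo + hi)
                left = values <= thr
                if left.sum() < min_node or (~left).sum() < min_node:
                    continue
                imp = parent - two_pass_ss(Y[left]) - two_pass_ss(Y[~left])
                cand = (name, kind, float(thr), imp)
                best = _better(best, cand, columns)
        else:
            present = [l for l in levels if (values == l).any()]
            for subset in enumerate_level_sets(present):
                left = np.isin(values, list(subset))
                if left.sum() < min_node or (~left).sum() < min_node:
                    continue
                imp = parent - two_pass_ss(Y[left]) - two_pass_ss(Y[~left])
                cand = (name, kind, frozenset(subset), imp)
                best = _better(best, cand, columns)
    return best


def _better(best, cand, columns):
    if best is None:
        return cand
    order = {c[0]: i for i, c in enumerate(columns)}
    if cand[3] > best[3] + 1e-12:
        return cand
    if abs(cand[3] - best[3]) <= 1e-12:
        if order[cand[0]] < order[best[0]]:
            return cand
        if order[cand[0]] == order[best[0]]:
            if isinstance(cand[2], float) and cand[2] < best[2]:
                return cand
            if isinstance(cand[2], frozenset) and \
                    tuple(sorted(map(str, cand[2]))) < tuple(sorted(map(str, best[2]))):
                return cand
    return best


def contingency_ari(a, b) -> float:
    """Adjusted Rand Index from the contingency table, by the direct
    pair-counting formula."""
    a = np.asarray(a)
    b = np.asarray(b)
    ua, ub = np.unique(a), np.unique(b)
    table = np.array([[(np.logical_and(a == x, b == y)).sum() for y in ub]
                      for x in ua], dtype=float)

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(table).sum()
    sum_a = comb2(table.sum(axis=1)).sum()
    sum_b = comb2(table.sum(axis=0)).sum()
    n = comb2(len(a))
    expected = sum_a * sum_b / n
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))
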