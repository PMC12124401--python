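"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — exhaustive enumeration, set
intersections, dynamic programming over margins — and shares no code with
the package paths it checks.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np


def brute_force_co_engagement(membership: dict) -> dict:
    """Pairwise shared-user counts by explicit set intersection."""
    communities = sorted({c for cs in membership.values() for c in cs})
    users_of = {c: {u for u, cs in membership.items() if c in cs} for c in communities}
    out = {}
    for a, b in itertools.combinations(communities, 2):
        w = len(users_of[a] & users_of[b])
        if w:
            out[(a, b)] = w
    return out


def enumerate_fixed_margin_matrices(row_degrees, col_degrees):
    """All binary matrices with the given row and column sums (tiny inputs)."""
    row_degrees = list(row_degrees)
    col_degrees = list(col_degrees)
    n_cols = len(col_degrees)
    if sum(row_degrees) != sum(col_degrees):
        return []
    results = []

    def recurse(u, remaining, rows):
        if u == len(row_degrees):
            if all(r == 0 for r in remaining):
                results.append(np.array(rows, dtype=bool))
            return
        for cols in itertools.combinations(range(n_cols), row_degrees[u]):
            if all(remaining[c] > 0 for c in cols):
                new_remaining = list(remaining)
                for c in cols:
                    new_remaining[c] -= 1
                row = [c in cols for c in range(n_cols)]
                recurse(u + 1, tuple(new_remaining), rows + [row])

    recurse(0, tuple(col_degrees), [])
    return results


def exact_pair_expectations(row_degrees, col_degrees) -> np.ndarray:
    """E[W_ij] under the uniform fixed-margin ensemble, by margin DP.

    Returns a symmetric n_cols x n_cols matrix of expected shared-row
    counts for each column pair (diagonal unused). Exact for any instance
    whose margin state space fits in memory.
    """
    row_degrees = tuple(row_degrees)
    n_cols = len(col_degrees)
    col_subsets = {
        d: [frozenset(s) for s in itertools.combinations(range(n_cols), d)]
        for d in set(row_degrees)
    }

    @lru_cache(maxsize=None)
    def stats(u: int, remaining: tuple):
        """(#completions, flattened total pair-count over completions)."""
        if u == len(row_degrees):
            if all(r == 0 for r in remaining):
                return 1, tuple([0.0] * (n_cols * n_cols))
            return 0, tuple([0.0] * (n_cols * n_cols))
        total_count = 0
        total_pairs = np.zeros((n_cols, n_cols))
        for cols in col_subsets[row_degrees[u]]:
            if all(remaining[c] > 0 for c in cols):
                new_remaining = tuple(
                    r - 1 if c in cols else r for c, r in enumerate(remaining)
                )
                cnt, tp = stats(u + 1, new_remaining)
                if cnt == 0:
                    continue
                total_count += cnt
                total_pairs += np.array(tp).reshape(n_cols, n_cols)
                for i in cols:
                    for j in cols:
                        if i != j:
                            total_pairs[i, j] += cnt
        return total_count, tuple(total_pairs.ravel())

    count, pairs = stats(0, tuple(col_degrees))
    if count == 0:
        raise ValueError("no matrix satisfies the margins")
    return np.array(pairs).reshape(n_cols, n_cols) / count


def all_partitions(items):
    """Every partition of a list into non-empty blocks (Bell-number many)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in all_partitions(rest):
        for k in range(len(partition)):
            yield partition[:k] + [[first] + partition[k]] + partition[k + 1:]
        yield [[first]] + partition


def exact_null_precedence(uidx, lab, ts, n_users, tie_weight=0.5):
    """Exact E[P'] over all distinct label reassignments, plus feasibility.

    Enumerates every distinct assignment of the label multiset to event
    slots (uniform under the permutation null), drops assignments with no
    user holding both labels (matching the bootstrap's discard rule), and
    averages the per-assignment precedence probability.

    Returns (expected P', fraction of feasible assignments).
    """
    uidx = list(uidx)
    lab = list(lab)
    ts = list(ts)
    n_events = len(lab)
    n_ones = sum(lab)
    values, feasible, total = [], 0, 0
    for ones_at in itertools.combinations(range(n_events), n_ones):
        total += 1
        assign = [1 if k in ones_at else 0 for k in range(n_events)]
        first = {}
        for k in range(n_events):
            key = (uidx[k], assign[k])
            if key not in first or ts[k] < first[key]:
                first[key] = ts[k]
        scores = []
        for u in range(n_users):
            if (u, 0) in first and (u, 1) in first:
                fi, fj = first[(u, 0)], first[(u, 1)]
                scores.append(1.0 if fj > fi else (tie_weight if fj == fi else 0.0))
        if not scores:
            continue
        feasible += 1
        values.append(sum(scores) / len(scores))
    if not values:
        raise ValueError("no feasible assignment")
    return sum(values) / len(values), feasible / total
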