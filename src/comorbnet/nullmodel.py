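"""Degree-preserving bipartite null model and link significance.

The null ensemble holds both degree sequences of the binary incidence
fixed — each user keeps their number of distinct communities and each
community keeps its number of distinct users — and samples the space of
binary matrices with those margins via curveball trades. Averaging the
co-engagement counts over replicates gives the chance-expected weight
W~_ij; a link is significant when the observed weight exceeds it.

The trade kernel is numba-compiled over the dense boolean incidence with
an inline splitmix64 counter PRNG, so a replicate costs milliseconds even
on cohorts of thousands of users.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numba as nb
import numpy as np

from .bipartite import BipartiteIncidence, CoEngagementTable, pair_count_matrix


@nb.njit(inline="always", cache=True)
def _splitmix64(state):
    state = state + np.uint64(0x9E3779B97F4A7C15)
    z = state
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    z = z ^ (z >> np.uint64(31))
    return state, z


@nb.njit(cache=True)
def _curveball_trades(matrix, n_trades, seed):
    """In-place curveball trades on a boolean users x communities matrix.

    One trade picks two users and redistributes the communities held by
    exactly one of them, keeping each user's count — all row and column
    sums are invariant by construction.
    """
    n_users, n_comms = matrix.shape
    if n_users < 2:
        return
    state = np.uint64(seed)
    idx = np.empty(n_comms, np.int64)
    for _ in range(n_trades):
        state, z = _splitmix64(state)
        a = int(z % np.uint64(n_users))
        state, z = _splitmix64(state)
        b = int(z % np.uint64(n_users))
        if a == b:
            continue
        n_a_only = 0
        k = 0
        for c in range(n_comms):
            ma = matrix[a, c]
            mb = matrix[b, c]
            if ma and not mb:
                idx[k] = c
                k += 1
                n_a_only += 1
            elif mb and not ma:
                idx[k] = c
                k += 1
        if n_a_only == 0 or n_a_only == k:
            continue
        # Fisher-Yates over the exclusive communities
        for i in range(k - 1, 0, -1):
            state, z = _splitmix64(state)
            j = int(z % np.uint64(i + 1))
            tmp = idx[i]
            idx[i] = idx[j]
            idx[j] = tmp
        for i in range(k):
            c = idx[i]
            if i < n_a_only:
                matrix[a, c] = True
                matrix[b, c] = False
            else:
                matrix[a, c] = False
                matrix[b, c] = True


def default_n_trades(incidence: BipartiteIncidence) -> int:
    """5 x |edges| trades per replicate — comfortably past curveball mixing."""
    return 5 * incidence.n_edges


def shuffle_incidence(
    incidence: BipartiteIncidence, seed: int, n_trades: Optional[int] = None
) -> BipartiteIncidence:
    """One degree-preserving randomization of the incidence.

    Returns a fresh incidence with exactly the same user and community
    degree sequences, sampled approximately uniformly from the fixed-margin
    space; deterministic under ``seed``. Degree preservation is asserted on
    every call (a violation would be a hard implementation failure).
    """
    if n_trades is None:
        n_trades = default_n_trades(incidence)
    matrix = incidence.matrix.copy()
    _curveball_trades(matrix, int(n_trades), np.uint64(int(seed) % (1 << 64)))
    shuffled = BipartiteIncidence(incidence.users, incidence.communities, matrix)
    if not np.array_equal(shuffled.user_degree, incidence.user_degree) or not np.array_equal(
        shuffled.community_degree, incidence.community_degree
    ):
        raise AssertionError("curveball shuffle violated a degree sequence")
    return shuffled


@dataclass
class NullEnsemble:
    """Summary of co-engagement under the degree-preserving null.

    ``expected_weight`` maps each unordered pair that co-engaged in at
    least one replicate (or in the observed data) to the mean null weight
    W~_ij; ``exceedance_count`` counts replicates whose null weight was at
    least the observed weight; ``weight_se`` is the Monte-Carlo standard
    error of the mean.
    """

    n_replicates: int
    expected_weight: dict
    exceedance_count: dict
    weight_se: dict
    seed: int

    def __post_init__(self) -> None:
        for pair, c in self.exceedance_count.items():
            if not 0 <= c <= self.n_replicates:
                raise ValueError(f"exceedance count out of range for {pair}")
        if any(w < 0 for w in self.expected_weight.values()):
            raise ValueError("expected weights must be non-negative")


def expected_weights(
    incidence: BipartiteIncidence,
    n_replicates: int,
    seed: int,
    n_trades: Optional[int] = None,
) -> NullEnsemble:
    """Monte-Carlo expected co-engagement under the fixed-margin null.

    Each replicate starts fresh from the observed matrix, applies curveball
    trades, and recounts every pair's shared users; pairs never co-engaged
    in any replicate and absent from the observed table are omitted.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if n_trades is None:
        n_trades = default_n_trades(incidence)
    comms = incidence.communities
    n_c = len(comms)
    observed = pair_count_matrix(incidence)
    rep_seeds = np.random.SeedSequence(seed).generate_state(n_replicates, np.uint64)
    base = incidence.matrix
    work = base.copy()
    w_sum = np.zeros((n_c, n_c), dtype=np.int64)
    w_sumsq = np.zeros((n_c, n_c), dtype=np.int64)
    exceed = np.zeros((n_c, n_c), dtype=np.int64)
    for r in range(n_replicates):
        work[:] = base
        _curveball_trades(work, int(n_trades), rep_seeds[r])
        x = work.astype(np.int64)
        w_r = x.T @ x
        w_sum += w_r
        w_sumsq += w_r * w_r
        exceed += w_r >= observed
    expected, exceedance, se = {}, {}, {}
    for i in range(n_c):
        for j in range(i + 1, n_c):
            if w_sum[i, j] == 0 and observed[i, j] == 0:
                continue
            pair = (comms[i], comms[j])
            mean = w_sum[i, j] / n_replicates
            expected[pair] = mean
            exceedance[pair] = int(exceed[i, j])
            var = max(w_sumsq[i, j] / n_replicates - mean * mean, 0.0)
            se[pair] = float(np.sqrt(var / n_replicates))
    return NullEnsemble(
        n_replicates=n_replicates,
        expected_weight=expected,
        exceedance_count=exceedance,
        weight_se=se,
        seed=int(seed),
    )


class LinkRecord(NamedTuple):
    observed: int
    expected: float
    retained: bool
    empirical_p: float


@dataclass
class SignificantLinkTable:
    """Per-pair observed and expected weights with the retention verdict."""

    links: dict = field(default_factory=dict)

    def retained_pairs(self) -> list:
        return sorted(p for p, rec in self.links.items() if rec.retained)

    def __len__(self) -> int:
        return len(self.links)


def significant_links(
    observed: CoEngagementTable,
    ensemble: NullEnsemble,
    min_users: int = 5,
    p_threshold: Optional[float] = None,
) -> SignificantLinkTable:
    """Retain pairs whose observed co-engagement beats the null expectation.

    The retention rule is ``W_ij >= min_users`` and strictly
    ``W_ij > W~_ij``; when ``p_threshold`` is given, additionally
    ``empirical_p <= p_threshold`` with
    ``empirical_p = (exceedance + 1) / (n_replicates + 1)``. The empirical
    p-value is always reported.
    """
    if min_users < 1:
        raise ValueError("min_users must be >= 1")
    links = {}
    for pair, w in sorted(observed.weights.items()):
        if pair not in ensemble.expected_weight:
            raise ValueError(
                f"pair {pair} observed but absent from the null ensemble; "
                "was the ensemble built on the same incidence?"
            )
        expected = ensemble.expected_weight[pair]
        p = (ensemble.exceedance_count[pair] + 1) / (ensemble.n_replicates + 1)
        keep = w >= min_users and w > expected
        if p_threshold is not None:
            keep = keep and p <= p_threshold
        links[pair] = LinkRecord(observed=w, expected=expected, retained=keep, empirical_p=p)
    return SignificantLinkTable(links=links)
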