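"""User x community bipartite incidence and co-engagement counting.

The incidence is binary — a user either engaged a community at least once
or did not. Distinct-user counts, not instance counts, define the
co-engagement weight W_ij ("the number of users engaged in both"), so the
degree sequences of this binary relation are the invariant the null model
preserves. Instance counts matter only to the temporal statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import logger
from .io import CommunityCatalogue, as_event_frame


@dataclass
class BipartiteIncidence:
    """Binary engagement relation with both degree sequences.

    ``matrix`` is boolean, users x communities, with users and communities
    in lexicographic order for deterministic downstream behaviour.
    """

    users: list
    communities: list
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=bool)
        if self.matrix.shape != (len(self.users), len(self.communities)):
            raise ValueError("matrix shape does not match user/community lists")

    @property
    def user_degree(self) -> np.ndarray:
        return self.matrix.sum(axis=1)

    @property
    def community_degree(self) -> np.ndarray:
        return self.matrix.sum(axis=0)

    @property
    def n_edges(self) -> int:
        return int(self.matrix.sum())

    def community_index(self, token: str) -> int:
        return self.communities.index(token)

    @classmethod
    def from_membership(cls, membership: Mapping[str, Iterable[str]]) -> "BipartiteIncidence":
        """Build from an explicit user -> communities mapping (tests, oracles)."""
        users = sorted(membership)
        communities = sorted({c for cs in membership.values() for c in cs})
        cidx = {c: k for k, c in enumerate(communities)}
        matrix = np.zeros((len(users), len(communities)), dtype=bool)
        for ui, u in enumerate(users):
            for c in membership[u]:
                matrix[ui, cidx[c]] = True
        return cls(users, communities, matrix)


def build_incidence(
    events, catalogue: Optional[CommunityCatalogue] = None
) -> BipartiteIncidence:
    """Binary user x community incidence from an engagement log.

    Events in communities absent from the catalogue (when one is given)
    are dropped with a warning; zero retained events is fatal.
    """
    frame = as_event_frame(events)
    if catalogue is not None:
        allowed = set(catalogue.communities)
        keep = frame["community"].isin(allowed)
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.warning(
                "build_incidence: dropped %d events in communities outside the catalogue",
                n_dropped,
            )
        frame = frame.loc[keep]
    if frame.empty:
        raise ValueError("no events remain after catalogue filtering")
    users = sorted(frame["user_id"].unique())
    communities = sorted(frame["community"].unique())
    uidx = pd.Index(users)
    cidx = pd.Index(communities)
    matrix = np.zeros((len(users), len(communities)), dtype=bool)
    matrix[uidx.get_indexer(frame["user_id"]), cidx.get_indexer(frame["community"])] = True
    return BipartiteIncidence(users, communities, matrix)


@dataclass
class CoEngagementTable:
    """Symmetric pair counts W_ij of shared users, one entry per unordered pair."""

    weights: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        canonical = {}
        for (a, b), w in self.weights.items():
            if a == b:
                raise ValueError("self-pairs are not co-engagement")
            canonical[tuple(sorted((a, b)))] = int(w)
        self.weights = canonical

    def __getitem__(self, pair) -> int:
        return self.weights.get(tuple(sorted(pair)), 0)

    def __len__(self) -> int:
        return len(self.weights)

    def to_frame(self) -> pd.DataFrame:
        rows = [(a, b, w) for (a, b), w in sorted(self.weights.items())]
        return pd.DataFrame(rows, columns=["community_a", "community_b", "weight"])


def pair_count_matrix(incidence: BipartiteIncidence) -> np.ndarray:
    """Community x community shared-user counts (diagonal = degrees)."""
    m = incidence.matrix.astype(np.int64)
    return m.T @ m


def co_engagement(incidence: BipartiteIncidence) -> CoEngagementTable:
    """W_ij = number of distinct users engaged in both i and j.

    Pairs with zero shared users are omitted; each unordered pair is
    stored once under its lexicographically sorted key.
    """
    counts = pair_count_matrix(incidence)
    comms = incidence.communities
    weights = {}
    for i in range(len(comms)):
        for j in range(i + 1, len(comms)):
            if counts[i, j] > 0:
                weights[(comms[i], comms[j])] = int(counts[i, j])
    return CoEngagementTable(weights)


def rank_co_engaged(
    incidence: BipartiteIncidence, focal: Iterable[str], k: int
) -> list:
    """Top-k communities by users shared with the pooled focal communities.

    For each non-focal community the count is the number of distinct users
    engaged both there and in the union of the focal communities (users of
    all focal communities are pooled). Descending count, lexicographic
    tie-break; if fewer than ``k`` candidates exist the full list returns.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    focal = set(focal)
    missing = focal - set(incidence.communities)
    if missing:
        raise ValueError(f"focal communities not in incidence: {sorted(missing)}")
    fidx = [incidence.community_index(c) for c in sorted(focal)]
    focal_users = incidence.matrix[:, fidx].any(axis=1)
    scores = []
    for ci, c in enumerate(incidence.communities):
        if c in focal:
            continue
        shared = int((incidence.matrix[:, ci] & focal_users).sum())
        scores.append((c, shared))
    scores.sort(key=lambda t: (-t[1], t[0]))
    return scores[:k]
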