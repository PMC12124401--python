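"""Synthetic engagement cohorts with planted comorbidity and precursor structure.

The generator emulates the statistical structure the analysis assumes in
real community logs:

* a user population whose community memberships are independent Bernoulli
  draws with per-community baseline popularity;
* planted comorbid pairs whose joint membership follows the exact 2x2
  distribution with the configured marginals and odds ratio;
* heavy-tailed per-user activity driving the number of engagement
  instances per membership;
* instance timestamps i.i.d. uniform on the observation window, except
  that for planted precursor pairs a configurable fraction of co-engaged
  users have their first early-community engagement moved strictly before
  their first focal engagement, with an exponential lag;
* everything deterministic under a master seed, with per-user counter
  substreams so growing the population never perturbs earlier users.

Membership probability deliberately depends on the community alone (user
activity only scales instance counts): conditional on both degree
sequences the incidence is then uniform over the fixed-margin space, which
is exactly the ensemble the degree-preserving null samples.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import EventLog


@dataclass(frozen=True)
class GroundTruth:
    """The planted structure of a synthetic cohort."""

    planted_links: frozenset  # unordered community pairs, stored sorted
    planted_precursors: frozenset  # ordered (early, focal) pairs

    def to_dict(self) -> dict:
        return {
            "planted_links": sorted(list(p) for p in self.planted_links),
            "planted_precursors": sorted(list(p) for p in self.planted_precursors),
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def read_json(cls, path: str | Path) -> "GroundTruth":
        data = json.loads(Path(path).read_text())
        return cls(
            planted_links=frozenset(tuple(sorted(p)) for p in data["planted_links"]),
            planted_precursors=frozenset(tuple(p) for p in data["planted_precursors"]),
        )


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic cohort.

    ``baseline_popularity`` is either one probability shared by all
    communities or a per-community mapping. ``comorbid_pairs`` are
    ``(community_a, community_b, odds_multiplier)`` with multiplier >= 1;
    pairs must not share communities so the 2x2 construction stays exact.
    ``precursor_pairs`` are ``(early, focal, lag_mean_seconds, adherence)``.
    """

    n_users: int
    communities: Sequence[str]
    baseline_popularity: float | Mapping[str, float] = 0.15
    activity_shape: float = 2.2
    max_activity: int = 20
    comorbid_pairs: Sequence[tuple] = field(default_factory=list)
    precursor_pairs: Sequence[tuple] = field(default_factory=list)
    window: tuple = (1_300_000_000, 1_700_000_000)
    instances_per_membership: float = 3.0
    seed: int = 0

    def popularity(self, community: str) -> float:
        if isinstance(self.baseline_popularity, Mapping):
            return float(self.baseline_popularity[community])
        return float(self.baseline_popularity)

    def validate(self) -> None:
        if self.n_users < 0:
            raise ValueError("n_users must be non-negative")
        if len(set(self.communities)) != len(self.communities):
            raise ValueError("community tokens must be unique")
        t0, t1 = self.window
        if not (0 <= t0 < t1):
            raise ValueError("window must satisfy 0 <= t_start < t_end")
        if self.instances_per_membership < 1:
            raise ValueError("instances_per_membership must be >= 1")
        if self.activity_shape <= 0 or self.max_activity < 1:
            raise ValueError("activity_shape must be > 0 and max_activity >= 1")
        cset = set(self.communities)
        seen = set()
        for a, b, m in self.comorbid_pairs:
            if a not in cset or b not in cset:
                raise ValueError(f"comorbid pair ({a}, {b}) names unknown community")
            if m < 1:
                raise ValueError("odds_multiplier must be >= 1")
            if a in seen or b in seen or a == b:
                raise ValueError("comorbid pairs must be disjoint in communities")
            seen |= {a, b}
        for early, focal, lag, adh in self.precursor_pairs:
            if early not in cset or focal not in cset:
                raise ValueError(f"precursor pair ({early}, {focal}) names unknown community")
            if lag <= 0:
                raise ValueError("lag_mean_seconds must be > 0")
            if not 0 < adh <= 1:
                raise ValueError("adherence must lie in (0, 1]")
        for c in self.communities:
            p = self.popularity(c)
            if not 0 < p < 1:
                raise ValueError(f"baseline popularity of {c} must lie in (0, 1)")

    def ground_truth(self) -> GroundTruth:
        return GroundTruth(
            planted_links=frozenset(tuple(sorted((a, b))) for a, b, _ in self.comorbid_pairs),
            planted_precursors=frozenset((e, f) for e, f, _, _ in self.precursor_pairs),
        )


def joint_cell_probability(p_a: float, p_b: float, odds_ratio: float) -> float:
    """Joint membership probability of a 2x2 table with given marginals and OR.

    Solves the quadratic in the (1,1) cell; the root inside
    [max(0, p_a + p_b - 1), min(p_a, p_b)] is unique for odds_ratio > 0.
    """
    if abs(odds_ratio - 1.0) < 1e-12:
        return p_a * p_b
    m = odds_ratio
    s = 1.0 + (p_a + p_b) * (m - 1.0)
    disc = s * s - 4.0 * m * (m - 1.0) * p_a * p_b
    p11 = (s - math.sqrt(disc)) / (2.0 * (m - 1.0))
    lo, hi = max(0.0, p_a + p_b - 1.0), min(p_a, p_b)
    return min(max(p11, lo), hi)


def _activity_distribution(shape: float, max_activity: int) -> tuple:
    k = np.arange(1, max_activity + 1, dtype=float)
    w = k ** (-shape)
    p = w / w.sum()
    return k.astype(np.int64), p, float((k * p).sum())


def _user_rng(seed: int, user_index: int) -> np.random.Generator:
    # Counter-based substream: user u owns the counter block u << 192.
    return np.random.Generator(
        np.random.Philox(counter=user_index << 192, key=seed & ((1 << 128) - 1))
    )


def generate_cohort(config: SyntheticConfig) -> tuple[EventLog, GroundTruth]:
    """Generate an engagement log with the configured planted structure.

    Memberships first (independent Bernoulli, then each comorbid pair's two
    communities redrawn jointly from the exact odds-ratio 2x2 table), then
    per-membership instance counts (1 + Poisson scaled by the user's
    heavy-tailed activity), then uniform timestamps, then the precursor
    shift: for an adherent co-engaged user every early-community instance
    is translated so the earliest lands ``gap ~ 1 + Exp(lag_mean)`` seconds
    before the first focal instance.
    """
    config.validate()
    communities = list(config.communities)
    c_index = {c: k for k, c in enumerate(communities)}
    pops = np.array([config.popularity(c) for c in communities])
    act_vals, act_probs, act_mean = _activity_distribution(
        config.activity_shape, config.max_activity
    )
    pair_cells = [
        (c_index[a], c_index[b], _cell_probs(config.popularity(a), config.popularity(b), m))
        for a, b, m in config.comorbid_pairs
    ]
    t0, t1 = config.window
    extra_mean = config.instances_per_membership - 1.0

    users, comms, times = [], [], []
    for u in range(config.n_users):
        rng = _user_rng(config.seed, u)
        member = rng.random(len(communities)) < pops
        for ia, ib, cells in pair_cells:
            r = rng.random()
            member[ia] = r < cells[0] + cells[1]
            member[ib] = r < cells[0] or cells[0] + cells[1] <= r < cells[0] + cells[1] + cells[2]
        activity = act_vals[rng.choice(len(act_vals), p=act_probs)]
        mu = extra_mean * activity / act_mean
        member_idx = np.flatnonzero(member)
        inst: dict[int, np.ndarray] = {}
        for ci in member_idx:
            n_inst = 1 + (rng.poisson(mu) if mu > 0 else 0)
            inst[ci] = rng.integers(t0, t1, size=n_inst)
        for early, focal, lag_mean, adherence in config.precursor_pairs:
            ie, if_ = c_index[early], c_index[focal]
            if ie in inst and if_ in inst:
                if rng.random() < adherence:
                    gap = 1 + int(rng.exponential(lag_mean))
                    min_focal = int(inst[if_].min())
                    target = max(min_focal - gap, 0)
                    inst[ie] = inst[ie] + (target - int(inst[ie].min()))
        uid = f"u{u:06d}"
        for ci in member_idx:
            for t in inst[ci]:
                users.append(uid)
                comms.append(communities[ci])
                times.append(int(t))

    frame = pd.DataFrame(
        {"user_id": users, "community": comms, "timestamp": times, "event_kind": "post"}
    )
    return EventLog(frame), config.ground_truth()


def _cell_probs(p_a: float, p_b: float, odds_ratio: float) -> tuple:
    """(p11, p10, p01, p00) of the planted 2x2 membership table."""
    p11 = joint_cell_probability(p_a, p_b, odds_ratio)
    return (p11, p_a - p11, p_b - p11, 1.0 - p_a - p_b + p11)


def exchangeable_null_cohort(config: SyntheticConfig) -> EventLog:
    """The same cohort with no temporal structure at all.

    Precursor pairs are ignored and every timestamp is i.i.d. uniform on
    the window — the exchangeable regime in which the temporal precedence
    statistic should center on zero.
    """
    config.validate()
    stripped = SyntheticConfig(
        n_users=config.n_users,
        communities=list(config.communities),
        baseline_popularity=config.baseline_popularity,
        activity_shape=config.activity_shape,
        max_activity=config.max_activity,
        comorbid_pairs=list(config.comorbid_pairs),
        precursor_pairs=[],
        window=config.window,
        instances_per_membership=config.instances_per_membership,
        seed=config.seed,
    )
    events, _ = generate_cohort(stripped)
    return events
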