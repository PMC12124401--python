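"""Temporal Probability Difference: precedence, reassignment null, bootstrap."""

import collections

import numpy as np
import pytest

from comorbnet import (
    RunConfig,
    SyntheticConfig,
    first_engagements,
    generate_cohort,
    observed_precedence,
    reassign_instances,
    screen_early_signals,
    tpd_bootstrap,
)
from comorbnet.tpd import _restricted_arrays
from comorbnet.io import as_event_frame

from oracles import exact_null_precedence


class TestFirstEngagements:
    def test_minimum_per_user_community(self, events_builder):
        events = events_builder([("u1", "A", 10), ("u1", "A", 3), ("u1", "A", 7)])
        idx = first_engagements(events)
        assert idx.get("u1", "A") == 3

    def test_matches_independent_groupby(self):
        events, _ = generate_cohort(
            SyntheticConfig(n_users=600, communities=["a", "b", "c", "d"], seed=51)
        )
        idx = first_engagements(events)
        frame = events.frame
        for (u, c), t in frame.groupby(["user_id", "community"])["timestamp"].min().items():
            assert idx.get(u, c) == t
        assert len(idx) == len(frame.drop_duplicates(["user_id", "community"]))


class TestObservedPrecedence:
    def test_stated_tie_convention(self, events_builder):
        events = events_builder([
            ("u1", "i", 5), ("u1", "j", 3),
            ("u2", "i", 2), ("u2", "j", 7),
            ("u3", "i", 4), ("u3", "j", 4),
        ])
        p, n = observed_precedence(first_engagements(events), "i", "j", tie_weight=0.5)
        assert (p, n) == (0.5, 3)

    def test_all_candidates_first_gives_zero(self, events_builder):
        events = events_builder([("u1", "i", 9), ("u1", "j", 1), ("u2", "i", 8), ("u2", "j", 2)])
        p, _ = observed_precedence(first_engagements(events), "i", "j")
        assert p == 0.0

    def test_complementarity_without_ties(self):
        rng = np.random.default_rng(61)
        rows = []
        for u in range(40):
            times = rng.choice(10_000, size=6, replace=False)
            for k, t in enumerate(times):
                rows.append((f"u{u}", "i" if k < 3 else "j", int(t), "post"))
        import pandas as pd

        idx = first_engagements(pd.DataFrame(rows, columns=["user_id", "community", "timestamp", "event_kind"]))
        pij, n = observed_precedence(idx, "i", "j")
        pji, _ = observed_precedence(idx, "j", "i")
        assert n == 40 and pij + pji == pytest.approx(1.0)

    def test_no_co_engaged_users_flagged(self, events_builder):
        idx = first_engagements(events_builder([("u1", "i", 1), ("u2", "j", 2)]))
        p, n = observed_precedence(idx, "i", "j")
        assert n == 0 and np.isnan(p)


class TestReassignInstances:
    def test_label_multiset_and_user_counts_preserved(self, events_builder):
        events = events_builder([("u1", "i", 1), ("u1", "j", 2), ("u2", "i", 3), ("u2", "j", 4)])
        out = reassign_instances(events, seed=5)
        assert sorted(out.frame["community"]) == ["i", "i", "j", "j"]
        before = as_event_frame(events).groupby("user_id").size()
        after = out.frame.groupby("user_id").size()
        assert before.equals(after)
        assert sorted(map(tuple, out.frame[["user_id", "timestamp"]].values.tolist())) == \
            sorted(map(tuple, as_event_frame(events)[["user_id", "timestamp"]].values.tolist()))

    def test_single_community_is_identity(self, events_builder):
        events = events_builder([("u1", "i", 1), ("u2", "i", 9)])
        out = reassign_instances(events, seed=3)
        assert list(out.frame["community"]) == ["i", "i"]

    def test_assignments_uniform_over_multiset_permutations(self, events_builder):
        """Labels {i,i,j,j}: each of the 6 distinct assignments at 1/6 +- 0.02."""
        events = events_builder([("u1", "i", 1), ("u1", "j", 2), ("u2", "i", 3), ("u2", "j", 4)])
        counts = collections.Counter()
        for s in range(10_000):
            out = reassign_instances(events, seed=s)
            counts[tuple(out.frame["community"])] += 1
        assert len(counts) == 6
        for freq in counts.values():
            assert abs(freq / 10_000 - 1 / 6) < 0.02


class TestTpdBootstrap:
    def test_bootstrap_mean_matches_exhaustive_enumeration(self, events_builder):
        """Two users, one instance of each community: exact assignment oracle."""
        events = events_builder([("u1", "i", 1), ("u1", "j", 5), ("u2", "i", 8), ("u2", "j", 2)])
        cfg = RunConfig(min_co_engaged_users=2)
        res = tpd_bootstrap(events, "i", "j", n_bootstrap=4000, config=cfg, seed=71,
                            keep_iterations=True)
        uidx, lab, ts, n_users = _restricted_arrays(as_event_frame(events), "i", "j")
        exact, feasible = exact_null_precedence(uidx, lab, ts, n_users)
        se = res.tpd_iterations.std(ddof=1) / np.sqrt(res.n_effective_iterations)
        assert abs(res.p_null_mean - exact) < 3 * se
        # discard rate should match the infeasible-assignment fraction
        assert res.n_effective_iterations / 4000 == pytest.approx(feasible, abs=0.03)

    def test_antisymmetric_under_shared_shuffles(self):
        rng = np.random.default_rng(73)
        rows = []
        for u in range(30):
            times = rng.choice(100_000, size=5, replace=False)
            for k, t in enumerate(times):
                rows.append((f"u{u}", "i" if k % 2 else "j", int(t), "post"))
        import pandas as pd

        frame = pd.DataFrame(rows, columns=["user_id", "community", "timestamp", "event_kind"])
        cfg = RunConfig(min_co_engaged_users=2)
        fwd = tpd_bootstrap(frame, "i", "j", 400, cfg, seed=75, keep_iterations=True)
        rev = tpd_bootstrap(frame, "j", "i", 400, cfg, seed=75, keep_iterations=True)
        assert np.allclose(fwd.tpd_iterations, -rev.tpd_iterations)
        assert fwd.tpd_mean == pytest.approx(-rev.tpd_mean)

    def test_planted_precursor_detected(self):
        cfg = SyntheticConfig(n_users=400, communities=["early", "focal"],
                              baseline_popularity=0.9, seed=77,
                              precursor_pairs=[("early", "focal", 86_400.0, 1.0)])
        events, _ = generate_cohort(cfg)
        res = tpd_bootstrap(events, "focal", "early", n_bootstrap=300, seed=79)
        assert res.p_observed == 0.0
        assert res.tpd_mean < 0 and res.ci_high < 0 and res.significant_early

    def test_result_invariants(self):
        cfg = SyntheticConfig(n_users=300, communities=["a", "b"],
                              baseline_popularity=0.8, seed=81)
        events, _ = generate_cohort(cfg)
        res = tpd_bootstrap(events, "a", "b", n_bootstrap=300, seed=83)
        assert res.ci_low <= res.tpd_mean <= res.ci_high
        assert res.tpd_mean == pytest.approx(res.p_observed - res.p_null_mean)
        assert res.significant_early == (res.ci_high < 0)
        assert res.ci_low <= 0 <= res.ci_high  # exchangeable data: CI spans zero

    def test_too_few_co_engaged_users_fatal(self, events_builder):
        events = events_builder([("u1", "i", 1), ("u1", "j", 2)])
        with pytest.raises(ValueError, match="floor"):
            tpd_bootstrap(events, "i", "j", 100, RunConfig(min_co_engaged_users=5), seed=1)


class TestScreenEarlySignals:
    def _cohort(self):
        cfg = SyntheticConfig(
            n_users=500,
            communities=["focal", "early1", "early2", "noise1", "noise2", "noise3"],
            baseline_popularity=0.55,
            seed=85,
            precursor_pairs=[("early1", "focal", 86_400.0, 1.0),
                             ("early2", "focal", 86_400.0, 1.0)],
        )
        events, truth = generate_cohort(cfg)
        return events, truth

    def test_planted_precursors_rank_smallest_and_flagged(self):
        events, truth = self._cohort()
        cfg = RunConfig(n_bootstrap=300)
        screen = screen_early_signals(events, "focal",
                                      ["early1", "early2", "noise1", "noise2", "noise3"],
                                      config=cfg, seed=87)
        top_two = {r.candidate for r in screen.results[:2]}
        assert top_two == {e for e, _ in truth.planted_precursors}
        for r in screen.results[:2]:
            assert r.significant_early
        tpds = [r.tpd_mean for r in screen.results]
        assert tpds == sorted(tpds)

    def test_single_candidate_and_ineligible_listing(self, events_builder):
        rows = [(f"u{k}", "focal", 10 + k) for k in range(6)]
        rows += [(f"u{k}", "cand", 20 + k) for k in range(6)]
        rows += [("u0", "rare", 1)]
        events = events_builder(rows)
        cfg = RunConfig(n_bootstrap=100)
        screen = screen_early_signals(events, "focal", ["cand", "rare"], config=cfg, seed=89)
        assert len(screen.results) == 1 and screen.results[0].candidate == "cand"
        assert screen.ineligible and screen.ineligible[0][0] == "rare"

    def test_no_eligible_candidates_fatal(self, events_builder):
        events = events_builder([("u1", "focal", 1), ("u2", "other", 2)])
        with pytest.raises(ValueError, match="no eligible"):
            screen_early_signals(events, "focal", ["other"], config=RunConfig(), seed=1)
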