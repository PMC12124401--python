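"""Model/Results facade over the pipeline, in the statsmodels idiom.

Two fitted-model surfaces cover the two inference procedures:

* :class:`MultimorbidityModel` — fits the degree-preserving null to the
  observed co-engagement counts and returns a
  :class:`MultimorbidityResults` with expected weights, empirical
  p-values, the retained-link network, strength centralities and the
  Louvain partition.
* :class:`EarlySignalModel` — fits the TPD bootstrap to every candidate
  community against a focal cohort and returns
  :class:`EarlySignalResults` with per-pair estimates, confidence
  intervals and significance flags.

Both results objects expose ``summary()`` returning a plain-text table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from . import bipartite, network as netmod, nullmodel, tpd
from .config import RunConfig, derive_seed
from .io import CommunityCatalogue, as_event_frame, read_catalogue, read_events


class MultimorbidityModel:
    """Significance model for community co-engagement links.

    Parameters
    ----------
    events
        EventLog, DataFrame or iterable of engagement events.
    catalogue
        Optional community catalogue; events outside it are dropped.
    config
        RunConfig; ``n_null_replicates``, ``min_co_engaged_users`` and the
        optional ``p_threshold`` govern the fit.
    """

    def __init__(self, events, catalogue: Optional[CommunityCatalogue] = None,
                 config: Optional[RunConfig] = None):
        self.events = as_event_frame(events)
        self.catalogue = catalogue
        self.config = config or RunConfig()
        self.incidence = bipartite.build_incidence(self.events, catalogue)
        self.observed = bipartite.co_engagement(self.incidence)

    @classmethod
    def from_files(cls, events_path, catalogue_path=None, config: Optional[RunConfig] = None):
        events = read_events(events_path)
        catalogue = read_catalogue(catalogue_path) if catalogue_path else None
        return cls(events, catalogue, config)

    def fit(self, seed: Optional[int] = None) -> "MultimorbidityResults":
        cfg = self.config
        if seed is None:
            seed = derive_seed(cfg.master_seed, "null_replicates")
        ensemble = nullmodel.expected_weights(
            self.incidence, n_replicates=cfg.n_null_replicates, seed=seed
        )
        links = nullmodel.significant_links(
            self.observed, ensemble,
            min_users=cfg.min_co_engaged_users, p_threshold=cfg.p_threshold,
        )
        net = netmod.project_network(links)
        partition = netmod.detect_communities(net, seed=derive_seed(seed, "louvain"))
        return MultimorbidityResults(
            model=self, ensemble=ensemble, links=links, network=net, partition=partition,
        )


@dataclass
class MultimorbidityResults:
    """Fitted link-significance results and the projected network."""

    model: MultimorbidityModel
    ensemble: nullmodel.NullEnsemble
    links: nullmodel.SignificantLinkTable
    network: netmod.MultimorbidityNetwork
    partition: dict

    @property
    def strength(self) -> dict:
        return netmod.strength_centrality(self.network)

    def links_frame(self) -> pd.DataFrame:
        rows = [
            {
                "community_a": a,
                "community_b": b,
                "weight": rec.observed,
                "expected_weight": rec.expected,
                "empirical_p": rec.empirical_p,
                "retained": rec.retained,
            }
            for (a, b), rec in sorted(self.links.links.items())
        ]
        frame = pd.DataFrame(rows)
        if len(frame):
            frame = frame.sort_values(
                ["weight", "community_a", "community_b"], ascending=[False, True, True],
                kind="mergesort",
            ).reset_index(drop=True)
        return frame

    def summary(self, top: int = 15) -> str:
        frame = self.links_frame()
        retained = frame[frame["retained"]]
        q = netmod.modularity(self.network, self.partition)
        lines = [
            "Multimorbidity link significance",
            "=" * 56,
            f"users: {len(self.model.incidence.users)}   "
            f"communities: {len(self.model.incidence.communities)}",
            f"observed pairs: {len(frame)}   retained links: {len(retained)}",
            f"null replicates: {self.ensemble.n_replicates}   "
            f"modularity: {q:.4f}   blocks: {len(set(self.partition.values()))}",
            "-" * 56,
        ]
        shown = retained.head(top)
        lines.append(f"{'pair':<30}{'W':>6}{'W~':>9}{'p':>8}")
        for r in shown.itertuples(index=False):
            pair = f"{r.community_a}--{r.community_b}"
            lines.append(
                f"{pair:<30}{r.weight:>6d}{r.expected_weight:>9.2f}{r.empirical_p:>8.4f}"
            )
        if len(retained) > top:
            lines.append(f"... ({len(retained) - top} more retained links)")
        return "\n".join(lines)


class EarlySignalModel:
    """TPD screen of candidate communities against a focal cohort."""

    def __init__(self, events, focal: str, candidates: Iterable[str],
                 config: Optional[RunConfig] = None):
        self.events = as_event_frame(events)
        self.focal = focal
        self.candidates = sorted(set(candidates))
        self.config = config or RunConfig()

    def fit(self, seed: Optional[int] = None) -> "EarlySignalResults":
        cfg = self.config
        if seed is None:
            seed = derive_seed(cfg.master_seed, "tpd_screen", self.focal)
        screen = tpd.screen_early_signals(
            self.events, self.focal, self.candidates, config=cfg, seed=seed
        )
        return EarlySignalResults(model=self, screen=screen)


@dataclass
class EarlySignalResults:
    """Ranked TPD estimates with bootstrap confidence intervals."""

    model: EarlySignalModel
    screen: tpd.ScreenResult

    @property
    def results(self) -> list:
        return self.screen.results

    def to_frame(self) -> pd.DataFrame:
        return self.screen.to_frame()

    def significant(self) -> list:
        return [r for r in self.results if r.significant_early]

    def summary(self) -> str:
        ci_pct = 100 * self.model.config.ci_level
        lines = [
            f"Early-signal screen for focal community {self.screen.focal!r}",
            "=" * 72,
            f"candidates tested: {len(self.results)}   "
            f"ineligible: {len(self.screen.ineligible)}   "
            f"significant early signals: {len(self.significant())}",
            "-" * 72,
            f"{'candidate':<18}{'n':>6}{'P_ij':>8}{'TPD':>9}"
            f"{f'{ci_pct:.0f}% CI':>20}{'early':>7}",
        ]
        for r in self.results:
            ci = f"[{r.ci_low:+.3f}, {r.ci_high:+.3f}]"
            flag = "yes" if r.significant_early else ""
            lines.append(
                f"{r.candidate:<18}{r.n_co_engaged:>6d}{r.p_observed:>8.3f}"
                f"{r.tpd_mean:>+9.3f}{ci:>20}{flag:>7}"
            )
        for cand, reason in self.screen.ineligible:
            lines.append(f"{cand:<18}  skipped: {reason}")
        return "\n".join(lines)
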