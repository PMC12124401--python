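"""Readers and writers for engagement logs, catalogues and result tables.

Formats
-------
Events: CSV with header ``user_id,community,timestamp,event_kind`` or
JSON-lines with the same keys. Timestamps are integer Unix epoch seconds;
``event_kind`` (post/reply) is informational and optional.

Catalogue: CSV with header ``community,disease_label,focal``.

Edge tables: TSV, ordered by descending weight with lexicographic
tie-breaking, so reruns are byte-identical.

Networks: GraphML with node attributes ``strength`` and ``community_id``
and edge attributes ``weight`` and ``expected_weight``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .config import logger

EVENT_COLUMNS = ("user_id", "community", "timestamp", "event_kind")


class EngagementEvent(NamedTuple):
    """One user's single interaction with one community at one time."""

    user_id: str
    community: str
    timestamp: int
    event_kind: str = "post"


class EventLog:
    """Ordered collection of engagement events backed by a DataFrame."""

    def __init__(self, frame: pd.DataFrame, n_skipped: int = 0):
        missing = [c for c in ("user_id", "community", "timestamp") if c not in frame.columns]
        if missing:
            raise ValueError(f"event frame missing columns: {missing}")
        if "event_kind" not in frame.columns:
            frame = frame.assign(event_kind="post")
        frame = frame.loc[:, list(EVENT_COLUMNS)].reset_index(drop=True)
        frame["user_id"] = frame["user_id"].astype(str)
        frame["community"] = frame["community"].astype(str)
        frame["timestamp"] = frame["timestamp"].astype(np.int64)
        if len(frame) and (frame["timestamp"] < 0).any():
            raise ValueError("timestamps must be non-negative epoch seconds")
        self.frame = frame
        self.n_skipped = int(n_skipped)

    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self) -> Iterator[EngagementEvent]:
        for row in self.frame.itertuples(index=False):
            yield EngagementEvent(row.user_id, row.community, int(row.timestamp), row.event_kind)

    def write_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


def as_event_frame(events) -> pd.DataFrame:
    """Normalize an EventLog, DataFrame or iterable of events to a frame."""
    if isinstance(events, EventLog):
        return events.frame
    if isinstance(events, pd.DataFrame):
        return EventLog(events.copy()).frame
    return EventLog(pd.DataFrame(list(events), columns=list(EVENT_COLUMNS))).frame


def read_events(path: str | Path, format: Optional[str] = None) -> EventLog:
    """Read an engagement log, skipping malformed rows with a warning.

    Rows whose timestamp does not parse as an integer, or whose user or
    community token is empty, are skipped (real dump extracts are dirty);
    the skip count is logged and kept on the returned :class:`EventLog`.
    A missing file or a missing required column is fatal.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "jsonl" if path.suffix in (".jsonl", ".ndjson", ".json") else "csv"
    if format == "csv":
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    elif format == "jsonl":
        raw = pd.read_json(path, lines=True, dtype=str)
        if raw.empty:
            raw = pd.DataFrame(columns=["user_id", "community", "timestamp"])
    else:
        raise ValueError(f"unknown format {format!r}")
    missing = [c for c in ("user_id", "community", "timestamp") if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    ts = pd.to_numeric(raw["timestamp"], errors="coerce")
    ok = ts.notna() & (ts >= 0) & raw["user_id"].astype(str).str.len().gt(0) \
        & raw["community"].astype(str).str.len().gt(0)
    n_skipped = int((~ok).sum())
    if n_skipped:
        logger.warning("read_events: skipped %d malformed rows in %s", n_skipped, path)
    frame = raw.loc[ok].copy()
    frame["timestamp"] = ts[ok].astype(np.int64)
    if "event_kind" not in frame.columns:
        frame["event_kind"] = "post"
    return EventLog(frame.reset_index(drop=True), n_skipped=n_skipped)


@dataclass(frozen=True)
class CatalogueEntry:
    community: str
    disease_label: str
    focal: bool


@dataclass
class CommunityCatalogue:
    """Mapping of community tokens to disease labels and focal flags."""

    entries: list = field(default_factory=list)

    def __post_init__(self) -> None:
        tokens = [e.community for e in self.entries]
        if len(set(tokens)) != len(tokens):
            dupes = sorted({t for t in tokens if tokens.count(t) > 1})
            raise ValueError(f"duplicate community tokens in catalogue: {dupes}")

    @property
    def communities(self) -> list:
        return [e.community for e in self.entries]

    @property
    def focal_communities(self) -> list:
        return [e.community for e in self.entries if e.focal]

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, token: str) -> bool:
        return token in set(self.communities)

    def write_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            [(e.community, e.disease_label, e.focal) for e in self.entries],
            columns=["community", "disease_label", "focal"],
        ).to_csv(path, index=False)


_TRUE = {"true", "1", "yes", "t"}


def read_catalogue(path: str | Path) -> CommunityCatalogue:
    """Read a community catalogue CSV; duplicates and empty files are fatal."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in ("community", "disease_label", "focal") if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if raw.empty:
        raise ValueError(f"{path}: catalogue has zero rows")
    entries = [
        CatalogueEntry(r.community, r.disease_label, str(r.focal).strip().lower() in _TRUE)
        for r in raw.itertuples(index=False)
    ]
    return CommunityCatalogue(entries)


def _pair_rows(table) -> pd.DataFrame:
    """Rows for an edge table from a CoEngagementTable or link table."""
    rows = []
    if hasattr(table, "links"):  # SignificantLinkTable
        for (a, b), rec in table.links.items():
            rows.append(
                (a, b, rec.observed, rec.expected, rec.empirical_p, rec.retained)
            )
        cols = ["community_a", "community_b", "weight", "expected_weight",
                "empirical_p", "significant"]
    else:  # CoEngagementTable or plain mapping
        weights = table.weights if hasattr(table, "weights") else dict(table)
        for (a, b), w in weights.items():
            rows.append((a, b, w))
        cols = ["community_a", "community_b", "weight"]
    frame = pd.DataFrame(rows, columns=cols)
    if len(frame):
        frame = frame.sort_values(
            by=["weight", "community_a", "community_b"],
            ascending=[False, True, True],
            kind="mergesort",
        ).reset_index(drop=True)
    return frame


def write_edge_table(table, path: str | Path) -> None:
    """Write a co-engagement or significant-link table as deterministic TSV.

    Row order is descending weight with lexicographic tie-breaking on the
    community pair, so identical inputs produce byte-identical files.
    """
    _pair_rows(table).to_csv(path, sep="\t", index=False)


def read_edge_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def export_graphml(network, path: str | Path) -> None:
    """GraphML export of a multimorbidity network.

    Node attributes: ``strength``, ``community_id`` (when a partition has
    been computed). Edge attributes: ``weight``, ``expected_weight``.
    """
    import networkx as nx

    graph = network.graph.copy()
    strength = network.strength
    for node in graph.nodes:
        graph.nodes[node]["strength"] = float(strength[node])
        if network.partition is not None:
            graph.nodes[node]["community_id"] = int(network.partition[node])
    nx.write_graphml(graph, str(path))
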