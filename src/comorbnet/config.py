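"""Run configuration, deterministic seed derivation and structured logging.

Every randomized stage of the pipeline (null replicates, bootstrap,
synthetic cohort) draws its seed from a single ``master_seed`` through a
named substream, so stages can be rerun independently without perturbing
one another and identical configuration + inputs give byte-identical
outputs.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

logger = logging.getLogger("comorbnet")

_COHORT_RULES = ("any_focal", "per_focal_community")


@dataclass
class RunConfig:
    """Knobs shared by the significance and early-signal stages.

    Parameters
    ----------
    n_null_replicates
        Degree-preserving randomizations used to estimate expected
        co-engagement weights.
    n_bootstrap
        Instance-reassignment iterations per candidate pair in the TPD
        bootstrap.
    min_co_engaged_users
        Floor on the number of shared users below which a pair is not
        tested (guards against trivially "significant" near-zero pairs).
    ci_level
        Coverage of the percentile confidence interval on TPD.
    tie_weight
        Score given to a user whose first engagements in the two
        communities share a timestamp (0.5 preserves P_ij + P_ji = 1).
    p_threshold
        Optional empirical p-value cut for link retention. ``None``
        (default) reproduces the bare observed > expected rule.
    cohort_rule
        ``any_focal`` pools users of all focal communities into one
        screen; ``per_focal_community`` runs one screen per focal
        community over the users engaged with it.
    """

    n_null_replicates: int = 1000
    n_bootstrap: int = 1000
    min_co_engaged_users: int = 5
    ci_level: float = 0.95
    tie_weight: float = 0.5
    master_seed: int = 0
    cohort_rule: str = "any_focal"
    p_threshold: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("n_null_replicates", "n_bootstrap", "min_co_engaged_users"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError(f"ci_level must lie in (0, 1), got {self.ci_level}")
        if not 0.0 <= self.tie_weight <= 1.0:
            raise ValueError(f"tie_weight must lie in [0, 1], got {self.tie_weight}")
        if self.cohort_rule not in _COHORT_RULES:
            raise ValueError(
                f"cohort_rule must be one of {_COHORT_RULES}, got {self.cohort_rule!r}"
            )
        if self.p_threshold is not None and not 0.0 < self.p_threshold <= 1.0:
            raise ValueError(f"p_threshold must lie in (0, 1], got {self.p_threshold}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a YAML or JSON file whose keys mirror the field names."""
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        if data is None:
            data = {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


def derive_seed(master_seed: int, *names: str) -> int:
    """Derive a named substream seed (< 2**31) from the master seed.

    The derivation hashes the substream name, so adding a stage never
    perturbs the seeds of existing stages.
    """
    keys = [int(master_seed) & 0x7FFFFFFF]
    keys += [zlib.crc32(str(n).encode()) for n in names]
    ss = np.random.SeedSequence(keys)
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunReport:
    """Structured per-stage accounting for one pipeline run.

    Each executed stage appears exactly once in ``stages``; warnings are
    collected, never dropped.
    """

    config: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def record(self, stage: str, **counts) -> None:
        if stage in self.stages:
            raise ValueError(f"stage {stage!r} recorded twice")
        self.stages[stage] = dict(counts)
        logger.info("stage=%s %s", stage, " ".join(f"{k}={v}" for k, v in counts.items()))

    def warn(self, message: str) -> None:
        self.warnings.append(message)
        logger.warning(message)

    def to_json(self) -> str:
        return json.dumps(
            {"config": self.config, "stages": self.stages, "warnings": self.warnings},
            indent=2,
            sort_keys=True,
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")
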