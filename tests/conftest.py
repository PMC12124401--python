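import sys
from pathlib import Path

import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable


def make_events(rows):
    """Event frame from (user_id, community, timestamp) tuples."""
    return pd.DataFrame(
        [(u, c, t, "post") for u, c, t in rows],
        columns=["user_id", "community", "timestamp", "event_kind"],
    )


@pytest.fixture
def events_builder():
    return make_events


@pytest.fixture
def tiny_catalogue(tmp_path):
    """Catalogue CSV with one focal community and four others."""
    path = tmp_path / "catalogue.csv"
    pd.DataFrame(
        {
            "community": ["diabetes", "depression", "loseit", "Anxiety", "ibs"],
            "disease_label": ["diabetes", "depression", "obesity", "anxiety", "IBS"],
            "focal": [True, False, False, False, False],
        }
    ).to_csv(path, index=False)
    return path
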