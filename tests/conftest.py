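import numpy as np
import pandas as pd
import pytest

from emanet import EmaPanel


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_panel(rows, registry=None):
    """rows: iterable of (person, day, slot, variable, value)."""
    df = pd.DataFrame(rows, columns=["person", "day", "slot", "variable", "value"])
    return EmaPanel(df, registry or {})


@pytest.fixture
def two_person_panel():
    rows = []
    for p in ("a", "b"):
        for d in (1, 2, 3):
            for s in ("AM", "PM"):
                rows.append((p, d, s, "x", 50.0 + d))
                rows.append((p, d, s, "y", 40.0 - d))
    return make_panel(rows)
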