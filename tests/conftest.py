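import numpy as np
import pandas as pd
import pytest

from fragstat import Descriptor, GeometryTable


def make_table(columns: dict, kinds: dict | None = None, hidden=None) -> GeometryTable:
    """Build a small GeometryTable from plain column dicts."""
    n = len(next(iter(columns.values())))
    data = pd.DataFrame({k: list(v) for k, v in columns.items()})
    kinds = dict(kinds or {})
    for name in columns:
        if name not in kinds:
            # numeric test columns are linear unless stated otherwise
            kinds[name] = (
                "linear"
                if np.issubdtype(data[name].dtype, np.number)
                else "categorical"
            )
    descs = {name: Descriptor(name, kind) for name, kind in kinds.items()}
    return GeometryTable(
        [f"STR{i:04d}" for i in range(n)],
        np.ones(n, dtype=int),
        data,
        descs,
        hidden,
    )


@pytest.fixture
def simple_table():
    return make_table(
        {
            "D": [2.1, 2.5, 2.7, np.nan, 2.3],
            "TOR": [170.0, -170.0, 10.0, 20.0, 30.0],
            "GRP": [1, 2, 1, 2, 1],
            "LABEL": ["a", "b", "a", "b", "a"],
        },
        kinds={"D": "linear", "TOR": "circular", "GRP": "integer",
               "LABEL": "categorical"},
    )


def random_table(rng: np.random.Generator, n_rows=None, n_cols=None,
                 missing_rate=0.1) -> GeometryTable:
    """Random numeric table with missing cells, for property tests."""
    n = n_rows or int(rng.integers(2, 30))
    p = n_cols or int(rng.integers(1, 5))
    cols = {}
    for j in range(p):
        v = rng.normal(0, 10, size=n)
        v[rng.random(n) < missing_rate] = np.nan
        cols[f"C{j}"] = v
    cols["G"] = rng.integers(0, 3, size=n)
    return make_table(cols, kinds={"G": "integer"})
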