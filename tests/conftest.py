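import numpy as np
import pandas as pd
import pytest

from stmort import AdjacencyGraph, StudyPanel


@pytest.fixture
def path3():
    """0-1-2 path graph."""
    return AdjacencyGraph(3, frozenset({(0, 1), (1, 2)}))


@pytest.fixture
def pair_graph():
    """Two areas, one edge."""
    return AdjacencyGraph(2, frozenset({(0, 1)}))


def make_panel(records):
    """Build a StudyPanel from (area, year, gender, age, deaths, pop, R) rows."""
    rows = [dict(zip(["area_id", "year", "gender", "age_group", "deaths",
                      "population", "reference_rate"], r)) for r in records]
    df = pd.DataFrame(rows)
    df["deaths"] = df["deaths"].astype(float)
    return StudyPanel(df)


@pytest.fixture
def one_cell_panel():
    """Single area, single year: O=5, p=1, R=1."""
    return make_panel([("a0", 2000, "male", "65-74", 5, 1, 1.0)])
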