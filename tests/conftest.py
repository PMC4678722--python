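import numpy as np
import pandas as pd
import pytest


def _adjacency(genes: list[str], edges: list[tuple[str, str]]) -> pd.DataFrame:
    a = pd.DataFrame(0, index=genes, columns=genes, dtype=np.int8)
    for u, v in edges:
        a.loc[u, v] = 1
        a.loc[v, u] = 1
    return a


@pytest.fixture
def make_adjacency():
    return _adjacency


@pytest.fixture
def star_graph():
    """Hub A with leaves B, C, D."""
    return _adjacency(list("ABCD"), [("A", "B"), ("A", "C"), ("A", "D")])


@pytest.fixture
def two_triangles():
    """Disjoint triangles {A,B,C} and {D,E,F}."""
    return _adjacency(
        list("ABCDEF"),
        [("A", "B"), ("B", "C"), ("A", "C"), ("D", "E"), ("E", "F"), ("D", "F")],
    )


@pytest.fixture
def four_cycle():
    """Cycle A-B-C-D-A."""
    return _adjacency(list("ABCD"), [("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")])


@pytest.fixture
def small_expr():
    """3 genes x 4 samples toy expression matrix."""
    return pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [1.0, 3.0, 2.0, 4.0], [8.0, 6.0, 7.0, 5.0]],
        index=["GA", "GB", "GC"],
        columns=["s1", "s2", "s3", "s4"],
    )
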