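import networkx as nx
import pandas as pd
import pytest
from hypothesis import settings

from snetropy.network import TemplateNetwork

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def toy_edge_file(tmp_path):
    """Edge list with a self-loop, a sub-threshold edge and two strong edges."""
    path = tmp_path / "edges.tsv"
    path.write_text(
        "A\tB\t0.9\n"
        "B\tC\t0.5\n"
        "C\tC\t0.99\n"
        "D\tE\t0.71\n"
    )
    return path


@pytest.fixture
def string_dialect_file(tmp_path):
    """STRING detail-style file: header, extra columns, integer 0-999 scores."""
    path = tmp_path / "string.tsv"
    path.write_text(
        "protein1\tprotein2\tneighborhood\tcombined_score\n"
        "A\tB\t0\t900\n"
        "B\tC\t0\t500\n"
        "C\tC\t0\t990\n"
        "D\tE\t0\t710\n"
    )
    return path


def net_from_edges(edges):
    g = nx.Graph()
    g.add_edges_from(edges)
    return TemplateNetwork.from_graph(g)


@pytest.fixture
def path_net():
    return net_from_edges([("A", "B"), ("B", "C")])


@pytest.fixture
def star_net():
    return net_from_edges([("H", leaf) for leaf in ("L1", "L2", "L3", "L4")])


@pytest.fixture
def k4_net():
    return net_from_edges(
        [("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"), ("B", "D"), ("C", "D")]
    )


@pytest.fixture
def ref_matrix():
    """5 genes x 4 reference samples with distinct spreads."""
    return pd.DataFrame(
        {
            "r1": [1.0, 5.0, 0.0, 10.0, 2.0],
            "r2": [2.0, 5.0, 10.0, 10.0, 2.5],
            "r3": [3.0, 5.0, 5.0, 10.0, 1.5],
            "r4": [2.0, 5.0, 5.0, 10.0, 2.0],
        },
        index=["g1", "g2", "g3", "g4", "g5"],
    )
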