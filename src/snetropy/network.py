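"""Template interaction network: reading, confidence filtering and ego-network segmentation.

The global template network is an undirected graph built from a STRING-style
weighted edge list.  Each node ``g^k`` defines one *local network*: the ego
graph consisting of the center and its first-order neighbors.  All downstream
entropy scores are computed per local network, so the segmentation is stored
on the :class:`TemplateNetwork` itself.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx

__all__ = [
    "TemplateNetwork",
    "read_edge_list",
    "segment_local_networks",
    "restrict_to_measured",
]

_STRING_NAME_ALIASES = {
    "protein1": 0,
    "protein2": 1,
    "node1": 0,
    "node2": 1,
    "gene1": 0,
    "gene2": 1,
}
_SCORE_ALIASES = ("combined_score", "score", "weight", "confidence")


@dataclass
class TemplateNetwork:
    """Undirected interaction graph plus its decomposition into local (ego) networks.

    ``locals_`` maps every center gene ``g^k`` to its lexicographically ordered
    first-order neighbor list.  The number of local networks ``Q`` equals the
    number of nodes.
    """

    graph: nx.Graph
    locals_: dict[str, tuple[str, ...]] = field(default_factory=dict)

    @classmethod
    def from_graph(cls, graph: nx.Graph) -> "TemplateNetwork":
        net = cls(graph=graph)
        return segment_local_networks(net)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges}

    @property
    def q(self) -> int:
        """Number of local networks (one per node)."""
        return self.graph.number_of_nodes()

    def neighbors(self, center: str) -> tuple[str, ...]:
        return self.locals_[center]

    def local_members(self, center: str) -> tuple[str, ...]:
        """Center followed by its ordered neighbors: the gene set of ``N^k``."""
        return (center, *self.locals_[center])

    def summary(self) -> dict:
        degrees = [d for _, d in self.graph.degree()]
        hist: dict[int, int] = {}
        for d in degrees:
            hist[d] = hist.get(d, 0) + 1
        return {
            "n_nodes": self.graph.number_of_nodes(),
            "n_edges": self.graph.number_of_edges(),
            "degree_histogram": {str(k): hist[k] for k in sorted(hist)},
        }

    def summary_json(self) -> str:
        return json.dumps(self.summary(), indent=2, sort_keys=True)


def _detect_columns(fields: list[str]) -> tuple[int, int, int] | None:
    """Map a header row to (node-a, node-b, score) column indices, or None."""
    lowered = [f.strip().lower() for f in fields]
    score_idx = None
    for alias in _SCORE_ALIASES:
        if alias in lowered:
            score_idx = lowered.index(alias)
            break
    a_idx = b_idx = None
    for name, pos in _STRING_NAME_ALIASES.items():
        if name in lowered:
            if pos == 0:
                a_idx = lowered.index(name)
            else:
                b_idx = lowered.index(name)
    if score_idx is not None and a_idx is not None and b_idx is not None:
        return a_idx, b_idx, score_idx
    return None


def _split_row(line: str) -> list[str]:
    if "\t" in line:
        return [f for f in line.rstrip("\n").split("\t") if f != ""]
    return line.split()


def read_edge_list(path: str | Path, min_confidence: float = 0.7) -> TemplateNetwork:
    """Read a STRING-style weighted edge list into a filtered :class:`TemplateNetwork`.

    Keeps exactly the edges whose confidence score is strictly greater than
    ``min_confidence`` on the [0, 1] scale.  STRING dumps that report integer
    scores on 0-999 are auto-detected (any score > 1) and divided by 1000.
    Self-loops are dropped, duplicate pairs collapsed (max score wins), and
    nodes left without a surviving edge are removed.

    Parameters
    ----------
    path
        Tab- or whitespace-delimited file with two identifier columns and a
        numeric score column.  An optional header naming
        ``protein1/protein2/combined_score`` (STRING detail dialect, extra
        columns ignored) is recognized; otherwise the first, second and last
        columns are used.
    min_confidence
        Threshold on the [0, 1] confidence scale; edges must exceed it strictly.
    """
    if not 0.0 <= min_confidence <= 1.0:
        raise ValueError(f"min_confidence must be in [0, 1], got {min_confidence}")
    path = Path(path)

    raw_edges: list[tuple[str, str, float]] = []
    cols: tuple[int, int, int] | None = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = _split_row(line)
            if cols is None and not raw_edges:
                named = _detect_columns(fields)
                if named is not None:
                    cols = named
                    continue
                # headerless: score may still be non-numeric -> generic header
                try:
                    float(fields[-1])
                except (ValueError, IndexError):
                    if len(fields) >= 3:
                        cols = (0, 1, len(fields) - 1)
                        continue
                    raise ValueError(
                        f"{path}: malformed row at line {lineno}: {line.strip()!r}"
                    )
                cols = (0, 1, 2) if len(fields) == 3 else (0, 1, len(fields) - 1)
            ia, ib, isc = cols
            try:
                a, b = fields[ia], fields[ib]
                score = float(fields[isc])
            except (ValueError, IndexError):
                raise ValueError(
                    f"{path}: malformed row at line {lineno}: {line.strip()!r}"
                ) from None
            raw_edges.append((a, b, score))

    if not raw_edges:
        raise ValueError(f"{path}: no edges found")

    scale = 1000.0 if max(s for _, _, s in raw_edges) > 1.0 else 1.0
    best: dict[frozenset, float] = {}
    for a, b, score in raw_edges:
        if a == b:
            continue
        key = frozenset((a, b))
        score /= scale
        if score > best.get(key, float("-inf")):
            best[key] = score

    graph = nx.Graph()
    for key, score in best.items():
        if score > min_confidence:
            a, b = sorted(key)
            graph.add_edge(a, b, weight=score)

    if graph.number_of_nodes() == 0:
        raise ValueError(
            f"{path}: no edges exceed min_confidence={min_confidence}; empty network"
        )
    return TemplateNetwork.from_graph(graph)


def segment_local_networks(net: TemplateNetwork) -> TemplateNetwork:
    """Populate the per-center local networks of ``net`` (idempotent).

    The local network of center ``g^k`` is the center together with its
    first-order neighbors; neighbor order is lexicographic so vectors and
    reports are reproducible.
    """
    if net.graph.number_of_nodes() == 0:
        raise ValueError("cannot segment an empty network")
    net.locals_ = {
        node: tuple(sorted(net.graph.neighbors(node))) for node in net.graph.nodes
    }
    return net


def restrict_to_measured(
    net: TemplateNetwork, measured_genes: Iterable[str]
) -> TemplateNetwork:
    """Induced subgraph on the measured genes, isolated nodes removed, re-segmented.

    Network genes absent from the expression matrix carry no state information,
    so they are dropped rather than imputed.
    """
    measured = set(measured_genes)
    if not measured:
        raise ValueError("measured_genes is empty")
    keep = net.nodes & measured
    if not keep:
        raise ValueError("no overlap between network nodes and measured genes")
    sub = net.graph.subgraph(keep).copy()
    sub.remove_nodes_from([n for n, d in list(sub.degree()) if d == 0])
    if sub.number_of_nodes() == 0:
        raise ValueError(
            "network is empty after restricting to measured genes "
            "(all surviving nodes were isolated)"
        )
    return TemplateNetwork.from_graph(sub)
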