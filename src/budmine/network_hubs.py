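"""Weighted protein-interaction graphs, degree statistics, hub selection
and hub-subnetwork extraction.

Edges carry an integer combined confidence score on a 0–1000 scale; the
default retention threshold is 400 ("medium confidence").  Degree is the
unweighted edge count — hubs are the most-connected nodes — with weighted
degree available as an optional extra column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .errors import ParseError, ValidationError

__all__ = [
    "PPINetwork",
    "HubReport",
    "read_edge_list",
    "write_edge_list",
    "node_degrees",
    "select_hubs",
    "extract_subnetwork",
    "DEFAULT_MIN_SCORE",
]

DEFAULT_MIN_SCORE = 400


@dataclass
class PPINetwork:
    """Undirected simple graph with integer combined scores per edge."""

    graph: nx.Graph
    dropped_self_loops: int = 0

    def __post_init__(self):
        for u, v, data in self.graph.edges(data=True):
            score = data.get("combined_score")
            if score is None or not (0 <= int(score) <= 1000):
                raise ValidationError(
                    f"edge ({u}, {v}) lacks a combined score in 0..1000"
                )

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(
            (min(u, v), max(u, v), int(d["combined_score"]))
            for u, v, d in self.graph.edges(data=True)
        )
        return pd.DataFrame(rows, columns=["node_a", "node_b", "combined_score"])

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, min_score: int = DEFAULT_MIN_SCORE
    ) -> "PPINetwork":
        graph = nx.Graph()
        loops = 0
        for node_a, node_b, score in frame[
            ["node_a", "node_b", "combined_score"]
        ].itertuples(index=False):
            score = int(score)
            if not (0 <= score <= 1000):
                raise ValidationError(f"combined score {score} outside 0..1000")
            if node_a == node_b:
                loops += 1
                continue
            if score < min_score:
                continue
            # symmetric duplicates collapse keeping the maximum score
            if graph.has_edge(node_a, node_b):
                score = max(score, graph[node_a][node_b]["combined_score"])
            graph.add_edge(node_a, node_b, combined_score=score)
        return cls(graph, dropped_self_loops=loops)


def read_edge_list(path, min_score: int = DEFAULT_MIN_SCORE) -> PPINetwork:
    """Read a scored edge list TSV (node_a, node_b, combined_score),
    keeping edges with score >= ``min_score``, collapsing symmetric
    duplicates to the maximum score and dropping self-loops (counted)."""
    try:
        frame = pd.read_csv(
            path, sep="\t", dtype={"node_a": str, "node_b": str},
            converters={},
        )
    except Exception as exc:  # malformed table
        raise ParseError(f"could not read edge list: {exc}", path=path) from exc
    required = ["node_a", "node_b", "combined_score"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ParseError(f"edge list missing columns {missing}", path=path)
    scores = pd.to_numeric(frame["combined_score"], errors="coerce")
    if scores.isna().any():
        bad = int(frame.index[scores.isna()][0]) + 2  # +1 header, +1 1-based
        raise ParseError("non-numeric combined score", path=path, line=bad)
    frame = frame.assign(combined_score=scores.astype(int))
    return PPINetwork.from_frame(frame, min_score=min_score)


def write_edge_list(net: PPINetwork, path) -> None:
    net.to_frame().to_csv(path, sep="\t", index=False)


def node_degrees(net: PPINetwork) -> dict[str, int]:
    """Unweighted degree per node (sums to twice the edge count)."""
    return {node: int(degree) for node, degree in net.graph.degree()}


@dataclass
class HubReport:
    """Selected hub nodes with the selection rule echoed and, per hub, a
    sorted neighbour list."""

    rule: Mapping[str, int]
    degrees: Mapping[str, int]
    hubs: tuple[str, ...]
    neighbours: Mapping[str, tuple[str, ...]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "hub": list(self.hubs),
                "degree": [self.degrees[h] for h in self.hubs],
                "neighbours": [",".join(self.neighbours[h]) for h in self.hubs],
            }
        )


def select_hubs(net: PPINetwork, rule: Mapping[str, int]) -> HubReport:
    """Select hub nodes either by ``{"min_degree": d}`` (all nodes of degree
    >= d) or ``{"top_k": k}`` (k highest-degree nodes, ties broken
    lexicographically by node id)."""
    if set(rule.keys()) not in ({"min_degree"}, {"top_k"}):
        raise ValidationError(
            f"rule must be {{'min_degree': d}} or {{'top_k': k}}, got {dict(rule)}"
        )
    degrees = node_degrees(net)
    if "min_degree" in rule:
        d = int(rule["min_degree"])
        if d < 0:
            raise ValidationError("min_degree must be non-negative")
        hubs = sorted(n for n, deg in degrees.items() if deg >= d)
    else:
        k = int(rule["top_k"])
        if k < 0 or k > net.n_nodes:
            raise ValidationError(
                f"top_k must lie in 0..{net.n_nodes}, got {k}"
            )
        ranked = sorted(degrees.items(), key=lambda item: (-item[1], item[0]))
        hubs = [n for n, _ in ranked[:k]]
    neighbours = {h: tuple(sorted(net.graph.neighbors(h))) for h in hubs}
    return HubReport(dict(rule), degrees, tuple(hubs), neighbours)


def extract_subnetwork(net: PPINetwork, center: str, radius: int = 1) -> PPINetwork:
    """Induced subgraph on nodes within graph distance ``radius`` of
    ``center``."""
    if center not in net.graph:
        raise ValidationError(f"unknown center node {center!r}")
    if radius < 0:
        raise ValidationError("radius must be non-negative")
    sub = nx.ego_graph(net.graph, center, radius=radius)
    return PPINetwork(nx.Graph(sub))
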