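"""Weighted-network data model and random-walk geometry.

A :class:`WeightedNetwork` is an undirected graph with a fixed topology and
nonnegative symmetric edge weights.  The weights define a one-step random
walk: from node ``x`` the walker moves to neighbor ``y`` with probability
``w_xy / d_x`` where ``d_x`` is the node strength (sum of incident weights).
The ground metric for all transport computations is the *unweighted* hop
distance on the topology; weights only shape the walk measures.

Node identifiers are opaque strings (non-string inputs are coerced with
``str``) and all deterministic orderings are lexicographic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import (
    IsolatedNodeError,
    UnknownNodeError,
    ValidationError,
)

__all__ = [
    "WeightedNetwork",
    "ProbabilityMeasure",
    "node_strength",
    "node_measure",
    "hop_distance",
    "all_pairs_hop_distance",
    "read_network",
    "WEIGHT_TOLERANCE",
]

#: Weights below this threshold are treated as absent edges at construction.
WEIGHT_TOLERANCE = 1e-12

#: Reversed duplicate rows in an edge list must agree within this tolerance.
SYMMETRY_TOLERANCE = 1e-9


@dataclass(frozen=True)
class ProbabilityMeasure:
    """A finitely supported probability distribution over network nodes.

    Parameters
    ----------
    support
        Node identifiers carrying mass, in lexicographic order.
    mass
        Nonnegative masses aligned with ``support``; must sum to 1 within
        ``1e-12``.
    """

    support: tuple[str, ...]
    mass: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.support) != len(self.mass):
            raise ValidationError("support and mass must have equal length")
        if len(self.support) == 0:
            raise ValidationError("a probability measure needs nonempty support")
        if any(m < 0 for m in self.mass):
            raise ValidationError("probability masses must be nonnegative")
        total = math.fsum(self.mass)
        if abs(total - 1.0) > 1e-12:
            raise ValidationError(
                f"probability masses must sum to 1 (got {total!r})"
            )
        if len(set(self.support)) != len(self.support):
            raise ValidationError("support nodes must be distinct")

    @classmethod
    def from_dict(cls, masses: Mapping[str, float]) -> "ProbabilityMeasure":
        items = sorted((str(k), float(v)) for k, v in masses.items())
        return cls(tuple(k for k, _ in items), tuple(v for _, v in items))

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.support, self.mass))

    def __call__(self, node) -> float:
        return self.as_dict().get(str(node), 0.0)


class WeightedNetwork:
    """Undirected graph with symmetric nonnegative edge weights.

    The *topology* is the set of unordered pairs with positive weight; it is
    fixed at construction.  Self-loops are forbidden and weights below
    :data:`WEIGHT_TOLERANCE` are dropped as absent edges.

    Parameters
    ----------
    edges
        Iterable of ``(u, v, weight)`` triples.  A pair may appear twice
        (both orientations) provided the two weights agree within ``1e-9``.
    nodes
        Optional extra node identifiers (e.g. isolated genes) to include.
    """

    def __init__(
        self,
        edges: Iterable[tuple] = (),
        nodes: Iterable = (),
    ) -> None:
        g = nx.Graph()
        for n in nodes:
            g.add_node(str(n))
        for u, v, w in edges:
            u, v, w = str(u), str(v), float(w)
            if u == v:
                if w != 0.0:
                    raise ValidationError(f"self-loop with nonzero weight at {u!r}")
                g.add_node(u)
                continue
            if w < 0:
                raise ValidationError(f"negative weight {w!r} on edge ({u!r}, {v!r})")
            if g.has_edge(u, v) and abs(g[u][v]["weight"] - w) > SYMMETRY_TOLERANCE:
                raise ValidationError(
                    f"asymmetric duplicate edge ({u!r}, {v!r}): "
                    f"{g[u][v]['weight']!r} vs {w!r}"
                )
            g.add_node(u)
            g.add_node(v)
            if w > WEIGHT_TOLERANCE:
                g.add_edge(u, v, weight=w)
        self._g = g
        self._nodes = tuple(sorted(g.nodes))
        self._index = {n: i for i, n in enumerate(self._nodes)}
        self._hops: np.ndarray | None = None  # lazy all-pairs BFS cache

    # -- basic accessors -------------------------------------------------

    @property
    def nodes(self) -> tuple[str, ...]:
        """Node identifiers in lexicographic order."""
        return self._nodes

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    def edges(self) -> list[tuple[str, str, float]]:
        """Edges as ``(u, v, w)`` with ``u < v``, lexicographically sorted."""
        out = []
        for u, v, data in self._g.edges(data=True):
            a, b = (u, v) if u < v else (v, u)
            out.append((a, b, data["weight"]))
        out.sort()
        return out

    def edge_set(self) -> set[tuple[str, str]]:
        return {(u, v) for u, v, _ in self.edges()}

    def has_node(self, x) -> bool:
        return str(x) in self._g

    def has_edge(self, x, y) -> bool:
        return self._g.has_edge(str(x), str(y))

    def weight(self, x, y) -> float:
        """w_xy; zero for non-adjacent pairs of known nodes."""
        x, y = self._check(x), self._check(y)
        if self._g.has_edge(x, y):
            return self._g[x][y]["weight"]
        return 0.0

    def neighbors(self, x) -> tuple[str, ...]:
        x = self._check(x)
        return tuple(sorted(self._g.neighbors(x)))

    def degree(self, x) -> int:
        """Number of neighbors (topology degree, ignoring weights)."""
        x = self._check(x)
        return self._g.degree(x)

    def to_networkx(self) -> nx.Graph:
        """A defensive copy of the underlying :class:`networkx.Graph`."""
        return self._g.copy()

    def scaled(self, c: float) -> "WeightedNetwork":
        """The same topology with every weight multiplied by ``c > 0``."""
        if c <= 0:
            raise ValidationError("scale factor must be positive")
        return WeightedNetwork(
            ((u, v, w * c) for u, v, w in self.edges()), nodes=self._nodes
        )

    def _check(self, x) -> str:
        x = str(x)
        if x not in self._g:
            raise UnknownNodeError(f"unknown node {x!r}")
        return x

    def __repr__(self) -> str:
        return (
            f"WeightedNetwork(n_nodes={self.n_nodes}, "
            f"n_edges={self._g.number_of_edges()})"
        )

    # -- random-walk geometry --------------------------------------------

    def node_strength(self, x) -> float:
        x = self._check(x)
        return math.fsum(d["weight"] for _, _, d in self._g.edges(x, data=True))

    def node_measure(self, x) -> ProbabilityMeasure:
        x = self._check(x)
        d_x = self.node_strength(x)
        if d_x <= 0:
            raise IsolatedNodeError(
                f"node {x!r} is isolated (zero strength); "
                "its one-step walk measure is undefined"
            )
        nbrs = self.neighbors(x)
        return ProbabilityMeasure(
            nbrs, tuple(self._g[x][y]["weight"] / d_x for y in nbrs)
        )

    def hop_distance(self, x, y) -> float:
        """Shortest unweighted path length; ``math.inf`` when disconnected."""
        x, y = self._check(x), self._check(y)
        table = self._hop_table()
        return float(table[self._index[x], self._index[y]])

    def _hop_table(self) -> np.ndarray:
        if self._hops is None:
            n = self.n_nodes
            table = np.full((n, n), np.inf)
            for src, lengths in nx.all_pairs_shortest_path_length(self._g):
                i = self._index[src]
                for dst, hop in lengths.items():
                    table[i, self._index[dst]] = hop
            self._hops = table
        return self._hops

    def all_pairs_hop_distance(self) -> pd.DataFrame:
        """Symmetric hop-distance table over all nodes (``inf`` off-component)."""
        return pd.DataFrame(
            self._hop_table().copy(), index=self._nodes, columns=self._nodes
        )


# -- module-level functional surface (mirrors the class methods) ----------


def node_strength(net: WeightedNetwork, x) -> float:
    """Sum of edge weights incident to ``x`` (the walk normalizer d_x)."""
    return net.node_strength(x)


def node_measure(net: WeightedNetwork, x) -> ProbabilityMeasure:
    """One-step random-walk distribution from ``x``: mu_x(y) = w_xy / d_x."""
    return net.node_measure(x)


def hop_distance(net: WeightedNetwork, x, y) -> float:
    return net.hop_distance(x, y)


def all_pairs_hop_distance(net: WeightedNetwork) -> pd.DataFrame:
    return net.all_pairs_hop_distance()


# -- readers ----------------------------------------------------------------


def read_network(path, format: str = "edge-list") -> WeightedNetwork:
    """Read a weighted network from disk.

    Parameters
    ----------
    path
        File path.
    format
        ``"edge-list"``: whitespace- or tab-separated three-column rows
        (node, node, weight) with ``#`` comments; duplicate reversed rows
        must agree within 1e-9.  ``"adjacency-matrix"``: square CSV with a
        header row and first-column node names; asymmetry within 1e-9 is
        symmetrized by averaging, beyond it is an error.
    """
    if format == "edge-list":
        return _read_edge_list(Path(path))
    if format == "adjacency-matrix":
        return _read_adjacency(Path(path))
    raise ValidationError(f"unknown network format {format!r}")


def _read_edge_list(path: Path) -> WeightedNetwork:
    edges = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 3:
                raise ValidationError(
                    f"{path}:{lineno}: expected 3 columns, got {len(parts)}"
                )
            u, v, w = parts
            try:
                w = float(w)
            except ValueError as exc:
                raise ValidationError(
                    f"{path}:{lineno}: non-numeric weight {w!r}"
                ) from exc
            edges.append((u, v, w))
    if not edges:
        raise ValidationError(f"{path}: empty network (no edges found)")
    return WeightedNetwork(edges)


def _read_adjacency(path: Path) -> WeightedNetwork:
    df = pd.read_csv(path, index_col=0)
    if df.shape[0] == 0:
        raise ValidationError(f"{path}: empty network (no rows)")
    if df.shape[0] != df.shape[1]:
        raise ValidationError(
            f"{path}: adjacency matrix must be square, got {df.shape}"
        )
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    if list(df.index) != list(df.columns):
        raise ValidationError(f"{path}: row and column names disagree")
    a = df.to_numpy(dtype=float)
    asym = np.abs(a - a.T).max()
    if asym > SYMMETRY_TOLERANCE:
        raise ValidationError(
            f"{path}: adjacency asymmetric beyond tolerance (max |A-A^T| = {asym:g})"
        )
    a = 0.5 * (a + a.T)
    if np.any(np.diag(a) != 0):
        bad = df.index[np.nonzero(np.diag(a))[0][0]]
        raise ValidationError(f"{path}: nonzero self-loop weight at {bad!r}")
    if np.any(a < 0):
        raise ValidationError(f"{path}: negative weight in adjacency matrix")
    names = list(df.index)
    edges = [
        (names[i], names[j], a[i, j])
        for i in range(len(names))
        for j in range(i + 1, len(names))
        if a[i, j] > 0
    ]
    return WeightedNetwork(edges, nodes=names)
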