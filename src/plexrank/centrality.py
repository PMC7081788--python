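"""Per-layer weighted centrality metrics and dense ranking.

Three metrics are supported, chosen per layer by configuration:

* ``eigenvector`` — dominant eigenvector of the weighted adjacency by power
  iteration, with a small uniform teleportation mass added when the graph is
  not (strongly) connected so the dominant eigenvector is unique.
* ``in_degree`` / ``total_degree`` — weighted strength sums.
* ``betweenness`` — weighted shortest-path betweenness with edge distance
  1/weight (stronger ties are shorter), unnormalized.

Centrality values convert to dense ranks: rank 1 is the largest value, exact
ties share a rank, and ranks are consecutive integers.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .core_io import ConfigurationError, Layer, ValidationError

__all__ = [
    "CentralityVector",
    "NumericalError",
    "eigenvector_centrality",
    "degree_centrality",
    "betweenness_centrality",
    "compute_centrality",
    "dense_rank",
]

#: significant digits used when comparing centralities for exact ties;
#: absorbs float noise without merging genuinely distinct values
TIE_SIGNIFICANT_DIGITS = 12

#: uniform teleportation mass for eigenvector centrality on graphs that are
#: not strongly connected (degenerate/synthetic inputs need a defined answer)
DEFAULT_TELEPORT = 1e-3

_EIG_TOL = 1e-10
_EIG_MAXITER = 100_000


class NumericalError(RuntimeError):
    """Iterative computation failed to converge."""


@dataclass
class CentralityVector:
    """Centrality values for every node of one layer."""

    layer: str
    metric: str
    values: dict[str, float]

    def as_array(self, nodes: list[str]) -> np.ndarray:
        return np.array([self.values[n] for n in nodes], dtype=float)


def _node_order(layer: Layer) -> list[str]:
    return sorted(layer.nodes)


def _adjacency(layer: Layer, nodes: list[str]) -> np.ndarray:
    """Dense weighted adjacency, A[i, j] = weight of edge i -> j."""
    index = {n: i for i, n in enumerate(nodes)}
    a = np.zeros((len(nodes), len(nodes)))
    for (u, v), w in layer.edges.items():
        a[index[u], index[v]] += w
        if not layer.directed:
            a[index[v], index[u]] += w
    return a


def eigenvector_centrality(
    layer: Layer, teleport: float = DEFAULT_TELEPORT
) -> CentralityVector:
    """Dominant-eigenvector centrality by power iteration.

    A node's score grows with the scores of the nodes it directs edges *to*
    (out-going convention): x <- A x with A[i, j] the i -> j weight.  When the
    layer is not strongly connected, a uniform mass ``teleport / N`` is added
    to every entry so the iteration has a unique positive fixed point.
    Scores are normalized to unit maximum.
    """
    nodes = _node_order(layer)
    n = len(nodes)
    if n == 0:
        raise ValidationError(f"layer {layer.name!r} is empty")
    if n == 1:
        return CentralityVector(layer.name, "eigenvector", {nodes[0]: 1.0})

    a = _adjacency(layer, nodes)
    g = nx.DiGraph(a) if layer.directed else nx.Graph(a)
    connected = (
        nx.is_strongly_connected(g) if layer.directed else nx.is_connected(g)
    )
    if not connected:
        a = a + teleport / n

    # shift by a multiple of the identity: eigenvectors are unchanged but the
    # dominant eigenvalue becomes strictly largest in magnitude, so power
    # iteration cannot oscillate (e.g. on bipartite layers)
    a = a + np.eye(n) * a.max()

    x = np.full(n, 1.0 / n)
    for iteration in range(1, _EIG_MAXITER + 1):
        x_new = a @ x
        norm = x_new.max()
        if norm <= 0:
            raise NumericalError(
                f"layer {layer.name!r}: power iteration collapsed to zero "
                f"at iteration {iteration}"
            )
        x_new /= norm
        if np.abs(x_new - x).max() < _EIG_TOL:
            x = x_new
            break
        x = x_new
    else:
        raise NumericalError(
            f"layer {layer.name!r}: eigenvector iteration did not converge "
            f"within {_EIG_MAXITER} iterations"
        )
    x /= x.max()
    return CentralityVector(layer.name, "eigenvector", dict(zip(nodes, x)))


def degree_centrality(layer: Layer, mode: str) -> CentralityVector:
    """Weighted strength: ``in`` (in-strength) or ``total`` (in + out)."""
    if mode not in {"in", "total"}:
        raise ConfigurationError(f"unknown degree mode {mode!r}")
    if mode == "in" and not layer.directed:
        raise ConfigurationError(
            f"layer {layer.name!r}: in-degree requires a directed layer"
        )
    values = {n: 0.0 for n in layer.nodes}
    for (u, v), w in layer.edges.items():
        if layer.directed:
            if mode == "in":
                values[v] += w
            else:
                values[u] += w
                values[v] += w
        else:
            # undirected: each endpoint accrues the edge weight once
            values[u] += w
            values[v] += w
    metric = "in_degree" if mode == "in" else "total_degree"
    return CentralityVector(layer.name, metric, values)


def betweenness_centrality(layer: Layer) -> CentralityVector:
    """Weighted shortest-path betweenness, distance = 1/weight, unnormalized.

    Pair contributions are split equally among tied shortest paths (the
    standard Brandes accumulation).
    """
    for (u, v), w in layer.edges.items():
        if w <= 0:
            raise ValidationError(
                f"layer {layer.name!r}: nonpositive weight {w} on {u}-{v}; "
                "betweenness needs strictly positive weights"
            )
    g: nx.Graph | nx.DiGraph = nx.DiGraph() if layer.directed else nx.Graph()
    g.add_nodes_from(layer.nodes)
    for (u, v), w in layer.edges.items():
        g.add_edge(u, v, distance=1.0 / w)
    bc = nx.betweenness_centrality(g, weight="distance", normalized=False)
    return CentralityVector(layer.name, "betweenness", dict(bc))


def compute_centrality(layer: Layer, metric: str) -> CentralityVector:
    """Dispatch on the configured metric name."""
    if metric == "eigenvector":
        return eigenvector_centrality(layer)
    if metric == "in_degree":
        return degree_centrality(layer, "in")
    if metric == "total_degree":
        return degree_centrality(layer, "total")
    if metric == "betweenness":
        return betweenness_centrality(layer)
    raise ConfigurationError(f"unknown centrality metric {metric!r}")


def _tie_key(value: float) -> float:
    """Round to a fixed number of significant digits for tie detection."""
    if value == 0 or not np.isfinite(value):
        return float(value)
    from math import floor, log10

    digits = TIE_SIGNIFICANT_DIGITS - 1 - floor(log10(abs(value)))
    return round(value, digits)


def dense_rank(values: CentralityVector | dict[str, float]) -> dict[str, int]:
    """Dense ranks, 1 = largest value; exact ties share a rank.

    Ranks are consecutive integers 1..K where K is the number of distinct
    values.  Equality is judged after rounding to 12 significant digits so
    float noise does not split genuine ties.
    """
    mapping = values.values if isinstance(values, CentralityVector) else values
    keyed = {node: _tie_key(v) for node, v in mapping.items()}
    distinct = sorted(set(keyed.values()), reverse=True)
    rank_of_value = {v: r for r, v in enumerate(distinct, start=1)}
    return {node: rank_of_value[v] for node, v in keyed.items()}
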