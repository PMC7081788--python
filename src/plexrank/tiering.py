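"""Collapse centrality values into rank tiers.

Nodes are clustered by one-dimensional agglomerative clustering on their
centrality values (distance = absolute difference, complete linkage).  The
tree is cut at the minimum tier count whose tiered values (each node replaced
by its tier's mean centrality) explain at least a threshold fraction of the
variance of the original values.  Tier 1 holds the highest centralities; a
node's tier index is its within-layer rank fed to the Borda aggregation.

In one dimension with complete linkage the closest pair of clusters is always
adjacent in value order, so clusters are contiguous intervals of the sorted
values; the implementation exploits this for O(N^2) work and is verified
against naive agglomeration in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .centrality import CentralityVector

__all__ = ["TierAssignment", "build_linkage", "explained_variance", "assign_tiers"]

DEFAULT_THRESHOLD = 0.99


@dataclass
class TierAssignment:
    """Tiers for one layer: an ordered partition plus its r-squared path."""

    layer: str
    tiers: list[list[str]]  # tier 1 first (highest centrality)
    tier_of: dict[str, int]  # node -> 1-based tier index (the layer rank)
    tiered_value: dict[str, float]  # node -> mean centrality of its tier
    r2_path: list[float]  # r2 for every candidate tier count 1..N
    threshold: float

    @property
    def n_tiers(self) -> int:
        return len(self.tiers)


def _sorted_items(values: CentralityVector | dict[str, float]):
    mapping = values.values if isinstance(values, CentralityVector) else values
    # descending by value; node ID breaks exact ties deterministically
    return sorted(mapping.items(), key=lambda kv: (-kv[1], kv[0]))


def build_linkage(values: CentralityVector | dict[str, float]) -> list[list[tuple[int, int]]]:
    """Agglomerative complete-linkage merge tree over scalar centralities.

    Returns the nested partitions as boundary lists: ``partitions[k-1]`` is
    the partition into k clusters, each cluster a half-open index range
    ``(start, stop)`` into the descending-sorted value array.  Merge-height
    ties are broken by merging the leftmost (highest-centrality) pair first.
    """
    items = _sorted_items(values)
    vals = np.array([v for _, v in items], dtype=float)
    n = len(vals)
    if n == 0:
        raise ValueError("cannot tier an empty value set")

    # clusters are contiguous intervals [start, stop) of the sorted array;
    # complete-linkage distance between adjacent intervals is the spread of
    # their union: vals[left.start] - vals[right.stop - 1]
    bounds = [(i, i + 1) for i in range(n)]
    partitions = [None] * n
    partitions[n - 1] = list(bounds)
    for k in range(n - 1, 0, -1):
        best_i, best_d = 0, np.inf
        for i in range(len(bounds) - 1):
            d = vals[bounds[i][0]] - vals[bounds[i + 1][1] - 1]
            if d < best_d - 1e-15:  # strict improvement; ties keep leftmost
                best_i, best_d = i, d
        bounds = (
            bounds[:best_i]
            + [(bounds[best_i][0], bounds[best_i + 1][1])]
            + bounds[best_i + 2 :]
        )
        partitions[k - 1] = list(bounds)
    return partitions


def explained_variance(
    values: CentralityVector | dict[str, float],
    assignment: list[list[str]],
) -> float:
    """Fraction of variance explained by replacing values with tier means.

    Computed as between-tier sum of squares over total sum of squares, which
    equals the squared Pearson correlation between the original values and
    their tier means whenever the original values are non-constant.  Constant
    input is defined to score 1 (a single tier represents it exactly); a
    constant tiered vector against non-constant input scores 0.
    """
    mapping = values.values if isinstance(values, CentralityVector) else values
    covered = [node for tier in assignment for node in tier]
    if set(covered) != set(mapping) or len(covered) != len(mapping):
        raise ValueError("partition does not cover the node set exactly once")
    x = np.array([mapping[n] for n in covered], dtype=float)
    sst = float(np.sum((x - x.mean()) ** 2))
    if sst == 0.0:
        return 1.0
    ssb = 0.0
    for tier in assignment:
        tv = np.array([mapping[n] for n in tier], dtype=float)
        ssb += len(tv) * (tv.mean() - x.mean()) ** 2
    return float(ssb / sst)


def assign_tiers(
    values: CentralityVector | dict[str, float],
    threshold: float = DEFAULT_THRESHOLD,
    layer: str | None = None,
) -> TierAssignment:
    """Cut the linkage tree at the minimal tier count reaching the threshold.

    Scans k = 1..N and keeps the first k whose tiered values explain at least
    ``threshold`` of the variance.  Tiers are ordered by descending mean, so
    the tier index of a node is its layer rank.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if isinstance(values, CentralityVector):
        layer = layer or values.layer
        mapping = values.values
    else:
        mapping = values
        layer = layer or ""

    items = _sorted_items(mapping)
    nodes = [n for n, _ in items]
    vals = np.array([v for _, v in items], dtype=float)
    n = len(vals)
    partitions = build_linkage(mapping)

    grand = vals.mean()
    sst = float(np.sum((vals - grand) ** 2))

    # cumulative sums make per-cut between-SS O(k)
    csum = np.concatenate([[0.0], np.cumsum(vals)])

    def r2_for(bounds) -> float:
        if sst == 0.0:
            return 1.0
        ssb = 0.0
        for start, stop in bounds:
            size = stop - start
            mean = (csum[stop] - csum[start]) / size
            ssb += size * (mean - grand) ** 2
        return ssb / sst

    r2_path = [r2_for(partitions[k - 1]) for k in range(1, n + 1)]

    chosen = n
    for k in range(1, n + 1):
        # tolerate float round-off at the threshold boundary
        if r2_path[k - 1] >= threshold - 1e-12:
            chosen = k
            break

    bounds = partitions[chosen - 1]
    tiers = [[nodes[i] for i in range(start, stop)] for start, stop in bounds]
    tier_of = {}
    tiered_value = {}
    for idx, (start, stop) in enumerate(bounds, start=1):
        mean = float((csum[stop] - csum[start]) / (stop - start))
        for i in range(start, stop):
            tier_of[nodes[i]] = idx
            tiered_value[nodes[i]] = mean
    return TierAssignment(
        layer=layer,
        tiers=tiers,
        tier_of=tier_of,
        tiered_value=tiered_value,
        r2_path=r2_path,
        threshold=threshold,
    )
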