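"""Spearman correlations between layer rankings within a group.

Tier ranks contain many ties, so the midrank (average-rank) tie correction is
material; ``scipy.stats.spearmanr`` provides it.  A constant ranking makes
the correlation undefined — such entries are reported as NaN and flagged,
never coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LayerCorrelationMatrix",
    "spearman_matrix",
    "layer_vs_consensus",
    "correlation_summary",
]


@dataclass
class LayerCorrelationMatrix:
    """Symmetric layer-by-layer Spearman matrix for one group."""

    group: str
    layers: list[str]
    rho: np.ndarray  # L x L, NaN where undefined
    undefined: set[tuple[str, str]] = field(default_factory=set)
    consensus_rho: dict[str, float] | None = None

    def value(self, layer_a: str, layer_b: str) -> float:
        i, j = self.layers.index(layer_a), self.layers.index(layer_b)
        return float(self.rho[i, j])

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.layers):
            for j, b in enumerate(self.layers):
                if j <= i:
                    continue
                rows.append(
                    {
                        "group": self.group,
                        "layer_a": a,
                        "layer_b": b,
                        "rho": float(self.rho[i, j]),
                        "undefined": (a, b) in self.undefined,
                    }
                )
        return pd.DataFrame(rows)

    def to_wide(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=self.layers, columns=self.layers)


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    if np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def spearman_matrix(
    rankings: dict[str, dict[str, int]],
    nodes: list[str],
    group: str = "",
) -> LayerCorrelationMatrix:
    """Pairwise Spearman rho (midrank ties) between layer rank vectors."""
    if len(nodes) < 3:
        raise ValueError("need at least 3 nodes for rank correlation")
    layers = list(rankings)
    vectors = {}
    for name, ranks in rankings.items():
        missing = [n for n in nodes if n not in ranks]
        if missing:
            raise ValueError(f"layer {name!r} missing ranks for {missing}")
        vectors[name] = np.array([ranks[n] for n in nodes], dtype=float)

    big_l = len(layers)
    rho = np.eye(big_l)
    undefined: set[tuple[str, str]] = set()
    for i in range(big_l):
        for j in range(i + 1, big_l):
            r = _spearman(vectors[layers[i]], vectors[layers[j]])
            rho[i, j] = rho[j, i] = r
            if np.isnan(r):
                undefined.add((layers[i], layers[j]))
    return LayerCorrelationMatrix(group=group, layers=layers, rho=rho, undefined=undefined)


def correlation_summary(matrices: list[LayerCorrelationMatrix]) -> pd.DataFrame:
    """Min/mean/max of each layer-pair correlation across groups.

    Undefined (NaN) entries are excluded from the summary; a pair undefined
    in every group reports NaN throughout.
    """
    if not matrices:
        raise ValueError("need at least one correlation matrix")
    long = pd.concat([m.to_long() for m in matrices], ignore_index=True)
    return (
        long.groupby(["layer_a", "layer_b"])["rho"]
        .agg(["min", "mean", "max", "count"])
        .reset_index()
    )


def layer_vs_consensus(
    rankings: dict[str, dict[str, int]],
    consensus: dict[str, int],
    nodes: list[str],
) -> dict[str, float]:
    """Spearman rho of each layer's ranking against the consensus ranking."""
    cons = np.array([consensus[n] for n in nodes], dtype=float)
    out = {}
    for name, ranks in rankings.items():
        vec = np.array([ranks[n] for n in nodes], dtype=float)
        out[name] = _spearman(vec, cons)
    return out
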