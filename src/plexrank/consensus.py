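"""Borda-count aggregation of per-layer ranks into a consensus ranking.

Each node's Borda score is the arithmetic mean of its layer ranks; the node
with the lowest score is the top consensus candidate.  Scores are compared as
exact rationals (layer ranks are integers, so scores have denominator L),
making ties exact rather than float-fragile.  Consensus ranks are dense: tied
scores share a rank and the next distinct score takes the next integer.

The reversed-rank transform (max rank minus rank) turns the consensus ranking
into a nonnegative count-like outcome for regression, with larger values more
central.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

__all__ = [
    "ConsensusRanking",
    "borda_scores",
    "consensus_ranks",
    "reverse_ranks",
    "build_consensus",
]


@dataclass
class ConsensusRanking:
    """Borda scores plus dense consensus ranks and their reversal."""

    borda_score: dict[str, Fraction]
    consensus_rank: dict[str, int]
    reversed_rank: dict[str, int]

    @property
    def max_rank(self) -> int:
        return max(self.consensus_rank.values())


def borda_scores(layer_ranks: list[dict[str, int]]) -> dict[str, Fraction]:
    """Mean layer rank per node, as an exact rational with denominator L."""
    if not layer_ranks:
        raise ValueError("need at least one layer rank map")
    nodes = set(layer_ranks[0])
    big_l = len(layer_ranks)
    for i, ranks in enumerate(layer_ranks):
        if set(ranks) != nodes:
            missing = nodes.symmetric_difference(ranks)
            raise ValueError(
                f"layer rank map {i} does not cover the node set; "
                f"mismatched nodes: {sorted(missing)}"
            )
    return {
        node: Fraction(sum(ranks[node] for ranks in layer_ranks), big_l)
        for node in nodes
    }


def consensus_ranks(scores: dict[str, Fraction]) -> dict[str, int]:
    """Dense ranks ascending in Borda score: lowest score -> rank 1."""
    distinct = sorted(set(scores.values()))
    rank_of = {s: r for r, s in enumerate(distinct, start=1)}
    return {node: rank_of[s] for node, s in scores.items()}


def reverse_ranks(consensus: dict[str, int]) -> dict[str, int]:
    """Subtract each rank from the group maximum: 0 = least central."""
    top = max(consensus.values())
    return {node: top - rank for node, rank in consensus.items()}


def build_consensus(layer_ranks: list[dict[str, int]]) -> ConsensusRanking:
    scores = borda_scores(layer_ranks)
    ranks = consensus_ranks(scores)
    return ConsensusRanking(
        borda_score=scores,
        consensus_rank=ranks,
        reversed_rank=reverse_ranks(ranks),
    )
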