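"""End-to-end driver: layers -> centralities -> tiers -> consensus.

Thin orchestration shared by the CLI, the acceptance script, and tests.
"""

from __future__ import annotations

import pandas as pd

from .centrality import compute_centrality, dense_rank
from .consensus import ConsensusRanking, build_consensus
from .core_io import LayerConfig, MultiplexNetwork, ResultBundle
from .similarity import layer_vs_consensus, spearman_matrix
from .tiering import TierAssignment, assign_tiers

__all__ = ["rank_multiplex", "tier_tables", "consensus_table"]


def rank_multiplex(
    multiplex: MultiplexNetwork,
    config: LayerConfig,
    group: str = "",
    with_correlations: bool = True,
) -> ResultBundle:
    """Run the ranking pipeline on one group's multiplex."""
    assignments: dict[str, TierAssignment] = {}
    for layer in multiplex.layers:
        spec = config.spec_for(layer.name)
        cv = compute_centrality(layer, spec.metric)
        assignments[layer.name] = assign_tiers(cv, spec.tier_threshold)
    consensus = build_consensus([a.tier_of for a in assignments.values()])
    correlations = None
    if with_correlations and multiplex.n_nodes >= 3:
        rankings = {name: a.tier_of for name, a in assignments.items()}
        correlations = spearman_matrix(rankings, multiplex.nodes, group=group)
        correlations.consensus_rho = layer_vs_consensus(
            rankings, consensus.consensus_rank, multiplex.nodes
        )
    return ResultBundle(
        layer_rankings=assignments,
        consensus=consensus,
        correlations=correlations,
    )


def tier_tables(bundle: ResultBundle, group: str = "") -> pd.DataFrame:
    """Long-format per-layer tier table: node, layer, tier, tiered value."""
    rows = []
    for name, ta in bundle.layer_rankings.items():
        for node, tier in sorted(ta.tier_of.items()):
            rows.append(
                {
                    "group": group,
                    "node": node,
                    "layer": name,
                    "tier": tier,
                    "tiered_value": ta.tiered_value[node],
                }
            )
    return pd.DataFrame(rows)


def consensus_table(consensus: ConsensusRanking, group: str = "") -> pd.DataFrame:
    rows = [
        {
            "group": group,
            "node": node,
            "borda_score": float(consensus.borda_score[node]),
            "consensus_rank": consensus.consensus_rank[node],
            "reversed_rank": consensus.reversed_rank[node],
        }
        for node in sorted(consensus.consensus_rank)
    ]
    return pd.DataFrame(rows)
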