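"""Synthetic multiplex social groups for tests, calibration, and demos.

Groups emulate captive macaque-style societies: a latent dominance hierarchy
drives three directed layers (aggression, status signaling, policing), and
matriline kin structure plus rank biases drive two undirected affiliation
layers (grooming, huddling).  Layer densities are hit by calibrating a
logistic edge-probability intercept against the target; edge weights are
zero-truncated Poisson interaction frequencies.

``GROUP_PRESETS`` bundles seven demonstration scenarios (A-G) whose sizes,
sex ratios, matriline ranges, and per-layer densities match a published
seven-group captive population, so pipelines can be exercised at realistic
scale without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .core_io import AttributeTable, Layer, LayerConfig, LayerSpec, MultiplexNetwork

__all__ = [
    "GroupScenario",
    "GenerationError",
    "GROUP_PRESETS",
    "default_layer_config",
    "generate_group",
    "generate_null_attributes",
    "read_scenario",
]

LAYER_NAMES = ("aggression", "status", "policing", "grooming", "huddling")

#: (N, males, females, matriline max, nursery fraction, layer densities)
#: for the seven demonstration groups
GROUP_PRESETS: dict[str, dict] = {
    "A": dict(n=87, n_males=30, matriline_max=17, nursery_frac=0.149,
              densities=dict(aggression=0.271, status=0.085, policing=0.021,
                             grooming=0.259, huddling=0.190)),
    "B": dict(n=99, n_males=26, matriline_max=22, nursery_frac=0.0,
              densities=dict(aggression=0.219, status=0.090, policing=0.010,
                             grooming=0.188, huddling=0.299)),
    "C": dict(n=101, n_males=27, matriline_max=20, nursery_frac=0.0,
              densities=dict(aggression=0.261, status=0.086, policing=0.015,
                             grooming=0.235, huddling=0.244)),
    "D": dict(n=55, n_males=16, matriline_max=36, nursery_frac=0.0,
              densities=dict(aggression=0.355, status=0.177, policing=0.018,
                             grooming=0.346, huddling=0.314)),
    "E": dict(n=101, n_males=34, matriline_max=15, nursery_frac=0.089,
              densities=dict(aggression=0.243, status=0.086, policing=0.012,
                             grooming=0.237, huddling=0.316)),
    "F": dict(n=96, n_males=28, matriline_max=24, nursery_frac=0.052,
              densities=dict(aggression=0.332, status=0.138, policing=0.019,
                             grooming=0.237, huddling=0.132)),
    "G": dict(n=81, n_males=24, matriline_max=17, nursery_frac=0.185,
              densities=dict(aggression=0.182, status=0.120, policing=0.010,
                             grooming=0.212, huddling=0.211)),
}


class GenerationError(ValueError):
    """Scenario parameters cannot produce a valid group."""


@dataclass(frozen=True)
class GroupScenario:
    """Parameters for one synthetic group.

    Effect sizes are logistic-scale slopes on rank/kin quantities; setting
    them all to zero yields networks independent of every attribute (the
    null scenario used for calibration studies).
    """

    name: str = "S"
    n: int = 80
    n_males: int | None = None  # default: male:female about 1:2.5
    densities: dict[str, float] = field(
        default_factory=lambda: dict(
            aggression=0.26, status=0.10, policing=0.015,
            grooming=0.24, huddling=0.24,
        )
    )
    matriline_max: int = 20
    matriline_geom_p: float = 0.12  # truncated-geometric size parameter
    nursery_frac: float = 0.08
    # effect sizes (logistic slopes)
    rank_aggression: float = 8.0  # rank(i) - rank(j) -> aggression i->j
    rank_status: float = 10.0  # rank(target) - rank(signaler) -> status j->i
    policing_elite: float = 8.0  # concentration of policing on top males
    kin_bias: float = 2.5  # same-matriline boost, grooming/huddling
    rank_affiliation: float = 1.5  # mean pair rank boost, grooming/huddling
    # weight / noise parameters
    weight_mean: float = 2.0  # zero-truncated Poisson rate
    certainty_noise: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise GenerationError("scenario needs at least 2 nodes")
        for layer, d in self.densities.items():
            if not (0.0 < d < 1.0):
                raise GenerationError(f"density for {layer!r} must be in (0,1), got {d}")
        missing = set(LAYER_NAMES) - set(self.densities)
        if missing:
            raise GenerationError(f"densities missing for layers: {sorted(missing)}")

    def null_copy(self) -> "GroupScenario":
        """Same group, all attribute effect sizes zeroed."""
        return replace(
            self,
            rank_aggression=0.0,
            rank_status=0.0,
            policing_elite=0.0,
            kin_bias=0.0,
            rank_affiliation=0.0,
        )


def default_layer_config(threshold: float = 0.99) -> LayerConfig:
    """The metric-per-layer configuration used throughout: eigenvector for
    aggression, in-degree for status, total degree for policing, betweenness
    for the two affiliation layers."""
    return LayerConfig(
        [
            LayerSpec("aggression", directed=True, metric="eigenvector", tier_threshold=threshold),
            LayerSpec("status", directed=True, metric="in_degree", tier_threshold=threshold),
            LayerSpec("policing", directed=True, metric="total_degree", tier_threshold=threshold),
            LayerSpec("grooming", directed=False, metric="betweenness", tier_threshold=threshold),
            LayerSpec("huddling", directed=False, metric="betweenness", tier_threshold=threshold),
        ]
    )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def _calibrate_intercept(f: np.ndarray, target: float) -> float:
    """Solve mean(sigmoid(theta + f)) = target for theta by bisection."""
    lo, hi = -40.0, 40.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _sigmoid(mid + f).mean() < target:
            lo = mid
        else:
            hi = mid
    theta = 0.5 * (lo + hi)
    realized = _sigmoid(theta + f).mean()
    if abs(realized - target) > 0.02:
        raise GenerationError(
            f"cannot reach density {target} (best {realized:.3f}); "
            "effect sizes too extreme for the requested density"
        )
    return theta


def _zt_poisson(rng: np.random.Generator, lam: float, size: int) -> np.ndarray:
    """Zero-truncated Poisson draws by rejection (vectorized)."""
    out = rng.poisson(lam, size)
    for _ in range(1000):
        zeros = out == 0
        if not zeros.any():
            break
        out[zeros] = rng.poisson(lam, int(zeros.sum()))
    out[out == 0] = 1  # pathological lam: floor at one observation
    return out


def _matriline_sizes(rng: np.random.Generator, n: int, p: float, cap: int) -> list[int]:
    sizes: list[int] = []
    remaining = n
    while remaining > 0:
        s = int(min(rng.geometric(p), cap, remaining))
        sizes.append(s)
        remaining -= s
    return sizes


def generate_group(scenario: GroupScenario) -> tuple[MultiplexNetwork, AttributeTable]:
    """Generate one synthetic group: five layers plus a node attribute table.

    Deterministic under ``scenario.seed``.  The latent dominance order drives
    the directed layers (aggressors and signal targets are higher ranked,
    policing out-edges concentrate on top-ranked males); grooming and
    huddling mix matriline kin blocks with a mild rank bias.
    """
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n
    nodes = [f"{scenario.name}{i:03d}" for i in range(1, n + 1)]

    n_males = scenario.n_males
    if n_males is None:
        n_males = max(1, round(n * (1.0 / 3.5)))  # male:female about 1:2.5
    is_male = np.zeros(n, dtype=bool)
    is_male[rng.choice(n, size=n_males, replace=False)] = True

    # latent dominance: fraction of the group each node outranks
    order = rng.permutation(n)  # order[k] = node index of hierarchy position k (0 = top)
    position = np.empty(n, dtype=int)
    position[order] = np.arange(n)
    rank = (n - 1 - position) / (n - 1)

    # matrilines
    sizes = _matriline_sizes(rng, n, scenario.matriline_geom_p, scenario.matriline_max)
    matriline_of = np.empty(n, dtype=int)
    shuffled = rng.permutation(n)
    pos = 0
    for m, s in enumerate(sizes):
        matriline_of[shuffled[pos : pos + s]] = m
        pos += s
    matriline_size = np.array([sizes[m] for m in matriline_of])

    # dominance certainty: U-shaped in rank (mid-hierarchy is murky)
    raw = 0.69 + 0.29 * (2.0 * np.abs(rank - 0.5)) ** 1.5
    raw = raw + rng.normal(0.0, scenario.certainty_noise, n)
    raw = np.clip(raw, 0.69, 0.98)

    age = np.round(rng.uniform(3.0, 20.0, n), 1)
    rearing = np.where(rng.random(n) < scenario.nursery_frac, "nursery", "mother")

    layers = [
        _aggression_layer(scenario, rng, nodes, rank),
        _status_layer(scenario, rng, nodes, rank),
        _policing_layer(scenario, rng, nodes, rank, is_male),
        _affiliation_layer(scenario, rng, nodes, rank, matriline_of, "grooming"),
        _affiliation_layer(scenario, rng, nodes, rank, matriline_of, "huddling"),
    ]
    for layer in layers:
        layer.add_nodes(nodes)

    attrs = AttributeTable(
        pd.DataFrame(
            {
                "node": nodes,
                "group": scenario.name,
                "sex": np.where(is_male, "male", "female"),
                "age": age,
                "dominance_rank": rank,
                "dominance_certainty": raw,
                "matriline_size": matriline_size,
                "rearing": rearing,
            }
        )
    )
    multiplex = MultiplexNetwork(nodes=list(nodes), layers=layers)
    return multiplex, attrs


def _directed_pairs(n: int) -> tuple[np.ndarray, np.ndarray]:
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    mask = i != j
    return i[mask], j[mask]


def _undirected_pairs(n: int) -> tuple[np.ndarray, np.ndarray]:
    i, j = np.triu_indices(n, k=1)
    return i, j


def _realize(
    rng: np.random.Generator,
    name: str,
    directed: bool,
    nodes: list[str],
    src: np.ndarray,
    tgt: np.ndarray,
    f: np.ndarray,
    density: float,
    weight_mean: float,
) -> Layer:
    theta = _calibrate_intercept(f, density)
    p = _sigmoid(theta + f)
    draw = rng.random(len(p)) < p
    layer = Layer(name=name, directed=directed)
    weights = _zt_poisson(rng, weight_mean, int(draw.sum()))
    for (a, b), w in zip(zip(src[draw], tgt[draw]), weights):
        layer.add_edge(nodes[a], nodes[b], float(w))
    return layer


def _aggression_layer(sc, rng, nodes, rank) -> Layer:
    src, tgt = _directed_pairs(len(nodes))
    f = sc.rank_aggression * (rank[src] - rank[tgt])
    return _realize(rng, "aggression", True, nodes, src, tgt, f,
                    sc.densities["aggression"], sc.weight_mean)


def _status_layer(sc, rng, nodes, rank) -> Layer:
    # signaler j directs the signal at a dominant i: edge j -> i
    src, tgt = _directed_pairs(len(nodes))
    f = sc.rank_status * (rank[tgt] - rank[src])
    return _realize(rng, "status", True, nodes, src, tgt, f,
                    sc.densities["status"], sc.weight_mean)


def _policing_layer(sc, rng, nodes, rank, is_male) -> Layer:
    # out-edges concentrate on top-ranked males (the group's keystone animals)
    src, tgt = _directed_pairs(len(nodes))
    elite = is_male[src] * np.maximum(rank[src] - 0.6, 0.0) / 0.4
    f = sc.policing_elite * (elite - 0.5)
    return _realize(rng, "policing", True, nodes, src, tgt, f,
                    sc.densities["policing"], sc.weight_mean)


def _affiliation_layer(sc, rng, nodes, rank, matriline_of, name) -> Layer:
    src, tgt = _undirected_pairs(len(nodes))
    kin = (matriline_of[src] == matriline_of[tgt]).astype(float)
    f = sc.kin_bias * kin + sc.rank_affiliation * (rank[src] + rank[tgt]) / 2.0
    f = f - f.mean()
    return _realize(rng, name, False, nodes, src, tgt, f,
                    sc.densities[name], sc.weight_mean)


def generate_null_attributes(table: AttributeTable, seed: int) -> AttributeTable:
    """Re-deal attribute bundles independently of the network.

    Attribute row-tuples are permuted uniformly across all nodes (marginal
    multisets preserved exactly), severing any node-network association —
    the ingredient for type-I-error studies.
    """
    rng = np.random.default_rng(seed)
    df = table.df.copy().reset_index(drop=True)
    cols = ["sex", "age", "dominance_rank", "dominance_certainty",
            "matriline_size", "rearing"]
    perm = rng.permutation(len(df))
    df[cols] = df[cols].to_numpy()[perm]
    return table.with_rows(df)


def read_scenario(path) -> GroupScenario:
    """Load a scenario from a YAML mapping of GroupScenario fields."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    preset = raw.pop("preset", None)
    if preset is not None:
        base = GROUP_PRESETS[str(preset)]
        merged = dict(name=str(preset), n=base["n"], n_males=base["n_males"],
                      matriline_max=base["matriline_max"],
                      nursery_frac=base["nursery_frac"],
                      densities=dict(base["densities"]))
        merged.update(raw)
        raw = merged
    return GroupScenario(**raw)
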