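"""Domain types and delimited-text readers/writers.

Edge lists, node attribute tables, and layer configuration files are all
plain delimited text (comma default, tab accepted, header mandatory).
Node IDs are opaque strings; every output is keyed by ID, never position.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

__all__ = [
    "Layer",
    "LayerSpec",
    "LayerConfig",
    "MultiplexNetwork",
    "AttributeTable",
    "ResultBundle",
    "ValidationError",
    "ParseError",
    "ConfigurationError",
    "read_edge_list",
    "write_edge_list",
    "read_attributes",
    "write_attributes",
    "read_layer_config",
    "assemble_multiplex",
    "matriline_category",
]

VALID_METRICS = frozenset({"eigenvector", "in_degree", "total_degree", "betweenness"})
VALID_SEX = frozenset({"male", "female"})
VALID_REARING = frozenset({"mother", "nursery"})

MATRILINE_CATEGORIES = ("1-5", "6-10", "11+")


class ValidationError(ValueError):
    """Input violates a domain invariant."""


class ParseError(ValueError):
    """Malformed delimited-text input; message names the offending line."""


class ConfigurationError(ValueError):
    """Layer configuration inconsistent with the supplied layers."""


def matriline_category(size: int) -> str:
    """Bucket a matriline member count into small/medium/large bands."""
    if size < 1:
        raise ValidationError(f"matriline size must be >= 1, got {size}")
    if size <= 5:
        return "1-5"
    if size <= 10:
        return "6-10"
    return "11+"


@dataclass
class Layer:
    """One weighted network layer over opaque string node IDs.

    Undirected layers store each unordered pair once under a sorted key;
    ``weight(u, v)`` resolves either orientation.  Weights are nonnegative
    interaction frequencies; duplicate observations accumulate.
    """

    name: str
    directed: bool
    edges: dict[tuple[str, str], float] = field(default_factory=dict)
    nodes: set[str] = field(default_factory=set)

    def _key(self, u: str, v: str) -> tuple[str, str]:
        if self.directed or u <= v:
            return (u, v)
        return (v, u)

    def add_edge(self, u: str, v: str, weight: float = 1.0) -> None:
        if weight < 0:
            raise ValidationError(
                f"layer {self.name!r}: negative weight {weight} on edge {u}->{v}"
            )
        key = self._key(u, v)
        self.edges[key] = self.edges.get(key, 0.0) + weight
        self.nodes.add(u)
        self.nodes.add(v)

    def add_nodes(self, nodes: Iterable[str]) -> None:
        self.nodes.update(nodes)

    def weight(self, u: str, v: str) -> float:
        return self.edges.get(self._key(u, v), 0.0)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def density(self) -> float:
        """Fraction of possible (ordered or unordered) node pairs with an edge."""
        n = len(self.nodes)
        if n < 2:
            return 0.0
        possible = n * (n - 1) if self.directed else n * (n - 1) // 2
        return self.n_edges / possible


@dataclass(frozen=True)
class LayerSpec:
    """Per-layer analysis configuration."""

    name: str
    directed: bool
    metric: str
    tier_threshold: float = 0.99
    path: str | None = None

    def __post_init__(self) -> None:
        if self.metric not in VALID_METRICS:
            raise ConfigurationError(
                f"layer {self.name!r}: unknown metric {self.metric!r}; "
                f"expected one of {sorted(VALID_METRICS)}"
            )
        if not (0.0 < self.tier_threshold <= 1.0):
            raise ConfigurationError(
                f"layer {self.name!r}: tier_threshold must be in (0, 1], "
                f"got {self.tier_threshold}"
            )
        if self.metric == "in_degree" and not self.directed:
            raise ConfigurationError(
                f"layer {self.name!r}: in_degree requires a directed layer"
            )


@dataclass
class LayerConfig:
    """Ordered collection of LayerSpec records, one per layer."""

    specs: list[LayerSpec]

    def __post_init__(self) -> None:
        names = [s.name for s in self.specs]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate layer names in config: {names}")

    def __iter__(self):
        return iter(self.specs)

    def __len__(self) -> int:
        return len(self.specs)

    def spec_for(self, name: str) -> LayerSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise ConfigurationError(f"no configuration for layer {name!r}")


@dataclass
class MultiplexNetwork:
    """A fixed node set shared by L named weighted layers."""

    nodes: list[str]
    layers: list[Layer]

    def __post_init__(self) -> None:
        if len(self.nodes) < 1:
            raise ValidationError("multiplex requires at least one node")
        if len(self.layers) < 1:
            raise ValidationError("multiplex requires at least one layer")
        if len(set(self.nodes)) != len(self.nodes):
            raise ValidationError("duplicate node IDs in multiplex node set")
        node_set = set(self.nodes)
        for layer in self.layers:
            stray = layer.nodes - node_set
            if stray:
                raise ValidationError(
                    f"layer {layer.name!r} has endpoints outside node set: {sorted(stray)}"
                )
            # isolates participate in every layer so all N nodes get a rank
            layer.nodes = set(self.nodes)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def layer(self, name: str) -> Layer:
        for l in self.layers:
            if l.name == name:
                return l
        raise KeyError(name)

    @property
    def layer_names(self) -> list[str]:
        return [l.name for l in self.layers]


# required columns for an attribute table, in canonical order
ATTRIBUTE_COLUMNS = [
    "node",
    "group",
    "sex",
    "age",
    "dominance_rank",
    "dominance_certainty",
    "matriline_size",
    "rearing",
]


class AttributeTable:
    """Per-node covariates: group, sex, age, dominance rank/certainty,
    matriline size, rearing history.

    Derived columns added on construction:

    * ``dc`` — transformed dominance certainty, ``1 - dominance_certainty``,
      so 0 means complete certainty and 0.5 complete ambiguity.
    * ``matriline_size_category`` — ``1-5`` / ``6-10`` / ``11+`` bands.
    """

    def __init__(self, data: pd.DataFrame):
        missing = [c for c in ATTRIBUTE_COLUMNS if c not in data.columns]
        if missing:
            raise ValidationError(f"attribute table missing columns: {missing}")
        df = data.copy()
        df["node"] = df["node"].astype(str)
        df["group"] = df["group"].astype(str)
        if df["node"].duplicated().any():
            dupes = df.loc[df["node"].duplicated(), "node"].tolist()
            raise ValidationError(f"duplicate node IDs in attribute table: {dupes}")

        bad_sex = set(df["sex"]) - VALID_SEX
        if bad_sex:
            raise ValidationError(f"unknown sex level(s): {sorted(bad_sex)}")
        bad_rearing = set(df["rearing"]) - VALID_REARING
        if bad_rearing:
            raise ValidationError(f"unknown rearing level(s): {sorted(bad_rearing)}")

        cert = df["dominance_certainty"].astype(float)
        if ((cert < 0.5) | (cert > 1.0)).any():
            bad = df.loc[(cert < 0.5) | (cert > 1.0), "node"].tolist()
            raise ValidationError(
                f"dominance_certainty outside [0.5, 1] for node(s): {bad}"
            )
        rank = df["dominance_rank"].astype(float)
        if ((rank < 0.0) | (rank > 1.0)).any():
            bad = df.loc[(rank < 0.0) | (rank > 1.0), "node"].tolist()
            raise ValidationError(f"dominance_rank outside [0, 1] for node(s): {bad}")

        df["dominance_certainty"] = cert
        df["dominance_rank"] = rank
        df["age"] = df["age"].astype(float)
        df["matriline_size"] = df["matriline_size"].astype(int)
        df["dc"] = 1.0 - cert
        df["matriline_size_category"] = df["matriline_size"].map(matriline_category)
        self._df = df.reset_index(drop=True)

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def nodes(self) -> list[str]:
        return self._df["node"].tolist()

    @property
    def groups(self) -> list[str]:
        return sorted(self._df["group"].unique())

    def __len__(self) -> int:
        return len(self._df)

    def for_group(self, group: str) -> "AttributeTable":
        sub = self._df[self._df["group"] == group]
        if sub.empty:
            raise KeyError(group)
        return AttributeTable(sub[ATTRIBUTE_COLUMNS])

    def with_rows(self, df: pd.DataFrame) -> "AttributeTable":
        return AttributeTable(df[ATTRIBUTE_COLUMNS])


@dataclass
class ResultBundle:
    """Everything a full pipeline run produces, indexed over one node set."""

    layer_rankings: dict  # layer name -> tiering.TierAssignment
    consensus: object  # consensus.ConsensusRanking
    correlations: object | None = None  # similarity.LayerCorrelationMatrix
    model_fits: list | None = None
    permutations: object | None = None


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _sniff_delimiter(path: Path) -> str:
    with open(path, newline="") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_edge_list(path: str | Path, directed: bool, name: str | None = None) -> Layer:
    """Read a weighted edge list (columns: source, target[, weight]).

    Duplicate rows are summed — weights are interaction frequencies, so
    repeated observations accumulate.  The weight column defaults to 1.
    """
    path = Path(path)
    delim = _sniff_delimiter(path)
    layer = Layer(name=name or path.stem, directed=directed)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delim)
        header = next(reader, None)
        if header is None:
            raise ParseError(f"{path}: empty file, expected a header row")
        header = [h.strip().lower() for h in header]
        try:
            i_src = header.index("source")
            i_tgt = header.index("target")
        except ValueError:
            raise ParseError(
                f"{path}: header must contain 'source' and 'target', got {header}"
            ) from None
        i_w = header.index("weight") if "weight" in header else None
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            try:
                src = row[i_src].strip()
                tgt = row[i_tgt].strip()
                w = float(row[i_w]) if i_w is not None and row[i_w].strip() else 1.0
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}: malformed row at line {lineno}: {row}") from exc
            if not src or not tgt:
                raise ParseError(f"{path}: empty node ID at line {lineno}")
            if w < 0:
                raise ValidationError(
                    f"{path}: negative weight {w} at line {lineno}"
                )
            layer.add_edge(src, tgt, w)
    return layer


def write_edge_list(layer: Layer, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["source", "target", "weight"])
        for (u, v), w in sorted(layer.edges.items()):
            writer.writerow([u, v, repr(w)])


def read_attributes(path: str | Path) -> AttributeTable:
    path = Path(path)
    delim = _sniff_delimiter(path)
    df = pd.read_csv(path, sep=delim, dtype={"node": str, "group": str})
    return AttributeTable(df)


def write_attributes(table: AttributeTable, path: str | Path) -> None:
    table.df[ATTRIBUTE_COLUMNS].to_csv(path, index=False)


def read_layer_config(path: str | Path) -> LayerConfig:
    """Read a YAML layer configuration.

    Format::

        layers:
          - name: aggression
            path: aggression.csv
            directed: true
            metric: eigenvector
            threshold: 0.99
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping) or "layers" not in raw:
        raise ConfigurationError(f"{path}: expected a top-level 'layers' list")
    specs = []
    for entry in raw["layers"]:
        try:
            specs.append(
                LayerSpec(
                    name=str(entry["name"]),
                    directed=bool(entry["directed"]),
                    metric=str(entry["metric"]),
                    tier_threshold=float(entry.get("threshold", 0.99)),
                    path=entry.get("path"),
                )
            )
        except KeyError as exc:
            raise ConfigurationError(f"{path}: layer entry missing key {exc}") from None
    return LayerConfig(specs)


def assemble_multiplex(
    layers: list[Layer],
    config: LayerConfig,
    attributes: AttributeTable | None = None,
) -> MultiplexNetwork:
    """Combine layers into a multiplex over the union node set.

    The node set is the union of all edge endpoints plus any nodes listed in
    the attribute table; nodes absent from a layer become isolates there.
    """
    layer_names = [l.name for l in layers]
    if len(set(layer_names)) != len(layer_names):
        raise ConfigurationError(f"duplicate layer names: {layer_names}")
    config_names = {s.name for s in config}
    if set(layer_names) != config_names:
        raise ConfigurationError(
            f"config/layer name mismatch: layers={sorted(layer_names)} "
            f"config={sorted(config_names)}"
        )
    for layer in layers:
        spec = config.spec_for(layer.name)
        if spec.directed != layer.directed:
            raise ConfigurationError(
                f"layer {layer.name!r}: directedness disagrees with config"
            )
    nodes: set[str] = set()
    for layer in layers:
        nodes |= layer.nodes
    if attributes is not None:
        nodes |= set(attributes.nodes)
    ordered = [l for l in layers]  # preserve supplied layer order
    return MultiplexNetwork(nodes=sorted(nodes), layers=ordered)
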