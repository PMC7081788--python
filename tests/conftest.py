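import numpy as np
import pandas as pd
import pytest

from plexrank.core_io import AttributeTable, Layer


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_layer(rng, n_nodes, directed, p_edge=0.4, name="L", max_w=5.0):
    """Random weighted layer over nodes n0..n{k-1}; weights in (0, max_w]."""
    nodes = [f"n{i}" for i in range(n_nodes)]
    layer = Layer(name=name, directed=directed)
    layer.add_nodes(nodes)
    for i in range(n_nodes):
        for j in range(n_nodes):
            if i == j:
                continue
            if not directed and i > j:
                continue
            if rng.random() < p_edge:
                layer.add_edge(nodes[i], nodes[j], float(rng.uniform(0.1, max_w)))
    return layer


def small_attribute_frame(n=12, group="G1", seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "node": [f"a{i}" for i in range(n)],
            "group": group,
            "sex": rng.choice(["male", "female"], n),
            "age": rng.uniform(3, 20, n).round(1),
            "dominance_rank": np.linspace(0, 1, n),
            "dominance_certainty": rng.uniform(0.69, 0.98, n).round(3),
            "matriline_size": rng.integers(1, 20, n),
            "rearing": rng.choice(["mother", "nursery"], n, p=[0.9, 0.1]),
        }
    )


@pytest.fixture
def attribute_table():
    return AttributeTable(small_attribute_frame())
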