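import networkx as nx
import numpy as np
import pytest

from micronet import OtuTable, SyntheticParams, generate_community
from micronet.preprocess import AbundanceMatrix


@pytest.fixture
def small_table() -> OtuTable:
    """3 OTUs x 2 samples with taxonomy."""
    return OtuTable(
        otu_ids=["otu1", "otu2", "otu3"],
        sample_ids=["s1", "s2"],
        counts=np.array([[5, 0], [2, 3], [1, 7]]),
        lineages=[
            "k__Bacteria; p__Firmicutes; c__Clostridia",
            "Bacteria|Firmicutes|Clostridia|Clostridiales",
            "k__Bacteria; p__Bacteroidetes",
        ],
    )


@pytest.fixture
def two_cliques() -> nx.Graph:
    """Two 4-cliques joined by a single bridge edge."""
    g = nx.Graph()
    for base in ("a", "b"):
        nodes = [f"{base}{i}" for i in range(4)]
        for i, u in enumerate(nodes):
            for v in nodes[i + 1:]:
                g.add_edge(u, v, weight=1.0, sign="+")
    g.add_edge("a0", "b0", weight=1.0, sign="+")
    return g


@pytest.fixture
def synthetic_community():
    params = SyntheticParams(n_samples=30, module_sizes=(20, 20, 20),
                             n_background=0, loading=1.0, noise_sd=0.3,
                             dropout=0.0, seed=7)
    return generate_community(params)


def abundance_from(values: np.ndarray, log: bool = True) -> AbundanceMatrix:
    """Wrap a raw value matrix as a (log-flagged) AbundanceMatrix for tests."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return AbundanceMatrix([f"o{i}" for i in range(n)],
                           [f"s{j}" for j in range(m)],
                           values, log_transformed=log)
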