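import numpy as np
import pytest

from subcomp.hic_graph import ContactGraph, make_bin_table
from subcomp import synthetic_data as sd


def toy_graph(n_nodes: int, edges) -> ContactGraph:
    """Graph with one bin per chromosome, so any node pair may be linked."""
    bins = make_bin_table({f"c{i}": 100 for i in range(n_nodes)}, 100)
    edges = sorted((min(i, j), max(i, j), float(w)) for i, j, w in edges)
    ei = np.array([e[0] for e in edges], dtype=np.int64)
    ej = np.array([e[1] for e in edges], dtype=np.int64)
    ew = np.array([e[2] for e in edges], dtype=np.float64)
    return ContactGraph(bins, ei, ej, ew)


def random_toy_graph(rng: np.random.Generator, n_nodes: int,
                     p_edge: float = 0.5, integer_weights: bool = False
                     ) -> ContactGraph:
    edges = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                w = float(rng.integers(1, 9)) if integer_weights \
                    else float(rng.uniform(0.5, 5.0))
                edges.append((i, j, w))
    if not edges:
        edges = [(0, 1, 1.0)]
    return toy_graph(n_nodes, edges)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def planted():
    """Small planted-partition dataset shared across tests."""
    cfg = sd.SimConfig(n_chroms=4, bins_per_chrom=15, K=3, mu_in=20.0,
                       mu_out=2.0, n_loops=400, seed=11)
    bins, graph, labels = sd.simulate_hic(cfg)
    return cfg, bins, graph, labels
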