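import numpy as np
import pytest

import biparclust as bp
from biparclust.bipartite import BipartiteNetwork


@pytest.fixture()
def toy():
    """Deterministic two-block 8-case x 12-gene fixture with metadata."""
    return bp.worked_toy()


@pytest.fixture()
def toy_network(toy):
    matrix, _records = toy
    return bp.build_network(matrix, matrix.gene_ids)


@pytest.fixture(scope="session")
def study_data():
    """Study-shaped synthetic dataset: 44 ROIs (33 cases + 11 TNIL), 1,000 genes."""
    return bp.study_shaped(seed=3)


@pytest.fixture(scope="session")
def study_network(study_data):
    matrix, records, _truth = study_data
    log2 = bp.log2_transform(matrix)
    selected = bp.select_top_cv(bp.gene_cv(log2), 0.10)
    cases, _ = bp.split_cases_controls(matrix, records)
    return bp.build_network(cases, selected)


def random_network(rng: np.random.Generator, n: int, d: int) -> BipartiteNetwork:
    """Random sparse-ish nonnegative network with at least one edge."""
    weights = rng.random((n, d)) * rng.integers(0, 2, size=(n, d))
    if weights.sum() == 0:
        weights[0, 0] = 1.0
    return BipartiteNetwork(
        [f"c{i}" for i in range(n)], [f"g{j}" for j in range(d)], weights
    )


def block_network(k: int, n_per: int = 3, d_per: int = 4) -> BipartiteNetwork:
    """k equal disjoint unit-weight blocks; optimum Q = 1 - 1/k."""
    weights = np.zeros((k * n_per, k * d_per))
    for b in range(k):
        weights[b * n_per : (b + 1) * n_per, b * d_per : (b + 1) * d_per] = 1.0
    return BipartiteNetwork(
        [f"c{i}" for i in range(k * n_per)],
        [f"g{j}" for j in range(k * d_per)],
        weights,
    )


def set_partitions(elements):
    """All set partitions (exhaustive-search oracle helper)."""
    if not elements:
        yield []
        return
    first, rest = elements[0], elements[1:]
    for partition in set_partitions(rest):
        for i in range(len(partition)):
            yield partition[:i] + [[first] + partition[i]] + partition[i + 1 :]
        yield [[first]] + partition


def exhaustive_best_q(network: BipartiteNetwork) -> float:
    """Brute-force maximum Barber modularity over all joint set partitions."""
    n, d = network.n_cases, network.n_genes
    best = -2.0
    for partition in set_partitions(list(range(n + d))):
        case_labels = np.zeros(n, dtype=int)
        gene_labels = np.zeros(d, dtype=int)
        for label, group in enumerate(partition):
            for element in group:
                if element < n:
                    case_labels[element] = label
                else:
                    gene_labels[element - n] = label
        best = max(best, bp.modularity(network, case_labels, gene_labels))
    return best
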