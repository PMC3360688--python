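"""Shared fixtures: small synthetic templates, samples and trees."""

import numpy as np
import pytest

from cytoemd import (
    CellMatrix,
    ClusterAssignment,
    SpadeTree,
    build_tree,
    make_template,
    normalize_fsc,
    simulate_sample,
)


@pytest.fixture(scope="session")
def template():
    """Default-condition template (8 populations, 8 tubes, effect 1.5)."""
    return make_template(seed=11)


@pytest.fixture(scope="session")
def small_template():
    """Smaller template for fast unit tests: 4 populations, 2 full-panel tubes."""
    return make_template(n_populations=4, n_tubes=2, effect_size=1.5, seed=12)


@pytest.fixture(scope="session")
def normal_sample(template):
    """One normal sample (tube 2 panel), FSC already rescaled."""
    tubes = simulate_sample(template, "normal", 3000, seed=21, sample_id="n1")
    return normalize_fsc(tubes[1])


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_tree(rng, n_nodes, n_channels=2):
    """Uniformly random spanning tree (each node attaches to a prior node)."""
    edges = np.array(
        [[int(rng.integers(0, i)), i] for i in range(1, n_nodes)], dtype=int
    ).reshape(-1, 2)
    lengths = rng.uniform(0.1, 3.0, size=max(n_nodes - 1, 0))
    return SpadeTree(
        node_medians=rng.normal(size=(n_nodes, n_channels)),
        edges=edges,
        edge_lengths=lengths,
    )


def path_tree(n_nodes, lengths=None):
    """Path graph 0-1-...-(n-1)."""
    edges = np.array([[i, i + 1] for i in range(n_nodes - 1)], dtype=int)
    if lengths is None:
        lengths = np.ones(n_nodes - 1)
    return SpadeTree(
        node_medians=np.arange(n_nodes, dtype=float)[:, None],
        edges=edges,
        edge_lengths=np.asarray(lengths, dtype=float),
    )


def make_cells(values, channels=("FSC", "SSC"), sample_id="s", tube_id=1):
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    if values.shape[1] < len(channels):
        pad = np.zeros((values.shape[0], len(channels) - values.shape[1]))
        values = np.hstack([values, pad])
    return CellMatrix(sample_id, tube_id, list(channels), values)


def kruskal_total(D):
    """Independent MST oracle: textbook Kruskal with union-find."""
    K = D.shape[0]
    order = sorted((D[i, j], i, j) for i in range(K) for j in range(i + 1, K))
    parent = list(range(K))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    total, used = 0.0, 0
    for w, i, j in order:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            total += w
            used += 1
            if used == K - 1:
                break
    return total
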