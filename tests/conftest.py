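import numpy as np
import pytest

from layerseg import (
    FigureSpec,
    PipelineConfig,
    add_dummy_node,
    build_grid_graph,
    generate_figure,
    segment_parts,
)
from layerseg.arms import compute_hand_probabilities


@pytest.fixture(scope="session")
def crossing():
    """Noise-free frontal figure with the right forearm crossing the torso."""
    return generate_figure(FigureSpec(pose="crossing"))


@pytest.fixture(scope="session")
def hanging():
    """Noise-free figure with both arms hanging (no occlusion)."""
    return generate_figure(FigureSpec(pose="hanging"))


@pytest.fixture(scope="session")
def crossing_hand_probs(crossing):
    """Hand probability maps on the dummy-augmented flat graph."""
    depth, mask, truth, parts = crossing
    g = add_dummy_node(build_grid_graph(depth, mask, 90.0), 1e-3)
    right = parts.by_name("right_hand")
    left = parts.by_name("left_hand")
    p_r, p_l = compute_hand_probabilities(g, right.pos, left.pos)
    return g, p_r, p_l


@pytest.fixture(scope="session")
def crossing_run(crossing):
    """Full layered pipeline run on the crossing figure, with details."""
    depth, mask, truth, parts = crossing
    labels, details = segment_parts(depth, mask, parts, PipelineConfig(),
                                    return_details=True)
    return labels, details


def random_weighted_graph(rng, max_nodes=12):
    """A small random connected WeightedGraph plus a seeded label set.

    Built on a random spanning tree with extra random edges and weights in
    (0, 1]; used as input for solver-vs-oracle comparisons.
    """
    from layerseg.graph import BASE, WeightedGraph
    from layerseg.random_walker import SeedSet

    n = int(rng.integers(3, max_nodes + 1))
    g = WeightedGraph((1, n))
    g.add_layer(BASE, np.ones((1, n), dtype=bool))
    edges = set()
    order = rng.permutation(n)
    for i in range(1, n):  # random spanning tree keeps the graph connected
        u = int(order[i])
        v = int(order[rng.integers(0, i)])
        edges.add((min(u, v), max(u, v)))
    for _ in range(int(rng.integers(0, n))):
        u, v = rng.choice(n, size=2, replace=False)
        edges.add((min(u, v), max(u, v)))
    e = sorted(edges)
    w = rng.uniform(0.05, 1.0, len(e))
    g.add_edges([u for u, _ in e], [v for _, v in e], w)

    k = int(rng.integers(2, 4))
    seed_nodes = rng.choice(n, size=k, replace=False)
    seeds = SeedSet([(int(s), i + 1) for i, s in enumerate(seed_nodes)], k)
    return g, seeds


def absorption_probabilities(graph, seeds):
    """Brute-force absorbing-Markov-chain oracle for the random walker.

    Transition probabilities proportional to edge weights; seed nodes
    absorbing.  Returns the (n, k) matrix of per-label absorption
    probabilities computed by dense matrix inversion.
    """
    W = graph.adjacency().toarray()
    n = W.shape[0]
    P = W / W.sum(axis=1, keepdims=True)
    seed_nodes = seeds.nodes
    free = np.setdiff1d(np.arange(n), seed_nodes)
    Q = P[np.ix_(free, free)]
    R = P[np.ix_(free, seed_nodes)]
    A = np.linalg.solve(np.eye(free.size) - Q, R)  # (I - Q)^-1 R
    probs = np.zeros((n, seeds.k))
    onehot = np.zeros((seed_nodes.size, seeds.k))
    onehot[np.arange(seed_nodes.size), seeds.labels - 1] = 1.0
    probs[seed_nodes] = onehot
    probs[free] = A @ onehot
    return probs
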