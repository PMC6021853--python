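"""Seeded multi-label random-walker solver on weighted graphs.

For each label, the probability that a random walker starting at an
unlabelled node reaches a seed of that label first is the solution of the
combinatorial Dirichlet problem: the harmonic function on the graph
Laplacian with boundary values 1 at that label's seeds and 0 at all other
seeds.  Equivalently, with edge conductances equal to the weights, it is the
electric potential when the label's seeds are held at unit potential and the
rest are grounded.  Solving k sparse linear systems replaces any actual walk
simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import cg, splu

from .graph import BASE, WeightedGraph

__all__ = ["SeedSet", "ProbabilityImage", "solve_random_walker", "assign_labels"]


@dataclass
class SeedSet:
    """Seed nodes with labels ``1..k``.

    Duplicate (node, label) entries collapse; the same node with two
    different labels is an error, as is a label in ``1..k`` without a seed.
    """

    entries: list
    k: int

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be at least 1")
        seen: dict[int, int] = {}
        for node, label in self.entries:
            node, label = int(node), int(label)
            if not 1 <= label <= self.k:
                raise ValueError(f"label {label} outside 1..{self.k}")
            if seen.get(node, label) != label:
                raise ValueError(
                    f"node {node} seeded with conflicting labels "
                    f"{seen[node]} and {label}"
                )
            seen[node] = label
        missing = set(range(1, self.k + 1)) - set(seen.values())
        if missing:
            raise ValueError(f"labels without any seed: {sorted(missing)}")
        self.entries = sorted(seen.items())

    @property
    def nodes(self) -> np.ndarray:
        return np.array([n for n, _ in self.entries], dtype=np.int64)

    @property
    def labels(self) -> np.ndarray:
        return np.array([l for _, l in self.entries], dtype=np.int64)


@dataclass
class ProbabilityImage:
    """Per-node probabilities of one label on a graph.

    ``values[i]`` is the probability that a walker from node ``i`` first
    reaches a seed of ``label``.  :meth:`image` renders one layer as a 2-D
    float image with NaN off-layer.
    """

    graph: WeightedGraph
    values: np.ndarray
    label: int

    def image(self, layer: str = BASE) -> np.ndarray:
        out = np.full(self.graph.shape, np.nan)
        ids = self.graph.node_ids(layer)
        mask = self.graph.layer_masks[layer]
        out[mask] = self.values[ids[mask]]
        return out

    def save(self, path, layer: str = BASE) -> None:
        """Debug dump of one layer as 32-bit float TIFF or CSV text grid."""
        from pathlib import Path

        path = Path(path)
        img = self.image(layer).astype(np.float32)
        if path.suffix.lower() in (".tif", ".tiff"):
            import tifffile

            tifffile.imwrite(path, img)
        else:
            np.savetxt(path, img, fmt="%.9g", delimiter=",")


def solve_random_walker(
    graph: WeightedGraph,
    seeds: SeedSet,
    direct_max_nodes: int = 300_000,
    cg_tol: float = 1e-8,
) -> list[ProbabilityImage]:
    """Solve the seeded random-walker problem; one probability map per label.

    Seed nodes get probability 1 for their own label and 0 for the others.
    Every connected component of the graph must contain at least one seed
    (otherwise the Dirichlet problem has no boundary there).  Uses a sparse
    LU factorization shared across labels, or conjugate gradients above
    ``direct_max_nodes`` nodes.
    """
    n = graph.n_nodes
    k = seeds.k
    seed_nodes = seeds.nodes
    if seed_nodes.size and seed_nodes.max() >= n:
        raise ValueError("seed node id outside the graph")

    adj = graph.adjacency()
    n_comp, comp = connected_components(adj, directed=False)
    seeded_comps = set(comp[seed_nodes].tolist())
    for c in range(n_comp):
        if c not in seeded_comps:
            size = int(np.sum(comp == c))
            raise ValueError(
                f"connected component {c} ({size} node(s)) contains no seed"
            )

    probs = np.zeros((n, k))
    onehot = np.zeros((seed_nodes.size, k))
    onehot[np.arange(seed_nodes.size), seeds.labels - 1] = 1.0
    probs[seed_nodes] = onehot

    is_seed = np.zeros(n, dtype=bool)
    is_seed[seed_nodes] = True
    free = np.nonzero(~is_seed)[0]
    if free.size and k > 1:
        lap = graph.laplacian().tocsr()
        l_uu = lap[free][:, free]
        b = lap[free][:, seed_nodes]
        rhs = -b @ onehot
        rhs = np.asarray(rhs)
        if n <= direct_max_nodes:
            x = splu(l_uu.tocsc()).solve(rhs)
        else:
            x = np.empty_like(rhs)
            for j in range(k):
                x[:, j], info = cg(l_uu, rhs[:, j], rtol=cg_tol, atol=0.0)
                if info != 0:
                    raise RuntimeError(f"CG failed for label {j + 1}: {info}")
        probs[free] = np.clip(x, 0.0, 1.0)
    elif free.size:  # single label: everything reaches it
        probs[free] = 1.0

    return [ProbabilityImage(graph, probs[:, j], j + 1) for j in range(k)]


def assign_labels(probs: list[ProbabilityImage]) -> np.ndarray:
    """Per-node argmax label; exact ties go to the lowest label index."""
    if not probs:
        raise ValueError("no probability maps given")
    n = probs[0].values.size
    g = probs[0].graph
    for p in probs:
        if p.values.size != n or p.graph is not g:
            raise ValueError("probability maps are on mismatched node sets")
    stacked = np.stack([p.values for p in probs], axis=1)
    return np.argmax(stacked, axis=1) + 1
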