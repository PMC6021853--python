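"""Grid-graph construction: flat, dummy-augmented and layered graphs.

A depth image with a foreground mask is turned into an undirected weighted
graph with one node per foreground pixel and edges between 4-adjacent pixels.
The edge weight between pixels ``u`` and ``v`` is

    w_uv = exp(-beta * (i_u - i_v)^2 / max_squared_difference)

i.e. the standard random-walker weighting of the squared depth difference,
normalized across the image by the maximum squared difference over all
4-adjacent foreground pairs, so the exponent lies in ``[-beta, 0]`` and
``beta`` is dimensionless.  The same image-wide constant is used for every
graph built from a frame (flat or layered), keeping their weights
comparable.

Self-occlusion by the arms is modelled by a *layered* graph: a base layer
with one node per foreground pixel whose depths are smoothly interpolated
across the occluding-arm regions, plus one extra layer per validated arm
carrying the original (nearer) arm depths.  A pixel inside an arm segment is
therefore represented twice.  The layers are joined by unit-weight edges at
the low-gradient part of the arm's inner boundary, where the arm physically
connects to the body.
"""

from __future__ import annotations

import logging

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from .cluster import mean_shift_1d, nearest_centroid
from .images import DepthImage, as_depth, as_mask

logger = logging.getLogger(__name__)

#: Layer identifiers.
BASE = "base"
RIGHT = "right"
LEFT = "left"
DUMMY = "dummy"

__all__ = [
    "BASE",
    "RIGHT",
    "LEFT",
    "DUMMY",
    "WeightedGraph",
    "build_grid_graph",
    "max_squared_difference",
    "add_dummy_node",
    "interpolate_base_depth",
    "build_layered_graph",
    "connect_layers",
]


class WeightedGraph:
    """An undirected weighted graph over (layer, row, col) pixel nodes.

    Nodes are identified by integer ids ``0..n-1``; each id maps to a key
    ``(layer, row, col)`` (the dummy node, if present, has the key
    ``("dummy", -1, -1)``).  Edges are stored once, as parallel arrays
    ``edges_u``, ``edges_v``, ``weights``.
    """

    def __init__(self, shape: tuple[int, int]):
        self.shape = tuple(shape)
        self._keys: list[tuple[str, int, int]] = []
        self._index: dict[tuple[str, int, int], int] = {}
        self.edges_u = np.empty(0, dtype=np.int64)
        self.edges_v = np.empty(0, dtype=np.int64)
        self.weights = np.empty(0, dtype=float)
        self.dummy_node: int | None = None
        #: pixel membership per layer (boolean image per layer id)
        self.layer_masks: dict[str, np.ndarray] = {}
        #: depth image used to weight base-layer edges (set for layered graphs)
        self.base_depth: np.ndarray | None = None

    # -- node bookkeeping -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self._keys)

    @property
    def n_edges(self) -> int:
        return self.edges_u.size

    def add_layer(self, layer: str, mask: np.ndarray) -> np.ndarray:
        """Add one node per true pixel of ``mask`` (row-major order).

        Returns an (H, W) array of node ids, -1 where the layer has no node.
        """
        if layer in self.layer_masks:
            raise ValueError(f"layer {layer!r} already exists")
        mask = np.asarray(mask, dtype=bool)
        rows, cols = np.nonzero(mask)
        start = self.n_nodes
        ids = np.full(self.shape, -1, dtype=np.int64)
        ids[rows, cols] = start + np.arange(rows.size)
        for r, c in zip(rows.tolist(), cols.tolist()):
            key = (layer, r, c)
            self._index[key] = len(self._keys)
            self._keys.append(key)
        self.layer_masks[layer] = mask
        return ids

    def node_id(self, layer: str, row: int, col: int) -> int:
        try:
            return self._index[(layer, int(row), int(col))]
        except KeyError:
            raise KeyError(
                f"no node on layer {layer!r} at pixel ({row}, {col})"
            ) from None

    def has_node(self, layer: str, row: int, col: int) -> bool:
        return (layer, int(row), int(col)) in self._index

    def node_key(self, node: int) -> tuple[str, int, int]:
        return self._keys[node]

    def node_ids(self, layer: str) -> np.ndarray:
        """(H, W) array of node ids for ``layer``; -1 off-layer."""
        ids = np.full(self.shape, -1, dtype=np.int64)
        mask = self.layer_masks[layer]
        rows, cols = np.nonzero(mask)
        ids[rows, cols] = [self._index[(layer, r, c)] for r, c in
                           zip(rows.tolist(), cols.tolist())]
        return ids

    # -- edges ------------------------------------------------------------

    def add_edges(self, u: np.ndarray, v: np.ndarray, w: np.ndarray) -> None:
        u = np.asarray(u, dtype=np.int64)
        v = np.asarray(v, dtype=np.int64)
        w = np.asarray(w, dtype=float)
        if np.any(u == v):
            raise ValueError("self-loops are not allowed")
        if w.size and (np.any(w <= 0) or np.any(w > 1)):
            raise ValueError("edge weights must lie in (0, 1]")
        self.edges_u = np.concatenate([self.edges_u, u])
        self.edges_v = np.concatenate([self.edges_v, v])
        self.weights = np.concatenate([self.weights, w])

    def adjacency(self) -> sp.csr_matrix:
        """Symmetric sparse weighted adjacency matrix."""
        n = self.n_nodes
        a = sp.coo_matrix(
            (self.weights, (self.edges_u, self.edges_v)), shape=(n, n)
        )
        return (a + a.T).tocsr()

    def laplacian(self) -> sp.csr_matrix:
        """Combinatorial graph Laplacian ``L = D - W``."""
        w = self.adjacency()
        deg = np.asarray(w.sum(axis=1)).ravel()
        return (sp.diags(deg) - w).tocsr()

    def copy(self) -> "WeightedGraph":
        g = WeightedGraph(self.shape)
        g._keys = list(self._keys)
        g._index = dict(self._index)
        g.edges_u = self.edges_u.copy()
        g.edges_v = self.edges_v.copy()
        g.weights = self.weights.copy()
        g.dummy_node = self.dummy_node
        g.layer_masks = {k: v.copy() for k, v in self.layer_masks.items()}
        g.base_depth = None if self.base_depth is None else self.base_depth.copy()
        return g

    def dump_edges(self, path) -> None:
        """Debug dump of the edge list as CSV (node_u, node_v, weight)."""
        arr = np.column_stack([self.edges_u, self.edges_v, self.weights])
        np.savetxt(path, arr, fmt=["%d", "%d", "%.17g"], delimiter=",",
                   header="node_u,node_v,weight", comments="")


# -- flat grid graph ------------------------------------------------------


def _grid_edge_pairs(ids: np.ndarray, mask: np.ndarray, values: np.ndarray):
    """4-neighbourhood edges among true pixels: (u, v, squared depth diff)."""
    vals = values.astype(float)
    us, vs, d2 = [], [], []
    # horizontal neighbours
    m = mask[:, :-1] & mask[:, 1:]
    us.append(ids[:, :-1][m])
    vs.append(ids[:, 1:][m])
    d2.append((vals[:, :-1][m] - vals[:, 1:][m]) ** 2)
    # vertical neighbours
    m = mask[:-1, :] & mask[1:, :]
    us.append(ids[:-1, :][m])
    vs.append(ids[1:, :][m])
    d2.append((vals[:-1, :][m] - vals[1:, :][m]) ** 2)
    return np.concatenate(us), np.concatenate(vs), np.concatenate(d2)


def _weights_from_sqdiff(d2: np.ndarray, beta: float,
                         norm: float | None = None) -> np.ndarray:
    """exp(-beta * d2 / norm); all ones when every difference is zero.

    ``norm`` is the image-wide maximum squared depth difference over
    4-adjacent foreground pairs; it defaults to ``max(d2)``.  Keeping the
    normalization a property of the image (not of a particular graph) makes
    flat and layered graphs of the same frame directly comparable: the
    layered graph, having interpolated away the occlusion step, would
    otherwise rescale sensor noise into near-impassable barriers.
    """
    if d2.size == 0:
        return d2.copy()
    mx = d2.max() if norm is None else float(norm)
    if mx == 0:
        return np.ones_like(d2)
    return np.exp(-beta * (d2 / mx))


def max_squared_difference(depth, mask) -> float:
    """Image-wide max squared depth difference over 4-adjacent foreground pairs."""
    depth = as_depth(depth)
    mask = as_mask(mask, depth.shape)
    ids = np.full(depth.shape, -1, dtype=np.int64)
    _, _, d2 = _grid_edge_pairs(ids, mask, depth.values)
    return float(d2.max()) if d2.size else 0.0


def build_grid_graph(depth, mask, beta: float = 90.0) -> WeightedGraph:
    """Build the flat 4-neighbourhood grid graph over the foreground.

    One node per foreground pixel; an edge for every 4-adjacent foreground
    pixel pair, weighted by ``exp(-beta * normalized squared depth
    difference)``.  Background pixels have no node.
    """
    if not beta > 0:
        raise ValueError(f"beta must be positive, got {beta}")
    depth = as_depth(depth)
    mask = as_mask(mask, depth.shape)
    g = WeightedGraph(depth.shape)
    ids = g.add_layer(BASE, mask)
    u, v, d2 = _grid_edge_pairs(ids, mask, depth.values)
    g.add_edges(u, v, _weights_from_sqdiff(d2, beta))
    return g


def add_dummy_node(graph: WeightedGraph, w: float = 1e-3) -> WeightedGraph:
    """Return a copy of ``graph`` with a dummy node tied to every pixel node.

    The dummy node is connected to each existing node by an edge of small
    weight ``w``.  It gives a random walker everywhere a small escape
    probability, which restores variance to the hand probabilities when a
    depth barrier would otherwise saturate them at 0 or 1.
    """
    if not 0 < w < 1:
        raise ValueError(f"dummy weight must lie in (0, 1), got {w}")
    if graph.dummy_node is not None:
        raise ValueError("graph already has a dummy node")
    g = graph.copy()
    n = g.n_nodes
    key = (DUMMY, -1, -1)
    g._index[key] = n
    g._keys.append(key)
    g.dummy_node = n
    pix = np.arange(n, dtype=np.int64)
    g.add_edges(np.full(n, n, dtype=np.int64), pix, np.full(n, float(w)))
    return g


# -- depth interpolation and layered graph --------------------------------


def interpolate_base_depth(depth, mask, arm_masks) -> DepthImage:
    """Fill arm regions of the base layer with smoothly interpolated depths.

    Background pixels stand at the median foreground depth for the purpose of
    interpolation; each arm region is then filled by solving the discrete
    Laplace equation with Dirichlet boundary conditions taken from the
    surrounding pixels, so each filled value equals the mean of its
    4-neighbours (inward interpolation).  Outside the arm regions the
    returned image equals the input.
    """
    depth = as_depth(depth)
    mask = as_mask(mask, depth.shape)
    out = depth.values.astype(float).copy()
    if len(arm_masks) == 0:
        return DepthImage(out, depth.meters_per_unit)

    unknown = np.zeros(depth.shape, dtype=bool)
    for am in arm_masks:
        am = np.asarray(am, dtype=bool)
        if am.shape != depth.shape:
            raise ValueError("arm mask shape does not match the image")
        if np.any(am & ~mask):
            raise ValueError("arm masks must lie inside the foreground")
        unknown |= am
    if not unknown.any():
        return DepthImage(out, depth.meters_per_unit)
    if not np.any(mask & ~unknown):
        raise ValueError("arm masks cover the entire foreground")

    median_depth = float(np.median(depth.values[mask]))
    boundary = out.copy()
    boundary[~mask] = median_depth

    h, w = depth.shape
    ids = np.full((h, w), -1, dtype=np.int64)
    rows, cols = np.nonzero(unknown)
    n = rows.size
    ids[rows, cols] = np.arange(n)

    diag = np.zeros(n)
    rhs = np.zeros(n)
    off_u, off_v = [], []
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        nr, nc = rows + dr, cols + dc
        inside = (nr >= 0) & (nr < h) & (nc >= 0) & (nc < w)
        diag += inside  # pixels outside the image do not enter the stencil
        ni = np.where(inside, ids[nr % h, nc % w], -1)
        free = inside & (ni >= 0)
        fixed = inside & (ni < 0)
        off_u.append(ids[rows[free], cols[free]])
        off_v.append(ni[free])
        np.add.at(rhs, ids[rows[fixed], cols[fixed]],
                  boundary[nr[fixed], nc[fixed]])
    off_u = np.concatenate(off_u)
    off_v = np.concatenate(off_v)
    a = sp.coo_matrix(
        (np.concatenate([diag, -np.ones(off_u.size)]),
         (np.concatenate([np.arange(n), off_u]),
          np.concatenate([np.arange(n), off_v]))),
        shape=(n, n),
    ).tocsc()
    out[rows, cols] = spsolve(a, rhs)
    return DepthImage(out, depth.meters_per_unit)


def build_layered_graph(depth, mask, valid_arms, beta: float = 90.0) -> WeightedGraph:
    """Build the layered grid graph: base layer plus one layer per valid arm.

    The base layer spans the whole foreground with interpolated depths over
    the arm regions; each arm layer spans its segment with the original
    depths.  All squared depth differences are normalized jointly before
    weighting, so the weights of different layers are comparable.  No
    inter-layer edges are added here (see :func:`connect_layers`).

    With no valid arms this degenerates to the flat grid graph.
    """
    if not beta > 0:
        raise ValueError(f"beta must be positive, got {beta}")
    depth = as_depth(depth)
    mask = as_mask(mask, depth.shape)
    arms = list(valid_arms)
    if len(arms) > 2:
        raise ValueError("at most two arm segments are supported")
    for i, a in enumerate(arms):
        for b in arms[i + 1:]:
            if np.any(a.mask & b.mask):
                raise ValueError("arm segments overlap")

    interp = interpolate_base_depth(depth, mask, [a.mask for a in arms])
    g = WeightedGraph(depth.shape)
    base_ids = g.add_layer(BASE, mask)
    us, vs, d2s = [], [], []
    u, v, d2 = _grid_edge_pairs(base_ids, mask, interp.values)
    us.append(u); vs.append(v); d2s.append(d2)
    for a in arms:
        if a.side not in (RIGHT, LEFT):
            raise ValueError(f"unknown arm side {a.side!r}")
        ids = g.add_layer(a.side, a.mask)
        u, v, d2 = _grid_edge_pairs(ids, a.mask, depth.values)
        us.append(u); vs.append(v); d2s.append(d2)
    d2 = np.concatenate(d2s)
    norm = max_squared_difference(depth, mask)
    g.add_edges(np.concatenate(us), np.concatenate(vs),
                _weights_from_sqdiff(d2, beta, norm=norm or None))
    g.base_depth = interp.values
    logger.info(
        "layered graph: %d nodes (%d foreground + %s arm pixels)",
        g.n_nodes, int(mask.sum()),
        "+".join(str(int(a.mask.sum())) for a in arms) or "0",
    )
    return g


def connect_layers(
    lg: WeightedGraph,
    arm,
    grad: np.ndarray,
    bandwidth: float | None = None,
    quantile: float = 0.07,
) -> WeightedGraph:
    """Join an arm layer to the base layer through low-gradient boundary pixels.

    The probability-gradient values on the arm's inner boundary ``B_inner``
    are clustered with mean shift; ``B_connect`` is the subset belonging to
    the lowest-value cluster — the part of the boundary where the arm meets
    the body rather than occluding it.  For each pixel of ``B_connect`` a
    unit-weight edge is inserted between its base node and its arm node.
    Modifies ``lg`` in place (and records ``B_connect`` on ``arm``) and
    returns it.
    """
    if arm.side not in lg.layer_masks:
        raise ValueError(f"layered graph has no {arm.side!r} layer")
    inner = np.asarray(arm.inner, dtype=bool)
    if not inner.any():
        raise ValueError(
            "B_inner is empty: the arm segment is not adjacent to the rest "
            "of the foreground"
        )
    rows, cols = np.nonzero(inner)
    vals = np.asarray(grad, dtype=float)[rows, cols]
    if np.any(~np.isfinite(vals)):
        raise ValueError("gradient undefined on some inner boundary pixels")
    centroids = mean_shift_1d(vals, bandwidth=bandwidth, quantile=quantile)
    members = nearest_centroid(vals, centroids) == 0  # lowest centroid
    if not members.any():  # pragma: no cover - nearest-centroid guarantees one
        logger.warning("empty B_connect after clustering; using all of B_inner")
        members = np.ones(vals.size, dtype=bool)
    connect = np.zeros(lg.shape, dtype=bool)
    connect[rows[members], cols[members]] = True

    base_nodes = [lg.node_id(BASE, r, c)
                  for r, c in zip(rows[members], cols[members])]
    arm_nodes = [lg.node_id(arm.side, r, c)
                 for r, c in zip(rows[members], cols[members])]
    lg.add_edges(np.array(base_nodes), np.array(arm_nodes),
                 np.ones(len(base_nodes)))
    arm.connect = connect
    logger.info("connected %s layer through %d of %d inner boundary pixels",
                arm.side, int(members.sum()), int(inner.sum()))
    return lg
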