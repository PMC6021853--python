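"""Arm segmentation from hand-seeded random-walker probabilities.

An occluding arm sits strictly nearer to the sensor than the body behind it,
so the depth step along its silhouette acts as a barrier to a random walker
seeded at the hand: the hand probability is high on the arm and drops
sharply across the silhouette.  The arm segment is recovered by clustering
the probability values with mean shift and choosing the prefix union of
clusters (in descending probability) that minimizes a gradient cost — a
segment that is too small or too large cuts across the high-gradient ring
around the arm, while the right one avoids it.

The candidate segment is then validated as genuinely occluding: it must be a
single connected component, its inner boundary must be nearer than the
adjacent outer pixels (median depth difference at least one unit by
default), and its probabilities must dominate the surroundings (median
difference at least one percentage point).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .cluster import mean_shift_1d, nearest_centroid
from .config import PipelineConfig
from .graph import WeightedGraph
from .images import as_depth, as_mask
from .random_walker import ProbabilityImage, SeedSet, solve_random_walker

logger = logging.getLogger(__name__)

#: 4-neighbourhood (cross) structuring element used for all morphology.
CROSS = ndimage.generate_binary_structure(2, 1)

__all__ = [
    "CROSS",
    "ArmSegment",
    "ClusterSegmentation",
    "compute_hand_probabilities",
    "cluster_probabilities",
    "probability_gradient",
    "arm_cost",
    "segment_arm",
    "resolve_overlap",
    "boundary_sets",
    "validate_arm",
]


@dataclass
class ClusterSegmentation:
    """Foreground pixels partitioned by mean-shift clusters of a probability map.

    ``labels`` holds cluster indices 1..k (0 on background), with index 1
    the highest-centroid cluster — the one containing the hand pixel — and
    ascending index meaning descending centroid value.
    """

    labels: np.ndarray
    centroids: np.ndarray  # descending

    @property
    def k(self) -> int:
        return self.centroids.size


@dataclass
class ArmSegment:
    """A candidate arm segment and its occlusion-validity verdict."""

    side: str
    mask: np.ndarray
    valid: bool
    inner: np.ndarray
    outer: np.ndarray
    connect: np.ndarray | None = None
    reason: str = ""


def _prob_and_mask(P, mask=None):
    """Coerce a ProbabilityImage or 2-D array to (image, foreground mask)."""
    if isinstance(P, ProbabilityImage):
        img = P.image()
        m = P.graph.layer_masks["base"]
    else:
        img = np.asarray(P, dtype=float)
        m = np.isfinite(img) if mask is None else as_mask(mask, img.shape)
    if mask is not None:
        m = as_mask(mask, img.shape)
    return img, m


def compute_hand_probabilities(
    graph_with_dummy: WeightedGraph,
    right_hand: tuple[int, int],
    left_hand: tuple[int, int],
    direct_max_nodes: int = 300_000,
) -> tuple[ProbabilityImage, ProbabilityImage]:
    """Random-walker probability maps for the two hands.

    Three seeds are used — the two hand pixels and the dummy node, labelled
    1 to 3 — and the two hand-label maps are returned (the dummy-label map
    is discarded).  The dummy node must be present; it keeps the hand
    probabilities from saturating behind depth barriers.
    """
    g = graph_with_dummy
    if g.dummy_node is None:
        raise ValueError("graph has no dummy node; call add_dummy_node first")
    seeds = []
    for pix, label in ((right_hand, 1), (left_hand, 2)):
        r, c = int(pix[0]), int(pix[1])
        if not g.has_node("base", r, c):
            raise ValueError(f"hand pixel ({r}, {c}) is not on the foreground")
        seeds.append((g.node_id("base", r, c), label))
    seeds.append((g.dummy_node, 3))
    probs = solve_random_walker(g, SeedSet(seeds, 3),
                                direct_max_nodes=direct_max_nodes)
    return probs[0], probs[1]


def cluster_probabilities(
    P,
    hand: tuple[int, int],
    n_samples: int = 100,
    bandwidth: float | None = None,
    quantile: float = 0.07,
) -> ClusterSegmentation:
    """Mean-shift clustering of a hand-probability map over the foreground.

    The sorted foreground probabilities are subsampled to ``n_samples``
    uniformly spaced values (clamped to the pixel count) and clustered;
    every foreground pixel is then assigned to the cluster with the closest
    centroid.  Clusters are indexed by descending centroid, so the hand
    pixel (probability 1) always lands in cluster 1.
    """
    if n_samples < 2:
        raise ValueError(f"n_samples must be >= 2, got {n_samples}")
    img, mask = _prob_and_mask(P)
    vals = np.sort(img[mask])
    n = min(int(n_samples), vals.size)
    # centred uniform positions: sample the distribution of values, not its
    # extremes (the seed pixels' exact 0/1 boundary values would otherwise
    # form spurious single-pixel clusters)
    idx = ((np.arange(n) + 0.5) * (vals.size / n)).astype(int)
    samples = vals[np.minimum(idx, vals.size - 1)]
    centroids = mean_shift_1d(samples, bandwidth=bandwidth, quantile=quantile)
    order = np.argsort(centroids)[::-1]  # descending
    centroids_desc = centroids[order]
    rank_of = np.empty_like(order)
    rank_of[order] = np.arange(order.size)

    labels = np.zeros(img.shape, dtype=np.int64)
    rows, cols = np.nonzero(mask)
    nearest = nearest_centroid(img[rows, cols], centroids)
    labels[rows, cols] = rank_of[nearest] + 1

    hr, hc = int(hand[0]), int(hand[1])
    if not mask[hr, hc]:
        raise ValueError(f"hand pixel ({hr}, {hc}) is not on the foreground")
    return ClusterSegmentation(labels, centroids_desc)


def probability_gradient(P, mask=None) -> np.ndarray:
    """Gradient magnitude of a probability map, foreground only.

    Central differences on the foreground; one-sided differences where the
    stencil would touch background (background values never enter the
    computation), and 0 where a pixel has no foreground neighbour along an
    axis.  Background output is NaN (undefined).
    """
    img, m = _prob_and_mask(P, mask)
    vals = np.where(m, img, 0.0)
    grads = []
    for axis in (0, 1):
        nxt = np.roll(vals, -1, axis=axis)
        prv = np.roll(vals, 1, axis=axis)
        has_nxt = np.roll(m, -1, axis=axis)
        has_prv = np.roll(m, 1, axis=axis)
        # roll wraps around the image border; the wrapped entries are invalid
        edge_hi = [slice(None)] * 2
        edge_hi[axis] = -1
        edge_lo = [slice(None)] * 2
        edge_lo[axis] = 0
        has_nxt[tuple(edge_hi)] = False
        has_prv[tuple(edge_lo)] = False

        g = np.zeros_like(vals)
        both = m & has_nxt & has_prv
        fwd = m & has_nxt & ~has_prv
        bwd = m & ~has_nxt & has_prv
        g[both] = (nxt[both] - prv[both]) / 2.0
        g[fwd] = nxt[fwd] - vals[fwd]
        g[bwd] = vals[bwd] - prv[bwd]
        grads.append(g)
    mag = np.hypot(grads[0], grads[1])
    mag[~m] = np.nan
    return mag


def arm_cost(B: np.ndarray, grad: np.ndarray) -> float:
    """Gradient cost of a candidate arm segment.

    ``B_union = erosion(B) ∪ erosion(~B)`` with the 4-neighbourhood cross;
    the complement ``~B`` includes background pixels, and pixels outside the
    image border also count as background (so ``~B`` is not eroded at the
    border).  The cost is the mean of the defined (foreground) gradient
    values inside ``B_union``; eroding both sides keeps each segment's own
    perimeter gradients out of its mean.
    """
    B = np.asarray(B, dtype=bool)
    grad = np.asarray(grad, dtype=float)
    if B.shape != grad.shape:
        raise ValueError("mask and gradient shapes differ")
    e1 = ndimage.binary_erosion(B, structure=CROSS, border_value=0)
    e2 = ndimage.binary_erosion(~B, structure=CROSS, border_value=1)
    union = e1 | e2
    if not union.any():
        raise ValueError("B_union is empty; image too small to evaluate cost")
    vals = grad[union]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return float("inf")
    return float(vals.mean())


def segment_arm(Iseg: ClusterSegmentation, grad: np.ndarray) -> np.ndarray:
    """Choose the prefix union of clusters minimizing the gradient cost.

    Candidates are ``B_i = {pixels with cluster index <= i}`` for
    ``i = 1..k`` (descending-probability prefixes, so ``B_1`` contains the
    hand).  Returns the candidate with minimal :func:`arm_cost`; ties go to
    the smallest prefix.
    """
    best_cost = np.inf
    best = None
    for i in range(1, Iseg.k + 1):
        b = (Iseg.labels >= 1) & (Iseg.labels <= i)
        c = arm_cost(b, grad)
        if c < best_cost:
            best_cost = c
            best = b
    return best


def resolve_overlap(right, left, P_right, P_left):
    """Assign pixels claimed by both arm segments to the likelier side.

    A contested pixel goes to the side whose hand probability is larger;
    exact ties go to the right side.  The union of the two masks is
    preserved and the outputs are disjoint.
    """
    right = np.asarray(right, dtype=bool).copy()
    left = np.asarray(left, dtype=bool).copy()
    if right.shape != left.shape:
        raise ValueError("arm masks are on different grids")
    both = right & left
    if both.any():
        pr, _ = _prob_and_mask(P_right)
        pl, _ = _prob_and_mask(P_left)
        to_left = both & (pl > pr)
        right[both & ~to_left] = True
        right[to_left] = False
        left[both & ~to_left] = False
        logger.info("resolved %d contested arm pixels", int(both.sum()))
    return right, left


def boundary_sets(B_arm: np.ndarray, F) -> tuple[np.ndarray, np.ndarray]:
    """Inner and outer boundary of an arm segment against the rest of the body.

    ``B_inner``: pixels of ``B_arm`` 4-adjacent to the rest of the
    foreground ``F_other = F ∩ ~B_arm`` (dilation of ``F_other`` intersected
    with ``B_arm``); ``B_outer``: pixels of ``F_other`` 4-adjacent to
    ``B_arm``.
    """
    B_arm = np.asarray(B_arm, dtype=bool)
    F = np.asarray(F, dtype=bool)
    if np.any(B_arm & ~F):
        raise ValueError("arm segment must lie inside the foreground")
    f_other = F & ~B_arm
    inner = ndimage.binary_dilation(f_other, structure=CROSS) & B_arm
    outer = ndimage.binary_dilation(B_arm, structure=CROSS) & f_other
    return inner, outer


def validate_arm(
    B_arm: np.ndarray,
    depth,
    P,
    F,
    cfg: PipelineConfig | None = None,
    side: str = "right",
) -> ArmSegment:
    """Decide whether a candidate arm segment is genuinely occluding.

    Valid iff the segment is whole (a single 4-connected component), its
    boundary is nearer than the surroundings
    (``median(D_outer) - median(D_inner) >= depth_validity_threshold``) and
    its hand probabilities dominate
    (``median(P_inner) - median(P_outer) >= probability_validity_threshold``).
    An empty inner or outer boundary makes the segment invalid, not an error.
    """
    cfg = cfg or PipelineConfig()
    B_arm = np.asarray(B_arm, dtype=bool)
    if not B_arm.any():
        raise ValueError("arm segment is empty")
    depth = as_depth(depth)
    F = as_mask(F, depth.shape)
    pimg, _ = _prob_and_mask(P)
    inner, outer = boundary_sets(B_arm, F)

    _, n_comp = ndimage.label(B_arm, structure=CROSS)
    if n_comp != 1:
        return ArmSegment(side, B_arm, False, inner, outer,
                          reason=f"not whole ({n_comp} components)")
    if not inner.any() or not outer.any():
        return ArmSegment(side, B_arm, False, inner, outer,
                          reason="empty boundary set")
    d_gap = (np.median(depth.values[outer].astype(float))
             - np.median(depth.values[inner].astype(float)))
    if d_gap < cfg.depth_validity_threshold:
        return ArmSegment(side, B_arm, False, inner, outer,
                          reason=f"depth gap {d_gap:.3g} below threshold")
    p_gap = np.median(pimg[inner]) - np.median(pimg[outer])
    if p_gap < cfg.probability_validity_threshold:
        return ArmSegment(side, B_arm, False, inner, outer,
                          reason=f"probability gap {p_gap:.3g} below threshold")
    return ArmSegment(side, B_arm, True, inner, outer)
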