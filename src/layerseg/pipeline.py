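"""End-to-end layered segmentation pipeline.

Given a depth image, a foreground mask and one annotated pixel per body
part, the pipeline (1) computes hand-probability maps on the dummy-augmented
flat graph, (2) segments and validates the two arms, (3) builds the layered
graph with interpolated base depths and connects the layers, (4) assigns
each part to its layer and converts part positions (plus optional Bresenham
seed lines between adjacent parts) into seed nodes, (5) solves the
random-walker problem on the layered graph and (6) projects node labels
back to a per-pixel label image, with arm-layer labels taking precedence
over the base layer inside the arm segments.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from skimage.draw import line as _skimage_line

from . import arms as _arms
from .config import PipelineConfig
from .graph import (
    BASE,
    LEFT,
    RIGHT,
    WeightedGraph,
    add_dummy_node,
    build_grid_graph,
    build_layered_graph,
    connect_layers,
)
from .images import DepthImage, as_depth, as_mask
from .random_walker import SeedSet, assign_labels, solve_random_walker

logger = logging.getLogger(__name__)

__all__ = [
    "Part",
    "PartSet",
    "assign_parts_to_layers",
    "bresenham_line",
    "generate_seeds",
    "preprocess_depth",
    "segment_parts",
    "segment_parts_flat",
]


@dataclass(frozen=True)
class Part:
    """One annotated body part: id, name and (row, col) image position."""

    id: int
    name: str
    row: int
    col: int

    @property
    def pos(self) -> tuple[int, int]:
        return (self.row, self.col)


@dataclass
class PartSet:
    """Annotated part positions plus optional seed-line adjacency pairs.

    ``lines`` entries are ``(part_id_a, part_id_b, ratio)``: a Bresenham
    line is drawn between the two part positions and its first
    ``ceil(ratio * length)`` pixels take part A's label, the rest part B's.
    ``layer_of`` maps part ids to graph layers (parts default to the base
    layer).
    """

    parts: list = field(default_factory=list)
    lines: list = field(default_factory=list)
    layer_of: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [p.id for p in self.parts]
        if len(ids) != len(set(ids)):
            raise ValueError("part ids must be unique")
        for a, b, r in self.lines:
            if not 0 < r < 1:
                raise ValueError(f"line ratio must lie in (0, 1), got {r}")
            known = set(ids)
            if a not in known or b not in known:
                raise ValueError(f"line ({a}, {b}) references unknown part id")

    def by_id(self, pid: int) -> Part:
        for p in self.parts:
            if p.id == pid:
                return p
        raise KeyError(f"no part with id {pid}")

    def by_name(self, name: str):
        for p in self.parts:
            if p.name == name:
                return p
        return None

    def layer(self, pid: int) -> str:
        return self.layer_of.get(pid, BASE)


def assign_parts_to_layers(
    parts: PartSet, valid_arms, cfg: PipelineConfig | None = None
) -> PartSet:
    """Assign each part to its graph layer.

    All parts default to the base layer.  For each valid arm X, the hand of
    that side moves to layer X unconditionally, and each configured forearm
    part (by default the lower arm) moves to layer X iff its position lies
    inside the arm segment.  No other part leaves the base layer.
    """
    cfg = cfg or PipelineConfig()
    layer_of: dict[int, str] = {}
    for arm in valid_arms:
        if not arm.valid:
            continue
        side = arm.side
        hand = parts.by_name(cfg.hand_parts[side])
        if hand is None:
            raise ValueError(f"valid {side} arm but no {cfg.hand_parts[side]!r} part")
        h, w = arm.mask.shape
        if not (0 <= hand.row < h and 0 <= hand.col < w):
            raise ValueError(
                f"{side} hand position {hand.pos} lies outside the image"
            )
        layer_of[hand.id] = side
        for name in cfg.forearm_parts.get(side, []):
            p = parts.by_name(name)
            if p is not None and arm.mask[p.row, p.col]:
                layer_of[p.id] = side
    return PartSet(parts.parts, parts.lines, layer_of)


def bresenham_line(a: tuple[int, int], b: tuple[int, int]) -> list:
    """Pixels of the Bresenham line from ``a`` to ``b``, inclusive.

    The result starts at ``a``, ends at ``b``, is 8-connected and has
    ``max(|dr|, |dc|) + 1`` pixels.
    """
    rr, cc = _skimage_line(int(a[0]), int(a[1]), int(b[0]), int(b[1]))
    return list(zip(rr.tolist(), cc.tolist()))


def generate_seeds(
    parts: PartSet, lg: WeightedGraph, use_lines: bool = False
) -> tuple[SeedSet, dict]:
    """Convert part positions (and optional seed lines) into graph seeds.

    Labels 1..k follow ascending part id; the returned dict maps labels back
    to part ids.  Part-position seeds are mandatory: a part whose position
    has no node on its assigned layer raises.  Line pixels are best-effort:
    pixels off the foreground, without a node on the required layer, or
    falling inside a different layer's arm segment are dropped (logged), and
    a line pixel never overrides an existing seed.
    """
    ids = sorted(p.id for p in parts.parts)
    if not ids:
        raise ValueError("no parts to seed")
    label_of = {pid: i + 1 for i, pid in enumerate(ids)}
    part_of_label = {v: k for k, v in label_of.items()}

    arm_layers = {name: m for name, m in lg.layer_masks.items() if name != BASE}
    seeded: dict[int, int] = {}
    for p in parts.parts:
        layer = parts.layer(p.id)
        if not lg.has_node(layer, p.row, p.col):
            raise ValueError(
                f"part {p.name!r} position {p.pos} has no node on layer "
                f"{layer!r}"
            )
        node = lg.node_id(layer, p.row, p.col)
        if seeded.get(node, label_of[p.id]) != label_of[p.id]:
            raise ValueError(
                f"parts collide at node for {p.pos} on layer {layer!r}"
            )
        seeded[node] = label_of[p.id]

    dropped = 0
    if use_lines:
        for pid_a, pid_b, ratio in parts.lines:
            pa, pb = parts.by_id(pid_a), parts.by_id(pid_b)
            pixels = bresenham_line(pa.pos, pb.pos)
            n_a = math.ceil(ratio * len(pixels))
            for idx, (r, c) in enumerate(pixels):
                pid = pid_a if idx < n_a else pid_b
                layer = parts.layer(pid)
                if not lg.has_node(layer, r, c):
                    dropped += 1
                    continue
                in_foreign_arm = any(
                    name != layer and m[r, c] for name, m in arm_layers.items()
                )
                if in_foreign_arm:
                    dropped += 1
                    continue
                node = lg.node_id(layer, r, c)
                if node in seeded:
                    if seeded[node] != label_of[pid]:
                        dropped += 1
                    continue
                seeded[node] = label_of[pid]
    if dropped:
        logger.info("dropped %d line seed pixels", dropped)
    seeds = SeedSet(sorted(seeded.items()), k=len(ids))
    return seeds, part_of_label


def preprocess_depth(depth, mask, cutoff_m: float | None = None):
    """Remove foreground pixels farther than an optional metric cutoff.

    Depth values themselves are untouched; only the mask shrinks.  The
    cutoff is compared against the depth in metres (via the image's
    ``meters_per_unit`` metadata; raw values are taken as metres if the unit
    is unknown).  Raises if the cutoff removes the whole foreground.
    """
    depth = as_depth(depth)
    mask = as_mask(mask, depth.shape)
    if cutoff_m is None:
        return depth, mask.copy()
    meters = depth.in_meters()
    new_mask = mask & ~(meters > cutoff_m)
    if not new_mask.any():
        raise ValueError(f"depth cutoff {cutoff_m} m removed the whole foreground")
    removed = int(mask.sum() - new_mask.sum())
    if removed:
        logger.info("depth cutoff removed %d foreground pixels", removed)
    return depth, new_mask


def _project_labels(
    lg: WeightedGraph, node_labels: np.ndarray, part_of_label: dict
) -> np.ndarray:
    """Render node labels as a part-id image; arm layers override the base."""
    out = np.zeros(lg.shape, dtype=np.int64)
    layers = [BASE] + [n for n in lg.layer_masks if n != BASE]
    for layer in layers:
        ids = lg.node_ids(layer)
        m = lg.layer_masks[layer]
        labels = node_labels[ids[m]]
        out[m] = np.vectorize(part_of_label.__getitem__)(labels)
    return out


def _solve_and_project(lg, parts, cfg):
    seeds, part_of_label = generate_seeds(parts, lg, cfg.use_lines)
    probs = solve_random_walker(
        lg, seeds, direct_max_nodes=cfg.direct_solver_max_nodes,
        cg_tol=cfg.cg_tol,
    )
    node_labels = assign_labels(probs)
    return _project_labels(lg, node_labels, part_of_label)


def _segment_arms(depth, mask, parts, cfg):
    """Hand probabilities, per-side arm segments and validity verdicts."""
    right = parts.by_name(cfg.hand_parts[RIGHT])
    left = parts.by_name(cfg.hand_parts[LEFT])
    if right is None or left is None:
        logger.info("hand part(s) missing; skipping arm segmentation")
        return [], {}
    flat = build_grid_graph(depth, mask, cfg.beta)
    g = add_dummy_node(flat, cfg.dummy_weight)
    p_right, p_left = _arms.compute_hand_probabilities(
        g, right.pos, left.pos, direct_max_nodes=cfg.direct_solver_max_nodes
    )
    masks = {}
    grads = {}
    for side, prob, hand in ((RIGHT, p_right, right), (LEFT, p_left, left)):
        iseg = _arms.cluster_probabilities(
            prob, hand.pos, cfg.n_samples,
            bandwidth=cfg.mean_shift_bandwidth,
            quantile=cfg.bandwidth_quantile,
        )
        grads[side] = _arms.probability_gradient(prob.image(), mask)
        masks[side] = _arms.segment_arm(iseg, grads[side])
        logger.info("%s arm candidate: %d pixels from %d clusters",
                    side, int(masks[side].sum()), iseg.k)
    masks[RIGHT], masks[LEFT] = _arms.resolve_overlap(
        masks[RIGHT], masks[LEFT], p_right, p_left
    )
    segments = []
    for side, prob in ((RIGHT, p_right), (LEFT, p_left)):
        seg = _arms.validate_arm(masks[side], depth, prob, mask, cfg, side=side)
        logger.info("%s arm %s%s", side,
                    "valid" if seg.valid else "invalid",
                    f" ({seg.reason})" if seg.reason else "")
        segments.append(seg)
    return segments, grads


def segment_parts(depth, mask, parts: PartSet, cfg: PipelineConfig | None = None,
                  return_details: bool = False):
    """Full occlusion-aware part segmentation of one depth frame.

    Returns the per-pixel part-id label image (0 on background); with
    ``return_details=True`` also returns a dict with the arm segments, the
    layered graph and the hand probability maps for inspection.
    """
    cfg = cfg or PipelineConfig()
    depth, mask = preprocess_depth(depth, mask, cfg.depth_cutoff_m)
    segments, grads = _segment_arms(depth, mask, parts, cfg)
    valid = [s for s in segments if s.valid]
    parts_layered = assign_parts_to_layers(parts, valid, cfg)
    lg = build_layered_graph(depth, mask, valid, cfg.beta)
    for seg in valid:
        connect_layers(lg, seg, grads[seg.side],
                       bandwidth=cfg.mean_shift_bandwidth,
                       quantile=cfg.bandwidth_quantile)
    labels = _solve_and_project(lg, parts_layered, cfg)
    if return_details:
        return labels, {"segments": segments, "graph": lg, "parts": parts_layered}
    return labels


def segment_parts_flat(depth, mask, parts: PartSet,
                       cfg: PipelineConfig | None = None) -> np.ndarray:
    """Standard (single-layer) random-walker segmentation baseline.

    Same seeds and weighting as the layered pipeline, but on the flat grid
    graph with no dummy node, arm layers or depth interpolation.
    """
    cfg = cfg or PipelineConfig()
    depth, mask = preprocess_depth(depth, mask, cfg.depth_cutoff_m)
    flat = build_grid_graph(depth, mask, cfg.beta)
    parts_base = PartSet(parts.parts, parts.lines, {})
    return _solve_and_project(flat, parts_base, cfg)
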