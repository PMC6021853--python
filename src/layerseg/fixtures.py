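"""Synthetic articulated human-figure depth images with ground truth.

The generator emulates a frontal upper-body (or full-body) depth scene of
the kind produced by a structured-light sensor: a torso, head and two arms
drawn as rectangles, discs and capsules on a 12-bit-range integer depth
raster.  Three arm poses are supported:

``hanging``
    both arms beside the torso at the body depth (no occlusion);
``outstretched``
    arms raised diagonally away from the body (no occlusion);
``crossing``
    one forearm and hand cross in front of the torso, with the depth
    ramping from the body depth at the elbow down to ``base_depth -
    arm_depth_offset`` at the wrist and hand, so the crossing arm is
    strictly nearer than the torso beneath it.

Ground-truth labels follow the visible surface (the occluded torso is
labelled as the arm covering it), mirroring how real datasets are
annotated.  Optional Gaussian depth noise and joint-position jitter are
driven by a seeded generator, so figures are bit-reproducible.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .images import DepthImage
from .pipeline import Part, PartSet

logger = logging.getLogger(__name__)

__all__ = [
    "FigureSpec",
    "UPPER7_NAMES",
    "FULL11_NAMES",
    "generate_figure",
    "annotate_from_truth",
]

#: Seven-label upper-body part topology (head pixels belong to the torso).
UPPER7_NAMES = {
    1: "torso",
    2: "left_upper_arm",
    3: "right_upper_arm",
    4: "left_lower_arm",
    5: "right_lower_arm",
    6: "left_hand",
    7: "right_hand",
}

#: Eleven-label full-body variant.
FULL11_NAMES = {
    1: "head",
    2: "torso",
    3: "left_upper_arm",
    4: "right_upper_arm",
    5: "left_lower_arm",
    6: "right_lower_arm",
    7: "left_hand",
    8: "right_hand",
    9: "hips",
    10: "left_leg",
    11: "right_leg",
}


@dataclass
class FigureSpec:
    """Parameters of one synthetic figure.

    ``arm_depth_offset`` is how much nearer (in raw depth units) the
    crossing wrist/hand sits than the torso; ``noise_sigma`` is the
    standard deviation of the additive Gaussian depth noise (0 for exact
    tests); ``jitter`` perturbs the arm joint positions by up to that many
    pixels, varying the pose between seeds; ``wrist_gap`` carves a one-pixel
    background gap between each hand and its forearm, making the hands
    isolated extremities (as when a sleeve edge drops out of the depth
    image).
    """

    shape: tuple[int, int] = (120, 160)
    pose: str = "crossing"
    crossing_side: str = "right"
    variant: str = "upper7"
    base_depth: int = 1000
    arm_depth_offset: int = 50
    noise_sigma: float = 0.0
    jitter: int = 0
    wrist_gap: bool = False
    torso_exception: bool = True
    seed: int = 0
    upper_arm_radius: int = 7
    forearm_radius: int = 6
    wrist_radius: int = 3
    hand_radius: int = 8

    def __post_init__(self) -> None:
        if self.pose not in ("crossing", "hanging", "outstretched"):
            raise ValueError(f"unknown pose {self.pose!r}")
        if self.crossing_side not in ("right", "left"):
            raise ValueError(f"unknown crossing side {self.crossing_side!r}")
        if self.variant not in ("upper7", "full11"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.pose == "crossing" and self.arm_depth_offset <= 0:
            raise ValueError("crossing pose requires a positive depth offset")


# -- shape rasterizers ----------------------------------------------------


def _check_bounds(shape, points, radius, what):
    h, w = shape
    for r, c in points:
        if not (radius <= r < h - radius and radius <= c < w - radius):
            raise ValueError(
                f"degenerate geometry: {what} at ({r}, {c}) with radius "
                f"{radius} leaves the {h}x{w} image"
            )


def _disc(shape, center, radius) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _capsule(shape, a, b, radius, end_radius=None):
    """Pixels within the (possibly tapered) capsule ab, and the axis fraction t.

    With ``end_radius`` the thickness shrinks linearly from ``radius`` at
    ``a`` to ``end_radius`` at ``b`` (a forearm tapering into the wrist).
    """
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    ar, ac = float(a[0]), float(a[1])
    dr, dc = float(b[0]) - ar, float(b[1]) - ac
    denom = dr * dr + dc * dc
    if denom == 0:
        return _disc(shape, a, radius), np.zeros(shape)
    t = np.clip(((rr - ar) * dr + (cc - ac) * dc) / denom, 0.0, 1.0)
    d2 = (rr - (ar + t * dr)) ** 2 + (cc - (ac + t * dc)) ** 2
    r = radius if end_radius is None else radius + (end_radius - radius) * t
    return d2 <= r**2, t


def _rect(shape, r0, r1, c0, c1) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    m[r0 : r1 + 1, c0 : c1 + 1] = True
    return m


# -- figure assembly ------------------------------------------------------


def _arm_geometry(spec: FigureSpec, rng: np.random.Generator) -> dict:
    """Joint positions for both arms, jittered by the spec's seed."""

    def jit(p):
        if spec.jitter == 0:
            return p
        j = rng.integers(-spec.jitter, spec.jitter + 1, size=2)
        return (int(p[0] + j[0]), int(p[1] + j[1]))

    geom = {
        "left": {"shoulder": (36, 53)},
        "right": {"shoulder": (36, 107)},
    }
    # hand centres sit less than one hand radius past the wrist so the
    # hand disc overlaps the forearm tip and the wrist junction is solid
    hang = {
        "left": {"elbow": (64, 36), "wrist": (86, 32), "hand": (92, 32)},
        "right": {"elbow": (64, 124), "wrist": (86, 128), "hand": (92, 128)},
    }
    out = {
        "left": {"elbow": (48, 28), "wrist": (42, 16), "hand": (40, 10)},
        "right": {"elbow": (48, 132), "wrist": (42, 144), "hand": (40, 150)},
    }
    for side in ("left", "right"):
        pose = spec.pose if spec.pose != "crossing" else (
            "crossing" if side == spec.crossing_side else "hanging"
        )
        if pose == "hanging":
            joints = hang[side]
        elif pose == "outstretched":
            joints = out[side]
        else:  # crossing: the arm hangs to the elbow, then the forearm
            # sweeps across the mid-torso toward the opposite side
            elbow = (66, 112) if side == "right" else (66, 48)
            wrist = (56, 66) if side == "right" else (56, 94)
            hand = (56, 60) if side == "right" else (56, 100)
            joints = {"elbow": elbow, "wrist": wrist, "hand": hand}
        geom[side].update({k: jit(v) for k, v in joints.items()})
        geom[side]["crossing"] = spec.pose == "crossing" and side == spec.crossing_side
    return geom


def generate_figure(spec: FigureSpec):
    """Render one figure: (DepthImage, foreground mask, truth labels, PartSet).

    Deterministic given ``spec.seed``.  Truth labels cover the foreground
    exactly; in the crossing pose the forearm and hand are drawn over the
    torso at strictly nearer depth.
    """
    names = UPPER7_NAMES if spec.variant == "upper7" else FULL11_NAMES
    ids = {v: k for k, v in names.items()}
    shape = spec.shape if spec.variant == "upper7" else (
        (200, 160) if spec.shape == (120, 160) else spec.shape
    )
    rng = np.random.default_rng(spec.seed)
    geom = _arm_geometry(spec, rng)

    truth = np.zeros(shape, dtype=np.int64)
    depth = np.zeros(shape, dtype=float)
    base = float(spec.base_depth)

    def paint(mask, label, depths):
        truth[mask] = label
        depth[mask] = depths[mask] if isinstance(depths, np.ndarray) else depths

    head = _disc(shape, (21, 80), 11)
    _check_bounds(shape, [(21, 80)], 11, "head")
    paint(head, ids.get("head", ids["torso"]), base)
    paint(_rect(shape, 30, 86, 55, 105), ids["torso"], base)
    if spec.variant == "full11":
        paint(_rect(shape, 87, 102, 55, 105), ids["hips"], base)
        for side, col in (("left", 70), ("right", 90)):
            leg, _ = _capsule(shape, (102, col), (175, col + (2 if side == "right" else -2)), 9)
            _check_bounds(shape, [(102, col), (175, col)], 9, f"{side} leg")
            paint(leg, ids[f"{side}_leg"], base)

    for side in ("left", "right"):
        g = geom[side]
        # limbs narrow toward the joints: the elbow and wrist are natural
        # constrictions of the silhouette, and the hand is broader than the
        # wrist it attaches to
        upper, _ = _capsule(shape, g["shoulder"], g["elbow"],
                            spec.upper_arm_radius, end_radius=spec.forearm_radius)
        lower, t = _capsule(shape, g["elbow"], g["wrist"], spec.forearm_radius,
                            end_radius=spec.wrist_radius)
        hand = _disc(shape, g["hand"], spec.hand_radius)
        _check_bounds(shape, [g["shoulder"], g["elbow"], g["wrist"]],
                      spec.upper_arm_radius, f"{side} arm")
        _check_bounds(shape, [g["hand"]], spec.hand_radius, f"{side} hand")
        paint(upper, ids[f"{side}_upper_arm"], base)
        if g["crossing"]:
            # depth leaves the body at the elbow and levels off once the
            # forearm is in front of the chest
            ramp = base - spec.arm_depth_offset * np.minimum(t / 0.3, 1.0)
            paint(lower, ids[f"{side}_lower_arm"], ramp)
            paint(hand, ids[f"{side}_hand"], base - spec.arm_depth_offset)
        else:
            paint(lower, ids[f"{side}_lower_arm"], base)
            paint(hand, ids[f"{side}_hand"], base)

    if spec.wrist_gap:
        eight = ndimage.generate_binary_structure(2, 2)
        for side in ("left", "right"):
            hand = truth == ids[f"{side}_hand"]
            ring = ndimage.binary_dilation(hand, structure=eight) & ~hand
            cut = ring & (truth > 0)
            truth[cut] = 0
            depth[cut] = 0.0

    mask = truth > 0
    if spec.noise_sigma > 0:
        depth[mask] += rng.normal(0.0, spec.noise_sigma, int(mask.sum()))
    depth = np.rint(depth).astype(np.int32)
    depth[mask] = np.clip(depth[mask], 1, None)
    depth[~mask] = 0

    parts = annotate_from_truth(truth, torso_exception=spec.torso_exception,
                                names=names)
    return DepthImage(depth), mask, truth, parts


def annotate_from_truth(
    truth: np.ndarray,
    torso_exception: bool = False,
    names: dict | None = None,
    line_ratio: float = 2.0 / 3.0,
) -> PartSet:
    """Derive annotated part positions from a ground-truth label image.

    Each part's position is the foreground pixel closest (Euclidean) to the
    centroid of its truth pixels — the chosen pixel need not carry the
    part's own label.  With ``torso_exception`` and both upper arms present,
    the torso position is instead the mean of the two upper-arm positions,
    snapped to the nearest foreground pixel.  Parts absent from the truth
    are omitted with a warning.  Seed lines between the torso and the two
    upper arms (ratio ``line_ratio``) are attached when those parts exist.
    """
    truth = np.asarray(truth)
    names = dict(names) if names else dict(UPPER7_NAMES)
    fg_rows, fg_cols = np.nonzero(truth > 0)
    if fg_rows.size == 0:
        raise ValueError("truth image has no foreground")

    def snap(point):
        d2 = (fg_rows - point[0]) ** 2 + (fg_cols - point[1]) ** 2
        i = int(np.argmin(d2))  # ties: first in row-major order
        return int(fg_rows[i]), int(fg_cols[i])

    parts = []
    for pid in sorted(names):
        rows, cols = np.nonzero(truth == pid)
        if rows.size == 0:
            warnings.warn(f"part {names[pid]!r} has no truth pixels; omitted")
            continue
        r, c = snap((rows.mean(), cols.mean()))
        parts.append(Part(pid, names[pid], r, c))
    pset = PartSet(parts)

    if torso_exception:
        torso = pset.by_name("torso")
        lua = pset.by_name("left_upper_arm")
        rua = pset.by_name("right_upper_arm")
        if torso and lua and rua:
            r, c = snap(((lua.row + rua.row) / 2.0, (lua.col + rua.col) / 2.0))
            parts = [Part(p.id, p.name, r, c) if p.name == "torso" else p
                     for p in pset.parts]
            pset = PartSet(parts)

    torso = pset.by_name("torso")
    lines = []
    for name in ("left_upper_arm", "right_upper_arm"):
        ua = pset.by_name(name)
        if torso and ua:
            lines.append((torso.id, ua.id, line_ratio))
    pset.lines = lines
    return pset
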