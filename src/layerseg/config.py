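"""Pipeline configuration.

All tunable parameters of the segmentation pipeline live in
:class:`PipelineConfig`.  The defaults are the values used throughout the
package's own experiments: an edge-weighting parameter ``beta`` of 90, a
dummy-node weight of 1e-3, a line-seed split ratio of 2/3 and an arm
validity threshold of one raw depth unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field


def _default_hand_parts() -> dict:
    return {"right": "right_hand", "left": "left_hand"}


def _default_forearm_parts() -> dict:
    # Parts that may move onto an arm layer when their position falls inside
    # the arm segment (the hand itself moves unconditionally).
    return {"right": ["right_lower_arm"], "left": ["left_lower_arm"]}


@dataclass
class PipelineConfig:
    """Parameters of the layered random-walker segmentation pipeline.

    Attributes
    ----------
    beta:
        Sensitivity of the edge weight ``exp(-beta * d)`` to the normalized
        squared depth difference ``d`` between 4-adjacent pixels.  Must be
        positive.  Default 90, the stock value of the reference random-walker
        implementation.
    dummy_weight:
        Weight ``w`` of the edge connecting every pixel node to the auxiliary
        dummy node used when computing hand probabilities.  Must lie strictly
        between 0 and 1.  Default 1e-3.
    n_samples:
        Number of uniformly spaced samples drawn from the sorted foreground
        probabilities before mean-shift clustering.  Clamped to the number of
        foreground pixels.  Default 100.
    line_ratio:
        Ratio ``r`` in (0, 1) splitting a seed line between two adjacent
        parts: the first ``ceil(r * len)`` line pixels take the first part's
        label.  Default 2/3.
    use_lines:
        Whether ``segment_parts`` adds line seeds for the part adjacency
        pairs listed in the part set.  Default False.
    depth_cutoff_m:
        Optional cutoff in metres; foreground pixels farther than this are
        removed before segmentation (useful for sensors that emit spurious
        far values along silhouettes).  ``None`` disables the cutoff.
    depth_validity_threshold:
        Minimum ``median(D_outer) - median(D_inner)`` (raw depth units) for
        an arm segment to count as occluding.  Default 1.  The unit follows
        the depth image, so datasets with different encodings can rescale it.
    probability_validity_threshold:
        Minimum ``median(P_inner) - median(P_outer)`` for validity.
        Default 0.01 (one percentage point).
    mean_shift_bandwidth:
        Fixed bandwidth for 1-D mean-shift clustering, or ``None`` to
        estimate it per call with the quantile rule below.
    bandwidth_quantile:
        Quantile used by the bandwidth estimator when no fixed bandwidth is
        given.  Default 0.07: small enough that well-separated probability
        plateaus (arm vs body) and the low-gradient part of an arm's inner
        boundary form their own modes.
    direct_solver_max_nodes:
        Above this node count the random-walker linear systems are solved
        with conjugate gradients instead of a sparse LU factorization.
    cg_tol:
        Relative tolerance of the conjugate-gradient fallback.
    hand_parts / forearm_parts:
        Part names (per side) of the hands and of the parts eligible to move
        onto an arm layer.
    """

    beta: float = 90.0
    dummy_weight: float = 1e-3
    n_samples: int = 100
    line_ratio: float = 2.0 / 3.0
    use_lines: bool = False
    depth_cutoff_m: float | None = None
    depth_validity_threshold: float = 1.0
    probability_validity_threshold: float = 0.01
    mean_shift_bandwidth: float | None = None
    bandwidth_quantile: float = 0.07
    direct_solver_max_nodes: int = 300_000
    cg_tol: float = 1e-8
    hand_parts: dict = field(default_factory=_default_hand_parts)
    forearm_parts: dict = field(default_factory=_default_forearm_parts)

    def __post_init__(self) -> None:
        if not self.beta > 0:
            raise ValueError(f"beta must be positive, got {self.beta}")
        if not 0 < self.dummy_weight < 1:
            raise ValueError(
                f"dummy_weight must lie in (0, 1), got {self.dummy_weight}"
            )
        if not 0 < self.line_ratio < 1:
            raise ValueError(
                f"line_ratio must lie in (0, 1), got {self.line_ratio}"
            )
        if self.n_samples < 2:
            raise ValueError(f"n_samples must be >= 2, got {self.n_samples}")
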