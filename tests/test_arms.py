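import numpy as np
import pytest
from scipy import ndimage

from layerseg import (
    PipelineConfig,
    arm_cost,
    boundary_sets,
    cluster_probabilities,
    probability_gradient,
    resolve_overlap,
    segment_arm,
    validate_arm,
)
from layerseg.arms import CROSS, ClusterSegmentation, compute_hand_probabilities


class TestHandProbabilities:
    def test_hand_pixels_are_their_own_seeds(self, crossing, crossing_hand_probs):
        _, _, _, parts = crossing
        _, p_r, p_l = crossing_hand_probs
        rh, lh = parts.by_name("right_hand"), parts.by_name("left_hand")
        assert p_r.image()[rh.pos] == 1.0
        assert p_l.image()[lh.pos] == 1.0
        assert p_r.image()[lh.pos] == 0.0

    def test_probability_concentrates_on_occluding_arm(self, crossing,
                                                       crossing_hand_probs):
        depth, mask, truth, _ = crossing
        _, p_r, _ = crossing_hand_probs
        img = p_r.image()
        arm = (truth == 5) | (truth == 7)
        assert img[arm].mean() > img[mask & ~arm].mean()

    def test_coincident_hand_pixels_raise(self, crossing):
        depth, mask, _, parts = crossing
        from layerseg import add_dummy_node, build_grid_graph

        g = add_dummy_node(build_grid_graph(depth, mask, 90.0))
        rh = parts.by_name("right_hand")
        with pytest.raises(ValueError, match="conflicting"):
            compute_hand_probabilities(g, rh.pos, rh.pos)

    def test_hand_off_foreground_raises(self, crossing):
        depth, mask, _, parts = crossing
        from layerseg import add_dummy_node, build_grid_graph

        g = add_dummy_node(build_grid_graph(depth, mask, 90.0))
        with pytest.raises(ValueError, match="not on the foreground"):
            compute_hand_probabilities(g, (0, 0), parts.by_name("left_hand").pos)

    def test_dummy_node_required(self, crossing):
        depth, mask, _, parts = crossing
        from layerseg import build_grid_graph

        g = build_grid_graph(depth, mask, 90.0)
        with pytest.raises(ValueError, match="dummy"):
            compute_hand_probabilities(g, parts.by_name("right_hand").pos,
                                       parts.by_name("left_hand").pos)


class TestClustering:
    def test_constant_map_gives_single_cluster(self):
        P = np.full((6, 6), 0.4)
        seg = cluster_probabilities(P, (3, 3), n_samples=10)
        assert seg.k == 1
        assert np.all(seg.labels == 1)

    def test_bimodal_map_separates_arm_from_body(self):
        P = np.full((10, 10), 0.05)
        P[:3] = 0.95  # the "arm" rows
        seg = cluster_probabilities(P, (0, 0), n_samples=50)
        assert seg.k == 2
        assert np.all(seg.labels[:3] == 1)
        assert np.all(seg.labels[3:] == 2)
        assert seg.centroids[0] > seg.centroids[1]

    def test_hand_pixel_is_always_in_cluster_one(self, crossing,
                                                 crossing_hand_probs):
        _, _, _, parts = crossing
        _, p_r, _ = crossing_hand_probs
        rh = parts.by_name("right_hand")
        seg = cluster_probabilities(p_r, rh.pos)
        assert seg.labels[rh.pos] == 1

    def test_n_samples_below_two_raises(self):
        with pytest.raises(ValueError, match="n_samples"):
            cluster_probabilities(np.full((3, 3), 0.5), (0, 0), n_samples=1)


class TestGradient:
    def test_constant_map_has_zero_gradient(self):
        mask = np.ones((5, 5), bool)
        g = probability_gradient(np.full((5, 5), 0.3), mask)
        assert np.allclose(g[mask], 0.0)

    def test_linear_ramp_has_constant_gradient(self):
        W = 8
        P = np.tile(np.arange(W) / W, (5, 1))
        g = probability_gradient(P, np.ones((5, W), bool))
        assert np.allclose(g[:, 1:-1], 1.0 / W)

    def test_step_edge_maximal_along_step(self):
        P = np.zeros((5, 6))
        P[:, 3:] = 1.0
        g = probability_gradient(P, np.ones((5, 6), bool))
        assert g[2, 2] == g[2, 3] == np.max(g)

    def test_background_is_nan_and_never_contaminates(self):
        P = np.where(np.eye(4, dtype=bool), 0.5, 1000.0)
        mask = np.eye(4, dtype=bool)
        g = probability_gradient(np.where(mask, 0.5, 1000.0), mask)
        assert np.all(np.isnan(g[~mask]))
        assert np.allclose(g[mask], 0.0)  # isolated pixels: no neighbours


class TestArmCost:
    def test_zero_gradient_costs_zero(self):
        B = np.zeros((6, 6), bool)
        B[2:4, 2:4] = True
        assert arm_cost(B, np.zeros((6, 6))) == 0.0

    def test_thin_segment_costs_only_complement_side(self):
        grad = np.full((5, 5), 0.2)
        B = np.zeros((5, 5), bool)
        B[2, 1:4] = True  # 1-pixel thick: erosion(B) is empty
        e2 = ndimage.binary_erosion(~B, structure=CROSS, border_value=1)
        assert arm_cost(B, grad) == pytest.approx(grad[e2].mean())

    def test_ring_interior_beats_wrong_sizes(self):
        """The segment bounded by a closed high-gradient ring costs less
        than a half-sized or oversized segment that cuts across the ring."""
        h = w = 21
        rr, cc = np.mgrid[:h, :w]
        dist = np.hypot(rr - 10, cc - 10)
        ring = (dist >= 5.5) & (dist < 6.5)
        grad = np.where(ring, 1.0, 0.0)
        exact = dist <= 6.5
        half = exact & (cc <= 10)
        too_big = dist <= 9.0
        c_exact = arm_cost(exact, grad)
        assert c_exact < arm_cost(half, grad)
        assert c_exact < arm_cost(too_big, grad)

    def test_translation_invariance(self):
        rng = np.random.default_rng(5)
        grad = rng.uniform(0, 1, (9, 9))
        B = np.zeros((9, 9), bool)
        B[1:4, 1:5] = True
        c0 = arm_cost(B, grad)
        c1 = arm_cost(np.roll(B, (3, 2), (0, 1)),
                      np.roll(grad, (3, 2), (0, 1)))
        assert c0 == pytest.approx(c1)

    def test_empty_union_raises(self):
        with pytest.raises(ValueError, match="B_union"):
            arm_cost(np.array([[True]]), np.array([[0.5]]))


def brute_force_best_prefix(iseg, grad):
    """Independent exhaustive minimization over cluster prefix unions."""
    best, best_cost = None, np.inf
    for i in range(1, iseg.k + 1):
        b = (iseg.labels >= 1) & (iseg.labels <= i)
        e1 = ndimage.binary_erosion(b, structure=CROSS, border_value=0)
        e2 = ndimage.binary_erosion(~b, structure=CROSS, border_value=1)
        vals = grad[e1 | e2]
        vals = vals[np.isfinite(vals)]
        cost = vals.mean() if vals.size else np.inf
        if cost < best_cost:
            best, best_cost = b, cost
    return best


class TestSegmentArm:
    def test_single_cluster_returns_whole_foreground(self):
        labels = np.zeros((5, 5), dtype=int)
        labels[1:, 1:] = 1
        iseg = ClusterSegmentation(labels, np.array([0.7]))
        out = segment_arm(iseg, np.full((5, 5), 0.1))
        assert np.array_equal(out, labels == 1)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_prefix_minimum(self, seed):
        rng = np.random.default_rng(seed)
        h, w = 12, 14
        k = int(rng.integers(1, 6))
        # random smooth field quantized into k descending-probability bands
        field = ndimage.gaussian_filter(rng.normal(size=(h, w)), 2.0)
        qs = np.quantile(field, np.linspace(0, 1, k + 1)[1:-1])
        labels = 1 + np.digitize(-field, np.sort(-qs))
        iseg = ClusterSegmentation(labels, np.sort(rng.uniform(0, 1, k))[::-1])
        grad = np.abs(ndimage.gaussian_filter(rng.normal(size=(h, w)), 1.0))
        out = segment_arm(iseg, grad)
        assert np.array_equal(out, brute_force_best_prefix(iseg, grad))

    def test_chosen_cost_is_minimal(self, crossing, crossing_hand_probs):
        depth, mask, _, parts = crossing
        _, p_r, _ = crossing_hand_probs
        rh = parts.by_name("right_hand")
        iseg = cluster_probabilities(p_r, rh.pos)
        grad = probability_gradient(p_r.image(), mask)
        out = segment_arm(iseg, grad)
        chosen = arm_cost(out, grad)
        for i in range(1, iseg.k + 1):
            b = (iseg.labels >= 1) & (iseg.labels <= i)
            assert chosen <= arm_cost(b, grad) + 1e-12


class TestResolveOverlap:
    def test_disjoint_masks_unchanged(self):
        r = np.zeros((4, 4), bool); r[0] = True
        l = np.zeros((4, 4), bool); l[2] = True
        r2, l2 = resolve_overlap(r, l, np.zeros((4, 4)), np.zeros((4, 4)))
        assert np.array_equal(r, r2) and np.array_equal(l, l2)

    def test_contested_pixel_goes_to_higher_probability(self):
        r = np.zeros((3, 3), bool); r[1, 1] = r[0, 0] = True
        l = np.zeros((3, 3), bool); l[1, 1] = l[2, 2] = True
        pr = np.full((3, 3), 0.6)
        pl = np.full((3, 3), 0.3)
        r2, l2 = resolve_overlap(r, l, pr, pl)
        assert r2[1, 1] and not l2[1, 1]
        r2, l2 = resolve_overlap(r, l, pl, pr)
        assert l2[1, 1] and not r2[1, 1]
        # exact tie goes to the right side
        r2, l2 = resolve_overlap(r, l, pr, pr)
        assert r2[1, 1] and not l2[1, 1]

    def test_union_is_conserved_and_outputs_disjoint(self):
        rng = np.random.default_rng(0)
        r = rng.random((6, 6)) < 0.5
        l = rng.random((6, 6)) < 0.5
        union = (r | l).sum()
        r2, l2 = resolve_overlap(r, l, rng.random((6, 6)), rng.random((6, 6)))
        assert not np.any(r2 & l2)
        assert r2.sum() + l2.sum() == union


class TestBoundarySets:
    def test_two_column_arm_against_body(self):
        F = np.zeros((6, 6), bool)
        F[1:5, 1:5] = True
        B = np.zeros((6, 6), bool)
        B[1:5, 3:5] = True  # arm abuts body on its left edge
        inner, outer = boundary_sets(B, F)
        expect_inner = np.zeros((6, 6), bool); expect_inner[1:5, 3] = True
        expect_outer = np.zeros((6, 6), bool); expect_outer[1:5, 2] = True
        assert np.array_equal(inner, expect_inner)
        assert np.array_equal(outer, expect_outer)

    def test_arm_equal_to_foreground_has_empty_boundaries(self):
        F = np.zeros((4, 4), bool)
        F[1:3, 1:3] = True
        inner, outer = boundary_sets(F, F)
        assert not inner.any() and not outer.any()

    def test_inner_and_outer_are_disjoint(self, crossing_run):
        _, details = crossing_run
        for seg in details["segments"]:
            assert not np.any(seg.inner & seg.outer)
            assert np.all(seg.inner <= seg.mask)
            assert not np.any(seg.outer & seg.mask)


class TestValidateArm:
    def test_coplanar_arm_is_invalid(self):
        F = np.ones((8, 8), bool)
        B = np.zeros_like(F); B[2:5, 2:6] = True
        depth = np.full((8, 8), 500.0)
        P = np.where(B, 0.9, 0.1)
        seg = validate_arm(B, depth, P, F)
        assert not seg.valid and "depth" in seg.reason

    def test_split_segment_is_invalid_despite_depth(self):
        F = np.ones((8, 8), bool)
        B = np.zeros_like(F); B[1, 1:4] = True; B[5, 1:4] = True
        depth = np.full((8, 8), 500.0); depth[B] = 400.0
        seg = validate_arm(B, depth, np.where(B, 0.9, 0.1), F)
        assert not seg.valid and "whole" in seg.reason

    def test_arm_covering_foreground_is_invalid_not_error(self):
        F = np.zeros((6, 6), bool); F[1:5, 1:5] = True
        seg = validate_arm(F.copy(), np.full((6, 6), 100.0),
                           np.where(F, 0.5, np.nan), F)
        assert not seg.valid and "boundary" in seg.reason

    def test_occluding_fixture_arm_is_valid(self, crossing_run):
        _, details = crossing_run
        segs = {s.side: s for s in details["segments"]}
        assert segs["right"].valid
        assert not segs["left"].valid

    def test_threshold_is_configurable(self):
        F = np.ones((8, 8), bool)
        B = np.zeros_like(F); B[2:5, 2:6] = True
        depth = np.full((8, 8), 500.0); depth[B] = 450.0  # 50 units nearer
        P = np.where(B, 0.9, 0.1)
        assert validate_arm(B, depth, P, F).valid
        strict = PipelineConfig(depth_validity_threshold=100.0)
        assert not validate_arm(B, depth, P, F, strict).valid
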