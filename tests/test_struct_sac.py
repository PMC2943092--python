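"""Structure-based sample consensus: Huber scoring and outlier rejection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fundusreg.errors import DegenerateSampleError, NoStableStructuresError
from fundusreg.matching import CorrespondenceSet
from fundusreg.struct_sac import (HuberParams, StructSacParams,
                                  estimate_similarity, huber,
                                  local_consistency_test, score_model,
                                  struct_sac)
from fundusreg.transforms import SimilarityTransform, \
    mutual_nearest_neighbors
from util import matches_with_outliers, small_graph_pair


class TestEstimateSimilarity:
    def test_exact_recovery(self, rng):
        true = SimilarityTransform(1.2, math.radians(20), (5.0, -3.0))
        src = rng.uniform(0, 100, (12, 2))
        est = estimate_similarity(src, true.apply(src))
        assert est.scale == pytest.approx(1.2, abs=1e-9)
        assert est.rotation == pytest.approx(math.radians(20), abs=1e-9)
        np.testing.assert_allclose(est.translation, (5.0, -3.0), atol=1e-8)

    def test_two_pairs_interpolate_exactly(self):
        src = np.array([[0.0, 0.0], [10.0, 0.0]])
        dst = np.array([[5.0, 5.0], [5.0, 25.0]])
        est = estimate_similarity(src, dst)
        np.testing.assert_allclose(est.apply(src), dst, atol=1e-9)

    def test_noisy_fit_matches_nonlinear_optimizer(self, rng):
        # oracle: scipy nonlinear least squares over (scale, rot, t)
        from scipy.optimize import least_squares

        true = SimilarityTransform(1.1, 0.3, (2.0, 4.0))
        src = rng.uniform(0, 100, (10, 2))
        dst = true.apply(src) + rng.normal(0, 0.5, (10, 2))

        def resid(p):
            t = SimilarityTransform(p[0], p[1], (p[2], p[3]))
            return (t.apply(src) - dst).ravel()

        opt = least_squares(resid, [1.0, 0.0, 0.0, 0.0]).x
        est = estimate_similarity(src, dst)
        assert est.scale == pytest.approx(opt[0], abs=1e-6)
        assert est.rotation == pytest.approx(opt[1], abs=1e-6)
        np.testing.assert_allclose(est.translation, opt[2:], atol=1e-5)

    def test_degenerate_points_rejected(self):
        src = np.zeros((3, 2))
        with pytest.raises(DegenerateSampleError):
            estimate_similarity(src, src + 1.0)


class TestHuber:
    def test_zero(self):
        assert huber(0.0, 3.0) == 0.0

    def test_branch_continuity_at_sigma(self):
        sigma = 2.5
        quad = 0.5 * sigma ** 2
        lin = sigma * sigma - 0.5 * sigma ** 2
        assert quad == pytest.approx(lin)
        assert huber(sigma, sigma) == pytest.approx(sigma ** 2 / 2)

    def test_linear_branch_value(self):
        sigma = 3.0
        assert huber(2 * sigma, sigma) == pytest.approx(1.5 * sigma ** 2)

    @given(t=st.floats(0, 100), sigma=st.floats(0.1, 10))
    @settings(deadline=None, max_examples=50)
    def test_below_quadratic_everywhere(self, t, sigma):
        assert huber(t, sigma) <= 0.5 * t * t + 1e-9

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            HuberParams(sigma_huber=0.0)


class TestScoreModel:
    def test_exact_transform_scores_zero_with_all_inliers(self):
        pair = small_graph_pair(21)
        score = score_model(pair.true_transform, pair.graph_ref,
                            pair.graph_float)
        assert score.epsilon == pytest.approx(0.0, abs=1e-12)
        assert len(score.inlier_pairs) == len(pair.true_correspondences)

    def test_equals_bruteforce_sum(self, rng):
        # oracle: direct loop over mutual-NN gated pairs
        pair = small_graph_pair(22)
        theta = SimilarityTransform(1.08, 0.15, (12.0, -7.0))
        params = StructSacParams()
        score = score_model(theta, pair.graph_ref, pair.graph_float, params)
        g1, g2 = pair.graph_ref, pair.graph_float
        p1 = g1.positions(g1.node_ids)
        p2t = theta.apply(g2.positions(g2.node_ids))
        ia, ib, dist = mutual_nearest_neighbors(p1, p2t, params.gate_radius)
        sigma = params.huber.sigma_huber
        expected = 0.0
        for d in dist:
            rho = 0.5 * d * d if d <= sigma else sigma * d - 0.5 * sigma ** 2
            expected += rho ** 2
        assert score.epsilon == pytest.approx(expected, rel=1e-12)

    def test_outlier_contribution_is_linear_squared(self):
        """A far-away residual contributes (sigma*t - sigma^2/2)^2, not t^4."""
        import dataclasses as dc

        from fundusreg.graph import (VascularEdge, VascularGraph,
                                     VascularNode, normalize_attributes)

        # widely separated nodes so mutual-NN pairing is unambiguous
        pos = [(0.0, 0.0), (0.0, 500.0), (500.0, 0.0), (500.0, 500.0)]
        nodes = {i: VascularNode(i, p) for i, p in enumerate(pos)}
        edges = [VascularEdge(i, i + 1,
                              np.array([pos[i], pos[i + 1]]), 500.0, 500.0)
                 for i in range(3)]
        g1 = normalize_attributes(VascularGraph(nodes, edges, (600, 600)))
        g2 = dc.replace(g1, nodes=dict(g1.nodes))
        g2.nodes[0] = dc.replace(g1.nodes[0], position=(100.0, 0.0))
        params = StructSacParams(gate_radius=200.0)
        s2 = score_model(SimilarityTransform(), g1, g2, params)
        sigma = params.huber.sigma_huber
        expected = (sigma * 100.0 - 0.5 * sigma ** 2) ** 2
        assert s2.epsilon == pytest.approx(expected, rel=1e-12)

    def test_empty_gate_scores_infinite(self):
        pair = small_graph_pair(24)
        far = SimilarityTransform(1.0, 0.0, (10000.0, 10000.0))
        score = score_model(far, pair.graph_ref, pair.graph_float)
        assert math.isinf(score.epsilon)


class TestLocalConsistency:
    def test_identical_stars_pass(self):
        pair = small_graph_pair(25, scale=1.0, rot_deg=0.0,
                                translation=(0, 0))
        g = pair.graph_ref
        center = next(i for i in g.nodes if g.degree(i) == 3)
        nbrs = g.neighbors(center)
        assert local_consistency_test((center, center),
                                      [(n, n) for n in nbrs], g, g,
                                      tol_edge=0.01, tol_angle_deg=1.0)

    def test_similarity_transformed_star_passes(self):
        pair = small_graph_pair(26, scale=1.15, rot_deg=25.0)
        g1, g2 = pair.graph_ref, pair.graph_float
        shared = dict(pair.true_correspondences)
        center = next(i for i in g1.nodes
                      if g1.degree(i) == 3 and i in shared
                      and all(n in shared for n in g1.neighbors(i)))
        nb = [(n, shared[n]) for n in g1.neighbors(center)
              if shared[n] in g2.nodes]
        assert local_consistency_test((center, shared[center]), nb, g1, g2,
                                      tol_edge=0.15, tol_angle_deg=10.0)

    def test_reflected_neighbor_fails_angle_test(self):
        import dataclasses as dc

        pair = small_graph_pair(27, scale=1.0, rot_deg=0.0, translation=(0, 0))
        g1 = pair.graph_ref
        g2 = dc.replace(g1, nodes=dict(g1.nodes))
        center = next(i for i in g1.nodes if g1.degree(i) == 3)
        nbrs = g1.neighbors(center)
        # reflect one neighbor through the center (angle flips by 180)
        c = np.asarray(g1.nodes[center].position)
        p = np.asarray(g1.nodes[nbrs[0]].position)
        g2.nodes[nbrs[0]] = dc.replace(g1.nodes[nbrs[0]],
                                       position=tuple(2 * c - p))
        assert not local_consistency_test((center, center),
                                          [(n, n) for n in nbrs], g1, g2,
                                          tol_edge=1.0, tol_angle_deg=90.0)


class TestStructSac:
    def test_ground_truth_matches_give_exact_transform(self):
        pair = small_graph_pair(30)
        cs = CorrespondenceSet([(a, b, 1.0)
                                for a, b in pair.true_correspondences],
                               method="truth")
        res = struct_sac(cs, pair.graph_ref, pair.graph_float)
        t, tw = res.transform, pair.true_transform
        assert t.scale == pytest.approx(tw.scale, abs=1e-6)
        assert t.rotation == pytest.approx(tw.rotation, abs=1e-6)
        np.testing.assert_allclose(t.translation, tw.translation, atol=1e-4)
        assert len(res.inliers) == len(pair.true_correspondences)

    @pytest.mark.parametrize("trial", range(20))
    def test_injected_wrong_matches_never_become_inliers(self, trial):
        rng = np.random.default_rng(5000 + trial)
        pair = small_graph_pair(300 + trial)
        cs, wrong = matches_with_outliers(pair, rng, wrong_fraction=0.5)
        res = struct_sac(cs, pair.graph_ref, pair.graph_float)
        inliers = {(a, b) for a, b, _ in res.inliers.pairs}
        assert not (inliers & wrong)

    def test_all_wrong_matches_signal_failure(self, rng):
        pair = small_graph_pair(31)
        ids1 = [a for a, _ in pair.true_correspondences]
        ids2 = [b for _, b in pair.true_correspondences]
        shifted = list(np.roll(ids2, 3))
        cs = CorrespondenceSet([(a, b, 1.0)
                                for a, b in zip(ids1, shifted)], method="t")
        with pytest.raises(NoStableStructuresError):
            struct_sac(cs, pair.graph_ref, pair.graph_float)

    def test_too_few_matches_signal_failure(self):
        pair = small_graph_pair(32)
        a, b = pair.true_correspondences[0]
        with pytest.raises(NoStableStructuresError):
            struct_sac(CorrespondenceSet([(a, b, 1.0)], method="t"),
                       pair.graph_ref, pair.graph_float)

    def test_deterministic(self):
        pair = small_graph_pair(33)
        cs = CorrespondenceSet([(a, b, 1.0)
                                for a, b in pair.true_correspondences],
                               method="truth")
        r1 = struct_sac(cs, pair.graph_ref, pair.graph_float)
        r2 = struct_sac(cs, pair.graph_ref, pair.graph_float)
        assert r1.transform == r2.transform
        assert r1.inliers.pairs == r2.inliers.pairs

    def test_inliers_are_gated_mutual_neighbors(self):
        pair = small_graph_pair(34)
        cs = CorrespondenceSet([(a, b, 1.0)
                                for a, b in pair.true_correspondences],
                               method="truth")
        params = StructSacParams()
        res = struct_sac(cs, pair.graph_ref, pair.graph_float, params)
        g1, g2 = pair.graph_ref, pair.graph_float
        p1 = g1.positions(g1.node_ids)
        p2t = res.transform.apply(g2.positions(g2.node_ids))
        ia, ib, _ = mutual_nearest_neighbors(p1, p2t, params.gate_radius)
        allowed = {(g1.node_ids[a], g2.node_ids[b]) for a, b in zip(ia, ib)}
        assert {(a, b) for a, b, _ in res.inliers.pairs} <= allowed
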