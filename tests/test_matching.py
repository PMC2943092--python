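"""Graduated-assignment graph matching: compatibility, Sinkhorn, annealing."""

import math

import numpy as np
import pytest

from fundusreg.errors import EmptyGraphError, ParameterError
from fundusreg.graph import VascularEdge, VascularGraph, VascularNode, \
    normalize_attributes
from fundusreg.matching import (CorrespondenceSet, MatchingParams,
                                attribute_ranges, bistochastic_normalize,
                                compute_compatibility, discretize,
                                graduated_assignment, match_graphs,
                                normalized_compatibility)
from fundusreg.pipeline import matching_recall
from fundusreg.transforms import SimilarityTransform
from util import (assignment_objective, brute_force_best_objective,
                  permuted_copy, random_attributed_graph, small_graph_pair)


class TestCompatibility:
    def test_identical_edge_scores_one(self, rng):
        g = random_attributed_graph(rng, 6)
        compat = compute_compatibility(g, g)
        # every edge paired with itself has zero attribute difference
        assert np.diag(compat.s) == pytest.approx(np.ones(len(g.edges)))

    def test_maximal_difference_scores_zero(self):
        # two single-edge graphs cannot differ (normalization fixes a=1);
        # use two-edge graphs whose attribute difference spans the range
        g1 = _chain_graph([1.0, 3.0])
        g2 = _chain_graph([1.0, 3.0])
        compat = compute_compatibility(g1, g2)
        l1, l2 = attribute_ranges(g1, g2)
        # edge 0 (a=0.5) against edge 1 (a=1.5): |diff| = 1.0
        expected = 0.5 * (1 - 1.0 / l1) + 0.5 * (1 - 1.0 / l2)
        assert compat.s[0, 1] == pytest.approx(expected)
        assert (compat.s >= -1e-12).all() and (compat.s <= 1 + 1e-12).all()

    def test_sparse_matches_dense_bruteforce(self, rng):
        # independent oracle: evaluate the compatibility rule entrywise from
        # the graph attributes, for every pair of node quadruples
        g1 = random_attributed_graph(rng, 6)
        g2 = random_attributed_graph(rng, 6)
        compat = compute_compatibility(g1, g2)
        l1, l2 = attribute_ranges(g1, g2)
        w = compat.dense()
        n2 = len(g2.nodes)
        for i in range(6):
            for j in range(6):
                e1 = g1.edge_between(i, j)
                for ip in range(6):
                    for jp in range(6):
                        e2 = g2.edge_between(ip, jp)
                        if e1 is None or e2 is None or i == j or ip == jp:
                            expected = 0.0
                        else:
                            expected = (0.5 * (1 - abs(e1.a1 - e2.a1) / l1)
                                        + 0.5 * (1 - abs(e1.a2 - e2.a2) / l2))
                        assert w[i * n2 + ip, j * n2 + jp] == pytest.approx(
                            expected), (i, j, ip, jp)

    def test_weight_validation(self, rng):
        g = random_attributed_graph(rng, 5)
        with pytest.raises(ParameterError):
            compute_compatibility(g, g, omega1=0.7, omega2=0.5)

    def test_empty_graph_rejected(self, rng):
        g = random_attributed_graph(rng, 5)
        empty = VascularGraph({0: VascularNode(0, (0.0, 0.0))}, [], (10, 10))
        with pytest.raises(EmptyGraphError):
            compute_compatibility(g, empty)


class TestBistochasticNormalize:
    def test_square_positive_converges_to_doubly_stochastic(self, rng):
        s = bistochastic_normalize(rng.uniform(0.1, 1.0, (8, 8)), tol=1e-9)
        np.testing.assert_allclose(s.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_allclose(s.sum(axis=0), 1.0, atol=1e-6)

    def test_dominant_entries_sharpen(self):
        s = np.eye(5) * 10 + 0.01
        out = bistochastic_normalize(s, tol=1e-9)
        assert (np.diag(out) > 0.95).all()

    def test_rectangular_matches_literal_iteration(self, rng):
        # oracle: a literal re-implementation of the alternating updates
        s0 = rng.uniform(0.1, 1.0, (5, 7))
        ours = bistochastic_normalize(s0, tol=1e-7, max_iter=200)
        ref = s0.copy()
        for _ in range(200):
            prev = ref.copy()
            ref = ref / ref.sum(axis=1, keepdims=True)
            ref = ref / ref.sum(axis=0, keepdims=True)
            if np.abs(ref - prev).max() < 1e-7:
                break
        np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_zero_rows_left_untouched(self):
        s = np.array([[1.0, 2.0], [0.0, 0.0]])
        out = bistochastic_normalize(s, max_iter=5)
        assert (out[1] == 0).all()

    def test_negative_rejected(self):
        with pytest.raises(ParameterError):
            bistochastic_normalize(np.array([[1.0, -0.1]]))


class TestGraduatedAssignment:
    def test_self_matching_recovers_identity(self, rng):
        g = random_attributed_graph(rng, 6)
        matches, _ = match_graphs(g, g)
        assert len(matches) >= 5
        assert all(a == b for a, b, _ in matches.pairs)

    def test_relabeled_copy_recovered(self, rng):
        g1 = random_attributed_graph(rng, 7)
        g2, mapping = permuted_copy(rng, g1, attr_noise=0.0)
        matches, _ = match_graphs(g1, g2)
        assert len(matches) >= 6
        assert all(mapping[a] == b for a, b, _ in matches.pairs)

    def test_attains_exhaustive_optimum_on_small_graphs(self, rng):
        hits = 0
        trials = 25
        for _ in range(trials):
            n = int(rng.integers(5, 9))
            g1 = random_attributed_graph(rng, n)
            g2, _ = permuted_copy(rng, g1)
            compat = normalized_compatibility(g1, g2)
            soft = graduated_assignment(compat)
            ours = assignment_objective(compat, discretize(soft).pairs)
            best = brute_force_best_objective(compat)
            hits += ours >= best - 1e-9
        assert hits >= 0.9 * trials

    def test_two_way_constraints(self, rng):
        g1 = random_attributed_graph(rng, 7)
        g2, _ = permuted_copy(rng, g1)
        soft = graduated_assignment(normalized_compatibility(g1, g2))
        assert soft.m.min() >= 0
        assert soft.m.sum(axis=1).max() <= 1 + 1e-6
        assert soft.m.sum(axis=0).max() <= 1 + 1e-6

    def test_objective_monotone_over_annealing(self, rng):
        g1 = random_attributed_graph(rng, 8)
        g2, _ = permuted_copy(rng, g1)
        soft = graduated_assignment(normalized_compatibility(g1, g2))
        trace = np.asarray(soft.objective_trace)
        assert (np.diff(trace) >= -1e-6 * max(trace.max(), 1)).all()

    def test_deterministic(self, rng):
        g1 = random_attributed_graph(rng, 7)
        g2, _ = permuted_copy(rng, g1)
        a = graduated_assignment(normalized_compatibility(g1, g2))
        b = graduated_assignment(normalized_compatibility(g1, g2))
        np.testing.assert_array_equal(a.m, b.m)


class TestDiscretize:
    def test_identity_dominant_matrix(self, rng):
        g1 = random_attributed_graph(rng, 5)
        soft = graduated_assignment(normalized_compatibility(g1, g1))
        pairs = discretize(soft).pairs
        assert all(a == b for a, b, _ in pairs)

    def test_uniform_matrix_gives_empty_set(self):
        from fundusreg.matching import SoftAssignment

        m = np.full((4, 6), 1.0 / 6.0)
        soft = SoftAssignment(m, 30.0, list(range(4)), list(range(6)))
        assert len(discretize(soft, accept_threshold=1.0 / 4.0)) == 0

    def test_agrees_with_hungarian_on_sharp_assignment(self, rng):
        from scipy.optimize import linear_sum_assignment

        g1 = random_attributed_graph(rng, 8)
        g2, _ = permuted_copy(rng, g1)
        soft = graduated_assignment(normalized_compatibility(g1, g2))
        ours = {(a, b) for a, b, _ in discretize(soft).pairs}
        ri, ci = linear_sum_assignment(-soft.m)
        hungarian = {(soft.node_ids1[i], soft.node_ids2[j])
                     for i, j in zip(ri, ci)}
        assert ours <= hungarian

    def test_one_to_one_enforced(self):
        with pytest.raises(ParameterError):
            CorrespondenceSet([(0, 1, 0.5), (0, 2, 0.5)])


class TestGeometricInvariance:
    @pytest.mark.parametrize("seed", range(5))
    def test_matching_invariant_under_similarity_transform(self, seed):
        """Only scale-normalized attributes enter the affinities, so a
        similarity transform of one graph cannot change the matching."""
        pair = small_graph_pair(seed)
        base, _ = match_graphs(pair.graph_ref, pair.graph_float)
        sim = SimilarityTransform(2.3, math.radians(77), (120.0, -45.0))
        transformed = _apply_similarity(pair.graph_float, sim)
        after, _ = match_graphs(pair.graph_ref, transformed)
        assert [(a, b) for a, b, _ in base.pairs] \
            == [(a, b) for a, b, _ in after.pairs]

    def test_outlier_robustness(self):
        """Qualitative noise-robustness: half spurious nodes, recall >= 0.5."""
        recalls = []
        for seed in range(20):
            pair = small_graph_pair(700 + seed, structure_noise=0.5)
            matches, _ = match_graphs(pair.graph_ref, pair.graph_float)
            recalls.append(matching_recall(pair, matches))
        assert np.mean(recalls) >= 0.5


def _chain_graph(d_vps):
    nodes = {i: VascularNode(i, (0.0, 10.0 * i))
             for i in range(len(d_vps) + 1)}
    edges = [VascularEdge(i, i + 1,
                          np.array([nodes[i].position, nodes[i + 1].position]),
                          float(d), float(d))
             for i, d in enumerate(d_vps)]
    return normalize_attributes(VascularGraph(nodes, edges, (100, 100)))


def _apply_similarity(g, sim):
    import dataclasses as dc

    nodes = {i: VascularNode(i, tuple(sim.apply(n.position)[0]))
             for i, n in g.nodes.items()}
    edges = []
    for e in g.edges:
        edges.append(dc.replace(e, path=sim.apply(e.path),
                                d_vp=e.d_vp * sim.scale,
                                d_e=e.d_e * sim.scale))
    return normalize_attributes(VascularGraph(nodes, edges, g.source_shape))
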