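"""Shared fixture builders and independent oracles for the test suite."""

from __future__ import annotations

import itertools
import math

import numpy as np

from fundusreg.graph import (VascularEdge, VascularGraph, VascularNode,
                             normalize_attributes)
from fundusreg.matching import CompatibilityMatrix, _DirectedExpansion
from fundusreg.phantom import PhantomSpec, SimilarityTransform, TreeParams, \
    make_graph_pair
from fundusreg.vessels import FundusImage


# ---------------------------------------------------------------------------
# image builders


def bar_image(shape=(96, 96), angle_deg=0.0, sigma=2.5, contrast=0.5,
              background=1.0):
    """Dark straight bar of Gaussian cross-profile through the image center."""
    h, w = shape
    rr, cc = np.meshgrid(np.arange(h, dtype=float),
                         np.arange(w, dtype=float), indexing="ij")
    th = math.radians(angle_deg)
    d = np.abs((rr - h / 2) * math.cos(th) - (cc - w / 2) * math.sin(th))
    px = background - contrast * np.exp(-d * d / (2 * sigma * sigma))
    return FundusImage(np.clip(px, 0, 1)), d


# ---------------------------------------------------------------------------
# skeleton builders


def skeleton_from_pixels(shape, pixels):
    from fundusreg.vessels import CenterlineImage

    mask = np.zeros(shape, dtype=bool)
    for r, c in pixels:
        mask[r, c] = True
    return CenterlineImage(mask=mask, guaranteed_thin=True)


def plus_skeleton(size=21):
    mid = size // 2
    px = [(mid, c) for c in range(2, size - 2)] \
        + [(r, mid) for r in range(2, size - 2)]
    return skeleton_from_pixels((size, size), px)


def line_skeleton(length=10, size=21):
    mid = size // 2
    return skeleton_from_pixels((size, size),
                                [(mid, 3 + k) for k in range(length)])


# ---------------------------------------------------------------------------
# random attributed graphs and the exhaustive-search oracle


def random_attributed_graph(rng, n):
    """Connected random graph with positive edge-length attributes."""
    pos = rng.uniform(0, 100, size=(n, 2))
    edge_set = set()
    for v in range(1, n):
        edge_set.add((int(rng.integers(0, v)), v))
    for _ in range(int(rng.integers(0, n // 2 + 1))):
        u, v = (int(x) for x in rng.choice(n, 2, replace=False))
        edge_set.add((min(u, v), max(u, v)))
    nodes = {i: VascularNode(i, tuple(pos[i])) for i in range(n)}
    edges = []
    for u, v in sorted(edge_set):
        d_e = float(np.linalg.norm(pos[u] - pos[v]))
        edges.append(VascularEdge(u, v, np.array([pos[u], pos[v]]),
                                  d_e * float(rng.uniform(1.0, 1.5)), d_e))
    return normalize_attributes(VascularGraph(nodes, edges, (100, 100)))


def permuted_copy(rng, g, attr_noise=0.05):
    """Node-relabeled copy with mild multiplicative attribute noise."""
    n = len(g.nodes)
    perm = rng.permutation(n)
    nodes = {int(perm[i]): VascularNode(int(perm[i]), g.nodes[i].position)
             for i in range(n)}
    edges = []
    for e in g.edges:
        d_vp = e.d_vp * (1 + float(rng.normal(0, attr_noise)))
        d_e = min(e.d_e * (1 + abs(float(rng.normal(0, attr_noise)))), d_vp)
        edges.append(VascularEdge(int(perm[e.u]), int(perm[e.v]),
                                  e.path.copy(), d_vp, d_e))
    g2 = normalize_attributes(VascularGraph(nodes, edges, g.source_shape))
    return g2, {i: int(perm[i]) for i in range(n)}


def brute_force_best_objective(compat: CompatibilityMatrix) -> float:
    """Exhaustive maximum of the assignment objective over all permutations.

    Independent of the graduated-assignment path: evaluates the quadratic
    form directly for every permutation matrix (n <= 8).
    """
    n = compat.n1
    assert n == compat.n2 <= 8
    exp = _DirectedExpansion(compat)
    perms = np.array(list(itertools.permutations(range(n))))
    total = np.zeros(len(perms))
    for d1 in range(len(exp.tails1)):
        a = perms[:, exp.tails1[d1], None] == exp.tails2[None, :]
        b = perms[:, exp.heads1[d1], None] == exp.heads2[None, :]
        total += ((a & b) * exp.s_dir[d1]).sum(axis=1)
    return float(total.max())


def assignment_objective(compat, pairs):
    """Objective value of a discrete (possibly partial) assignment."""
    from fundusreg.matching import objective

    m = np.zeros((compat.n1, compat.n2))
    idx2 = {b: j for j, b in enumerate(compat.node_ids2)}
    idx1 = {a: i for i, a in enumerate(compat.node_ids1)}
    for a, b, *_ in pairs:
        m[idx1[a], idx2[b]] = 1.0
    return objective(compat, m)


# ---------------------------------------------------------------------------
# phantom pairs for matching / consensus tests


def small_graph_pair(seed, scale=1.1, rot_deg=10.0, translation=(15, -10),
                     structure_noise=0.0, jitter_px=0.0):
    """Graph-level phantom pair with ~20 nodes and a known similarity warp."""
    from fundusreg.phantom import NoiseParams

    tp = TreeParams(depth=3, n_roots=2)
    warp = SimilarityTransform(scale, math.radians(rot_deg), translation)
    spec = PhantomSpec(seed=seed, tree=tp, warp=warp,
                       noise=NoiseParams(structure_noise=structure_noise,
                                         jitter_px=jitter_px))
    return make_graph_pair(spec)


def matches_with_outliers(pair, rng, wrong_fraction=0.5):
    """Half the true pairs plus a derangement of the other half.

    Returns ``(correspondences, wrong_set)`` where ``wrong_set`` holds the
    injected (deranged) pairs.
    """
    from fundusreg.matching import CorrespondenceSet

    ids1 = [a for a, _ in pair.true_correspondences]
    ids2 = [b for _, b in pair.true_correspondences]
    k = len(ids1)
    half = int(round(k * (1 - wrong_fraction)))
    good = [(ids1[i], ids2[i], 1.0) for i in range(half)]
    da = ids1[half:]
    db = ids2[half:]
    sh = list(rng.permutation(len(db)))
    for i in range(len(sh)):  # force a derangement
        if sh[i] == i:
            sh[i], sh[(i + 1) % len(sh)] = sh[(i + 1) % len(sh)], sh[i]
    wrong = [(da[i], db[sh[i]], 1.0) for i in range(len(da)) if sh[i] != i]
    return CorrespondenceSet(good + wrong, method="test"), \
        {(a, b) for a, b, _ in wrong}
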