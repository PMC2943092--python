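"""Structure-based sample consensus (STRUCT-SAC) outlier rejection.

Graph matching returns globally plausible node correspondences that can still
contain a large fraction of wrong pairs.  Instead of random RANSAC subsets,
this stage enumerates *local structures* deterministically: every matched
node of degree 2 or 3 together with its matched neighbors is a candidate
sample (correct matches cluster, so a correctly matched node tends to have
correctly matched neighbors — the "stable structure" idea).  Each sample is
screened by a local geometric consistency test (pairwise edge-attribute
similarity plus triplewise subtended-angle similarity, both invariant under
similarity transforms), then used to estimate a closed-form similarity
transform which is scored globally with a Huber-robustified sum of squared
residuals over mutually-nearest gated node pairs.  The lowest-scoring model
and its inlier correspondences win.
"""

from __future__ import annotations

import dataclasses
import itertools
import math

import numpy as np

from .errors import DegenerateSampleError, NoStableStructuresError
from .graph import VascularGraph
from .matching import CorrespondenceSet, attribute_ranges
from .transforms import SimilarityTransform, mutual_nearest_neighbors


@dataclasses.dataclass(frozen=True)
class HuberParams:
    """Huber transition scale, in pixels."""

    sigma_huber: float = 3.0

    def __post_init__(self):
        if not self.sigma_huber > 0:
            raise ValueError("sigma_huber must be positive")


@dataclasses.dataclass(frozen=True)
class StructSacParams:
    huber: HuberParams = HuberParams()
    gate_radius: float = 15.0  # px, global-consistency pairing gate
    tol_edge: float = 0.25  # relative edge-attribute tolerance
    tol_angle_deg: float = 20.0  # subtended-angle tolerance
    max_neighbors: int = 4  # above this, enumerate subsets of this size
    rho_squared: str = "literal"  # "literal": sum rho(|t|)^2; "conventional": sum rho(|t|^2)
    refit_inliers: bool = True


@dataclasses.dataclass
class ModelScore:
    epsilon: float
    inlier_pairs: list[tuple[int, int, float]]  # (g1 id, g2 id, residual px)
    params: SimilarityTransform


@dataclasses.dataclass
class StructSacResult:
    transform: SimilarityTransform
    inliers: CorrespondenceSet
    score: ModelScore
    n_samples_tested: int

    def to_dict(self) -> dict:
        d = self.transform.to_dict()
        d.update(epsilon=self.score.epsilon, n_inliers=len(self.inliers))
        return d


def huber(t, sigma: float | HuberParams):
    """Huber penalty: t^2/2 below the transition scale, linear above."""
    if isinstance(sigma, HuberParams):
        sigma = sigma.sigma_huber
    t = np.abs(np.asarray(t, dtype=float))
    quad = 0.5 * t * t
    lin = sigma * t - 0.5 * sigma * sigma
    return np.where(t <= sigma, quad, lin)


def estimate_similarity(src, dst) -> SimilarityTransform:
    """Closed-form least-squares similarity from matched point pairs."""
    return SimilarityTransform.estimate(src, dst)


def score_model(theta: SimilarityTransform, g1: VascularGraph,
                g2: VascularGraph,
                params: StructSacParams | None = None) -> ModelScore:
    """Global consistency score of a transform hypothesis.

    Builds a fresh correspondence set C_theta by mutual nearest-neighbor
    pairing of all G1 nodes with all transformed G2 nodes inside the gate,
    then sums the (squared, by default) Huber penalty of the residual norms.
    An empty C_theta scores +inf.
    """
    params = params or StructSacParams()
    ids1, ids2 = g1.node_ids, g2.node_ids
    p1 = g1.positions(ids1)
    p2t = theta.apply(g2.positions(ids2))
    ia, ib, dist = mutual_nearest_neighbors(p1, p2t, params.gate_radius)
    if len(ia) == 0:
        return ModelScore(math.inf, [], theta)
    if params.rho_squared == "literal":
        eps = float(np.sum(huber(dist, params.huber) ** 2))
    elif params.rho_squared == "conventional":
        eps = float(np.sum(huber(dist ** 2, params.huber)))
    else:
        raise ValueError(f"unknown rho mode {params.rho_squared!r}")
    pairs = [(ids1[a], ids2[b], float(d)) for a, b, d in zip(ia, ib, dist)]
    return ModelScore(eps, pairs, theta)


def _subtended_angles(center: np.ndarray, nbrs: np.ndarray) -> list[float]:
    """Unsigned angles (deg) subtended at ``center`` by each neighbor pair."""
    vecs = nbrs - center
    out = []
    for a, b in itertools.combinations(range(len(vecs)), 2):
        va, vb = vecs[a], vecs[b]
        na, nb = np.linalg.norm(va), np.linalg.norm(vb)
        if na == 0 or nb == 0:
            out.append(0.0)
            continue
        cosang = np.clip(np.dot(va, vb) / (na * nb), -1.0, 1.0)
        out.append(math.degrees(math.acos(cosang)))
    return out


def local_consistency_test(center_pair: tuple[int, int],
                           neighbor_pairs: list[tuple[int, int]],
                           g1: VascularGraph, g2: VascularGraph,
                           tol_edge: float = 0.25,
                           tol_angle_deg: float = 20.0) -> bool:
    """Screen a local structure sample before estimating a transform.

    Passes iff (a) every matched center-neighbor edge pair has attribute
    differences within ``tol_edge`` relative to the attribute range L_r, and
    (b) every matched neighbor triple subtends angles at the center differing
    by at most ``tol_angle_deg``.  Both checks are similarity-invariant.
    """
    if len(neighbor_pairs) < 2:
        return False
    c1, c2 = center_pair
    l1, l2 = attribute_ranges(g1, g2)
    for n1_id, n2_id in neighbor_pairs:
        e1 = g1.edge_between(c1, n1_id)
        e2 = g2.edge_between(c2, n2_id)
        if e1 is None or e2 is None:
            return False
        if abs(e1.a1 - e2.a1) / l1 > tol_edge:
            return False
        if abs(e1.a2 - e2.a2) / l2 > tol_edge:
            return False
    center1 = np.asarray(g1.nodes[c1].position)
    center2 = np.asarray(g2.nodes[c2].position)
    nbrs1 = np.array([g1.nodes[n].position for n, _ in neighbor_pairs])
    nbrs2 = np.array([g2.nodes[n].position for _, n in neighbor_pairs])
    ang1 = _subtended_angles(center1, nbrs1)
    ang2 = _subtended_angles(center2, nbrs2)
    return all(abs(a - b) <= tol_angle_deg for a, b in zip(ang1, ang2))


def _candidate_samples(matches: CorrespondenceSet, g1: VascularGraph,
                       g2: VascularGraph, max_neighbors: int):
    """Deterministic traversal of degree-2/3 matched nodes on both sides."""
    fwd = matches.as_mapping()
    rev = {b: a for a, b in fwd.items()}
    seen: set[frozenset] = set()

    def emit(center1, center2, nb_pairs):
        groups = [nb_pairs]
        if len(nb_pairs) > max_neighbors:
            groups = [list(c) for c in
                      itertools.combinations(nb_pairs, max_neighbors)]
        for grp in groups:
            key = frozenset([(center1, center2)] + list(grp))
            if key not in seen:
                seen.add(key)
                yield (center1, center2), list(grp)

    for c1 in sorted(fwd):
        if g1.degree(c1) not in (2, 3):
            continue
        nb_pairs = [(n, fwd[n]) for n in g1.neighbors(c1) if n in fwd]
        if len(nb_pairs) >= 2:
            yield from emit(c1, fwd[c1], nb_pairs)
    for c2 in sorted(rev):
        if g2.degree(c2) not in (2, 3):
            continue
        nb_pairs = [(rev[n], n) for n in g2.neighbors(c2) if n in rev]
        if len(nb_pairs) >= 2:
            yield from emit(rev[c2], c2, nb_pairs)


def struct_sac(matches: CorrespondenceSet, g1: VascularGraph,
               g2: VascularGraph,
               params: StructSacParams | None = None) -> StructSacResult:
    """Hypothesize-and-verify over deterministic local-structure samples.

    For every matched degree-2/3 node (searched symmetrically in both
    graphs), the node and its matched neighbors form the source subset; the
    input matches map it to the object subset.  Samples passing the local
    consistency test yield similarity hypotheses, each scored globally; the
    minimum-score model and its inlier correspondences are returned,
    optionally re-estimated from the inliers.

    Raises ``NoStableStructuresError`` ("insufficient stable structures")
    when no sample survives — e.g. fewer than three stable nodes overlap.
    """
    params = params or StructSacParams()
    if len(matches) < 2:
        raise NoStableStructuresError(
            "insufficient stable structures: fewer than 2 input matches")
    best: ModelScore | None = None
    n_tested = 0
    for center_pair, nb_pairs in _candidate_samples(matches, g1, g2,
                                                    params.max_neighbors):
        n_tested += 1
        if not local_consistency_test(center_pair, nb_pairs, g1, g2,
                                      params.tol_edge, params.tol_angle_deg):
            continue
        sample = [center_pair] + nb_pairs
        src = np.array([g2.nodes[b].position for _, b in sample])
        dst = np.array([g1.nodes[a].position for a, _ in sample])
        try:
            theta = estimate_similarity(src, dst)
        except DegenerateSampleError:
            continue
        score = score_model(theta, g1, g2, params)
        if math.isinf(score.epsilon):
            continue
        if best is None or score.epsilon < best.epsilon:
            best = score
    if best is None:
        raise NoStableStructuresError(
            "insufficient stable structures: no local sample passed the "
            "consistency test")
    if params.refit_inliers:
        for _ in range(2):
            if len(best.inlier_pairs) < 2:
                break
            src = np.array([g2.nodes[b].position
                            for _, b, _ in best.inlier_pairs])
            dst = np.array([g1.nodes[a].position
                            for a, _, _ in best.inlier_pairs])
            try:
                theta = estimate_similarity(src, dst)
            except DegenerateSampleError:
                break
            rescored = score_model(theta, g1, g2, params)
            if rescored.epsilon < best.epsilon:
                best = rescored
            else:
                break
    inliers = CorrespondenceSet(
        [(a, b, float(d)) for a, b, d in best.inlier_pairs],
        method="struct_sac")
    return StructSacResult(best.params, inliers, best, n_tested)
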