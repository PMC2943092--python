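"""Global bifurcation correspondences by graduated-assignment graph matching.

The correspondence problem between two vascular structure graphs is posed as
an assignment that maximizes the sum of pairwise edge affinities

    E = sum_{i,i',j,j'} M_{ii'} M_{jj'} W_{ii'jj'},

where ``W_{ii'jj'}`` compares the normalized path-length and chord-length
attributes of edge (i, j) in G1 with edge (i', j') in G2 and is zero when
either edge is absent.  Because only existing edge pairs carry weight, W is
stored as an |E1| x |E2| edge-similarity matrix S.  S is balanced by
iterative bistochastic (Sinkhorn-style) row/column normalization, which
suppresses non-discriminative edges, before the graduated assignment loop —
deterministic annealing with softassign updates and two-way Sinkhorn
normalization on a slack-augmented match matrix — relaxes the discrete
problem into a doubly (sub)stochastic matrix.  Mutual row/column maxima of
the converged matrix yield one-to-one node correspondences.

Everything here is deterministic: the match matrix starts uniform, so
identical inputs give identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging

import numpy as np

from .errors import EmptyGraphError, ParameterError
from .graph import VascularGraph

log = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class MatchingParams:
    """Annealing and normalization schedule of the graph matcher.

    The annealing inverse temperature beta grows geometrically from ``beta0``
    to ``beta_max``; each beta step runs at most ``inner_max`` softassign
    updates, each followed by at most ``sinkhorn_max`` row/column
    normalization sweeps.  After the last beta step an extra Sinkhorn polish
    (``polish_tol``) tightens the two-way constraints.
    """

    omega1: float = 0.5
    omega2: float = 0.5
    beta0: float = 0.5
    beta_max: float = 30.0
    beta_rate: float = 1.075
    inner_max: int = 30
    inner_tol: float = 1e-3
    sinkhorn_max: int = 30
    sinkhorn_tol: float = 1e-3
    polish_max: int = 300
    polish_tol: float = 1e-9
    bistochastic_tol: float = 1e-6
    bistochastic_max: int = 200
    accept_threshold: float | None = None
    epsilon: float = 1e-12  # guards logs/divisions; the alpha of the barrier

    def __post_init__(self):
        if abs(self.omega1 + self.omega2 - 1.0) > 1e-9:
            raise ParameterError("omega1 + omega2 must equal 1")


@dataclasses.dataclass
class CompatibilityMatrix:
    """Sparse pairwise edge affinities between two graphs.

    ``s[e, f]`` holds the affinity of G1 edge ``e`` with G2 edge ``f``;
    ``edges1``/``edges2`` give the node *indices* (into ``node_ids1``/
    ``node_ids2``) of each edge's endpoints.
    """

    s: np.ndarray  # (M1, M2)
    edges1: np.ndarray  # (M1, 2) node indices
    edges2: np.ndarray  # (M2, 2)
    node_ids1: list[int]
    node_ids2: list[int]

    @property
    def n1(self) -> int:
        return len(self.node_ids1)

    @property
    def n2(self) -> int:
        return len(self.node_ids2)

    def dense(self) -> np.ndarray:
        """Dense (n1*n2, n1*n2) compatibility matrix W (debugging aid)."""
        n1, n2 = self.n1, self.n2
        w = np.zeros((n1 * n2, n1 * n2))
        for e, (i, j) in enumerate(self.edges1):
            for f, (ip, jp) in enumerate(self.edges2):
                val = self.s[e, f]
                for (x, xp, y, yp) in ((i, ip, j, jp), (i, jp, j, ip),
                                       (j, ip, i, jp), (j, jp, i, ip)):
                    w[x * n2 + xp, y * n2 + yp] = val
        return w


@dataclasses.dataclass
class SoftAssignment:
    """Continuous match variables after annealing."""

    m: np.ndarray  # (n1, n2), non-slack block
    beta: float
    node_ids1: list[int]
    node_ids2: list[int]
    objective_trace: list[float] = dataclasses.field(default_factory=list)


@dataclasses.dataclass
class CorrespondenceSet:
    """One-to-one node matches ``(g1 node id, g2 node id, confidence)``."""

    pairs: list[tuple[int, int, float]]
    method: str = "graduated_assignment"

    def __post_init__(self):
        g1_ids = [p[0] for p in self.pairs]
        g2_ids = [p[1] for p in self.pairs]
        if len(set(g1_ids)) != len(g1_ids) or len(set(g2_ids)) != len(g2_ids):
            raise ParameterError("correspondences must be one-to-one")

    def __len__(self) -> int:
        return len(self.pairs)

    def as_mapping(self) -> dict[int, int]:
        return {a: b for a, b, _ in self.pairs}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"method": self.method,
                       "pairs": [{"g1_node": a, "g2_node": b, "confidence": c}
                                 for a, b, c in self.pairs]}, fh)

    @classmethod
    def from_json(cls, path) -> "CorrespondenceSet":
        with open(path) as fh:
            d = json.load(fh)
        return cls([(p["g1_node"], p["g2_node"], p["confidence"])
                    for p in d["pairs"]], method=d.get("method", "loaded"))


# ---------------------------------------------------------------------------
# compatibility


def attribute_ranges(g1: VascularGraph, g2: VascularGraph) -> tuple[float, float]:
    """L_r = max over both graphs of the r-th normalized edge attribute."""
    if not g1.edges or not g2.edges:
        raise EmptyGraphError("both graphs need at least one edge")
    l1 = max(max(e.a1 for e in g1.edges), max(e.a1 for e in g2.edges))
    l2 = max(max(e.a2 for e in g1.edges), max(e.a2 for e in g2.edges))
    return l1, l2


def compute_compatibility(g1: VascularGraph, g2: VascularGraph,
                          omega1: float = 0.5,
                          omega2: float = 0.5) -> CompatibilityMatrix:
    """Edge-pair affinities: sum_r omega_r (1 - |A1_r - A2_r| / L_r)."""
    if abs(omega1 + omega2 - 1.0) > 1e-9:
        raise ParameterError("omega1 + omega2 must equal 1")
    ids1, ids2 = g1.node_ids, g2.node_ids
    index1 = {nid: k for k, nid in enumerate(ids1)}
    index2 = {nid: k for k, nid in enumerate(ids2)}
    edges1 = np.array([[index1[e.u], index1[e.v]] for e in g1.edges], int)
    edges2 = np.array([[index2[e.u], index2[e.v]] for e in g2.edges], int)
    a1_1 = np.array([e.a1 for e in g1.edges])
    a2_1 = np.array([e.a2 for e in g1.edges])
    a1_2 = np.array([e.a1 for e in g2.edges])
    a2_2 = np.array([e.a2 for e in g2.edges])
    l1, l2 = attribute_ranges(g1, g2)
    s = (omega1 * (1.0 - np.abs(a1_1[:, None] - a1_2[None, :]) / l1)
         + omega2 * (1.0 - np.abs(a2_1[:, None] - a2_2[None, :]) / l2))
    return CompatibilityMatrix(s, edges1, edges2, ids1, ids2)


def bistochastic_normalize(s: np.ndarray, tol: float = 1e-6,
                           max_iter: int = 200) -> np.ndarray:
    """Alternating row/column normalization of a nonnegative matrix.

    Iterates until the largest elementwise change across one full (row +
    column) sweep falls below ``tol``.  All-zero rows or columns are left
    untouched (and logged); if ``max_iter`` is reached without convergence a
    warning is logged and the current iterate returned.
    """
    s = np.array(s, dtype=float)
    if np.any(s < 0):
        raise ParameterError("bistochastic normalization needs s >= 0")
    if (s.sum(axis=1) == 0).any() or (s.sum(axis=0) == 0).any():
        log.info("zero rows/columns present; they are skipped")
    for _ in range(max_iter):
        prev = s.copy()
        rs = s.sum(axis=1, keepdims=True)
        np.divide(s, rs, out=s, where=rs > 0)
        cs = s.sum(axis=0, keepdims=True)
        np.divide(s, cs, out=s, where=cs > 0)
        if np.abs(s - prev).max() < tol:
            return s
    log.warning("bistochastic normalization did not converge in %d sweeps",
                max_iter)
    return s


def normalized_compatibility(g1: VascularGraph, g2: VascularGraph,
                             params: MatchingParams | None = None
                             ) -> CompatibilityMatrix:
    params = params or MatchingParams()
    compat = compute_compatibility(g1, g2, params.omega1, params.omega2)
    compat.s = bistochastic_normalize(compat.s, tol=params.bistochastic_tol,
                                      max_iter=params.bistochastic_max)
    return compat


# ---------------------------------------------------------------------------
# graduated assignment


class _DirectedExpansion:
    """Directed edge-pair view of the compatibility matrix.

    Each undirected edge contributes both orientations, so the quadratic
    form over ordered index quadruples becomes a sum over directed edge
    pairs; sparse tail-incidence matrices turn the gradient into two
    matmuls.
    """

    def __init__(self, compat: CompatibilityMatrix):
        from scipy import sparse

        i1, j1 = compat.edges1[:, 0], compat.edges1[:, 1]
        i2, j2 = compat.edges2[:, 0], compat.edges2[:, 1]
        self.tails1 = np.concatenate([i1, j1])
        self.heads1 = np.concatenate([j1, i1])
        self.tails2 = np.concatenate([i2, j2])
        self.heads2 = np.concatenate([j2, i2])
        sv = np.vstack([compat.s, compat.s])
        self.s_dir = np.hstack([sv, sv])  # (2 M1, 2 M2)
        m1d, m2d = len(self.tails1), len(self.tails2)
        self.u1 = sparse.csr_matrix(
            (np.ones(m1d), (self.tails1, np.arange(m1d))),
            shape=(compat.n1, m1d))
        self.u2 = sparse.csr_matrix(
            (np.ones(m2d), (np.arange(m2d), self.tails2)),
            shape=(m2d, compat.n2))

    def gradient(self, m: np.ndarray) -> np.ndarray:
        x = self.s_dir * m[np.ix_(self.heads1, self.heads2)]
        return np.asarray(self.u1 @ x @ self.u2)

    def objective(self, m: np.ndarray) -> float:
        return float(np.sum(self.s_dir
                            * m[np.ix_(self.tails1, self.tails2)]
                            * m[np.ix_(self.heads1, self.heads2)]))


def _gradient(compat: CompatibilityMatrix, m: np.ndarray) -> np.ndarray:
    """Q_{ii'} = sum_{jj'} W_{ii'jj'} M_{jj'} over existing edge pairs."""
    return _DirectedExpansion(compat).gradient(m)


def objective(compat: CompatibilityMatrix, m: np.ndarray) -> float:
    """The quadratic assignment objective E(M) over ordered index quadruples."""
    return _DirectedExpansion(compat).objective(m)


def _sinkhorn(mfull: np.ndarray, n1: int, n2: int, tol: float,
              max_iter: int) -> np.ndarray:
    """Two-way normalization of the slack-augmented matrix.

    Real rows and columns (including their slack entry) are normalized to sum
    to one; the slack row/column themselves are unconstrained, which realizes
    the inequality constraints for graphs of unequal size.
    """
    for _ in range(max_iter):
        rs = mfull[:n1].sum(axis=1, keepdims=True)
        mfull[:n1] /= np.maximum(rs, 1e-300)
        cs = mfull[:, :n2].sum(axis=0, keepdims=True)
        mfull[:, :n2] /= np.maximum(cs, 1e-300)
        dev = np.abs(mfull[:n1].sum(axis=1) - 1.0).max()
        if dev < tol:
            break
    return mfull


def graduated_assignment(compat: CompatibilityMatrix,
                         params: MatchingParams | None = None
                         ) -> SoftAssignment:
    """Deterministic-annealing softassign loop on the compatibility matrix.

    At each inverse temperature beta the gradient ``Q`` of the assignment
    objective is exponentiated (softmax with overflow guarding) into a
    positive match matrix, which Sinkhorn normalization projects toward the
    doubly substochastic polytope; beta then grows geometrically.  The
    entropy barrier of the underlying objective is realized implicitly by
    this exponential update.
    """
    params = params or MatchingParams()
    n1, n2 = compat.n1, compat.n2
    if n1 == 0 or n2 == 0:
        raise EmptyGraphError("cannot match empty graphs")
    slack0 = 1.0 / (n1 * n2)
    mfull = np.full((n1 + 1, n2 + 1), slack0)
    trace: list[float] = []
    expansion = _DirectedExpansion(compat)
    beta = params.beta0
    while beta <= params.beta_max * (1 + 1e-12):
        for _ in range(params.inner_max):
            prev = mfull[:n1, :n2].copy()
            q = expansion.gradient(prev)
            # scale-free annealing: the gradient is normalized to unit peak,
            # so the beta schedule sharpens identically regardless of the
            # magnitude the balanced compatibilities happen to have
            qscale = q.max() if q.size and q.max() > 0 else 1.0
            qn = q / qscale
            new = np.empty_like(mfull)
            new[:n1, :n2] = np.exp(beta * (qn - 1.0))
            new[n1, :] = np.exp(beta * (0.0 - 1.0))
            new[:, n2] = np.exp(beta * (0.0 - 1.0))
            mfull = _sinkhorn(new, n1, n2, params.sinkhorn_tol,
                              params.sinkhorn_max)
            if np.abs(mfull[:n1, :n2] - prev).max() < params.inner_tol:
                break
        trace.append(expansion.objective(mfull[:n1, :n2]))
        beta *= params.beta_rate
    mfull = _sinkhorn(mfull, n1, n2, params.polish_tol, params.polish_max)
    m = mfull[:n1, :n2].copy()
    # exact projection onto the inequality constraints: scaling down any
    # row above one, then any column above one, only ever decreases sums
    rs = m.sum(axis=1)
    over = rs > 1.0
    m[over] /= rs[over, None]
    cs = m.sum(axis=0)
    over = cs > 1.0
    m[:, over] /= cs[over]
    return SoftAssignment(m, beta / params.beta_rate,
                          compat.node_ids1, compat.node_ids2, trace)


def discretize(soft: SoftAssignment,
               accept_threshold: float | None = None) -> CorrespondenceSet:
    """Mutual row/column maxima of the soft assignment above a threshold."""
    m = soft.m
    n1, n2 = m.shape
    if accept_threshold is None:
        accept_threshold = 1.0 / (min(n1, n2) + 1.0)
    pairs: list[tuple[int, int, float]] = []
    row_arg = m.argmax(axis=1)
    col_arg = m.argmax(axis=0)
    for i in range(n1):
        j = row_arg[i]
        if col_arg[j] == i and m[i, j] > accept_threshold:
            pairs.append((soft.node_ids1[i], soft.node_ids2[j],
                          float(m[i, j])))
    return CorrespondenceSet(pairs)


def match_graphs(g1: VascularGraph, g2: VascularGraph,
                 params: MatchingParams | None = None
                 ) -> tuple[CorrespondenceSet, SoftAssignment]:
    """Full matching chain: compatibility, balancing, annealing, discretize."""
    params = params or MatchingParams()
    compat = normalized_compatibility(g1, g2, params)
    soft = graduated_assignment(compat, params)
    return discretize(soft, params.accept_threshold), soft


def save_similarity_matrix(path, compat: CompatibilityMatrix) -> None:
    """Dump the edge-similarity matrix in a matrix-market-style text format."""
    s = compat.s
    with open(path, "w") as fh:
        fh.write("%%MatrixMarket matrix coordinate real general\n")
        nz = np.argwhere(s != 0)
        fh.write(f"{s.shape[0]} {s.shape[1]} {len(nz)}\n")
        for e, f in nz:
            fh.write(f"{e + 1} {f + 1} {s[e, f]:.12g}\n")
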