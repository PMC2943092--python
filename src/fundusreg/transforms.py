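"""Geometric transforms shared by the coarse and fine registration stages.

Two models form the transform hierarchy: a 4-parameter similarity transform
(scale, rotation, translation) used for the global alignment hypothesis, and a
12-parameter second-order polynomial ("quadratic") transform used at the fine
level, which accounts for the curvature of the retina under a weak-perspective
camera.

Coordinate convention: points are ``(row, col)`` float arrays of shape
``(n, 2)``, 0-based, pixel centers at integer coordinates.  Transforms map
*floating*-image coordinates into the *reference* frame.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.spatial import cKDTree
from skimage.transform import SimilarityTransform as _SkSimilarity

from .errors import DegenerateSampleError, ParameterError

#: Monomial order of the quadratic model: (r^2, c^2, r*c, r, c, 1).
QUADRATIC_MONOMIALS = ("r2", "c2", "rc", "r", "c", "1")


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[None, :]
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ParameterError(f"expected (n, 2) point array, got shape {pts.shape}")
    return pts


@dataclasses.dataclass(frozen=True)
class SimilarityTransform:
    """Similarity map ``p -> scale * R(rotation) @ p + translation``."""

    scale: float = 1.0
    rotation: float = 0.0  # radians
    translation: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if not self.scale > 0:
            raise ParameterError("similarity scale must be positive")

    @property
    def matrix(self) -> np.ndarray:
        c, s = math.cos(self.rotation), math.sin(self.rotation)
        return self.scale * np.array([[c, -s], [s, c]])

    def apply(self, points) -> np.ndarray:
        pts = _as_points(points)
        return pts @ self.matrix.T + np.asarray(self.translation)

    def inverse(self) -> "SimilarityTransform":
        inv_rot = -self.rotation
        inv_scale = 1.0 / self.scale
        c, s = math.cos(inv_rot), math.sin(inv_rot)
        m = inv_scale * np.array([[c, -s], [s, c]])
        t = -m @ np.asarray(self.translation)
        return SimilarityTransform(inv_scale, inv_rot, (t[0], t[1]))

    @classmethod
    def identity(cls) -> "SimilarityTransform":
        return cls()

    @classmethod
    def estimate(cls, src, dst) -> "SimilarityTransform":
        """Closed-form (Umeyama) least-squares fit of ``dst ~ T(src)``."""
        src = _as_points(src)
        dst = _as_points(dst)
        if len(src) != len(dst) or len(src) < 2:
            raise DegenerateSampleError("need >= 2 point pairs")
        if np.allclose(src, src[0]):
            raise DegenerateSampleError("source points are coincident")
        if hasattr(_SkSimilarity, "from_estimate"):
            tf = _SkSimilarity.from_estimate(src, dst)
            ok = bool(tf)
        else:  # scikit-image < 0.26
            tf = _SkSimilarity()
            ok = tf.estimate(src, dst)
        if not ok:
            raise DegenerateSampleError("similarity estimation failed")
        params = np.asarray(tf.params)
        if not np.all(np.isfinite(params)) or tf.scale <= 0:
            raise DegenerateSampleError("similarity estimation failed")
        return cls(float(tf.scale), float(tf.rotation),
                   (float(tf.translation[0]), float(tf.translation[1])))

    def to_dict(self) -> dict:
        return {
            "model": "similarity",
            "scale": self.scale,
            "rotation_deg": math.degrees(self.rotation),
            "translation": list(self.translation),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimilarityTransform":
        return cls(float(d["scale"]), math.radians(float(d["rotation_deg"])),
                   tuple(float(x) for x in d["translation"]))


def _monomials(points: np.ndarray) -> np.ndarray:
    r, c = points[:, 0], points[:, 1]
    return np.column_stack([r * r, c * c, r * c, r, c, np.ones_like(r)])


@dataclasses.dataclass(frozen=True)
class QuadraticTransform:
    """12-parameter second-order polynomial map.

    ``coeffs`` is a (2, 6) array over the monomials (r^2, c^2, r*c, r, c, 1),
    in pixel units; the first row produces the output row coordinate, the
    second the output column.  With the quadratic block (first three columns)
    zero the map reduces exactly to an affine transform.
    """

    coeffs: np.ndarray

    def __post_init__(self):
        coeffs = np.asarray(self.coeffs, dtype=float)
        if coeffs.shape != (2, 6) or not np.all(np.isfinite(coeffs)):
            raise ParameterError("quadratic transform needs a finite (2, 6) array")
        object.__setattr__(self, "coeffs", coeffs)

    def apply(self, points) -> np.ndarray:
        pts = _as_points(points)
        return _monomials(pts) @ self.coeffs.T

    @property
    def quadratic_block(self) -> np.ndarray:
        return self.coeffs[:, :3]

    @classmethod
    def identity(cls) -> "QuadraticTransform":
        m = np.zeros((2, 6))
        m[0, 3] = 1.0
        m[1, 4] = 1.0
        return cls(m)

    @classmethod
    def from_similarity(cls, sim: SimilarityTransform) -> "QuadraticTransform":
        m = np.zeros((2, 6))
        m[:, 3:5] = sim.matrix
        m[:, 5] = np.asarray(sim.translation)
        return cls(m)

    def to_dict(self) -> dict:
        return {"model": "quadratic", "coeffs": self.coeffs.tolist(),
                "monomials": list(QUADRATIC_MONOMIALS)}

    @classmethod
    def from_dict(cls, d: dict) -> "QuadraticTransform":
        return cls(np.asarray(d["coeffs"], dtype=float))


def _denormalize_row(p: np.ndarray, center: np.ndarray, s: float,
                     c_out: float) -> np.ndarray:
    """Map one output row of coefficients fitted on ``(p - center)/s``
    coordinates (both sides normalized identically) back to pixel units.

    The composition of the normalization affinities with a quadratic is again
    an exact quadratic; this expands it analytically.
    """
    cr, cc = center
    out = np.empty(6)
    out[0] = p[0] / s
    out[1] = p[1] / s
    out[2] = p[2] / s
    out[3] = (-2.0 * cr * p[0] - cc * p[2]) / s + p[3]
    out[4] = (-2.0 * cc * p[1] - cr * p[2]) / s + p[4]
    out[5] = ((p[0] * cr * cr + p[1] * cc * cc + p[2] * cr * cc) / s
              - (p[3] * cr + p[4] * cc) + s * p[5] + c_out)
    return out


def fit_quadratic(src, dst, weights=None,
                  restrict_affine: bool = False) -> QuadraticTransform:
    """Weighted linear least-squares fit of the quadratic model ``dst ~ Q(src)``.

    The two output coordinates are solved independently on the monomial basis.
    Source and target coordinates are internally rescaled to roughly [-1, 1]
    about the source centroid to condition the design matrix; the returned
    coefficients are expressed in pixel units.

    Raises
    ------
    DegenerateSampleError
        If fewer than 6 pairs are given or the (weighted) design matrix does
        not have full column rank.
    """
    src = _as_points(src)
    dst = _as_points(dst)
    n_coef = 3 if restrict_affine else 6
    if len(src) != len(dst):
        raise DegenerateSampleError("src/dst length mismatch")
    if len(src) < n_coef:
        raise DegenerateSampleError(f"need >= {n_coef} pairs, got {len(src)}")
    if weights is None:
        w = np.ones(len(src))
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0):
            raise ParameterError("weights must be nonnegative")

    center = src.mean(axis=0)
    s = float(np.abs(src - center).max())
    s = max(s, 1.0)
    u = (src - center) / s
    v = (dst - center) / s

    design = _monomials(u)
    if restrict_affine:
        design = design[:, 3:]
    sw = np.sqrt(w)[:, None]
    a = design * sw
    rank = np.linalg.matrix_rank(a)
    if rank < design.shape[1]:
        raise DegenerateSampleError(
            f"design matrix rank {rank} < {design.shape[1]}: "
            "point configuration is degenerate for the requested model")
    sol, *_ = np.linalg.lstsq(a, v * sw, rcond=None)
    p = np.zeros((6, 2))
    if restrict_affine:
        p[3:, :] = sol
    else:
        p[:, :] = sol

    coeffs = np.vstack([
        _denormalize_row(p[:, 0], center, s, center[0]),
        _denormalize_row(p[:, 1], center, s, center[1]),
    ])
    return QuadraticTransform(coeffs)


def approximate_inverse(t: QuadraticTransform, shape,
                        grid_step: int = 8) -> QuadraticTransform:
    """Quadratic least-squares approximation of ``t``'s inverse.

    Samples a grid over an image of the given ``(rows, cols)`` shape, maps it
    forward and fits the reverse map.  Exact for affine ``t``; for bounded
    quadratic warps the residual is far below a pixel.
    """
    h, w = shape
    rr, cc = np.meshgrid(np.arange(0, h, grid_step), np.arange(0, w, grid_step),
                         indexing="ij")
    pts = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    fwd = t.apply(pts)
    return fit_quadratic(fwd, pts)


def mutual_nearest_neighbors(a_pts, b_pts, gate: float):
    """Mutual nearest-neighbor pairs between two point sets within ``gate``.

    Returns ``(idx_a, idx_b, dist)`` index arrays such that ``a_pts[idx_a]``
    and ``b_pts[idx_b]`` are each other's nearest neighbors at distance
    ``<= gate``.  Equidistant ties resolve to the lowest index (kd-tree order).
    """
    a = _as_points(a_pts)
    b = _as_points(b_pts)
    tree_b = cKDTree(b)
    d_ab, j_ab = tree_b.query(a, distance_upper_bound=gate)
    tree_a = cKDTree(a)
    _, j_ba = tree_a.query(b, distance_upper_bound=gate)
    idx_a = np.nonzero(np.isfinite(d_ab))[0]
    keep = [i for i in idx_a if j_ba[j_ab[i]] == i]
    idx_a = np.asarray(keep, dtype=int)
    idx_b = j_ab[idx_a].astype(int)
    return idx_a, idx_b, d_ab[idx_a]
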