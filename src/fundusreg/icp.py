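"""Fine-level centerline registration: multiresolution ICP with a quadratic map.

After the global similarity hypothesis, the two vessel centerline point sets
are aligned with a revised iterative-closest-point loop: kd-tree gated
nearest-neighbor pairing, a binary pair-weighting step that rejects residual
outliers, and a closed-form weighted linear regression of the 12-parameter
second-order polynomial transform.  The loop runs coarse-to-fine over
subsampled point sets with a shrinking pairing gate, which lets the early
iterations survive a few pixels of initial misalignment while the final
level converges to subpixel residuals.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial import cKDTree

from .errors import IcpDivergenceError, ParameterError
from .struct_sac import huber
from .transforms import (QuadraticTransform, SimilarityTransform,
                         fit_quadratic)


@dataclasses.dataclass(frozen=True)
class IcpParams:
    """Multiresolution schedule and pair weighting.

    ``strides`` subsample the centerline point sets per level (coarse to
    fine); ``gates`` are the per-level pairing distances in pixels.  The
    default weighting keeps pairs whose residual is at most 2.5x the median
    residual of the current iteration; "huber" soft-weights instead.
    """

    strides: tuple[int, ...] = (4, 2, 1)
    gates: tuple[float, ...] = (20.0, 10.0, 5.0)
    max_iter: int = 50
    tol: float = 1e-3  # px change of mean residual
    weighting: str = "median"  # "median" | "huber" | "none"
    median_factor: float = 2.5
    huber_sigma: float = 3.0
    restrict_affine: bool = False
    min_pairs: int = 6

    def __post_init__(self):
        if len(self.strides) != len(self.gates):
            raise ParameterError("strides and gates must have equal length")


@dataclasses.dataclass
class PairSet:
    """Gated nearest-neighbor pairs with per-pair weights."""

    source_idx: np.ndarray
    target_idx: np.ndarray
    distance: np.ndarray
    weight: np.ndarray

    def __len__(self) -> int:
        return len(self.source_idx)


@dataclasses.dataclass
class IcpResult:
    transform: QuadraticTransform
    residual_trace: list[list[float]]  # per level, mean residual per iteration
    n_pairs_final: int


def closest_pairs(source, target, max_dist: float) -> PairSet:
    """Nearest target point for each source point within ``max_dist``.

    Backed by a kd-tree whose results equal exhaustive search; source points
    without a gated neighbor are excluded.  Weights start at 1.
    """
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if len(source) == 0 or len(target) == 0:
        raise ParameterError("point sets must be nonempty")
    dist, idx = cKDTree(target).query(source, distance_upper_bound=max_dist)
    ok = np.isfinite(dist)
    src = np.nonzero(ok)[0]
    return PairSet(src, idx[ok].astype(int), dist[ok],
                   np.ones(ok.sum(), dtype=float))


def _weights(residuals: np.ndarray, params: IcpParams) -> np.ndarray:
    if params.weighting == "none" or len(residuals) == 0:
        return np.ones_like(residuals)
    if params.weighting == "median":
        cutoff = params.median_factor * np.median(residuals)
        return (residuals <= cutoff).astype(float)
    if params.weighting == "huber":
        # influence-function weights derived from the Huber penalty
        r = np.maximum(residuals, 1e-12)
        return np.minimum(1.0, 2.0 * huber(r, params.huber_sigma) / (r * r))
    raise ParameterError(f"unknown weighting {params.weighting!r}")


def icp(source, target, init: SimilarityTransform | QuadraticTransform,
        params: IcpParams | None = None) -> IcpResult:
    """Register ``source`` onto ``target`` (both (n, 2) centerline points).

    The initial transform — typically the STRUCT-SAC similarity — is embedded
    into quadratic coefficients; at every iteration the *original* source
    points of the current level are re-fit to their matched targets, so the
    model never compounds.  Raises ``IcpDivergenceError`` when fewer than
    ``min_pairs`` weighted pairs survive at the finest level.
    """
    params = params or IcpParams()
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if isinstance(init, SimilarityTransform):
        transform = QuadraticTransform.from_similarity(init)
    else:
        transform = init
    trace: list[list[float]] = []
    n_final = 0
    n_levels = len(params.strides)
    for level, (stride, gate) in enumerate(zip(params.strides, params.gates)):
        finest = level == n_levels - 1
        src = source[::stride]
        tgt = target[::stride]
        level_trace: list[float] = []
        for _ in range(params.max_iter):
            moved = transform.apply(src)
            pairs = closest_pairs(moved, tgt, gate)
            w = _weights(pairs.distance, params)
            usable = int((w > 0).sum())
            if usable < params.min_pairs:
                if finest:
                    raise IcpDivergenceError(
                        f"only {usable} usable pairs at the finest level")
                break
            mean_res = float(np.average(pairs.distance, weights=np.maximum(w, 0))
                             if w.sum() > 0 else np.mean(pairs.distance))
            level_trace.append(mean_res)
            keep = w > 0
            transform = fit_quadratic(src[pairs.source_idx[keep]],
                                      tgt[pairs.target_idx[keep]],
                                      weights=w[keep],
                                      restrict_affine=params.restrict_affine)
            n_final = usable
            if len(level_trace) >= 2 and \
                    abs(level_trace[-2] - level_trace[-1]) < params.tol:
                break
        trace.append(level_trace)
    return IcpResult(transform, trace, n_final)
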