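"""Registration assessment: CEM, NCC, NMI, success rule, overlap percentage.

The vessel Centerline Error Measure (CEM) is the median distance over
corresponding centerline points after applying the recovered transform; a
registration counts as successful when CEM < 3.0 px.  NCC is the Pearson
correlation of intensities over the registered overlap and NMI the
entropy-normalized mutual information over a joint histogram; both are
computed on raw (unpreprocessed) intensities.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
from scipy import ndimage

from .errors import UndefinedCemError, UndefinedMetricError
from .transforms import (QuadraticTransform, approximate_inverse,
                         mutual_nearest_neighbors)
from .vessels import FundusImage

SUCCESS_THRESHOLD_PX = 3.0


@dataclasses.dataclass(frozen=True)
class EvalParams:
    cem_gate: float = 10.0  # px, correspondence gate after warping
    success_threshold: float = SUCCESS_THRESHOLD_PX
    nmi_bins: int = 64
    nmi_variant: str = "sum_over_joint"  # or "two_i_over_sum" in [0, 1]
    border_erosion: int = 2  # px eroded off the overlap mask


@dataclasses.dataclass
class RegistrationReport:
    cem: float | None
    ncc: float | None
    nmi: float | None
    success: bool
    overlap_pct: float | None
    runtime_s: float
    stage: str = "ok"  # "ok" or the failure stage tag
    n_correspondences: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def cem(ref_centerline, float_centerline, t: QuadraticTransform,
        gate: float = 10.0) -> float:
    """Median distance over gated mutual-NN centerline correspondences."""
    ref = np.asarray(ref_centerline, dtype=float)
    flo = np.asarray(float_centerline, dtype=float)
    if len(ref) == 0 or len(flo) == 0:
        raise UndefinedCemError("empty centerline point set")
    moved = t.apply(flo)
    ia, ib, dist = mutual_nearest_neighbors(ref, moved, gate)
    if len(ia) == 0:
        raise UndefinedCemError("no centerline correspondences inside gate")
    return float(np.median(dist))


def success(cem_value: float, threshold: float = SUCCESS_THRESHOLD_PX) -> bool:
    """The success decision rule: CEM strictly below the threshold."""
    return cem_value < threshold


def warp_image(float_image: FundusImage, t: QuadraticTransform,
               ref_shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Resample the floating image into the reference frame under ``t``.

    ``t`` maps floating to reference coordinates, so each reference pixel is
    sampled at its (approximate) pre-image.  Returns ``(warped, valid_mask)``
    where the mask marks reference pixels whose pre-image lies inside the
    floating image.
    """
    inv = approximate_inverse(t, ref_shape)
    h, w = ref_shape
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    grid = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    pre = inv.apply(grid)
    fh, fw = float_image.shape
    eps = 1e-6  # tolerate float round-off at the frame boundary
    inside = ((pre[:, 0] >= -eps) & (pre[:, 0] <= fh - 1 + eps)
              & (pre[:, 1] >= -eps) & (pre[:, 1] <= fw - 1 + eps))
    coords = pre.T.reshape(2, h, w).copy()
    np.clip(coords[0], 0, fh - 1, out=coords[0])
    np.clip(coords[1], 0, fw - 1, out=coords[1])
    warped = ndimage.map_coordinates(float_image.pixels, coords, order=1,
                                     mode="constant", cval=0.0)
    return warped, inside.reshape(h, w)


def overlap_mask(valid: np.ndarray, border_erosion: int = 2) -> np.ndarray:
    """Overlap region with interpolation borders eroded away."""
    if border_erosion <= 0:
        return valid
    return ndimage.binary_erosion(valid, iterations=border_erosion)


def ncc(ref: FundusImage | np.ndarray, warped_float: np.ndarray,
        mask: np.ndarray) -> float:
    """Pearson correlation of intensities over the overlap region."""
    a = ref.pixels if isinstance(ref, FundusImage) else np.asarray(ref)
    b = np.asarray(warped_float)
    if not np.any(mask):
        raise UndefinedMetricError("empty overlap region")
    x = a[mask].astype(float)
    y = b[mask].astype(float)
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        raise UndefinedMetricError("zero-variance overlap region")
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def nmi(ref: FundusImage | np.ndarray, warped_float: np.ndarray,
        mask: np.ndarray, bins: int = 64,
        variant: str = "sum_over_joint") -> float:
    """Normalized mutual information over the overlap joint histogram.

    ``sum_over_joint`` returns (H(A) + H(B)) / H(A, B) (2 for identical
    images); ``two_i_over_sum`` returns 2 I(A; B) / (H(A) + H(B)) in [0, 1].
    """
    a = ref.pixels if isinstance(ref, FundusImage) else np.asarray(ref)
    b = np.asarray(warped_float)
    if not np.any(mask):
        raise UndefinedMetricError("empty overlap region")
    joint, _, _ = np.histogram2d(a[mask].ravel(), b[mask].ravel(), bins=bins,
                                 range=[[0, 1], [0, 1]])
    total = joint.sum()
    if total == 0:
        raise UndefinedMetricError("empty joint histogram")
    pj = joint / total

    def entropy(p):
        p = p[p > 0]
        return float(-(p * np.log(p)).sum())

    h_a = entropy(pj.sum(axis=1))
    h_b = entropy(pj.sum(axis=0))
    h_ab = entropy(pj.ravel())
    if variant == "sum_over_joint":
        if h_ab == 0:
            raise UndefinedMetricError("degenerate joint histogram")
        return (h_a + h_b) / h_ab
    if variant == "two_i_over_sum":
        if h_a + h_b == 0:
            raise UndefinedMetricError("degenerate marginal histograms")
        return 2.0 * (h_a + h_b - h_ab) / (h_a + h_b)
    raise ValueError(f"unknown NMI variant {variant!r}")


def overlap_pct(ref_shape: tuple[int, int], t: QuadraticTransform,
                float_shape: tuple[int, int] | None = None) -> float:
    """Percentage of reference pixels whose pre-image under ``t`` falls
    inside the floating image bounds."""
    float_shape = float_shape or ref_shape
    inv = approximate_inverse(t, ref_shape)
    h, w = ref_shape
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    pre = inv.apply(np.column_stack([rr.ravel(), cc.ravel()]).astype(float))
    fh, fw = float_shape
    eps = 1e-6  # tolerate float round-off at the frame boundary
    inside = ((pre[:, 0] >= -eps) & (pre[:, 0] <= fh - 1 + eps)
              & (pre[:, 1] >= -eps) & (pre[:, 1] <= fw - 1 + eps))
    return 100.0 * float(inside.mean())


def evaluate(ref: FundusImage, float_image: FundusImage,
             ref_centerline, float_centerline, t: QuadraticTransform,
             params: EvalParams | None = None,
             runtime_s: float = 0.0) -> RegistrationReport:
    """Full report: CEM + success, NCC/NMI over the warped overlap, overlap%."""
    params = params or EvalParams()
    cem_value = cem(ref_centerline, float_centerline, t, params.cem_gate)
    warped, valid = warp_image(float_image, t, ref.shape)
    mask = overlap_mask(valid, params.border_erosion)
    try:
        ncc_value = ncc(ref, warped, mask)
        nmi_value = nmi(ref, warped, mask, params.nmi_bins, params.nmi_variant)
    except UndefinedMetricError:
        ncc_value = None
        nmi_value = None
    return RegistrationReport(
        cem=cem_value,
        ncc=ncc_value,
        nmi=nmi_value,
        success=success(cem_value, params.success_threshold),
        overlap_pct=overlap_pct(ref.shape, t, float_image.shape),
        runtime_s=runtime_s,
    )
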