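"""Synthetic fundus-like phantoms with ground truth.

The clinical image pairs this pipeline targets are not redistributable, so
this module generates surrogate data: branching vascular trees rendered as
dark Gaussian-profile ridges (optionally with a central light-reflex ridge)
on a bright, unevenly illuminated background, plus the exact vascular graph,
the ground-truth warp between the two frames of a pair, and node-level
correspondences.  Structure noise (spurious and deleted branches) is injected
at the tree level so that rendered images and derived graphs stay consistent.

All randomness flows from the single PhantomSpec seed: identical specs
produce bit-identical phantoms.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import ndimage

from .errors import ParameterError
from .graph import VascularEdge, VascularGraph, VascularNode, \
    normalize_attributes
from .transforms import QuadraticTransform, SimilarityTransform
from .vessels import FundusImage


# ---------------------------------------------------------------------------
# specification


@dataclasses.dataclass(frozen=True)
class TreeParams:
    """Branching-tree geometry, in pixels and degrees."""

    n_roots: int = 3
    depth: int = 4
    segment_length: float = 110.0
    length_jitter: float = 0.2
    length_decay: float = 0.82
    branch_angle_deg: float = 65.0
    branch_angle_jitter_deg: float = 8.0
    curvature: float = 0.08  # heading drift per step, radians RMS
    root_width: float = 4.0
    width_decay: float = 0.85
    min_width: float = 1.8


@dataclasses.dataclass(frozen=True)
class NoiseParams:
    """Appearance and structure noise of the rendered phantom."""

    background: float = 0.85
    vessel_contrast: float = 0.5
    illumination_amplitude: float = 0.10
    noise_std: float = 0.02
    central_reflex: float = 0.0  # fraction of contrast added back on-axis
    structure_noise: float = 0.0  # fraction of floating nodes without partner
    delete_fraction: float = 0.0  # fraction of floating leaf segments removed
    jitter_px: float = 0.0  # white positional jitter on floating nodes


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    seed: int = 0
    image_shape: tuple[int, int] = (600, 700)
    tree: TreeParams = TreeParams()
    noise: NoiseParams = NoiseParams()
    warp: SimilarityTransform | None = None
    overlap_target: float | None = None  # percent

    def __post_init__(self):
        if not 0.0 <= self.noise.structure_noise <= 0.9:
            raise ParameterError("structure_noise must lie in [0, 0.9]")


# ---------------------------------------------------------------------------
# tree generation


@dataclasses.dataclass
class VesselSegment:
    path: np.ndarray  # (k, 2) float polyline
    width: float
    start_node: int
    end_node: int
    depth: int


@dataclasses.dataclass
class VesselTree:
    segments: list[VesselSegment]
    node_positions: dict[int, tuple[float, float]]
    image_shape: tuple[int, int]

    @property
    def bifurcation_ids(self) -> list[int]:
        counts: dict[int, int] = {}
        for s in self.segments:
            counts[s.start_node] = counts.get(s.start_node, 0) + 1
            counts[s.end_node] = counts.get(s.end_node, 0) + 1
        return sorted(n for n, c in counts.items() if c >= 3)


def _grow_segment(start, heading, length, curvature, shape, rng, step=4.0):
    """Polyline with smoothly drifting heading, clipped at the image margin."""
    h, w = shape
    margin = 6.0
    pts = [np.asarray(start, dtype=float)]
    n_steps = max(2, int(round(length / step)))
    hd = heading
    for _ in range(n_steps):
        hd += rng.normal(0.0, curvature)
        nxt = pts[-1] + step * np.array([math.sin(hd), math.cos(hd)])
        if not (margin <= nxt[0] < h - margin and margin <= nxt[1] < w - margin):
            break
        pts.append(nxt)
    return np.asarray(pts), hd


def generate_tree(spec: PhantomSpec,
                  rng: np.random.Generator | None = None) -> VesselTree:
    """Recursive binary vascular tree inside the image bounds.

    Roots emanate from a disc-like origin toward the image interior; each
    segment either terminates (leaf) or bifurcates into two children with
    decayed length and width.  Bifurcation positions become ground-truth
    graph nodes.
    """
    rng = rng or np.random.default_rng(spec.seed)
    tp = spec.tree
    h, w = spec.image_shape
    origin = np.array([h / 2.0, w * 0.18])
    segments: list[VesselSegment] = []
    positions: dict[int, tuple[float, float]] = {}
    counter = [0]

    def new_node(pos) -> int:
        nid = counter[0]
        counter[0] += 1
        positions[nid] = (float(pos[0]), float(pos[1]))
        return nid

    headings = np.linspace(-1.1, 1.1, tp.n_roots) if tp.n_roots > 1 \
        else np.array([0.0])

    def grow(start, start_id, heading, depth, length, width):
        path, final_heading = _grow_segment(start, heading, length,
                                            tp.curvature, spec.image_shape,
                                            rng)
        if len(path) < 2:
            return
        end_id = new_node(path[-1])
        segments.append(VesselSegment(path, width, start_id, end_id, depth))
        hit_border = _arc_len(path) < 0.8 * length
        if depth >= tp.depth or width <= tp.min_width or hit_border:
            return
        half = math.radians(tp.branch_angle_deg) / 2.0
        jit = math.radians(tp.branch_angle_jitter_deg)
        child_len = length * tp.length_decay
        child_w = width * tp.width_decay
        for sign in (-1.0, 1.0):
            ang = final_heading + sign * half + rng.normal(0.0, jit / 2.0)
            ln = child_len * (1.0 + rng.normal(0.0, tp.length_jitter))
            grow(path[-1], end_id, ang, depth + 1, max(ln, 12.0), child_w)

    for k in range(tp.n_roots):
        start = origin + rng.normal(0.0, 4.0, size=2)
        start[0] = np.clip(start[0], 8, h - 8)
        start[1] = np.clip(start[1], 8, w - 8)
        root_id = new_node(start)
        grow(start, root_id, headings[k] + rng.normal(0.0, 0.1), 1,
             tp.segment_length * (1.0 + rng.normal(0.0, tp.length_jitter)),
             tp.root_width)

    return VesselTree(segments, positions, spec.image_shape)


def _arc_len(path: np.ndarray) -> float:
    d = np.diff(path, axis=0)
    return float(np.sqrt((d * d).sum(axis=1)).sum())


# ---------------------------------------------------------------------------
# tree -> graph


def tree_to_graph(tree: VesselTree) -> VascularGraph:
    """Exact attributed graph of a tree (the extraction-free ground truth)."""
    used: dict[int, int] = {}
    edges = []
    for s in tree.segments:
        used[s.start_node] = used.get(s.start_node, 0) + 1
        used[s.end_node] = used.get(s.end_node, 0) + 1
    nodes = {}
    for nid, cnt in used.items():
        kind = "bifurcation" if cnt >= 3 else "endpoint"
        nodes[nid] = VascularNode(nid, tree.node_positions[nid], cnt, kind)
    for s in tree.segments:
        p_u = np.asarray(tree.node_positions[s.start_node])
        p_v = np.asarray(tree.node_positions[s.end_node])
        d_e = float(np.linalg.norm(p_u - p_v))
        edges.append(VascularEdge(s.start_node, s.end_node, s.path.copy(),
                                  max(_arc_len(s.path), d_e), d_e))
    g = VascularGraph(nodes, edges, tree.image_shape)
    return normalize_attributes(g)


# ---------------------------------------------------------------------------
# rendering


def render(tree: VesselTree, spec: PhantomSpec,
           rng: np.random.Generator | None = None
           ) -> tuple[FundusImage, dict]:
    """Render dark vessels on a bright, smoothly illuminated background.

    Vessels have a Gaussian cross-profile of per-segment width; with
    ``central_reflex > 0`` a narrower bright ridge is added on the vessel
    axis, producing the minimum-maximum-minimum cross-section of wide
    vessels.  Returns the image and a ground-truth dict with the vessel mask
    (half-maximum footprint), the centerline mask and centerline points.
    """
    rng = rng or np.random.default_rng(spec.seed + 1)
    nz = spec.noise
    h, w = spec.image_shape
    # smooth illumination field: tilted plane + radial falloff
    rr, cc = np.meshgrid(np.linspace(-1, 1, h), np.linspace(-1, 1, w),
                         indexing="ij")
    gr, gc = rng.uniform(-1, 1, size=2)
    field = 0.5 * (gr * rr + gc * cc) + 0.5 * (rr * rr + cc * cc)
    background = nz.background * (1.0 - nz.illumination_amplitude * field)

    # rasterize centerlines grouped by width so one distance transform per
    # width bucket suffices
    buckets: dict[float, np.ndarray] = {}
    centerline = np.zeros((h, w), dtype=bool)
    for s in tree.segments:
        width = round(float(s.width), 2)
        canvas = buckets.setdefault(width, np.zeros((h, w), dtype=bool))
        dense = _densify(s.path, 0.5)
        ij = np.round(dense).astype(int)
        ok = (ij[:, 0] >= 0) & (ij[:, 0] < h) & (ij[:, 1] >= 0) & (ij[:, 1] < w)
        canvas[ij[ok, 0], ij[ok, 1]] = True
        centerline[ij[ok, 0], ij[ok, 1]] = True

    attenuation = np.zeros((h, w))
    vessel_mask = np.zeros((h, w), dtype=bool)
    for width, canvas in buckets.items():
        if not canvas.any():
            continue
        d = ndimage.distance_transform_edt(~canvas)
        sigma_prof = max(width / 2.0, 0.6)
        prof = nz.vessel_contrast * np.exp(-d * d / (2 * sigma_prof ** 2))
        if nz.central_reflex > 0:
            reflex_sigma = max(sigma_prof / 3.0, 0.4)
            prof -= (nz.central_reflex * nz.vessel_contrast
                     * np.exp(-d * d / (2 * reflex_sigma ** 2)))
        attenuation = np.maximum(attenuation, prof)
        vessel_mask |= d <= sigma_prof * math.sqrt(2 * math.log(2))

    img = background - attenuation
    if nz.noise_std > 0:
        img = img + rng.normal(0.0, nz.noise_std, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    truth = {"vessel_mask": vessel_mask, "centerline_mask": centerline,
             "centerline_points": np.argwhere(centerline).astype(float)}
    return FundusImage(img), truth


def _densify(path: np.ndarray, step: float) -> np.ndarray:
    out = [path[0]]
    for a, b in zip(path[:-1], path[1:]):
        seg = b - a
        n = max(1, int(math.ceil(np.linalg.norm(seg) / step)))
        for k in range(1, n + 1):
            out.append(a + seg * (k / n))
    return np.asarray(out)


# ---------------------------------------------------------------------------
# pairs


@dataclasses.dataclass
class PhantomPair:
    image_ref: FundusImage | None
    image_float: FundusImage | None
    graph_ref: VascularGraph
    graph_float: VascularGraph
    true_transform: SimilarityTransform  # maps floating -> reference coords
    true_correspondences: list[tuple[int, int]]
    truth_ref: dict | None
    truth_float: dict | None
    spec: PhantomSpec


def _transform_tree(tree: VesselTree, t: SimilarityTransform,
                    shape: tuple[int, int]) -> VesselTree:
    """Map a tree into a new frame, truncating segments at the frame bounds.

    Nodes whose position survives keep their id; truncation points become
    fresh endpoint nodes with ids offset by 100000.
    """
    h, w = shape
    positions: dict[int, tuple[float, float]] = {}
    segments: list[VesselSegment] = []
    fresh = [100000]

    def inside(p):
        return 0 <= p[0] < h and 0 <= p[1] < w

    for s in tree.segments:
        path = t.apply(s.path)
        ok = np.array([inside(p) for p in path])
        if not ok.any():
            continue
        # longest contiguous inside run
        runs = []
        start = None
        for k, flag in enumerate(ok):
            if flag and start is None:
                start = k
            elif not flag and start is not None:
                runs.append((start, k))
                start = None
        if start is not None:
            runs.append((start, len(ok)))
        a, b = max(runs, key=lambda r: r[1] - r[0])
        sub = path[a:b]
        if len(sub) < 2:
            continue
        if a == 0:
            u = s.start_node
            positions[u] = tuple(sub[0])
        else:
            u = fresh[0]
            fresh[0] += 1
            positions[u] = tuple(sub[0])
        if b == len(ok):
            v = s.end_node
            positions[v] = tuple(sub[-1])
        else:
            v = fresh[0]
            fresh[0] += 1
            positions[v] = tuple(sub[-1])
        segments.append(VesselSegment(sub, s.width, u, v, s.depth))
    return VesselTree(segments, positions, shape)


def _inject_structure_noise(tree: VesselTree, spec: PhantomSpec,
                            rng: np.random.Generator) -> VesselTree:
    """Add spurious segments / delete leaves on the floating tree."""
    nz = spec.noise
    segments = list(tree.segments)
    positions = dict(tree.node_positions)
    if nz.delete_fraction > 0 and segments:
        counts: dict[int, int] = {}
        for s in segments:
            counts[s.start_node] = counts.get(s.start_node, 0) + 1
            counts[s.end_node] = counts.get(s.end_node, 0) + 1
        leaves = [k for k, s in enumerate(segments)
                  if counts[s.end_node] == 1]
        n_del = int(round(nz.delete_fraction * len(leaves)))
        for k in sorted(rng.choice(len(leaves), size=min(n_del, len(leaves)),
                                   replace=False), reverse=True):
            del segments[leaves[k]]
    if nz.structure_noise > 0:
        n_true = len({s.start_node for s in segments}
                     | {s.end_node for s in segments})
        n_spur_nodes = int(round(nz.structure_noise * n_true
                                 / (1.0 - nz.structure_noise)))
        h, w = tree.image_shape
        fresh = 200000
        tp = spec.tree
        n_added = 0
        attempts = 0
        while n_added < n_spur_nodes and attempts < 10 * (n_spur_nodes + 1):
            attempts += 1
            # alternate between spurs attached to the existing network
            # (fake bifurcations, the harder case) and free-floating segments
            attach = (attempts % 2 == 0) and positions
            if attach:
                anchor = sorted(positions)[
                    int(rng.integers(0, len(positions)))]
                start = np.asarray(positions[anchor], dtype=float)
            else:
                start = np.array([rng.uniform(10, h - 10),
                                  rng.uniform(10, w - 10)])
            heading = rng.uniform(0, 2 * math.pi)
            length = tp.segment_length * tp.length_decay ** 2 \
                * rng.uniform(0.6, 1.4)
            path, _ = _grow_segment(start, heading, length, tp.curvature,
                                    tree.image_shape, rng)
            if len(path) < 2:
                continue
            if attach:
                u = anchor
            else:
                u = fresh
                fresh += 1
                positions[u] = tuple(path[0])
                n_added += 1
            v = fresh
            fresh += 1
            positions[v] = tuple(path[-1])
            n_added += 1
            segments.append(VesselSegment(path, max(tp.min_width, 1.5),
                                          u, v, tp.depth))
    used = {s.start_node for s in segments} | {s.end_node for s in segments}
    positions = {k: v for k, v in positions.items() if k in used}
    return VesselTree(segments, positions, tree.image_shape)


def _jitter_tree(tree: VesselTree, jitter: float,
                 rng: np.random.Generator) -> VesselTree:
    if jitter <= 0:
        return tree
    positions = {}
    offsets = {nid: rng.normal(0.0, jitter, size=2)
               for nid in tree.node_positions}
    for nid, pos in tree.node_positions.items():
        positions[nid] = tuple(np.asarray(pos) + offsets[nid])
    segments = []
    for s in tree.segments:
        path = s.path.copy()
        # shift the whole polyline consistently with its endpoint jitter
        ramp = np.linspace(0, 1, len(path))[:, None]
        path = path + (1 - ramp) * offsets[s.start_node] \
            + ramp * offsets[s.end_node]
        segments.append(dataclasses.replace(s, path=path))
    return VesselTree(segments, positions, tree.image_shape)


def _overlap_fraction(t: SimilarityTransform, shape) -> float:
    """Fraction of the reference frame covered by the floating frame under t."""
    h, w = shape
    rr, cc = np.meshgrid(np.arange(0, h, 4), np.arange(0, w, 4),
                         indexing="ij")
    pts = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    pre = t.inverse().apply(pts)
    inside = ((pre[:, 0] >= 0) & (pre[:, 0] <= h - 1)
              & (pre[:, 1] >= 0) & (pre[:, 1] <= w - 1))
    return float(inside.mean())


def resolve_warp(spec: PhantomSpec) -> SimilarityTransform:
    """The ground-truth floating->reference warp, with overlap control.

    If ``overlap_target`` is set, a translation along the column axis is
    added (binary search, monotone in the shift) until the covered fraction
    of the reference frame matches the target within one percent.
    """
    t = spec.warp or SimilarityTransform.identity()
    if spec.overlap_target is None:
        return t
    target = spec.overlap_target / 100.0
    base = _overlap_fraction(t, spec.image_shape)
    if base <= target + 0.01:
        return t
    lo, hi = 0.0, float(sum(spec.image_shape))

    def with_shift(delta):
        return SimilarityTransform(t.scale, t.rotation,
                                   (t.translation[0], t.translation[1] + delta))

    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if _overlap_fraction(with_shift(mid), spec.image_shape) > target:
            lo = mid
        else:
            hi = mid
    return with_shift(lo)


def make_pair(spec: PhantomSpec, render_images: bool = True) -> PhantomPair:
    """Reference/floating phantom pair with full ground truth.

    The reference tree is generated from the seed; the floating tree is its
    image under the inverse ground-truth warp (the warp maps floating to
    reference), truncated to the floating frame, with structure noise and
    positional jitter applied.  Ground-truth correspondences are the node
    ids present in both graphs.
    """
    rng = np.random.default_rng(spec.seed)
    tree_ref = generate_tree(spec, rng)
    t_true = resolve_warp(spec)
    tree_float = _transform_tree(tree_ref, t_true.inverse(), spec.image_shape)
    tree_float = _inject_structure_noise(tree_float, spec, rng)
    tree_float = _jitter_tree(tree_float, spec.noise.jitter_px, rng)
    graph_ref = tree_to_graph(tree_ref)
    graph_float = tree_to_graph(tree_float)
    shared = sorted(set(graph_ref.nodes) & set(graph_float.nodes))
    pairs = [(n, n) for n in shared]
    image_ref = truth_ref = image_float = truth_float = None
    if render_images:
        image_ref, truth_ref = render(tree_ref, spec,
                                      np.random.default_rng(spec.seed + 1))
        image_float, truth_float = render(tree_float, spec,
                                          np.random.default_rng(spec.seed + 2))
    return PhantomPair(image_ref, image_float, graph_ref, graph_float,
                       t_true, pairs, truth_ref, truth_float, spec)


def make_graph_pair(spec: PhantomSpec) -> PhantomPair:
    """Graph-only phantom pair (no rendering); fast path for matching tests."""
    return make_pair(spec, render_images=False)
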