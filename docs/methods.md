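# Methods

This note records the modeling choices behind `fundusreg`, the defaults that
matter, and what the synthetic phantoms do and do not establish about
performance on clinical images.

## Vessel detection

**Model.**  A vessel cross-section is modeled as a dark ridge on a brighter
background whose profile is the Gaussian-Hermite mixture
`H(x) = (1 + a(x² − 1)) · (2πσ²)^{-1/2} exp(−x²/2σ²)`.  The Hermite term
reproduces the central light reflex of wide vessels; at `a = 0` the model
is a plain Gaussian.  The oriented response correlates the image with the
second derivative `H_vv` across the putative vessel and smooths with `H`
along it.  Because the vessel template is the *negated* kernel (dark on
bright), the response definition carries a leading minus sign that cancels
against the template's sign; the implementation therefore correlates with
`+H_vv` directly, and dark vessels score positive while bright ridges score
negative.  `x` is measured in pixels.

**Sampling and zero-mean correction.**  Kernels are sampled at integer
offsets over `[−h, h]` with `h = ceil(3σ)`.  The sampled `H_vv` is made
exactly zero-mean by subtracting its sample mean; without this, truncation
leaves a small DC residue and flat image regions would not yield an exactly
zero response (an invariant the tests assert).

**Defaults.**  `a = 0.3`, `σ = 1.2 px`, 12 orientations at 15°.  The
response of this kernel family peaks for profile widths near `1.8σ`;
`σ = 1.2` centers that optimum on the 2–4-px-wide vessels found in fundus
images resampled to roughly 700 × 600, and keeps 1-px capillaries above the
detection floor.  Profiles narrower than about `0.8σ` are penalized by the
Hermite side lobes — a single-scale filter cannot serve every caliber, and
multiscale banks are deliberately out of scope.

**Orientation handling.**  The image frame (not the kernel) is rotated per
orientation: reflect-padded by enough to cover the rotated diagonal,
bilinear interpolation, axis-aligned separable convolution, rotation back,
crop.  θ is the angle of the vessel tangent measured from the +column axis
toward the +row axis; rotating an image by exactly 90° shifts the winning
orientation bins by 6 (mod 12), up to interpolation effects at region
boundaries.

**Preprocessing.**  A 3 × 3 median filter precedes filtering.  Histogram
matching is applied only against an explicit reference image (normally the
other frame of the pair); mapping onto a uniform-equalized profile is
available but not the default, because rank-based equalization stretches
the dense background mode and amplifies noise into spurious responses.

**Threshold probing.**  Vessels are separated from background by seeded
region growing on the response map: the map is lightly smoothed
(Gaussian, `σ = 1.5` px — the orientation-bank maximum has scalloped level
sets that otherwise skeletonize into bristles), robust background
statistics are estimated (median and scaled MAD), seeds are pixels above
`med + 20·mad`, regions grow down to `med + 8·mad`, and a grown region is
accepted if its pixel count lies in `[30, 50000]`.  On essentially
noise-free maps (MAD ≈ 0) the thresholds fall back to 0.5/0.2 of the peak
response.  Thresholds tied to background statistics rather than to response
percentiles are essential when the vessel-area fraction varies, e.g. in
low-overlap frames where most of the image is empty.

**Thinning.**  Two-subiteration morphological thinning (Zhang-Suen family,
via scikit-image), iterated to a fixed point so re-thinning a skeleton is
the identity.

## Vascular structure graph

Nodes are skeleton pixels whose 8-neighborhood ring shows ≥ 3 branch
transitions (bifurcations; adjacent candidates merge to the cluster
centroid snapped onto the skeleton) or exactly 1 (endpoints).  Edges are
traced by breadth-first walks that prefer axial over diagonal steps, so
corners are followed through their corner pixel; `d_vp` accumulates 1 per
axial and √2 per diagonal step, `d_e` is the endpoint chord.  Node-free
cycles and dangling walks are dropped and logged.

Pruning applies three rules to a fixed point with the default threshold
`min_edge_px = 10`: short *leaf* edges (skeletonization spurs) are deleted;
short *interior* edges are contracted by merging their endpoints (junction
clusters that the skeleton split into nearby nodes) — deleting them instead
would fragment the graph; degree-2 nodes left behind are dissolved by
concatenating their two edges (`d_vp` adds, `d_e` is recomputed).

Attributes are normalized by the per-graph means (`a1 = d_vp / mean`,
`a2 = d_e / mean`), so every graph has mean attribute exactly 1 and the
representation is invariant under similarity transforms of the image.
Node kind (bifurcation vs endpoint) is metadata only; matching treats all
nodes uniformly.

## Graph matching

Compatibilities between edge pairs use equal weights `ω1 = ω2 = 0.5` on the
two attributes and the shared range `L_r = max` over both graphs, giving
values in [0, 1].  The |E1| × |E2| edge-similarity matrix is balanced by
alternating row/column normalization (tolerance 1e-6, ≤ 200 sweeps;
all-zero rows/columns are skipped and logged) — balancing suppresses
non-discriminative edges that would otherwise drag the assignment toward
ambiguous matches.

The graduated assignment loop anneals `β` geometrically from 0.5 by ×1.075
up to 30, with ≤ 30 softassign updates per β and ≤ 30 Sinkhorn sweeps per
update (inner tolerances 1e-3).  Two details matter in practice:

- **Scale-free annealing.**  Balancing shrinks compatibilities by roughly
  1/|E|, so `β·Q` would stay ≪ 1 and the schedule would never sharpen.  The
  gradient is therefore normalized to unit peak before exponentiation; the
  β schedule then behaves identically regardless of graph size.  `β_max =
  30` (rather than ~10) is needed for ~50-node extracted graphs to reach an
  assignment sharp enough to discretize.
- **Inequality constraints.**  Unequal graph sizes are handled by one slack
  row and column; real rows/columns (including their slack entry) are
  normalized to sum 1, the slack line itself is unconstrained.  After the
  final β a longer Sinkhorn polish runs (≤ 300 sweeps, tolerance 1e-9), and
  the result is projected exactly onto the inequality region by scaling
  down any row, then any column, that exceeds one — scaling down only ever
  decreases sums, so feasibility is exact rather than asymptotic (plain
  Sinkhorn converges only like 1/t when the slack mass is tiny).

Discretization keeps mutual row/column maxima above
`1/(min(n1, n2) + 1)`.  The matcher is fully deterministic: the match
matrix starts uniform and no randomness enters anywhere.

## STRUCT-SAC

Candidate samples are enumerated deterministically and symmetrically: every
matched node of degree 2 or 3 in either graph, with ≥ 2 matched neighbors.
(After pruning, interior nodes have degree ≥ 3, so degree-3 bifurcations
dominate the candidate pool.)  The local screen requires every matched
center-neighbor edge pair to agree in both attributes within `tol_edge =
0.25` relative to the attribute range, and every neighbor pair to subtend
angles at the center within `tol_angle = 20°` — both tests are invariant
under similarity transforms, so a correctly matched star passes regardless
of the unknown warp.  Unsigned subtended angles are used; a reflected
neighbor flips the angle and fails.

Surviving samples yield closed-form (Umeyama) similarity fits, scored by
`ε(θ) = Σ ρ²(‖residual‖)` with Huber scale `σ = 3 px` over mutual nearest
neighbors of *all* graph nodes within a 15-px gate (the correspondence set
is rebuilt fresh from each hypothesis, not restricted to input matches).
The squared-Huber form is the default; the conventional `ρ(‖t‖²)` reading
is a config switch.  The minimum-ε model is refined up to twice on its own
inliers, keeping the refit only if ε improves.  If no sample passes the
local screen the stage raises "insufficient stable structures" — the
method's documented failure mode at very low overlap or extreme structure
noise, where fewer than three stable nodes coincide.

## Quadratic ICP

The fine stage registers the full centerline point sets (not just nodes)
under the 12-parameter second-order polynomial map over monomials
`(r², c², rc, r, c, 1)`.  Fitting is weighted linear least squares solved
independently per output coordinate; coordinates are internally rescaled to
roughly [−1, 1] about the source centroid to condition the monomial design
matrix, and the fitted coefficients are mapped back to pixel units by exact
analytic expansion of the composed polynomial.  Rank deficiency (e.g.
collinear points) raises a degeneracy error naming the problem.

The loop runs coarse-to-fine with subsampling strides (4, 2, 1), pairing
gates (20, 10, 5) px, ≤ 50 iterations per level, and stops when the mean
residual changes by < 1e-3 px.  Pairing uses a kd-tree whose gated results
equal exhaustive search.  Pair weights are binary — a pair survives if its
residual is ≤ 2.5 × the current median residual — recomputed every
iteration; Huber influence weights are a config alternative.  Each
iteration refits the *original* source points of the level to their matched
targets, so the polynomial never compounds with itself.  Fewer than 6
usable pairs at the finest level raises an ICP divergence failure.

## Evaluation

CEM is the median distance over mutual-nearest-neighbor centerline pairs
within a 10-px gate after warping; a registration succeeds iff CEM < 3.0 px
(strict).  NCC is the Pearson correlation over the registered overlap and
NMI defaults to `(H(A) + H(B)) / H(A,B)` over a 64-bin joint histogram
(the `2I/(H(A)+H(B))` variant is a config option); both are computed on raw
intensities, with the overlap mask eroded by 2 px to exclude interpolation
borders.  The overlap percentage is the fraction of reference pixels whose
pre-image lies inside the floating frame; pre-images come from a quadratic
least-squares approximation of the inverse map, which is exact for affine
transforms and sub-pixel for the bounded quadratic warps used here.

## Phantoms: what they emulate, and what they do not

The generator grows binary trees from a disc-like origin (3 roots, depth 4,
segment length 110 px decaying ×0.82, branching angle 65° ± 8°, widths
4.0 px decaying ×0.85 down to 1.8 px, mild heading curvature) inside a
600 × 700 frame, and renders dark Gaussian-profile vessels (optional
central-reflex ridge) on a bright background with a smooth illumination
field and additive Gaussian noise (default σ = 0.02).  Branching angles and
calibers are in the range reported for human retinal arcades; the frame
matches the working resolution the pipeline targets.  Pairs are produced by
applying a ground-truth similarity (or quadratic) warp, cropping to a
target overlap via a monotone translation search, and injecting structure
noise at the *tree* level — spurious segments, half of them attached to
existing nodes so they corrupt real local structures, plus optional leaf
deletions and positional jitter — so images and graphs stay consistent.
Everything derives from the single spec seed and is bit-reproducible.

Phantoms do **not** emulate: pathology (lesions, exudates), the optic disc
and macula, vessel crossings of independent arterial/venous trees,
camera vignetting and chromatic effects, or inter-visit physiological
change.  Passing the phantom battery therefore demonstrates the geometric
and algorithmic correctness of the pipeline and its robustness to the
modeled noise sources — not clinical-grade performance, which the
undeposited clinical material would be required to establish.

A note on failure semantics: two *different* phantom trees from the same
generator can genuinely register (the shared disc origin and branching
statistics produce similar global layouts), so "unrelated inputs" is not a
reliable negative control; the graceful-failure path is instead exercised
with vessel-free frames and with all-wrong correspondence sets.

## Known limitations

- The single-scale matched filter misses vessels much narrower than ~1.5 px
  or much wider than ~2 σ above the kernel's optimum; widths are not
  estimated.
- Skeleton junctions displace from true bifurcation centers by up to a few
  pixels when vessel branches leave at shallow angles (the medial axis of
  the merged mask forks late).  The displacement is systematic and nearly
  identical in both frames of a pair, so registration is unaffected, but
  absolute junction localization is ~2 px at best.
- Matching uses only two scalar edge attributes; graphs with strong
  internal symmetry can lock onto a wrong assignment, which STRUCT-SAC can
  only repair if at least one stable structure is correctly matched.
- The quadratic model is fitted globally; it cannot represent local elastic
  deformation.
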