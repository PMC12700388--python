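# Methods

This note records the models, estimators and numerical choices behind
`skeletrace`, what the synthetic phantoms do and do not emulate, and the
known limitations.

## Saliency construction

A binary segmentation is turned into a twice-differentiable scalar field by a
Euclidean distance transform (foreground voxels carry the distance to the
nearest background voxel, background is 0) followed by an isotropic Gaussian
(`sigma`, default 2 voxels, reflective boundaries to avoid spurious ridges at
the volume faces). The ridge set of this field is the segmentation's
skeleton: the deepest voxels of a sheet lie on its mid-surface, of a tube on
its centerline, of a ball at its center. `sigma` should be of the order of
half the structure's thickness: much smaller and digitization corrugation
survives into the ridge; much larger and thin structures are washed out.
Anisotropic voxels are not supported — all distances are in (isotropic) voxel
units, converted to nm only when lengths are reported.

Two degenerate inputs are defined explicitly: an empty segmentation returns
an all-zero map with a warning, and an all-foreground segmentation treats the
volume faces as background so the transform is well defined (it then grows
from the borders and peaks at the volume center).

## Hessian eigen-decomposition

First derivatives are finite differences (centered by default, exact for
quadratics and free of the half-voxel bias of forward differences; the
forward scheme remains available via `scheme="forward"`), with replicate
padding at the boundary. Second derivatives apply the same stencil to the
first derivatives, so the discrete mixed partials commute (to floating-point
rounding; the two evaluation orders group additions differently, giving
relative differences of order 1e-13).

The per-voxel symmetric eigenproblem is solved analytically: eigenvalues by
the trigonometric (Cardano) solution of the characteristic cubic, vectorized
over the volume; eigenvectors as the largest cross product of rows of
`H - lambda I`. When the relative eigenvalue gap falls below 1e-6, or a cross
product underflows, that voxel is recomputed with an iterative dense
symmetric solver (`numpy.linalg.eigh`) — the analytic path is
ill-conditioned exactly where eigenvalues collide. Output is sorted by
descending |lambda|, stable on ties. Eigenvector sign is arbitrary and
immaterial downstream (probing is symmetric in +-v). Tests verify the
analytic eigenvalues against an independent Jacobi-rotation solver to 1e-8
relative on 1000 random matrices, plus the reconstruction identity
`sum_k lambda_k v_k v_k^T = H`.

## Non-maximum suppression and the dimensionality filter

`nms` implements the literal probing rule: a voxel with saliency above
`threshold` is a skeleton point of dimension `d` when it is a *strict* local
maximum along the top `3-d` eigendirections, with probes at `x +- delta*v_j`
evaluated by trilinear interpolation (coordinates clamped at the volume
boundary; one-voxel border excluded). `delta` defaults to 1/3 voxel:
sub-voxel probing is what makes a one-voxel-thick skeleton possible, and
strict inequalities prevent plateaus from producing thick skeletons.
A voxel where the field equals an all-volume minimum of a non-negative map
can never pass the strict test, so exact zeros are skipped as a pure
optimization.

Probing alone is not a sufficient dimensionality test. Around any curved
structure, the smoothed saliency tail has an inflection shell where the
second derivative along the gradient vanishes; there the largest-|lambda|
direction flips to a tangent of the level set, and every point of the shell
is a strict tangential maximum (moving along the tangent of a sphere of
radius r changes the radius to sqrt(r^2 + delta^2), strictly lowering a
radially decreasing field). These points satisfy the probe test yet have
|l1| ~ |l2|, both tiny — the spectrum of nothing in particular, not of a
surface. `skeletonize` therefore applies a dimensionality filter after NMS:
a d-manifold maximum must have its suppressed directions dominate its
manifold directions by an order of magnitude, `|l_{3-d}| >= 10 |l_{4-d}|`
(l1 >> l2 for center-surfaces, l2 >> l3 for centerlines; d = 0 checks all
three directions already and needs no filter). The factor 10 encodes "one
order of magnitude"; it is exposed as `skeletrace.nms.DIMENSION_RATIO`.
Without the filter, the inflection shell contributes ~1% stray points on
thin shells and up to ~40% on heavily thickened ones, which is what makes
the thickness-robustness of DICE_d (below) possible to demonstrate cleanly.
The raw probing rule remains available (`dim_filter=False`, or `nms`
directly) and is what the brute-force equivalence tests exercise.

The NMS threshold is applied to the saliency before evaluation (default 0 =
evaluate everything). For distance-transform saliency the threshold has
units of voxels-of-depth; a value around half the expected ridge height
(e.g. 1.5 for tubes of radius 4, whose smoothed ridge reads ~1.9) suppresses
weak corrugation maxima caused by digitizing oblique structures. Subsampling
(voxel-grid, keeping the point nearest each cell centroid) is off by default
and recommended before graph construction at roughly cell size 6 with
epsilon ~ 1.5x the cell size.

## Filament graphs and curves

Graph construction connects skeleton points closer than `epsilon` (strict
inequality; coincident points are merged first so zero-length edges cannot
arise). Cycles are removed per component by Kruskal's minimum spanning tree
on edge length with a deterministic tie-break (weight, then smaller node id,
then larger). Branch splitting processes nodes in ascending id: at each node
of degree m > 2 the pair of edges with the largest subtended angle — the
straightest continuation — is kept and each remaining edge is re-attached to
a duplicate node at identical coordinates (ties keep the first pair in edge
order; edge count is conserved; component count grows by exactly m - 2 per
branch node). Curves are read off per path component, ordered from the
lexicographically smaller endpoint, and can be filtered by geodesic length
in nm.

Curve descriptors use standard convergent discrete estimators chosen so that
closed-form validation is possible: Menger curvature (inverse circumradius of
three consecutive points — exact on circles), and torsion from the signed
volume of the chord tetrahedron of four consecutive points divided by the
product of pairwise arc-length differences and the window's squared
curvature; the sign carries handedness. Both reproduce the Frenet values of
a helix to better than 1% at ~0.14 radian sampling steps. Endpoint values
are replicated from the nearest interior estimate; below the minimum point
count (3 for curvature, 4 for torsion) the arrays are zero-padded with a
warning, and near-straight windows (curvature < 1e-12/nm) define torsion as
0 rather than 0/0. Persistence length is fitted as the negative inverse
slope, through the origin, of log tangent-correlation against arc-length
lag, pooled over index lags up to half the mean contour length and weighted
by pair counts; wormlike-chain simulations at l_p = 100 recover it within a
few percent when pooling 50 chains of 200 segments. Single-curve estimates
(as reported in `global_properties`) carry large variance and should be
pooled via `persistence_length(curves)` whenever several filaments are
available.

## Mean shift

Flat-kernel mean shift with every point a seed: iterate x <- mean of the
points within `bandwidth` of x until the displacement is below 1e-3 voxels
or 300 iterations. Converged modes closer than bandwidth/2 are merged
greedily in order of decreasing membership (ties by lower seed index), so
surviving centers are pairwise at least bandwidth/2 apart and every input
point is assigned to exactly one center. The procedure is deterministic.
The bandwidth should match the particle scale; note that descriptions of
this step vary between reading it as the particle *radius* and the
*diameter* — the implementation applies the given value as the kernel radius
with no hidden factor, so calibrate on your own data.

## Metrics

The dimension-aware Dice skeletonizes both segmentations with identical
parameters and no subsampling, then measures the fraction of each skeleton
lying inside the *other* segmentation (nearest-voxel lookup — segmentations
are binary, so interpolation would be meaningless) and takes the harmonic
mean. An empty skeleton contributes 0 with a warning. Because skeletons are
one voxel thick and invariant under thickening, the score is stable under
dilation of either input, unlike the voxel Dice. Precision reports use
correct/(correct + failed); detection F1 matches predicted and true centers
greedily in ascending pair-distance order with an acceptance radius of half
the particle radius (strict), each point matched at most once. Greedy and
optimal assignment differ only when acceptance balls overlap several
candidates, which does not occur at the separations used here.

## Phantoms

The phantom generators provide the study conditions for every test:

- membranes: unions of non-overlapping spherical shells, radius 18-40
  voxels, per-shell thickness drawn from 4-7 voxels (mimicking the uneven
  sheets of real segmentations; a lipid bilayer at ~1 nm/voxel is ~5 voxels
  thick), ground truth sampled on the exact mid-spheres;
- filaments: tubes of radius 4 voxels (actin-like at ~1 nm/voxel) around
  straight chords spanning the volume, helices, wormlike chains (free-space
  tangent random walks at l_p = 100 voxels, truncated where they leave the
  volume — the analogue of a filament crossing the field of view, chosen
  over wall-steering because truncation leaves the tangent statistics
  unbiased), or random trees with branch angles in [60, 150] degrees;
- blobs: non-overlapping solid balls (default radius 5 voxels, ribosome-like
  at ~1 nm/voxel) with exact centers.

All generators are seeded and bit-reproducible; placement is rejection
sampling with a hard cap of 1000 attempts, failing loudly rather than
degrading. The dilation utility used in the robustness experiments applies
iterative 6-connected (face-neighbor) morphological dilation; 26-connected
is available. Note that iterated discrete dilation is anisotropic (an
octahedral/cuboid ball), which genuinely displaces the medial surface of a
curved sheet by up to ~2 voxels at 5 iterations near lattice-axis poles —
an effect of the structuring element, not of the skeletonization.

Phantoms are noise-free binary masks: no missing wedge, no contrast transfer
function, no reconstruction noise, no segmentation errors. Tests on them
bound the algorithmic error of the tracing itself; performance on real
tomograms depends additionally on the quality of the upstream segmentation.

## Problem sizes

The validation suite uses 128^3 phantoms (10 membrane + 10 filament) for the
pooled precision figures, 96^3 for the tracing and robustness experiments,
and 32^3 volumes for the exact brute-force NMS comparisons; these sizes give
stable statistics while keeping a full run on a single CPU within a few
minutes. Real tomograms (e.g. 1023x1440x150 voxels) process in the order of
minutes per structure class on one core; the per-voxel eigenproblem and the
NMS probes are fully vectorized.

## Known limitations

- Isotropic voxels are assumed throughout.
- The d = 2 surface skeleton is a point set; surface meshing / connectivity
  labelling beyond graph components is out of scope.
- The epsilon-ball graph can bridge filaments that approach closer than
  epsilon; choose epsilon below the minimum expected filament separation.
- Signed curvature for 3D curves has no canonical convention and is not
  reported; torsion carries the handedness sign instead.
- Mean shift assumes roughly equal particle sizes per run (one bandwidth).
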