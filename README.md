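# skeletrace

Post-processing for cryo-electron tomography segmentations: turn binary or
multi-label semantic segmentations of cellular tomograms into
dimension-specific skeletons — center points for macromolecules, centerlines
for filaments, center-surfaces for membranes — plus filament graphs and
curves, particle centers, and topology-aware segmentation-comparison metrics.

A semantic segmentation is a set of voxels; it carries no topology, its
thickness depends on who or what drew it, and it cannot be measured directly.
`skeletrace` converts it into quantitative data structures while preserving
geometry and topology, for people who need filament lengths and curvatures,
membrane surfaces, or particle coordinates out of their tomograms.

## Method

The input segmentation is first converted into a smooth saliency map
S : R^3 -> R by a Euclidean distance transform (each foreground voxel carries
its depth, the distance to the nearest background voxel) followed by Gaussian
smoothing (default sigma = 2 voxels). Ridges of S coincide with the skeleton
of the segmentation. A probability map from a segmentation network can be
used as S directly.

Skeletons are extracted by non-maximum suppression (NMS) along the
eigenvectors of the Hessian H_S. At each voxel the symmetric 3x3 Hessian is
assembled from repeated finite differences and diagonalized in closed form
(Cardano's solution of the characteristic cubic, eigenvectors from cross
products, an iterative fallback for near-degenerate spectra), giving
eigenvalues |l1| >= |l2| >= |l3| with eigenvectors v1, v2, v3. A voxel x
belongs to the dimension-d skeleton S_d when it is a strict local maximum
along the top 3-d directions,

    S(x) > S(x + delta v_j)  and  S(x) > S(x - delta v_j),  j = 1..3-d,

with probe values trilinearly interpolated (default delta = 1/3 voxel), and
when its spectrum has the dimensionality of a d-manifold maximum
(|l_{3-d}| >= 10 |l_{4-d}|, i.e. l1 dominant for surfaces, l2 >> l3 for
lines). d = 0 gives blob centers, d = 1 filament centerlines, d = 2 membrane
center-surfaces — all one voxel thick.

Downstream of the skeleton:

- **Filaments.** Skeleton points become nodes of a spatially embedded graph;
  edges connect pairs closer than an epsilon-ball radius; cycles are removed
  by a minimum spanning forest (edges weighted by length); nodes of degree
  m > 2 are split, keeping the edge pair with the largest subtended angle
  (the straightest continuation) and moving the other m-2 edges onto
  duplicate nodes. Every component is then a simple path = one filament,
  exported as a discrete curve with local properties (arc length, tangent,
  Menger curvature, torsion from chord tetrahedra) and global ones (length,
  sinuosity, persistence length, total curvature/torsion).
- **Macromolecules.** The d = 0 point cloud is clustered by flat-kernel mean
  shift with the bandwidth set to the particle size, one center per particle.
- **Metrics.** The revised DICE_d compares two segmentations through their
  skeletons: TP_d = |S_d^in inside S^ref| / |S_d^in|, TS_d symmetric, and
  DICE_d their harmonic mean — insensitive to thickness differences that
  collapse the standard voxel Dice. Also included: skeleton-in-segmentation
  precision and detection F1 = 2TP / (2TP + FP + FN) with centers matched
  greedily within half a particle radius.

No external data is needed: a phantom module generates shell, tube and ball
segmentations with exact ground truth for every stage.

## Worked example

```python
from skeletrace import (blob_phantom, skeletonize, mean_shift, detection_f1,
                        membrane_phantom, dilate, dice_d, voxel_dice)

# 20 spheres of radius 5 voxels in a 128^3 volume
seg, truth = blob_phantom(shape=128, n_blobs=20, radius=5, min_separation=20, seed=0)
cloud = skeletonize(seg, d=0)                      # blob-center maxima
centers = mean_shift(cloud, bandwidth=5.0)         # one mode per particle
report = detection_f1(centers, truth.gt_centers, particle_radius=5.0)
print(f"{len(cloud)} raw maxima -> {len(centers)} centers")
print(f"TP={report.tp} FP={report.fp} FN={report.fn} F1={report.f1:.3f}")

# thickness robustness of the topology-aware Dice
shell, _ = membrane_phantom(shape=96, n_shells=1, radius_range=(25, 32), seed=3)
thick = dilate(shell, 3)                           # thicken one segmentation
print(f"voxel Dice: {voxel_dice(thick, shell):.3f}")
rep = dice_d(thick, shell, d=2)
print(f"DICE_2: {rep.dice_d:.3f} (TP_2={rep.tp_d:.3f}, TS_2={rep.ts_d:.3f})")
```

prints

```
29 raw maxima -> 20 centers
TP=20 FP=0 FN=0 F1=1.000
voxel Dice: 0.651
DICE_2: 1.000 (TP_2=1.000, TS_2=1.000)
```

All 20 planted centers are recovered exactly (F1 = 1.0). Dilating one shell
segmentation three times drops the voxel Dice to 0.651 although the membrane
itself has not moved; the skeleton-based DICE_2 still reads 1.0 because both
skeletons stay inside both segmentations.

The same operations are available from the shell:

```sh
skeletrace phantom --kind membrane --shape 128 --seed 0 --out seg.mrc
skeletrace skeletonize --in seg.mrc --dim 2 --sigma 2 --out skel.csv
skeletrace trace --in skel.csv --epsilon 9 --out-prefix fil
skeletrace curves --in fil_curves.csv --voxel-size 1.0 --out props.csv
```

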