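# Methods

This note records the scientific and numerical choices behind `caveclass`:
what each stage assumes, which knobs matter, and what the synthetic data do
and do not establish about real SMLM experiments.

## Problem setting

The input is an SMLM eventlist: one row per detected molecule with X, Y, Z
in nm (or in camera pixels — 20 nm XY, 25 nm Z — converted at ingest; the
declared Z acquisition range is ±400 nm). The goal is to decide, for each
segmented 3D cluster of Cav1 localizations (a *blob*), whether it is a
caveola (positive class) or a non-caveolar structure. Ground-truth labels
for training come from a wide-field CAVIN1/PTRF mask: a blob is a caveola
iff it overlaps the mask (PTRF+) **and** contains at least 60 molecules.
Cells without CAVIN1/PTRF cannot form caveolae, so their blobs are negative
a priori; in the pipeline such cells are declared mask-free and labeled
all-PTRF− directly.

## Pre-processing

**Iterative merging** (multiple-blinking correction). One fluorophore can
blink several times, producing a tight clump of localizations. Repeatedly:
group points into connected components of the ≤20 nm adjacency relation,
replace each component by its centroid; stop when no pair is within 20 nm.
Component-wise grouping (rather than greedy pairwise merging) makes the
result independent of point order. The rule is accepted as stated even in
its degenerate cases — a long chain spaced just under the radius collapses
to one centroid. Merging is idempotent and never increases the point count.
A blob's molecule count is taken *after* merging (merged points are the
reconstructed molecules).

**Noise filtering.** Unclustered background localizations are removed by a
local-density test against complete spatial randomness (CSR): a point is
retained iff its neighbor count within `neighbor_radius_nm` (default 50 nm)
exceeds the CSR expectation λ = ρ·(4/3)πr³ — with ρ the dataset's global
density over its bounding box — by more than `k` (default 2) Poisson
standard deviations. This is a deliberately simple, testable criterion with
the same intent as cluster-vs-random-network feature comparisons: clustered
points survive, homogeneous background is rejected at roughly the Poisson
tail rate implied by `k`. It ignores edge effects (points near the bounding
box have truncated neighborhoods), which only makes it slightly more
conservative.

**Segmentation.** Blobs are connected components of the ≤radius adjacency
graph. The radius (default 80 nm) must exceed the merge radius and stay
well below inter-blob distances; it is exposed in `PreprocessConfig`. Blob
ids are ordered by each component's minimum source row, so segmentation is
deterministic.

**Labeling, stratification, balancing.** A blob is PTRF+ iff the fraction
of its points whose XY position falls inside a positive mask pixel is
≥ 0.5 (inclusive; threshold configurable). Caveolae = PTRF+ with ≥60
molecules. The majority class is then downsampled uniformly at random to
the minority count. These three steps only annotate or drop blobs — the
geometry is carried through bitwise.

## The 28 features

Order is frozen (`caveclass.features.FEATURE_NAMES`): size
(n_points, range_x/y/z, hull_volume, density), shape (λ₁, λ₂, λ₃, c_linear,
c_planar, c_spherical, FA), hollowness (min/max/mean/median/SD of distances
to the centroid), network (n_edges, mean/max/SD degree, mean clustering,
characteristic path length, global efficiency, modularity, degree
assortativity, graph density). Notes:

- Eigenvalues come from the sample covariance (N−1) of mean-centered
  points; the Westin formulas define the linear/planar/spherical
  coefficients (they sum to 1 whenever Σλ > 0). For N < 3 the shape block
  is set to a zero sentinel and flagged.
- Hull volume is the 3D convex-hull volume; coplanar/collinear blobs get
  volume 0. The density N/(V + 1 nm³) is regularized so degenerate hulls
  stay finite (small anisotropic blobs can have near-coplanar samples).
- Sample (N−1) standard deviations are used for hollowness and degree
  spread because blobs are small.
- The proximity threshold for the network block is global: the maximum over
  blobs of the longest Euclidean-MST edge, i.e. the smallest threshold at
  which every blob in the dataset is one connected component. A per-blob
  bottleneck mode is available (`BlobFeaturizer(per_blob_threshold=True)`).
- Network measures are computed analytically (dense adjacency algebra and
  BFS shortest paths); the greedy-agglomerative modularity partition comes
  from igraph's deterministic fast-greedy implementation. Degree
  assortativity is undefined on degree-regular graphs (zero variance); it
  is set to 0 there so the vector stays finite. A single-point blob gets
  the all-zero network sentinel.

All 28 features are translation invariant; all but the three axis ranges
are rotation invariant.

## Multi-view projections

A blob is centered (centroid → raster center) and each point sets one pixel
in each of three orthogonal views (xy, yz, xz); pixel assignment is
floor((coord − centroid)/pixel size) with half-open intervals. The default
raster is 512×512 at 1 nm — covering the 512 nm maximum blob extent — where
at most 512 of 2¹⁸ pixels are occupied (0.2% non-zero), which is also why a
full 512³ voxel grid (2²⁷ cells, 4·10⁻⁴ % non-zero) is not offered as a
model input. Binary pixels are the default; a count mode exists for
experimentation.

## Classifiers

**Random forest.** 100 bagged trees (scikit-learn), majority vote,
remaining hyperparameters at library defaults; the fitted model stores the
frozen feature order and refuses matrices declared in any other order.

**MVCNN.** Conv ladder (3→32), (32→64), (64→128), (128→256), (256→512),
each stage followed by a 3×3 non-overlapping max pool, then fully connected
256, 512, 2; ReLU everywhere except the final softmax; loss is
cross-entropy plus an L2 weight penalty; targets are one-hot ([1,0]
positive, [0,1] negative). Kernel geometry is not uniquely determined by
the layer list alone, so the implementation fixes 3×3 kernels, stride 1,
same padding, pool stride 3 (floor sizes: 512→170→56→18→6→2). The three
views enter as the three channels of one image. The ladder, image size and
head are configurable; the scaled configuration used in tests is 64-px
views (3 nm pixels), channels (8, 16, 32), one FC(32) hidden layer.

**PointNet-style.** A shared per-point dense stack (default 32→64→128)
lifts each point, an elementwise max over the point axis aggregates the set
(exactly permutation invariant), and a dense head (64→2) classifies.
Following the minimal variant of the source architecture, there is no
dropout and no input jittering. Batching pads every set to 512 points by
cyclic duplication, which the max cannot see. Points are centered at an
order-independent centroid (sorted summation) and divided by a fixed 10 nm
scale — one σ of the simulated blobs — purely to condition the
He-initialized layers; being a global constant, it preserves blob size
information. Both nets train with Adam (10⁻³, L2 10⁻⁴ by default) on a
small numpy backprop core (`caveclass._nn`, float32, fully seeded), keep
the best-on-validation checkpoint, and abort on non-finite loss.

## Simulated data

Each blob is N i.i.d. draws from a zero-mean 3D normal: positive/isotropic
Σ = diag(σ²,σ²,σ²), negative/anisotropic Σ = diag(2σ²,σ²,σ²), σ = 10 nm;
N uniform on 60–210 (positive) and 10–160 (negative), 1000 blobs per class.
Sampling applies the Cholesky factor of Σ to standard-normal draws; a
master seed spawns one substream per blob, so datasets are bitwise
reproducible and order independent. Two points worth flagging: the
anisotropic covariance as printed is *prolate* (one doubled variance →
elongated), although such structures are often described as planar — the
covariance is implemented exactly as printed; and the point-count
distribution is taken as discrete uniform with inclusive bounds, the
minimal assumption when no distribution is named.

The simulator mimics only the two-class shape contrast. It has no
localization error, no multiple-blinking artifacts, no background noise, no
membrane curvature, and its classes differ by a single covariance factor.
Passing the simulated validation therefore establishes that the feature
extraction and classifiers recover a known shape difference at realistic
point counts — not that real caveolae/scaffold discrimination reaches the
same accuracy. The synthetic multi-cell experiment
(`caveclass.synthetic_cells`) adds the missing workflow elements (several
cells, background localizations, a painted PTRF mask, unbalanced classes)
so the full pipeline is exercised end to end, but its geometry is likewise
idealized (well-separated jittered-grid clusters).

## Problem sizes and evaluation choices

- Cross-validation is stratified (the datasets are balanced by
  construction; stratification preserves that per fold) and reported as
  pooled confusion counts over folds; the per-fold reports and their mean
  are also emitted.
- The mixed split draws class-stratified test/validation sets (defaults
  200/100, the remainder trains); the cell-wise split assigns membership by
  cell id only, so no blob of a held-out cell can leak into training.
- The full-scale simulated validation (2000 blobs, 100 trees, 10-fold CV)
  runs in a few minutes on one CPU. The deep models are exercised at
  reduced scale — 64-px views with a (8, 16, 32) ladder, and the default
  PointNet at 60 epochs on a 1200/200/600 split — which reaches >0.9
  held-out accuracy in minutes; full 512-px training is supported by the
  same code but is a GPU-scale undertaking.
- t-SNE embeddings standardize features first and are deterministic per
  seed (perplexity 30 by default, clipped for small n).

## Known limitations

- The exact 28-feature identity, eventlist dialect, segmentation radius and
  mask-overlap rule of the original workflow are not fully specified
  anywhere; this package freezes documented, configurable choices (listed
  above) rather than guessing at hidden ones.
- The CSR noise filter is a stand-in for cluster-vs-random-network feature
  comparison; it shares the intent, not the exact statistics.
- MVCNN/PointNet parameter counts depend on kernel geometry choices and are
  not comparable to any particular published totals.
- `morphological_close` uses a disk structuring element; masks are assumed
  axis-aligned with the SMLM frame with a configurable origin (default 0).
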