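# Methods

## Problem and pipeline

The package classifies single axial brain-MRI slices (FLAIR-like contrast,
224×224×3 after resizing) as *normal* or *MS*. The pipeline is a fixed chain:
feature extraction (deep + hand-crafted), per-block feature selection by a
Brownian-walk firefly algorithm (BFA), serial fusion, and cross-validated
binary classification. Every stage is deterministic given its seed; a single
master seed fans out to per-stage seeds via
`numpy.random.SeedSequence(master, spawn_key=(stage_index,))`, so end-to-end
runs are bit-reproducible and interrupted runs can be resumed.

## Synthetic phantom generator

Real curated MS slice datasets are not redistributable, so the package ships
a phantom generator that every test and the acceptance script run on. A
phantom is a dark background (gray level 10), an elliptical parenchyma
(semi-axes 85×70 px, level 130), an optional skull annulus (level 230, ~7 px
thick) and, for the MS class, hyperintense lesion blobs with a Gaussian
radial profile placed uniformly inside the parenchyma; i.i.d. Gaussian noise
(σ = 5 gray levels) is added last and the result is clipped to 8 bits and
replicated to three channels.

Defaults and why:

| parameter | default | rationale |
| --- | --- | --- |
| `image_size` | 224 px | the pipeline's fixed input geometry |
| `lesion_intensity_gain` | 1.6 | FLAIR lesions are markedly hyperintense; peak = 1.6× parenchyma |
| `lesion_count_range` | (2, 5) | MS presents with multiple lesions; curated MS slices show several |
| `lesion_radius_range` | (5, 12) px | ≈4–11 mm at this matrix size, typical lesion calibre |
| `noise_sigma` | 5 | visible grain without obscuring lesions |
| `with_skull` | true | both with/without-skull conditions are studied |

The generator guarantees (and the suite empirically verifies) that the mean
intensity inside the parenchyma linearly separates the classes at 50 slices
per class: the smallest admissible lesion load (two 5-px lesions) raises the
parenchyma mean by ≈0.3 gray levels, while the standard error of a normal
slice's parenchyma mean is ≈0.04. This is the property that entitles the
end-to-end accuracy checks to expect near-perfect classification.

What the phantoms deliberately do **not** model: anatomy (ventricles, gyri,
gray/white contrast), partial-volume effects, bias fields, modality physics,
or 3D lesion continuity. Passing the phantom suite therefore demonstrates
that the pipeline machinery is correct and discriminative signal is
propagated — not that clinical-grade accuracy would be achieved on patient
data.

## Deep feature backbones

All backbones are frozen feature extractors emitting exactly 1000 features
per slice; nothing is trained. The pretrained ImageNet networks use their
1000-wide logit layer (the only 1000-wide layer) and are optional: they
require `torch`/`torchvision`, and requesting one without those installed
raises a dependency error pointing at the default backbone.

The default `test_projection` backbone averages each channel to its global
mean intensity and applies a fixed seeded random affine map
(weights ~ N(0, 1/√d_in), bias ~ 0.1·N(0,1)) to 1000 dimensions. Global
pooling is the fully position-tolerant limit of the average pooling the
pretrained networks end in, and that position tolerance is the property the
downstream stages actually need from a stand-in: lesion *presence* rather
than lesion *position* must drive the representation, as it does for
semantic CNN features. Finer pooling grids were evaluated and rejected: with
a g×g grid the representation's within-MS variance is dominated by where
lesions happen to fall, which overwhelms the between-class distance and
breaks distance-based classifiers — a failure of the stand-in's fidelity,
not of the pipeline. The cost of the choice is a low-rank feature block
(rank ≤ 3, rank 1 for channel-replicated input); the block still satisfies
the extractor contract (1000 finite features, linear in pixels up to the
bias, seeded determinism, class-mean separation on phantoms), which is what
the tests assert.

`epochs`, `optimizer` and `pooling` in the backbone spec are provenance
metadata only (epochs default 100); `batch_size` (default 8) batches
pretrained inference.

## Hand-crafted features

**LBP.** Uniform local binary patterns with 8 circular neighbours at radii
W = 1, 2, 3, 4; neighbours are sampled with bilinear interpolation
(scikit-image `nri_uniform`), a neighbour equal to the centre compares as ≥
and codes 1, and only interior pixels (full neighbourhood inside the image)
contribute. Each radius yields a 59-bin histogram (58 uniform codes + 1
catch-all) normalized to sum 1; the four histograms are concatenated to 236
features. One numerical caveat: where an interpolated neighbour ties the
centre *exactly* (constant patches), the floating-point resolution of the
tie depends on the intensity magnitude, so such pixels' codes are not
strictly invariant under a global intensity shift; generic images are.

**PHOG.** Sobel gradients of the grayscale image give magnitude and signed
orientation in [0°, 360°); a Canny edge map (σ = 1, fixed absolute
thresholds 0.1/0.2 on the unit intensity scale) masks the magnitudes, and
magnitude-weighted orientation histograms are computed for the whole image
(level 0) and a 2×2 cell partition (level 1), level 0 first, cells
row-major. Each level's block is L1-normalized unless its total mass is zero
(blank image), in which case it stays zero. Bin counts 17 and 34 give
descriptors of 85 and 170 features; because the cells partition the image
and share one gradient map, the four level-1 cell histograms sum exactly to
the level-0 histogram.

The combined hand-crafted vector is `[LBP-236 | PHOG-85 | PHOG-170]`, 491
features, with block offsets carried as metadata.

## Firefly feature selection

Positions live in `[0,1]^d`, one firefly per candidate solution (default
population 20, 100 iterations, β₀ = 1, γ = 1, Brownian σ = 0.1). A position
is binarized by rank — its `target_k` largest coordinates (ties to the lower
index) mark retained features — so every candidate mask has exactly the
target size; defaults are k = 618 for the 1000-dim deep block and k = 224
for the 491-dim hand-crafted block. Mask fitness is the Euclidean distance
between class centroids on per-feature z-scored data restricted to the mask;
z-scoring stops high-variance features from monopolizing the distance. The
fitness is additively separable per feature, so it is computed from
precomputed standardized class-mean gaps — mathematically identical to the
direct masked evaluation, which the public `subset_fitness` implements and a
test equates. Constant features are given zero gap rather than dividing by a
zero standard deviation.

Within an iteration every firefly moves toward each brighter one in index
order, with attraction `β₀ exp(−γ d²)` (squared-distance form, the canonical
formulation) and a Brownian perturbation per move; brightness is cached at
the iteration start. A fly with no brighter neighbour takes a pure Brownian
step — without this, once all flies hold the same mask (fitness depends only
on the mask) no fly is strictly brighter and the swarm would freeze.
Elitism keeps the best mask ever evaluated, so the fitness trace is
non-decreasing. `brute_force_select` enumerates all subsets (bounded at
10^5) as an independent oracle; ties break lexicographically.

## Classification and evaluation

The positive class is MS (encoded 1). Classifiers are scikit-learn
pipelines with a `StandardScaler` fit on training folds only: softmax/
logistic (SM), Gini decision tree (unlimited depth), random forest (100
trees), Gaussian naive Bayes, KNN (k = 5, Euclidean), and SVMs with linear
and RBF kernels (C = 1, RBF γ = 1/d). None of these hyperparameters are
tuned; they are fixed for reproducibility.

The headline evaluation is stratified five-fold cross-validation; per-fold
confusion counts are pooled and the metric suite (AC, PR, SE, SP, FS) is
computed from the pooled counts on the percent scale, rounded half-up to two
decimals (the rounding that reproduces every cell of the bundled benchmark
tables). A zero denominator yields 0.00 with a warning rather than NaN. An
80/10/10 stratified train/test/validation split (largest-remainder per
class) is also provided for protocol parity. ROC curves place one point per
threshold between distinct scores and integrate by the trapezoid rule;
continuous scores are class-1 probabilities where available, decision
values otherwise.

## Problem sizes

The test-suite and acceptance-script runs use 50 phantoms per class for
end-to-end checks (100 slices, five folds of 20), 20 seeds for swarm
robustness statistics, and d = 12, k = 3 (220 subsets) for exhaustive-oracle
comparisons — sizes at which every quantity is recomputed from scratch in a
few minutes on one CPU while keeping the statistical checks meaningful.

## Known limitations

- The phantom family is geometric, not anatomical; results on phantoms bound
  correctness of the machinery, not clinical performance.
- The default backbone is a low-rank linear stand-in; semantic deep features
  require the optional pretrained backends.
- The BFA fitness is filter-style (class-centroid separation), not a wrapper
  around classifier accuracy; with a separable fitness the selector's global
  optimum is the top-k standardized gaps, so the swarm is validated against
  that optimum rather than claimed to solve a harder landscape.
- Uniform-LBP tie codes are floating-point sensitive on exactly constant
  patches (see above).
- NIfTI ingestion assumes the third array axis is axial; permute volumes
  beforehand if their orientation differs.
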