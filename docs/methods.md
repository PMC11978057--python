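# Methods

`macaqueid` implements a classical face-recognition pipeline for the
individual identification of macaques (or any small cohort of visually
distinct animals) from face crops, plus a near-real-time identification
layer for video. This note records the models, the defaults and why they
were chosen, what the synthetic data generator does and does not emulate,
and the numerical decisions that were genuinely open.

## Pipeline overview

```
frame → detect (pluggable) → crop → grayscale (channel mean) → resize 300×200
      → features (EF | LBP-H | SIFT-BoW | SURF-BoW)
      → classifier (SVM linear/poly2/poly3/RBF, LDA, kNN) → per-class confidence
      → [video only] 0.5 s pooling → frames×classes table → majority vote
```

### Preprocessing

Grayscale is the plain arithmetic mean of the RGB channels, rounded
half-up in exact integer arithmetic so results are platform-independent.
The canonical resolution is 300×200 (height × width). The literature this
follows writes the size without naming the axes; face crops are taller than
wide, so the portrait orientation is the default, kept in
`imaging.CANONICAL_SHAPE` rather than hard-coded so the landscape reading
can be swapped in. Resizing is bilinear without an anti-aliasing
prefilter, which keeps output intensities inside the input's [min, max]
envelope. Video is resampled to 10 frames/s by nearest-previous frame
selection — never interpolation, because identification must operate on
real frames.

### Eigenfaces (EF)

Images are flattened to 60,000-dimensional vectors, mean-centered, and
decomposed by PCA; projections onto the leading components are the
features. With a few hundred samples the pixel-space covariance is rank
deficient, so the decomposition uses the snapshot method (eigendecompose
the n×n Gram matrix of the centered data and map back); this is exact and
avoids a 60,000-dimensional eigenproblem. Components are retained until
the cumulative explained-variance ratio reaches 0.90 — the minimum count
achieving the bound, including a component that hits it exactly.
Numerically-null directions (eigenvalue < 1e−12 of the largest) are
dropped before the retention rule; a dataset of identical images raises a
degenerate-data error rather than fabricating a basis.

### LBP histograms (LBP-H)

Each interior pixel receives an 8-bit code: bit b is set when neighbor b
compares `>=` against the center, neighbors ordered clockwise from the
top-left, least-significant bit first. Neighbor positions are
integer-rounded circle offsets (for radius 1 and 8 neighbors, the 8
adjacent pixels), so no interpolation is involved and the code depends only
on intensity *order*: any strictly increasing intensity remap leaves the
descriptor bit-identical. This exactness holds on unquantized intensities;
8-bit quantization can merge nearly-equal values and is the one practical
deviation from it. Codes are histogrammed per cell of an 8×8 grid
(remainder pixels to the last cells), each cell L1-normalized, and
concatenated (8·8·256 = 16,384 dims). The radius/neighborhood/grid and the
`>=` convention are package defaults in `LBPSpec` — the classical
formulation — and all configurable; codes are computed only where the full
neighborhood fits, avoiding padding artifacts.

### Keypoints and bag-of-visual-words

SIFT descriptors (128-dim) come from scikit-image with `upsampling=1`
(faces are already large; the initial 2× upscale costs 4× time for no
benefit at this scale). The detector exposes no per-keypoint strength, so
strength is measured as the scale-normalized |LoG| response σ²|∇²G∗I| at
the keypoint's position and scale; keypoint sigmas are binned to a
geometric grid (ratio 1.25) so only a handful of LoG filters are run — the
response is a ranking key, and a <12% scale error does not reorder blobs.

The SURF-style extractor is authored in-package: keypoints are local
maxima of the scale-normalized determinant of the Hessian over the scale
stack σ ∈ {1.6, 3.2, 4.8, 6.4}; the 64-dim upright descriptor sums
first-order Gaussian-derivative responses (Σdx, Σ|dx|, Σdy, Σ|dy|) over a
4×4 grid of subregions spanning 10σ, L2-normalized. Orientation
assignment is omitted (upright variant): face crops arrive roughly
upright after detection and the synthetic pose jitter is ±5°.

Only the strongest keypoints are kept — 5 for SIFT, 3 for SURF — ranked
by descending response with (y, x) scan order breaking ties, so extraction
is deterministic. Pooled training-fold descriptors are clustered by
k-means into a 200-word vocabulary (fixed seed); each image becomes the
L1-normalized histogram of nearest-centroid assignments. Normalization is
a package choice (the counts are "frequencies"); it makes images with
different keypoint counts comparable, which matters under top-k
truncation. An image with no descriptors encodes to the zero vector. The
codebook is refit per cross-validation fold on training descriptors only.

### Classifiers and tuning

Six classifiers: SVM with linear, quadratic, cubic and RBF kernels
(one-vs-one multiclass), LDA in standard form (untuned), and kNN with
Euclidean distance. Features are standardized (z-scored on the training
portion) before classification so the conventional search ranges mean the
same thing for eigenface projections (raw scale ~10³) and histogram
features (~10⁻²).

Hyperparameters are tuned by Bayesian optimization — a Gaussian-process
surrogate (Matérn 5/2 + white noise) with expected-improvement acquisition
over a random candidate set — maximizing mean accuracy on an inner
stratified 5-fold split of the training fold (never test data), with a
hard cap of 50 objective evaluations per model. Search spaces: C ∈ [1e−3,
1e3] (log), RBF γ ∈ [1e−5, 10] (log), polynomial coef0 ∈ [0, 10], kNN k ∈
[1, 25]. The first evaluated point is the conventional default (C = 1,
γ = 1/d on standardized features, coef0 = 1, k = 5), which keeps small
search budgets from landing in degenerate corners; remaining initial
points are random. A failed objective evaluation scores −∞ and the search
continues. Everything is deterministic for a fixed seed.

Per-class confidences: SVMs use Platt-style sigmoid calibration on
internal training folds; LDA its posteriors; kNN neighbor-vote fractions.
All are clipped non-negative and renormalized to sum to one — the voting
layer consumes exactly these vectors. How SVM margins become
"confidences" is underdetermined in the classical literature; Platt
calibration is this package's declared choice.

Implementation note: all four SVM kernels are functions of inner products
or squared distances, so each training call computes the linear Gram
matrix once and derives every candidate kernel from it
(`SVC(kernel="precomputed")`). On 16,384-dim LBP features this turns
multi-second fits into milliseconds without changing the fitted model.
kNN tuning likewise reuses one precomputed distance matrix.

### Cross-validation and the comparison grid

Stratified 10-fold CV with a fixed shuffle seed; a class with fewer
samples than folds raises an error naming the class (stratification keeps
unbalanced cohorts stable). Per fold, all feature state that involves
fitting (eigenbasis, codebook) is refit on training indices only, and the
extractor records those indices (`fit_history`) so leakage is auditable
after the fact. Both the mean of fold accuracies and the pooled fraction
correct are reported; the grid CSV displays the pooled value to 2
decimals. The extractor × classifier grid reuses one fold assignment for
every cell and computes features once per (extractor, fold), shared by all
classifier rows; a failed cell is marked NaN and the grid completes.
Per-class precision is diagonal over column sum; classes never predicted
are reported as absent rather than zero.

The benchmark harness defaults to 6 Bayesian-optimization evaluations per
fit (the cap stays 50) — a desk-scale choice: with the anchored default
as the first evaluation, accuracy on the synthetic benchmark saturates
well before the cap, and the full 24-cell grid stays in the minutes range
on one CPU.

### Realtime layer

Frames are pooled in half-open windows of 0.5 s, updated every 0.5 s (so
windows partition the timeline — no frame votes twice); at 10 frames/s a
full window holds exactly 5 frames. Each detected crop contributes one
row of per-class confidences to the window's table; each row votes for its
argmax; the modal class wins. Ties break by larger summed confidence over
the tied classes, then lexicographic identity order — both invented here,
since "most common outcome" underdetermines them. A window with fewer
than `min_rows` rows (default 1, i.e., only empty windows) abstains rather
than fabricate an identity. When several faces appear, detections are
linked across the window's frames into chains by IoU ≥ 0.3 continuity;
the longest chain decides the window. The session log is JSON-lines with
sorted keys and fixed rounding, so identical sessions produce identical
bytes; the result for window [t, t+0.5) depends only on frames with
timestamps below t+0.5. The single-selected-identity display mode emits
overlay events (bounding box of the last contributing frame) only for
windows predicting the selected identity.

## Synthetic data generator

No face recordings ship with the package, so `synth` renders procedural
face crops: an elliptical face with two eye discs, a brow band, a muzzle
with nostrils, and a band-limited fur-noise texture fixed per identity.
Identity lives in both global geometry (eye spacing, face axes, muzzle
size — favoring holistic eigenface features) and texture statistics (fur
frequency/contrast — favoring LBP), so all four extractor paths are
exercised non-trivially. Identities are drawn by rejection sampling with
pairwise parameter separation ≥ 0.8 (10-dim unit cube; typical random
pairs sit near 1.3, so the constraint prunes near-duplicates without
distorting the distribution).

Nuisance variation per image: lighting gain ∈ [0.85, 1.15], additive
lighting gradient ±15 intensity units across the image, pose jitter ±5 px
translation and ±5° rotation, Gaussian sensor noise σ = 8, optical blur
σ = 0.6 px. These defaults emulate the uncontrolled-lighting,
hand-held-camera conditions of the motivating application. The rendering
chain is scene → blur → lighting → noise, so a pure gain change is an
exact elementwise monotone map of the scene (used to verify LBP
invariance). The default cohort is 8 identities × 60 images, matching a
single-housing registration cohort; unbalanced per-identity counts (e.g.,
21–182) are supported for mimicking real registration sets.

What the generator does **not** emulate: real macaque facial morphology,
expression changes, occlusion, motion blur, out-of-plane pose, detector
localization error (the fixture detector replays ground-truth boxes), or
inter-individual similarity of real conspecifics. Passing benchmarks on
synthetic data therefore demonstrate that the pipeline's machinery is
correct and leakage-free and that its accuracy degrades sensibly with
noise — not that any particular accuracy transfers to real animals.

Group-cage video is emulated by compositing one identity's rendered face
per ~3 s segment onto a larger frame at jittered positions, with a
ground-truth sidecar (boxes + identity per frame) consumable by the
fixture detector.

## Problem sizes and seeds

The shipped benchmark sizes are desk-scale choices: the end-to-end grid
runs on 8 × 60 images with 10-fold CV and a 6-evaluation tuning budget;
the noise-robustness sweep uses 8 × 20 images across noise σ ∈ {0, 15,
30} and 3 seeds; sessions are 10 s at 10 frames/s. Every stochastic
component (population draw, per-image render configs, k-means, fold
shuffling, hyperparameter search, Platt calibration) takes an explicit
seed, and the acceptance script derives all of them from its single
`--seed` argument.

## Known limitations

- The SURF-style extractor is upright and uses Gaussian derivatives
  rather than integral-image box filters; it reproduces the SURF design's
  detector/descriptor structure, not its exact numerics or speed profile.
- LDA on 16,384-dim LBP features with a few hundred samples is heavily
  rank-deficient; scikit-learn's SVD solver handles it, but the cell is
  expected to be weak on small synthetic sets.
- Confidence calibration quality is not itself benchmarked; the voting
  layer only consumes argmax and relative sums.
- Frontal-face filtering (a manual step in the motivating workflow) is
  not automated; the detection contract is where a pose filter would go.
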