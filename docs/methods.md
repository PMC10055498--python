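# Methods

## Problem setting

`mssit` implements a hierarchical vision-transformer backbone for scalar
signals sampled on sphericalised cortical meshes — per-vertex metrics such
as sulcal depth, curvature, cortical thickness or T1w/T2w myelin, as used in
neonatal phenotyping (postmenstrual age / gestational age regression) and
cortical parcellation. The native cortical surface is assumed to have been
inflated and mapped to a sphere upstream (e.g. an HCP-style pipeline);
this package starts from signals on that sphere, resamples them to a
regular sixth-order icosphere when necessary, and trains either a
regression/classification network or a U-shaped segmentation network.

## Mesh hierarchy

All indexing rests on nested icospheres `I_k` built by recursive 4-fold
subdivision of a fixed icosahedron (poles on the z-axis), with
`|V_k| = 10·4^k + 2` vertices and `|F_k| = 20·4^k` faces. The subdivision
convention is canonical and load-bearing:

* midpoint vertices are appended after existing vertices, so vertex ids are
  stable across orders (the order-(k−1) vertices are a prefix of order-k);
* the four children of face `f` are stored at `4f … 4f+3`.

Consequences: patch merging is a stride-4 reshape, attention windows are
contiguous runs of the face-ordered token sequence, and the shifted-window
operation is a cyclic roll. The test suite verifies that this pure index
arithmetic coincides with explicit spherical-triangle containment
(exhaustively up to ico6).

## Architecture

The input signal `X ∈ R^{|V6|×C}` on ico6 is partitioned by the ico5 faces
into 20480 patches of 6 vertices (3 corners + 3 edge midpoints, midpoint
*i* opposite corner *i*), flattened channel-major into tokens of dimension
`6C`. Learned positional embeddings, LayerNorm and dropout are applied
once at the input. The encoder has four levels; level `l` projects to a
`2^(l−1)·D`-dimensional embedding, runs `depths[l]` local-MHSA blocks, and
merges sibling patches 4-to-1 (feature dimension ×4, reduced by the next
level's projection). Token counts per level on ico6: 20480, 5120, 1280,
320.

A local-MHSA block applies, each with pre-LayerNorm and residual:
window-MHSA, FFN, shifted-window-MHSA, FFN. Attention windows at level `l`
are the faces of the grid three orders below the sequence grid — 64
consecutive positions per window — except when that grid does not exist
(sequence order < 3), where a single global window covers the sequence;
on ico6 this makes level 4 global over the 320 ico2 patches. The shifted
sub-step rolls the sequence by `round(shift_fraction · 64)` positions
(default half a window) before windowing and rolls back after. Because the
sphere is closed there is no sequence border, and no attention mask is
applied to rolled-over tokens; tokens wrapped across the roll boundary are
geometric neighbours of a pole region rather than artificial padding. Global
windows are never shifted (a roll of a single window is a no-op).

For regression/classification the final 320-token sequence is layer-normed,
averaged into one token and passed through a linear head (zero-initialised
bias). The segmentation variant keeps each level's pre-merge output and
decodes with the mirror operation: each coarse token is copied to its four
children, concatenated with the skip connection and linearly projected,
followed by `decoder_depths` local-MHSA blocks per decoder level (default 1,
a deliberately light decoder). The head maps each of the 20480 level-1
decoder tokens to `6·K` logits scattered onto its patch vertices; vertices
shared between patches (corners) average their contributions.

Defaults `D=96`, `depths=(2,2,6,2)`, `heads=(3,6,12,24)`, `mlp_ratio=4`,
`dropout=0` follow the Swin-T parameterisation; all are configurable. The
model generalises to any input order ≥ 4 by the same rules, which is how the
desk-scale ico4 configurations used in the tests are built.

## Numerical core

No deep-learning framework is used: the package carries a small
reverse-mode autodiff engine over float64 numpy arrays
(`mssit.autodiff`) with exactly the operator set the architecture needs
(broadcasting arithmetic, batched matmul, reshapes, reductions, softmax,
log-softmax, layer norm, exact GELU, cyclic roll, 4-fold repeat,
scatter-mean). Every operator's gradient is tested against central finite
differences, and windowed/shifted attention is tested against a
brute-force masked global-attention reference. Softmax and log-softmax
subtract the row maximum for stability; LayerNorm uses eps 1e−5; GELU uses
the exact Gaussian CDF. Forward and backward passes are deterministic;
with fixed seeds training is bit-reproducible under single-threaded BLAS.

## Resampling and augmentation

Barycentric resampling treats each target point as a ray from the origin:
the value is the convex barycentric combination of the three vertices of
the source face hit by the ray (faces found via a KD-tree over normalised
face centroids with an expanding candidate search; ties at shared edges
resolved by the least-negative barycentric coordinate). Constants are
reproduced exactly and output ranges never exceed input ranges.

Two augmentations, applied online with probability 0.8 (one of the two,
50/50) per training sample:

* **Rotation** — per-axis angles uniform in ±30° (regression) or ±15°
  (segmentation), composed in fixed x→y→z order; the output at vertex `v`
  is the input interpolated at `R^{-1}v`.
* **Elastic warp** — each ico2 vertex is displaced by a random *tangential*
  vector of norm at most 1/8 of its mean great-circle neighbour distance
  (magnitude uniform in [0, bound], direction uniform in the tangent
  plane), reprojected to the sphere; the displacement field is
  barycentrically interpolated to the full grid and the signal pulled back
  through the warped positions. The 1/8 bound keeps the map diffeomorphic:
  the tests confirm no face orientation flips at ico6. Tangential (rather
  than unconstrained 3-D) displacements were chosen as the natural
  parameterisation of a deformation *of* the sphere; radial components
  would be removed by the reprojection anyway to first order.

Labels are transformed with the same geometry but nearest-corner (mode of
the barycentric corners) assignment, since they are categorical.

## Training recipe

AdamW (β=0.9/0.999, decoupled weight decay 0.01) with a linear learning-rate
warmup over the first 15% of steps followed by a cosine decay
`lr(s) = lr_min + (lr_max−lr_min)(1+cos(πs/S))/2` over the remainder. The
warmup matters in practice: without it the early AdamW updates can leave the
network on a mean-prediction plateau whose duration varies strongly with the
seed, while with warmup the desk-scale runs converge within a few epochs;
MSE loss on z-scored targets for regression; for segmentation an equally
weighted sum of cross-entropy and soft-Dice (smoothing 1e−5). Regression
uses a balancing sampler: targets are binned (default width 1.0 target
unit, i.e. one week for age tasks) and each sample is drawn with
probability proportional to the inverse of its bin count, equalising the
expected mass per non-empty bin. Channels are z-scored with training-split
statistics stored in the checkpoint. Early stopping monitors the
validation metric (MAE or 1 − mean Dice) with patience 20 epochs; the
best-validation parameters are restored.

## Synthetic data

The generators emulate the *structure* of cortical-surface datasets, not
their anatomy:

* **Regression** — per subject a scalar target `t` (default uniform in a
  PMA-like 26–45 week range; a skewed two-component mixture is available to
  exercise the balancing sampler). Channels are real-spherical-harmonic
  mixtures up to degree 8 whose coefficients depend affinely on the
  normalised target, with degree damping `1/(1+ℓ)`: the static part has
  unit scale, the target-dependent part twice that, and the DC slope is
  fixed at +2 so any area average of any channel is strictly increasing in
  `t`. I.i.d. Gaussian vertex noise (default sd 0.1) is added. The
  phenotype therefore modulates both the global level and the spatial
  pattern of every channel with magnitude comparable to the static
  anatomy.
* **Parcellation** — a nearest-seed (great-circle Voronoi) partition from
  `n_regions` random unit vectors, shared across subjects; channels are
  region mean levels (N(0, 2²) per region/channel) plus a smooth harmonic
  field (sd 0.25) and noise; each subject receives a small random rotation
  (±3° per axis) applied consistently to channels and labels by evaluating
  both analytically at the rotated positions.
* **Native mesh** — tangentially jittered icosphere vertices
  retriangulated by their convex hull, for exercising resampling from
  non-icosahedral spheres.

What passing the learning checks on these data does and does not show: it
demonstrates that the full pipeline — tokenisation, windowed/shifted
attention, merging, decoding, augmentation, balanced sampling,
optimisation — can extract spatially distributed, smooth signal and dense
region structure from multi-channel spherical data at realistic noise
levels. It does not demonstrate performance on real cortical metrics,
whose spatial statistics (folding correlations, subject covariance,
scanner effects) the generators deliberately do not model.

## Scaled-down study conditions

Desk-scale (single CPU) runs use an ico4 input grid (2562 vertices, 1280
patches) and a tiny model (`D=16`, one block per level, 2 heads,
`mlp_ratio=2`): regression with 128 subjects, 4 channels, 25 epochs, batch
16, lr 1e−3; segmentation with 30 subjects, 2 channels, 8 regions, 40
epochs, batch 8, lr 3e−3. These sizes were chosen as the smallest
configurations that exercise every architectural component (all four
levels, 64-patch windows at level 1, global attention above) while
training in minutes. The learning benchmarks compare the trained model to
a constant-mean predictor (regression) and measure hard Dice on held-out
subjects (segmentation).

## Known limitations

* Training is CPU-bound and float64; the engine is written for
  correctness and testability, not throughput, and large (ico6, `D=96`)
  configurations are impractical to *train* here, though they build and
  run forward passes.
* Shifted-window attention does not mask attention between tokens wrapped
  across the roll boundary (see above); a masking variant is not
  implemented.
* No pretraining/transfer-learning support; single-device only.
* The resampler assumes star-shaped (radially unambiguous) sphere meshes;
  heavily folded native surfaces must be sphericalised upstream.
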