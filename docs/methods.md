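# Methods

## Problem and approach

Fundus (retinal) image registration estimates the geometric transform mapping
a moving photograph of the retina into the coordinate frame of a fixed one.
Vessel bifurcations (degree-≥3 points of the vascular tree) and crossings
(artery/vein overlaps in the image plane) are the stable, repeatable landmarks
of a retina, so `retinakey` registers images by detecting *all* such keypoints
and matching them across the pair with a single network that produces, at full
input resolution,

* a keypoint probability map `p ∈ [0,1]^{H×W}` — pixel-level binary
  classification of junction locations, and
* a dense embedding map `E ∈ R^{H×W×D}` — a descriptor per pixel, compared
  with Euclidean distance to match keypoints across images.

Both images of a pair pass through the same weights (siamese application);
matching operates on per-keypoint embeddings afterwards.

## Network

The backbone is a U-Net-style encoder–decoder: `num_levels` downsampling
stages of double 3×3 convolution blocks (channel-norm + ReLU), 2×2 max
pooling, and a decoder that at each level bilinearly upsamples the deeper
feature, concatenates the skip feature and convolves:
`F̂_{i−1} = Conv(Concat(Up(F̂_i), F_{i−1}))`. Channel normalisation is
instance normalisation — the statistics a batch-norm layer would see at the
training batch size of 1.

### Spatially-varying context aggregation (SCA)

At the bottleneck, the deepest feature map `X ∈ R^{H×W×C}` predicts its own
depth-wise convolution kernel. Two 1×1 convolutions project `X` into a key
map `K ∈ R^{H×W×C}` and a query map `Q ∈ R^{H×W×s²}`; flattening the spatial
axes to `K' ∈ R^{HW×C}`, `Q' ∈ R^{HW×s²}`, the context kernel is the full
spatial contraction

    S'(i, j) = Σ_q Q'(q, i) · K'(q, j),   i.e.  S' = Q'ᵀ K'  ∈ R^{s²×C},

so every pair of pixel locations interacts once. `S'` is standardised per
output channel over its `s²` taps (exactly the batch-size-1 batch-norm
statistic) with a learned affine map, reshaped to `s×s×C`, and applied to `X`
as a depth-wise convolution (each channel convolved with its own 2-D slice;
zero padding preserves the spatial size). A 1×1 convolution and a sigmoid
produce the gate `F ∈ (0,1)^{H×W×C}`, and the module returns `F ⊙ X`.
Because `S` is computed from `X` itself, the modulation is input-adaptive —
two inputs differing in one pixel generally produce different kernels.

### Pyramid variant (SAPCA)

The pyramid module shares one predicted kernel `S` across three parallel
depth-wise branches with dilation rates 1, 3 and 5 (receptive fields of three
scales without resolution loss). Each branch has its own 1×1 convolution and
sigmoid, giving gates `R₁, R₂, R₃ ∈ (0,1)`; the fused weight is the
element-wise sum `R = R₁+R₂+R₃ ∈ (0,3)` and the output is `R ⊙ X`.

Choices the source architecture leaves open, fixed here: kernel size `s = 5`
(configurable; matches the dilation pyramid's receptive-field intent while
keeping the query head small); sigmoid applied per branch *before* the sum
(the literal reading of "three weight factors"; a pre-sum variant is a flag);
branch 1×1 convolutions independent, kernel prediction shared; convolution
implemented as correlation (deep-learning convention); the 1×1 convolution
after depth-wise modulation keeps the channel count.

## Losses

Keypoint location is supervised as dense binary classification against a
target mask that sets pixels within 2 px of any ground-truth keypoint to 1:

* mean binary cross-entropy `−[y log p + (1−y) log(1−p)]` with predictions
  clipped to `[1e−7, 1−1e−7]`;
* Dice loss `1 − (2|P∩Y| + δ)/(|P|+|Y| + δ)` with smoothing `δ = 1` guarding
  empty masks.

Keypoint matching is metric learning on embeddings read from the embedding
map at *ground-truth* keypoint locations (bilinear interpolation) during
training; detected locations are used only at inference. With Euclidean
distance `d` and margin `m = 1`:

* pair-wise (contrastive): `d(f_a, f_p)` for positives,
  `max(0, m − d(f_a, f_n))` for negatives;
* triplet: `max(0, m + d(f_a, f_p) − d(f_a, f_n))`;
* structured triplet ranking: for every positive pair `(i, j)`, both anchors
  are pushed away from *all* their negatives through a log-sum-exp,

      L = 1/(2|P|) Σ_{(i,j)∈P} [ d(f_i,f_j)
            + log( Σ_{(i,p)∈N} e^{m−d(f_i,f_p)} + Σ_{(j,l)∈N} e^{m−d(f_j,f_l)} ) ]₊

  evaluated with a numerically stable log-sum-exp; the hinge is plain (not
  squared; a squared variant is a flag). Positives are the ground-truth match
  pairs; the negatives of an anchor are all opposite-image keypoints other
  than its match (an exclusion radius around the true match is available and
  off by default).

The total objective is `w_ce·CE + w_dice·Dice + w_match·Match` with unit
weights, summed over both images of the pair; each term is logged separately.

## Training

Plain SGD with momentum 0.9, weight decay 1e−3 and batch size 1 (one image
pair per step). The learning rate — not dictated by the reference regime —
defaults to 0.02, chosen by a coarse sweep (0.01/0.02/0.05/0.1) on synthetic
validation splits; 0.02 trains the detector to clearly better F1 at a fixed
iteration budget and is stable across seeds. The detection head's bias is
initialised to −3: keypoints occupy a few percent of pixels, and starting the
detector near that prior keeps early iterations from being spent suppressing
background. A fixed seed controls data generation, weight initialisation and
sample order, making runs bit-reproducible. Training runs in float32 within
the protocol harness for speed; the engine defaults to float64, which the
finite-difference gradient tests rely on.

## Inference

1. **Decoding**: local maxima of the probability map above threshold 0.5,
   with a non-maximum-suppression spacing of 2 px, refined to
   probability-weighted centroids over a 5×5 window of supra-threshold
   pixels; refined points closer than the spacing are merged. Peak decoding
   replaced a connected-component design: annotated keypoints can sit just
   over 3 px apart, and component centroids merge adjacent junctions along
   supra-threshold ridges, capping recall near 0.5 on dense vessel trees. The
   2 px spacing sits deliberately below the 3 px annotation separation.
2. **Description**: bilinear sampling of the embedding map at each keypoint.
3. **Matching**: mutual nearest neighbours under Euclidean distance with an
   optional absolute cutoff (default ∞); one-to-one by construction. No ratio
   test: the method's premise is that learned embeddings make consensus
   pruning largely unnecessary.
4. **Estimation**: least squares for similarity/affine, normalised DLT for
   homography (default model: homography). A random-consensus loop
   (`robust=True`, inlier threshold 3 px) is available because plain least
   squares is fragile to even one wrong match; the benchmark harness enables
   it and fits the similarity model matching its generator's transform family.

## Synthetic data generator

Real training data (private clinical datasets) consists of fundus photographs
with annotated junctions. The generator emulates their *structure*, not their
appearance:

* **Geometry** — per image, 3 independent random binary-branching vessel
  trees grow inward from the rim of the field of view (segment length
  6–12 px, branch probability 0.4, branch angle 25–55°, initial radius
  1.6 px decaying ×0.9 per generation, depth ≤ 6, heading jitter 12°).
  Crossings require ≥ 2 trees, as a single tree cannot self-intersect here
  (arteries and veins cross in real fundi). Ground truth is exact: branching
  points are degree-≥3 tree nodes, crossings are analytic segment–segment
  intersections between distinct trees; points closer than 3 px merge to
  their centroid (label "crossing" wins).
* **Appearance** — dark anti-aliased strokes (width from the edge radius) on
  a bright disc with smooth background texture, a linear illumination
  gradient, Gaussian blur, additive Gaussian noise and gamma. Two presets:
  *high* (mild; adult-camera-like) and *low* (stronger blur, noise and
  illumination gradient; neonatal-camera-like).
* **Pairs** — the moving image is the fixed image warped through a sampled
  transform (identity/translation/similarity/affine/homography families with
  configurable ranges; default similarity: rotation ±15°, translation ±10% of
  the canvas, scale 0.9–1.1×) using inverse mapping + bilinear interpolation,
  then photometrically jittered (brightness/contrast/gamma/noise). Matches
  link every fixed keypoint whose transformed location stays on the moving
  canvas; the overlap fraction is the exact per-pixel in-bounds count.
  Coordinates are 0-based continuous (x = column, y = row); transforms act on
  homogeneous (x, y, 1) and map fixed → moving.

What the generator does **not** model: photorealistic texture, lesions,
camera optics, non-planar eye geometry (true fundus pairs are not exactly
homographies), or annotation noise. Passing tests therefore demonstrate that
the architecture, losses, decoding and scoring behave as specified on images
with the right *structure* — not clinical-grade performance.

## Evaluation

A registered pair's error is the mean Euclidean distance between the
estimated and ground-truth transforms over a 10×10 control-point grid on the
overlap region of the fixed image (independent of detection quality). The
success curve sweeps a threshold `t` over `[0, 25]` px on a 251-point grid;
success is `error ≤ t` (failed registrations fail at every threshold), and
the score is the left-rectangle-rule area under the curve normalised by
`t_max = 25` px — the established public-benchmark convention; the grid and
inequality direction are declared conventions, not reference facts.

## Scaled-down study protocol

The test suite and `scripts/acceptance.py` exercise the full method at desk
scale (problem sizes chosen as the package's own benchmark conditions):
25 synthetic 64×64 pairs per replicate (20 train / 5 held out), a tiny model
(2 levels, 8 base channels, 32-d embeddings, kernel size 5), 300 SGD
iterations, evaluated as: training-loss reduction (mean of first vs last 10
logged steps), detection F1 within 3 px, mutual-NN matching precision among
correctly detected keypoints, and held-out registration AUC for the trained
model against its untrained initialisation. The ablation harness repeats this
over {plain U-Net, SCA, SAPCA} × {pairwise, triplet, structured} cells with
shared per-seed datasets and reports per-seed AUCs and medians.

## Numerical notes and limitations

* The autodiff engine is a compact reverse-mode tape over NumPy written for
  this package's operator set; every backward rule is validated against
  central finite differences in float64.
* Distances add 1e−16 inside the square root so gradients at coincident
  embeddings stay finite; log-sum-exp subtracts the detached maximum.
* Dice uses δ = 1 by default; the closed-form unit tests set δ = 0.
* Degenerate inputs raise typed errors (`TooFewMatchesError`,
  `DegenerateTransformError`, `InvalidParameterError`, `CheckpointError`);
  an unregistrable pair in the pipeline returns a failure record instead of
  raising and counts as failed at every evaluation threshold.
* Known limitations: no GPU path, batch size fixed at 1, the generator's
  planar-homography assumption, and tiny-model capacity — detection recall
  on dense junction clusters is the binding constraint at this scale.
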