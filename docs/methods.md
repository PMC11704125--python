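# Methods

`augbias` studies how the choice of stochastic image transformations in
self-supervised representation learning (SSRL) acts as a hidden layer of
supervision. Three analyses are implemented end-to-end on synthetic data:
a transformation-parameter **sweep** with per-class probing and an
inter-class-bias statistics chain; a two-transformation-set **style** study on
two-factor glyph images; and a microscopy **phenotype** study comparing
random-crop, strong-rotation and dual-composition trainings on centered-cell
images. This note records the models, the parameters that matter, and the
design decisions taken where the problem left them open.

## The SSRL core

No deep-learning framework is assumed: the package carries a compact numpy
reverse-mode autodiff engine (`augbias.nn.autodiff`) with the operations a
small convolutional encoder and the five SSRL objectives need (broadcast
arithmetic, matmul, reductions, ReLU/exp/log/sqrt, concatenation, an
im2col-based conv2d, and a fused batch-normalization primitive with the
closed-form backward). Gradients are verified against central differences in
the test suite.

Encoders are registered as `small_conv` (three stride-2 3×3 conv–BN–ReLU
blocks with 16/32/64 channels, global average pooling, linear head; ≈30k
parameters) and `resnet_small` (the same stem with two residual blocks). A
projection MLP is attached during training; probing and clustering consume
the pre-projector embedding, except where noted. Optimization is momentum SGD
(momentum 0.9, weight decay 1e-4) under a cosine learning-rate schedule.

The five objectives follow their canonical formulations:

* **SimCLR** — NT-Xent over the 2N concatenated L2-normalized projections,
  temperature 0.5 by default;
* **MoCo v2** — InfoNCE of queries against momentum-encoder keys with a
  persistent negative queue (length 256 at desk scale), temperature 0.2,
  EMA momentum 0.99;
* **BYOL** — normalized-MSE between online predictions (2-layer predictor)
  and EMA-target projections, symmetrized;
* **VICReg** — invariance (MSE) + variance hinge at std 1 + covariance
  off-diagonal suppression, weighted 25/25/1;
* **Barlow Twins** — batch-standardized cross-correlation pushed to the
  identity, off-diagonal weight 5e-3.

Every loss is checked against an independent brute-force pairwise enumeration
to 1e-6 on random batches. The desk-scale studies use SimCLR, the most stable
of the five at ~100-step trainings with this encoder; the others are
config-selectable.

**Dual-composition objective.** Two transformation compositions each drive
their own loss instance (separate queue/target state), on view pairs drawn
independently per branch from the same image batch; the optimizer minimizes
`w_a·L_a + w_b·L_b`. A branch with zero weight is skipped entirely, so the
single-composition trainer is exactly the dual trainer with `w_b = 0` — the
two are trajectory-identical by construction. The branch weights are exposed
in config; the phenotype study uses 0.85/0.15 in favor of the
morphology-focused branch, selected by a small grid on the study conditions
(the weighted sum is the method's one free hyperparameter and published
protocols do not pin it down).

**Normalization recalibration at inference.** Batch-norm running statistics
accumulated during training describe *augmented views*, whose intensity and
scale distributions can differ sharply from un-augmented inference images —
in a dual training they are a mixture of two view distributions. Before
embedding, the running statistics are therefore replaced by the statistics of
one forward pass over (a stride-subsample of) the inference images.
Embeddings are then computed in eval mode; the step is deterministic. Without
it, dual-training embeddings in particular are dominated by the train/test
normalization mismatch.

## Synthetic data

**Centered-cell images** (`gen_cell_images`). Single-channel crops emulating
nucleus-centered microscopy fields: one central cell (a deformed ellipse with
area-preserving elongation — semi-axes r(1+e) and r/(1+e) — multiplicative
smoothed-noise texture with controllable grain, and a two-harmonic boundary
perturbation), Poisson(`neighbor_rate`)-many smaller, dimmer neighbor cells
kept off-center, and additive Gaussian background noise. Treated cells draw
from `n_phenotypes` sub-phenotype distributions that share a common response
axis — elongation plus coarser texture with a modest size increase while
brightness stays matched — so the condition signal lives in central-cell
morphology rather than trivial intensity statistics. A `resemble_fraction`
(default 0.2) of treated cells keeps untreated morphology (the lookalike
subpopulation), which caps the achievable condition AMI well below 1.
Neighbors in treated images respond to the treatment too (well-wide
response), giving the periphery a weaker, complementary condition signal.
Defaults: image size 64 (studies run at 32 for CPU budget), effect size 0.7,
neighbor rate 1.0, noise sd 0.03.

**Glyph images** (`gen_glyph_images`). Procedurally drawn strokes with two
independent factors: glyph class and stroke style (thickness plus a mild
slant). Two template families: `mixed` (bars, corners, crosses, zigzags) and
`bars` — single bars at evenly spaced orientations in [0°, 180°), used by the
style study because orientation classes are provably scrambled by full-circle
rotations and flips while thickness survives them. The style step is
deliberately subtle (thickness 0.060 vs 0.080 in unit coordinates) so that
glyph identity is the dominant factor, mirroring how digit identity dominates
handwriting style in handwritten-digit data.

**Planted accuracy surfaces** (`gen_accuracy_surfaces`). Per-class
accuracy-vs-parameter curves: a per-class base level U(0.35, 0.65), a linear
trend (ascending/descending/flat, default |slope| 0.3 over the unit parameter
range) and i.i.d. Gaussian accuracy noise per seed (default sd 0.02), clipped
to [0, 1]. The run-to-run noise model is an assumption — real sweep noise is
not i.i.d. — but it is the natural null for calibrating the statistics layer.

**Property classes** (`gen_property_classes`). Image families with known
property orderings: images on a d-dimensional linear manifold (smooth random
basis, uniform coefficients) for the intrinsic-dimension estimator;
low-pass, checkerboard and periodic families for the spectral split;
constant images as the all-zeros edge case.

What the generators do *not* emulate: optics (PSF, vignetting), cell-cell
occlusion, segmentation errors, batch effects, or natural-image semantics.
Passing tests show the pipeline recovers structure it is pointed at under a
controlled noise model — not that it would do so on any particular real
screen.

## Transformations

Ten parameterized stochastic ops (crop-resize, center crop, brightness/
contrast jitter — a hue component only for RGB — flips, rotation, affine,
pad, inversion, erasing), each with an application probability. Conventions
chosen where the literature is loose: random crop amplitude is the retained
**area** fraction range, center crop the retained **side** fraction; rotation
and affine warps are bilinear with reflection padding (`scipy.ndimage`
backend, verified against an independent implementation); "slight" rotation
defaults to ±15°, strong rotation to 360°; erasing blanks 10–30 % of the area
with the image mean. All ops map [0, 1] into [0, 1] (property-tested).

Named compositions used by the studies:

* `glyph_set1` — pad, inversion, ±8° rotation, mild crops (0.45–1.0 area):
  preserves glyph identity; the pad/crop pair also jitters apparent scale so
  stroke thickness is unreliable across views.
* `glyph_set2` — vertical flips, 360° rotation, crops (0.4–0.8), erasing:
  scrambles orientation identity, leaves thickness.
* `cell_crop_set` — jitter, flips, ±15° rotation, affine, random crops at
  0.25–0.35 area: views mostly miss or decenter the central cell.
* `cell_rotation_set` — the same minus the crop, plus 360° rotations:
  preserves the centered cell exactly.
* `cell_center_set` — 360° rotations plus a centered half-size crop, jitter,
  flips: concentrates views on the central cell.

## The statistics layer

Computed on seed-mean accuracy curves (the sweep protocol averages seeds
before correlating): Pearson/Kendall/Spearman with their standard two-sided
p-values (`scipy.stats`; Kendall's exact null at ≤20 points without ties);
a pair is an *opposite-behavior pair* when any coefficient is below −0.3 with
its own p below 0.05; the *bias ratio* is the fraction of classes in at least
one flagged pair. A constant curve has undefined correlations — recorded as
missing, never NaN-propagated, and unable to trigger a flag. No
multiple-testing correction is applied in flagging (the protocol is a raw
p < 0.05 rule); behavior labels use the OLS slope of accuracy on parameter
value with label `random` unless the slope's p-value clears `slope_alpha`
(default 0.05).

Class-property metrics (estimator choices are the package's own; the
properties are named but not defined in the protocol it follows):
two-nearest-neighbor maximum-likelihood intrinsic dimension
(d = n / Σ log(r₂/r₁)); mean gray-level co-occurrence contrast (32 levels,
distance 1, 0° and 90°); high-frequency energy fraction of the mean power
spectrum above half-Nyquist (DC excluded); effective rank
(exp of eigenvalue entropy) of the class feature covariance. The feature
source defaults to a PCA of raw pixels; any per-image feature matrix can be
passed instead. Association with behavior groups: one-way ANOVA per property
plus a Wilks'-lambda MANOVA with Rao's F approximation (cross-checked against
statsmodels).

Monte-Carlo calibration (`augbias.calibration`) under the surface noise
model (20 values, 5 seeds, |slope| 0.3, noise 0.02) measures flag
sensitivity/false-flag rate, behavior-label accuracy, and type-I rates on
flat surfaces; the ANOVA/MANOVA layer is calibrated on i.i.d. normal
properties with an optional 2-pooled-SD shift. The acceptance script
recomputes all of these at run time.

## Study conditions (desk scale)

All studies run on one CPU in minutes. Problem sizes: cells 32×32, 200+200
images, SimCLR, batch 100, 25 epochs (≈100 optimizer steps), embedding 16,
projector [64, 32], five training seeds; glyphs 6 orientation classes × 70
images, 2 styles, embedding 6, 30 epochs, k-means k = 6 with 10 restarts.
The glyph embedding is kept deliberately narrow so that the information loss
imposed by an identity-destroying composition is visible to a linear probe —
with a wide embedding a three-layer conv stack retains linearly decodable
orientation regardless of the objective at these training lengths.

Evaluations: k-means (best of 10 seeded restarts), silhouette (Euclidean,
singletons contribute 0), adjusted mutual information (arithmetic-mean
normalizer, hypergeometric expected MI), linear probe (L2-regularized
multinomial logistic regression on an 80/20 stratified split of embeddings;
per-class accuracy is per-class recall). The perceptual view-pair
dissimilarity follows the layered feature-space construction of learned
perceptual metrics but uses a fixed, seeded random-weight conv stack with
uniform layer weights, so no pretrained weights are required; a
pretrained-backbone backend can be plugged in.

## Known limitations

* Trainings are ~100 optimizer steps on ~400 images: directional claims
  (which composition wins) are reproduced; absolute score levels are not
  comparable to full-scale trainings.
* The dual-composition gain over its best single composition is small at this
  scale and sensitive to the branch weighting; with the default weighting it
  matches, and on favorable seeds exceeds, the center-focused single run.
* The i.i.d. accuracy-noise model behind the calibration rates is an
  idealization of run-to-run training variance.
* Single-channel microscopy only; the RGB path of the jitter op is exercised
  but no RGB study is bundled.
* The numpy engine is single-threaded and CPU-bound; it is a study vehicle,
  not a training framework.
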