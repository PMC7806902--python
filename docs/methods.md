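# Methods

## Problem and model

Paired visible-light and UV facial photographs differ in two ways that
matter for learning a translation between them: the photometric mapping
(melanin darkens UV strongly and the visible channels weakly, so pigment
spots that are faint in color are prominent in UV), and small local
geometric mismatches caused by subject movement between the two exposures.
The pipeline addresses both.

The translation model is a conditional GAN. The generator is a U-net: an
encoder of stride-2 convolutions halves the spatial size per level while
doubling channels, a decoder of nearest-neighbor upsampling + convolution
restores it, and skip connections concatenate each encoder level into the
matching decoder level so that fine spatial detail survives the bottleneck.
The output passes through a sigmoid, so synthetic UV intensities are bounded
in [0, 1]. The discriminator stacks the color patch and a candidate UV
patch along channels, reduces them with stride-2 convolutions, and emits a
single probability per pair through a global average pool, a dense layer
and a sigmoid clamped to (1e-6, 1 − 1e-6).

Training minimizes, over generator G and (adversarially) discriminator D,

    (1/|I|) Σ_{i∈I} [ meanpix |Y_i − G(X_i)| + λ log(1 − D(X_i, G(X_i))) ]
      + (λ/|J|) Σ_{j∈J} log D(X_j, Y_j)

with λ = 0.005. The fake index set I and real index set J are disjoint
halves of each sampled batch: if the discriminator saw the same pair both
as real and behind the generator, it could separate them trivially and
training destabilizes. Three phases run in sequence: (1) alternating D and
G updates; (2) discriminator-only refinement, keeping the parameters with
the lowest validation discriminator loss; (3) generator-only refinement,
keeping the lowest validation mean per-pixel L1. With λ = 0 the objective
reduces to pure L1, no discriminator exists, and only phase 1 runs — this
is both the "no discriminator" ablation and the *temporal* generator used
by the alignment stage. Augmentation applies random vertical/horizontal
flips and 90° rotations jointly to both patches of a pair.

Both discriminator inputs (real and generated UV patches) receive identical
additive Gaussian instance noise (σ = 0.01) during training. Without it the
discriminator wins trivially by detecting the sensor-noise texture that
real captures carry and a smooth generator output lacks — a cue that says
nothing about pigmentation — and its gradient teaches the generator
nothing. Equalizing the noise floor forces the discriminator onto image
structure. This is the standard instance-noise stabilization for GANs.
The generator's adversarial update uses the minimax term log(1 − D) as
written in the objective; the non-saturating surrogate −log D (same fixed
point, non-vanishing gradient under a confident discriminator) is
selectable through the schedule. In desk-scale experiments neither form
gave the generator a measurable advantage over the pure-L1 variant under
the toy FID — see the limitations section.

## Local alignment

Direct registration of color against UV fails because the modalities share
little pixel-level structure. Instead the temporal (L1-only) generator
produces a surrogate UV image from the color image; surrogate and real UV
are photometrically comparable, so large tiles of the two are aligned by
exhaustive search over integer translations (dy, dx) ∈ [−r, r]²,
minimizing mean per-pixel L1 on the valid overlap only (normalizing by the
overlap area keeps large shifts from being favored or penalized). Ties
break toward smaller |dy|+|dx|, then lexicographically — so two identical
tiles yield (0, 0) deterministically. Each small training window then
inherits the shift of the tile whose center is nearest (row-major order on
ties), the shift is applied to the *color* side of the pair, and windows
pushed out of bounds are dropped.

Tiles must be much larger than training patches so they contain enough
structure (face outline, shading gradients) to disambiguate shifts; the
clinical-scale configuration uses 900-pixel tiles for 256-pixel patches,
the desk configuration 96-pixel tiles for 64-pixel patches — the same ~3.5×
ratio at ~1/14 the linear image size. The search radius default is ±30 px
at clinical scale and ±8 px at desk scale; both exceed the largest
misalignment they are asked to recover.

## Spot segmentation

Spot Net shares the generator's U-net body but ends in a two-channel
softmax. The cost is cross-entropy plus soft Dice,
`1 − (2 Σ p·t + ε)/(Σ p + Σ t + ε)` with ε = 1 (the ε makes the empty-mask
case well-defined and the loss smooth at zero overlap), mixed 1:1:
cross-entropy drives per-pixel calibration while the Dice term counters the
extreme class imbalance of small spots. Augmentation adds a random global
brightness factor (±10%) on top of flips/rotations. When a trained
translation network is available, training inputs mix true-UV and
synthetic-UV patches 1:1 (with the same truth masks) so the segmenter
adapts to the generator's output statistics as well as to real captures. Detection runs
patchwise, assembles the probability map, binarizes at 0.5 (no minimum-spot
filter), and intersects with the evaluation region. The spot-area
percentage is 100·|mask ∩ region|/|region|.

## Evaluation metrics

*Per-pixel L1* is the median (mean as a variant) of |a − b| over masked
pixels, scaled to 0–255; the median resists outliers near specular or
shadowed regions. *FID* fits a Gaussian to the feature vectors of each
image set and evaluates |μ₁−μ₂|² + tr(Σ₁+Σ₂−2(Σ₁Σ₂)^{1/2}); the matrix
square root is computed as sqrt(Σ₁)·Σ₂·sqrt(Σ₁) by eigendecomposition with
negative eigenvalues clipped at zero, and covariances use ddof = 1. The
feature embedder is pluggable; the default is a fixed-seed random linear
projection of 16×16 block-averaged patch pixels to 64 dimensions — fully
deterministic and dependency-free. A pretrained perceptual network can be
plugged in where its weights are available locally; nothing in the package
downloads anything. Segmentation quality uses IoU, recall, precision and
F-measure with explicit conventions for empty masks (empty truth + empty
prediction scores 1; empty truth + non-empty prediction gives recall NaN,
IoU and precision 0). Cohort agreement uses Pearson correlation and the
no-intercept regression slope Σxy/Σx².

## Skin phantoms

The phantom generator renders what the pipeline actually depends on, with
exact ground truth:

- a melanin map (smooth base 0.25 ± 0.03 plus hard discs of radius 2–5 px
  boosted by 0.5) inside an elliptical face on a dark background;
- UV = clip(1 − 0.9·melanin) × shading: spots at full contrast;
- color = per-channel skin tone × (1 − absorption·visible-melanin) ×
  hemoglobin modulation × shading, where the visible melanin map carries
  only a fraction (0.35) of the spot boost — spots are deliberately faint
  in color, the property the whole method exploits;
- a smooth hemoglobin field modulating green/blue, a shared multiplicative
  shading field (±12%, correlation scale ~48 px), additive Gaussian sensor
  noise (σ = 0.01);
- a piecewise-constant integer displacement field between the two captures,
  constant on 96-px tiles with components uniform on [−6, 6]. The field is
  piecewise-constant rather than smooth so that tile-shift recovery has an
  exactly checkable answer. The magnitude is deliberately comparable to
  the spot radius: when displacements reach the spot scale, the L1-optimal
  translation (a conditional median over the shift distribution) washes
  spots out, which is precisely the failure mode the alignment stage
  exists to correct. Much smaller displacements would make alignment
  nearly irrelevant and the ablation comparisons degenerate.

Cohorts derive per-subject seeds from a master seed via `SeedSequence`;
the optional spot-density gradient raises the spot count monotonically
across subjects, mimicking the accumulation of pigment spots with age.

What phantoms do *not* model: 3-D facial geometry, specular reflectance,
shadowed eye/nasolabial regions, hair, camera optics, or inter-subject skin
tone variation. Passing phantom tests therefore demonstrates that the
pipeline's machinery is correct and that its comparative orderings hold
under controlled conditions — not clinical-grade performance on real faces.

## Scale presets and numerical choices

Two presets configure the same code. The `clinical` preset carries the
clinical-scale hyperparameters (256-px patches, 900-px tiles, λ = 0.005,
batch 80, Adam lr 1e-4, 150k/5k/50k schedule, dropout 0.5, ~30k face
patches of 120 px): it is provided for completeness and is far beyond
desk hardware. The `desk` preset is the configuration the tests and the
acceptance script actually run: 192×192 phantoms, 64-px patches, 96-px
tiles (stride 48, radius ±8), a depth-3 U-net with 4 base channels,
discriminator with 8, batch 8, Adam lr 1e-3, 2000 alternating iterations
plus 100 discriminator-only and 400 generator-only refinements, validation
every 250 iterations, cohorts of 20 subjects split 14/2/4, and 1500
iterations for the spot segmenter. These problem sizes were chosen so a
full ablation study (four trained variants plus alignment, conversion and
metrics) completes in CPU-minutes while leaving each phenomenon
measurable; the segmenter's 1500 iterations are what the mixed
true/synthetic input set needs to converge.

Numerical details worth knowing:

- All network arithmetic is float32; convolutions are evaluated as sums of
  kernel-offset channel matmuls (cache-friendlier than an im2col gather at
  these sizes). Gradients are exact (finite-difference-checked in tests).
- U-net activations are LeakyReLU(0.1). With only 4 base channels, plain
  ReLU left a substantial fraction of inits with dead or slow-starting
  units and made convergence depend visibly on the seed; the leaky slope
  removes that failure mode.
- Dropout (rate 0.5) acts on the two innermost decoder levels, active only
  during training; inference is deterministic.
- Log-loss arguments are clamped at 1e-6. Adam uses β₁ = 0.9, β₂ = 0.999.
- Training is bit-reproducible given a seed: all randomness (init,
  batching, augmentation, dropout) flows from explicit generators.
- Patch grids are 0-based, (row, col), half-open windows; edge windows are
  realized by reflect padding (zero padding selectable). Assembly averages
  overlapping windows uniformly; uncovered pixels take a designated fill
  (whole-image conversion fills with the input's grayscale).
- The ICA baseline removes shading by projecting log-RGB onto the plane
  orthogonal to (1,1,1) (keeping the removed scalar to reapply later), runs
  two-source FastICA (deflation, tol 1e-6, fixed seed) on the masked
  pixels, labels as melanin the component with the stronger blue:green
  absorption ratio (hemoglobin absorbs green most; melanin keeps rising
  into the blue), and orients signs so more component means more
  absorption. Unit weights reconstruct the input exactly; the weight grid
  search scans w_m ∈ {0, 0.1, …, 2.0}, w_h = 2 − w_m (21 candidates) and
  minimizes pooled median per-pixel L1 against UV references, ties to the
  smaller melanin weight. The weights selected in the original clinical
  study, (1.3, 0.7), are recorded as a configuration preset, not a result.

## Open choices made here

- The inference stitching policy is disjoint tiles by default with an
  optional overlapping mode averaged uniformly; seams were negligible on
  phantoms.
- Phase-1 early stopping snapshots generator and discriminator jointly at
  the best validation L1.
- The face classifier is a small 3-block CNN on 24-px patches (120 px at
  clinical scale) trained on mask-derived labels; landmark-based labeling
  for real photographs enters through the same labeling hook.
- Patches dropped because an alignment shift pushes them out of bounds are
  not re-sampled.
- The spot-area correlation analysis uses the alignment-trained generator
  variant for synthetic UV, and an elliptical sub-mask of the face as the
  "cheek" region on phantoms.

## Limitations

Desk-scale networks are deliberately tiny; they demonstrate orderings
(alignment helps L1, synthetic UV beats intensity baselines, spot-area
agreement between true and synthetic UV), not absolute clinical accuracy.

One comparative property did not miniaturize: the benefit of the
discriminator as measured by FID. At clinical scale the adversarial term
sharpens texture over ~150k iterations and Inception features reward it.
At desk scale the pure-L1 generator already matches everything a
downsampling embedder can measure, and across a systematic sweep
(λ ∈ [0.005, 0.1], minimax and non-saturating generator updates, scalar
and patch-map discriminator heads, instance noise 0–0.03) the adversarial
term never lowered toy-embedder FID below the λ = 0 variant — the
discriminator either saturated (leaving no generator gradient under the
minimax form) or added perturbation without restoring spot contrast within
the iteration budget. The corresponding acceptance test is retained and is
expected to fail at desk scale; it documents the scale limit rather than
an implementation defect (the discriminator itself demonstrably has the
capacity to separate real from generated patches when trained alone, and
every loss identity is verified exactly against stubs). The FID embedder is a random projection,
so FID values are comparable only within a run, not across embedders. The
alignment model is pure translation per tile — no rotation, scaling or
deformation. Phantom hemoglobin and shading fields are Gaussian-smooth,
which slightly flatters the ICA baseline's assumptions relative to real
skin.
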