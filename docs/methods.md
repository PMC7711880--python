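# Methods

`sbocad` implements a five-stage computer-aided diagnosis chain for
dermoscopy images: impulse-noise removal, lesion segmentation by a small
convolutional network trained with a hybrid gradient-descent / satin
bowerbird optimization (SBO) schedule, extraction of nineteen shape,
intensity and texture descriptors from the segmented lesion, SBO-driven
wrapper feature selection scored by the Matthews correlation coefficient,
and a kernel SVM producing the final cancerous/healthy call, scored by the
five standard diagnostic indexes over repeated stratified splits.

## Satin bowerbird optimization

Candidates ("bowers") are real vectors in a box. Per cycle:

1. Fitness: `fit = 1/(1+f)` for objective `f >= 0`, `1+|f|` for `f < 0` —
   strictly positive and order-reversing, so roulette probabilities
   `Prob_i = fit_i / sum(fit)` are always well defined.
2. Position update, per coordinate `j` of bower `h`: a target bower `i` is
   drawn by roulette, and
   `w_hj <- w_hj + lambda_j * ((w_ij + w_elite,j)/2 - w_hj)` with step
   `lambda_j = alpha / (1 + Prob_i)`, bounded in `[alpha/2, alpha]`. This
   is the standard formulation, for which an already-converged population
   (`old == target == elite`) is a fixed point; a literal variant in which
   the current position cancels out of the update is selectable with
   `legacy_update` but is not the default, because it discards the current
   position entirely.
3. Mutation: each coordinate independently, with probability 0.05, receives
   a Gaussian kick of standard deviation `alpha_mut = y * (ub - lb)` per
   dimension. The scale multiplies a unit normal directly (std, not
   variance).
4. The moved population is pooled with the previous one, sorted by
   objective and truncated — the elite can never be lost, so the
   per-iteration best is monotone non-increasing.

Defaults `alpha = 0.94`, `y = 0.02`, mutation probability 0.05 follow the
original description of the algorithm. Positions are clipped to the box
after every operator. Termination is a fixed iteration budget only, for
reproducibility. Non-finite objective values are treated as `+inf` and
logged. All randomness flows from a single integer seed recorded in the
result.

## Preprocessing

A 3x3 median filter (edge-replicated borders, per-channel for RGB) removes
the isolated extreme-valued "spot" pixels typical of dermoscopy
acquisition while preserving lesion borders. Images are resized bilinearly
to 256x256 and reduced to Rec.-709 luminance before texture analysis.
Whether the original system filtered RGB planes or a luminance copy is not
recoverable; the pipeline filters the luminance copy, which is what every
downstream stage consumes.

## Segmentation network and hybrid training

The segmenter is a patch classifier: a window slides over the image, each
patch is classified lesion/background, each patch's lesion probability is
spread over its footprint, per-pixel votes are averaged and thresholded at
0.5, and the largest connected component is kept with holes filled.

Two architectures are provided:

* the full-image geometry (256x256x3 input, 11x11 / 7x7 / 3x3 convolutions
  with 2x2 max pooling, dropout 0.6, a 256-wide fully connected layer, a
  2-way softmax head) — the reference stack, with filter counts 8/16/32
  chosen to keep the model under a million parameters;
* a desk-scale patch net (two 3x3 conv/relu/pool blocks with 8 and 16
  filters, a 32-wide FC layer) used by the default pipeline with 16x16
  patches at stride 4. 16/4 rather than the larger 32/8 window keeps the
  vote blur at about half a lesion-border lobe and makes sliding-window
  inference ~4x cheaper. Patches are grayscale: in both the emulated data
  and dermoscopy practice the lesion/background contrast is an intensity
  phenomenon.

Training phase 1 is full-batch gradient descent on the softmax
cross-entropy with an L2 penalty `(theta/2) * sum W^2` over connection
weights (never biases), `theta = 1e-4`, learning rate 0.1 on the
mean-reduced loss. Dropout is inverted (scaling at train time), with the
drop — not keep — probability 0.6 in the reference stack. Backpropagation
is exact and is verified coordinate-by-coordinate against central finite
differences in the tests.

Phase 2 re-optimizes the flattened weight vector with SBO against the mean
squared output error `E = (1/Ns) sum_i sum_j (d_ji - o_ji)^2`, in a box of
half-width `delta = 0.2` centered on the gradient solution, seeding the
population with that solution so elitism guarantees the refined error never
exceeds the starting one. The cross-entropy is deliberately the gradient
objective and the squared error the population objective; the two phases
answer different failure modes (conditioning vs. local minima). A separate
entry point searches integer sliding-window sizes in `[2, window_max]` by
SBO, training each candidate briefly; whether the original system tuned
weights, window hyperparameters, or both is ambiguous, so both modes exist
and neither is claimed as canonical.

Patch labels come from the mask value at the patch center; training draws
class-balanced patches from the first 24 images of the dataset. The
segmenter is trained with generator ground truth on the same pool of
images whose features later enter classification; lesion-mask supervision
and the benign/malignant labels are independent, so this does not leak
class information into the evaluation splits.

## Features

Nineteen descriptors per lesion, computed on the median-filtered luminance
image and the binary mask:

* geometry: area (pixel count), perimeter, solidity (area / convex area),
  elongation `2*sqrt(area)/(a*sqrt(pi))`, rectangularity (area / bounding
  box area), irregularity index `4*pi*area/perimeter^2`, form factor
  `area/a^2`, eccentricity `2/a * sqrt(a^2-b^2)` with `a, b` the full axis
  lengths of the second-moment ellipse. The eccentricity formula is twice
  the conventional ellipse eccentricity written with semi-axes; it is kept
  in this form deliberately as the package's defining convention. The
  `perimeter` feature is the Crofton 4-direction digital
  contour length, which is unbiased for smooth boundaries (a rasterized
  disk scores irregularity ~1.00, where a raw boundary-pixel count would
  score ~1.25); the raw 4-adjacent boundary-pixel count is kept as a
  separate geometry field.
* intensity: mean, population variance, standard deviation, and the
  entropy `-sum p log2 p` of a 32-bin histogram of the masked pixels.
* texture: contrast `sum (i-j)^2 p(i,j)`, correlation
  `(sum ij*p - mu_r mu_c)/(sigma_r sigma_c)`, energy `sum p^2`, homogeneity
  `sum p/(1+|i-j|)` of symmetric normalized co-occurrence matrices at
  distance 1, averaged over the 0/45/90/135 degree offsets, quantized to 8
  gray levels over the masked region's min-max intensity range (the
  conventional co-occurrence scaling; a fixed absolute range would let
  quantization noise swamp narrow-spread lesion textures). Only pixel
  pairs both inside the mask are counted. A constant region is degenerate:
  energy and homogeneity 1, contrast 0, correlation reported as 0 with a
  warning.
* moment invariants `phi_1 = eta20+eta02`,
  `phi_2 = (eta20-eta02)^2 + 4 eta11^2`,
  `phi_3 = (eta30-3 eta12)^2 + (3 eta21-eta03)^2` from normalized central
  moments of the mask — exactly translation invariant, rotation invariant
  up to rasterization.

## Feature selection

A subset is a point in `[0,1]^F`, decoded by thresholding at 0.5 (an empty
decode falls back to the highest coordinate, so subsets are never empty).
Its score is the Matthews correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TN+FP)(TP+FP)(TP+FN)(TN+FN))

of a stratified 5-fold cross-validated linear SVM (C = 1) restricted to
the selected columns, with fold predictions pooled into one confusion
matrix; a zero denominator factor yields 0. The search maximizes MCC —
minimizing a correlation coefficient would select the worst subsets.
Subset evaluations are memoized on the decoded mask.

## Classification and evaluation

The final classifier is a kernel SVM (default RBF with `gamma = 1/(F *
var)`, `C = 1`; both exposed), trained on z-scored features through a
standard SMO solver. The decision surface
`y = sgn(sum_i y_i alpha_i K(x, x_i) + b)` is evaluated directly from the
stored support vectors, multipliers and bias — the prediction path is the
explicit kernel sum, with `sgn(0) -> +1`. An optional mode tunes
`(log C, log gamma)` by SBO on cross-validated MCC; it is off by default.

Evaluation draws stratified 75/25 train/test splits (15 by default, the
desk-scale benchmark uses 5), derives one sub-seed per repeat from the
master seed, reruns selection + SVM per repeat, and reports mean and
standard deviation of accuracy, sensitivity, specificity, PPV and NPV.
Zero denominators yield 0 with a warning.

## Synthetic data

Each image is a star-convex pigmented blob on a lighter textured
background: boundary `r(theta) = r0 (1 + A * s(theta))` where `s` is a sum
of 3–7 sinusoidal harmonics normalized to unit peak, so the irregularity
amplitude `A` is the exact fractional boundary excursion. Textures are
spatially correlated Gaussian fields (smoothing length 3 px, normalized to
the requested std); artifacts are dark quadratic-Bezier "hairs" and
salt-and-pepper impulses at 0.2–1% of pixels. Benign lesions draw
`A in [0, 0.05]`, interior std in `[0.02, 0.04]`, axis stretch
`[1.0, 1.1]`; malignant (at difficulty 1) `A in [0.15, 0.35]`, std
`[0.07, 0.12]`, stretch `[1.15, 1.4]` — the three class-separating axes
are border irregularity, asymmetry and interior variance. A `difficulty`
knob interpolates the malignant ranges toward the benign ones; at 0 the
class distributions are identical, giving a null model under which the
whole downstream chain should score chance-level accuracy. Masks are the
exact rasterized blobs, so segmentation Dice is scored against exact
ground truth.

The generator reproduces statistical structure, not photorealism: no
modality differences, no vignetting or color constancy effects, no
clinically realistic pigment networks. Passing tests therefore demonstrate
that the chain exploits border/texture statistics correctly, not that it
would reach the same numbers on clinical images.

## Problem sizes and numerical choices

The default benchmark uses 200 images, a segmenter trained on balanced
16x16 patches (30 per image from 24 images, 300 gradient iterations,
then an SBO refinement of population 16 for 5 cycles on a 400-patch
subsample), stride-4 voting, and 5 evaluation repeats with selection
population 16 for 10 cycles per repeat. The null calibration runs 10
seeds at difficulty 0 with 80 images and ground-truth (oracle) masks —
segmentation is class-blind, so the null property concerns the
feature-to-classifier chain; the oracle mode exists precisely for such
ablations. The full-scale protocol (8000 gradient iterations, population
200, 15 repeats) remains the configuration default outside the benchmark
entry points.

Ties and degenerate inputs: median filter requires an odd window; empty
masks are rejected in feature extraction and dropped (with a warning) in
the pipeline; a probability of exactly 0 at a target class is clamped at
1e-12 in the loss; `sgn(0)` is positive; degenerate ellipse axes zero the
axis-ratio features with a warning.

## Known limitations

* The patch-voting segmenter blurs boundary detail at the patch scale;
  very ragged borders are smoothed, so shape features are attenuated
  relative to ground-truth masks (texture and intensity features carry
  most of the class signal after segmentation).
* MCC-wrapper selection with small populations is a stochastic search; on
  near-tied subsets different seeds return different masks.
* Metrics are reported per split without confidence intervals beyond the
  across-repeat standard deviation.
* The SVM dual is solved to the SMO solver's default tolerance (1e-3);
  duplicated-data equivalences hold to that tolerance, not machine
  precision.
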