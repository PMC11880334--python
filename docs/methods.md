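# Methods

This note documents the models and procedures implemented in `burnscope`,
the parameter choices that matter, what the synthetic phantoms do and do not
emulate, and the numerical conventions used throughout. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Color representation

All analysis runs in CIE 1976 L\*u\*v\* (luminance L\* in [0, 100],
chrominance u\*/v\*), assuming sRGB companding and the D65 white point —
the realistic assumption for consumer-camera JPEG/PNG input, which never
carries a reliable profile. The conversion is implemented directly rather
than through a library routine for one numerical reason: the white point is
taken as M·[1,1,1] of the sRGB→XYZ matrix itself, so the neutral axis maps
*exactly* to u\* = v\* = 0 (gray pixels land on the axis to machine
precision, and the 8-bit round trip errs by at most one level). Library
conversions that hard-code a slightly different D65 leave grays at
|u\*| ≈ 10⁻², which would leak false chroma into the texture features; the
implementation is cross-checked against `skimage.color.rgb2luv` at coarse
tolerance in the tests. Pixels with Y = 0 have undefined chromaticity; the
convention here is u\* = v\* = 0.

Gaussian smoothing uses the isotropic kernel
G(x, y) ∝ exp(−(x² + y²)/2σ²) on the integer offset grid, normalized to
sum 1, with **reflective** boundary padding — zero padding would create
dark halos at the border that bias the co-occurrence statistics. Default
5×5, σ = 1.5: small enough to keep lesion edges, large enough to suppress
pixel noise. Each of L, u, v is filtered independently.

## Contrast kinetics and enhancement

Tissue uptake follows the standard Tofts two-compartment model

    C_t(t) = K^trans ∫₀ᵗ C_p(τ) exp(−K^trans (t−τ)/v_e) dτ

with K^trans the plasma→EES transfer constant (1/min) and v_e the
extravascular-extracellular volume fraction (dimensionless, (0, 1]).
Defaults K^trans = 0.2/min, v_e = 0.4 are mid-range soft-tissue values. The
integral is evaluated by trapezoidal quadrature on the sample grid
(second-order accurate, grid-native); against the constant-input closed
form c·v_e·(1 − e^(−K^trans t/v_e)) the relative error is below 10⁻³ on a
1000-point grid (checked in the acceptance suite). Concentration units are
deliberately unspecified — only the normalized uptake enters the pipeline.
No arterial-input-function estimation is attempted; the plasma curve is
either constant or the standard biexponential decay.

The enhancement operator is this package's own definition (photograph
enhancement has no canonical "DCE" operator). It is a fixed, strictly
monotone pixelwise remap of L:

    L₁ = 100 (L/100)^γ                       (gamma lift, γ ∈ (0, 1])
    L′ = 50 + (1 + g·U)(L₁ − 50), clipped    (uptake-scaled contrast stretch)

where U = C_t(t_eval)/max C_t ∈ [0, 1] and g ≥ 0 is the gain. The gamma
lift brightens dark (deep-burn) tissue; the stretch about mid-scale widens
the histogram in proportion to uptake saturation. An earlier candidate —
blending toward white, L′ = L₁ + g·U·(100 − L₁) — was rejected because it
is an affine compression (slope < 1) that measurably *lowers* histogram
entropy on every phantom fixture, while the intended signature of
enhancement is a brighter image with *more* usable gray levels. The stretch
form delivers both (on the seed-42 phantom: mean 62.9 → 76.0, entropy
5.75 → 6.06 bits, computed by `examples/02`). Monotonicity makes the
operator order-preserving pixelwise, so segmentation boundaries cannot
invert under enhancement.

Plane statistics: mean, population std, Shannon entropy (base 2) of the
256-bin histogram over the plane's nominal range ([0, 100] for L, [0, 255]
for 8-bit), Fisher–Pearson skewness m₃/m₂^{3/2}, and raw (non-excess)
kurtosis m₄/m₂² — the non-excess convention is what makes heavy-tailed
8-bit images report kurtosis in the hundreds. A constant plane is flagged
degenerate with shape statistics reported as 0.

## ACICA + fuzzy C-means segmentation

Channel unmixing assumes the linear mixing model X = A·S and recovers
maximally non-Gaussian components by whitening plus fixed-point negentropy
maximization (scikit-learn's FastICA, logcosh contrast). Components are
ordered by decreasing |excess kurtosis| and sign-fixed to nonnegative
skewness, making the decomposition reproducible up to the model's inherent
permutation/sign ambiguity. Rank-deficient input raises an error naming
the dependent channel; if every recovered component is near-Gaussian
(|excess kurtosis| < 0.2) the model is flagged unidentifiable — with
Gaussian sources the unmixing rotation is arbitrary. Unmixing is an
optional pre-stage (off by default): the pipeline clusters L directly,
since luminance is the depth-bearing signal in the phantoms.

Fuzzy C-means on scalar intensities uses the standard Bezdek iteration:
memberships u_ik = 1/Σ_j (d_ik/d_ij)^(2/(m−1)), centers as u^m-weighted
means, fuzzifier m = 2, tolerance 10⁻⁵ on the center shift, at most 300
iterations, k-means++-style seeded center initialization. These are the
standard settings; seeding makes runs bit-reproducible. The objective
Σ u_ik^m d_ik² is nonincreasing across iterations (property-tested).
Centers are returned sorted ascending; pixels take the argmax-membership
label with exact ties resolved toward the lower label. Default
ncluster = 4: healthy skin plus three burn depths.

Region summaries: per-region mean intensities g(ii); the squared
differences of adjacent region means ("region PDF"); ḡ, the mean of the
cluster centers; and the dispersion Σ(g(ii) − ḡ)² (agent-contrast
concentration). A separate pixelwise map |I(i,j) − I(i+1,j+1)| over
diagonal neighbors is computed alongside — the two difference constructs
coexist in the burn-imaging literature under one name, so both are
implemented under distinct names and logged.

The pipeline maps ascending-luminance clusters to depth codes by the
darker-is-deeper heuristic (darkest cluster → deep, brightest → healthy).
This matches the phantom palette and charred/necrotic tissue generally,
but is a heuristic: erythematous superficial burns can be darker than
pale deep dermal injury in real photographs.

## Reference-region (RR) histogram segmentation

The RR chain on an 8-bit intensity plane: (1) quantize to `qlevels`
uniform bins (bin-center values; identity at 256 levels), discarding
pixels below Z_th; (2) find local maxima of the quantized histogram above
th = mean count of the nonzero bins; visit peaks in decreasing count
order, merging any candidate closer than D_th into its nearest accepted
center at the count-weighted mean position, repeating until all pairwise
gaps are ≥ D_th; fall back to the global maximum if no peak clears th;
(3) label every pixel by its nearest center if within the similarity
threshold, then raise the threshold to the largest minimum-center distance
among unlabeled pixels and repeat — the labeling is total by construction,
with residual pixels (and the discarded dark pixels) assigned the
background label 1. Equidistant pixels break toward the lower center.

Defaults Z_th = 10, D_th = 16, qlevels = 64: chosen once so that the four
class modes of a phantom histogram survive quantization as distinct peaks
(≈ 21 intensity levels apart at the default palette) while sensor-noise
side-peaks within a class mode merge. The pass-1 similarity threshold
defaults to D_th, keeping a single intensity scale for merging and
labeling. The peak-acceptance threshold (a count) and the labeling
threshold (an intensity) are deliberately separate quantities. The agent
percentage is the pixel share of non-background labels.

## Texture features

GLCMs are built on G = 8 quantized levels (uniform binning of the plane's
own [min, max]; a constant plane maps to level 0), distance d = 1, at the
four offsets 0° → (0, d), 45° → (−d, d), 90° → (−d, 0), 135° → (−d, −d) in
(row, col) coordinates, symmetric (each pair counted both ways) and
normalized to sum 1. Contrast = Σ(i−j)²P(i,j);
correlation = Σ(i−μᵢ)(j−μⱼ)P(i,j)/(σᵢσⱼ), defined as 0 when a marginal is
degenerate. The implementation is exact counting (verified against a
brute-force double-loop oracle to 10⁻¹²).

The 10-value descriptor takes, per source plane (L; chroma = √(u²+v²)):
contrast and correlation of the plane's GLCM and of the squared plane's
GLCM, each averaged over the four offsets, plus the plane mean. Averaging
over the rotation-closed offset set makes the descriptor invariant to
transposition and 90° rotation. Energy/homogeneity/entropy features are
deliberately out of scope.

## Classifiers and training protocol

Three architectures on a shared seeded numpy layer engine (im2col
convolution, BPTT recurrence, Adam), so results are byte-reproducible in
single-threaded runs:

* **CNN** — input: the three Luv planes affinely scaled to ~[0, 1] and
  resized to a square side (default 224; tests and the acceptance script
  use 32 — at phantom scale the extra resolution adds cost, not signal);
  three blocks of 3×3 convolution (32/64/128 filters) + ReLU + 2×2
  max-pool + dropout 0.25; dense 128 + ReLU; 3-way softmax.
* **FNN** — the 10-value texture descriptor, standardized on the training
  tier, through dense 32 → 16 → 3. The descriptor input is the natural
  reading of a plain weighted-sum dense network paired with GLCM features.
* **RNN** — rows of the 32×32-downsampled L plane as 32 timesteps of 32
  features; tanh recurrence h_t = tanh(W_hh h_{t−1} + W_xh x_t + b_h),
  hidden 64, softmax on the final state. Row-sequencing is a documented
  stand-in: images have no canonical temporal axis.

Splitting is stratified 70/15/15 with a fixed rounding rule — train
= ⌊0.70·n⌋, validation = round-half-up(0.15·n), test = remainder (63/14/13
at n = 90) — and largest-remainder allocation inside each tier, keeping
per-class counts within one item of exact proportionality. Stratified
5-fold cross-validation is available through scikit-learn's splitter.

Training: 50 epochs, batch 8, Adam at 10⁻³, per-epoch seeded shuffling,
categorical cross-entropy with probabilities clipped at 10⁻¹². Image-input
augmentation draws rotation U(−15°, 15°) with reflective fill, horizontal
and vertical flips at probability ½, brightness factor U(0.8, 1.2) with
clipping, zoom U(0.9, 1.1) with center crop/pad. For the CNN's Luv stacks
the brightness factor applies to the luminance channel only: the chroma
channels are offset-encoded, and scaling them shifts hue rather than
brightness, which measurably hurt generalization. Evaluation reports the
confusion matrix, accuracy, per-class precision/recall/F1 and
macro/weighted averages; a class absent from both truth and prediction is
flagged and scored 0. A two-class severity collapse (up-to-dermal vs.
deep) is provided for binary reporting.

## Synthetic phantoms

A phantom is a nested-ellipse lesion on healthy skin: superficial
outermost, dermal, then deep innermost — depth grades from the wound edge
to its core. Ring areas are set from target canvas-area fractions; the
"bands" geometry provides pixel-exact class areas for worked examples.
Class appearance: mean RGB ± channel noise of healthy (205,170,150)±8,
superficial (230,160,140)±10, dermal (200,90,80)±12, deep (120,40,35)±10 —
a plausible light-skin/erythema/deep-red/charred progression — with
spatially correlated noise whose correlation length shrinks with depth
(3.0/2.0/1.2/0.5 px), so GLCM contrast rises monotonically with depth and
luminance falls. Dataset images draw a dominant class (30–40% of canvas)
plus small admixtures of the other depths; the dominant class is the
classification label. Everything is a pure function of (spec, seed).

What phantoms do not emulate: illumination gradients and specular
highlights, camera scale/distance variation (capture distance is not
modeled), skin-tone diversity, irregular lesion boundaries, wound dressing
and background clutter. Passing tests therefore validate the pipeline's
mechanics — conservation, determinism, oracle agreement, separability-given
-signal — not clinical performance; the classifiers' near-perfect phantom
accuracy reflects the generator's constructed separability.

## Numerical conventions and degenerate inputs

Coordinates are (row, col), origin top-left, 0-based. PNG fixtures keep
tests bit-exact (JPEG decoding varies across codecs); 16-bit inputs are
right-shifted with a provenance note. Ties break toward the lower label
everywhere (FCM argmax, RR nearest-center). Degenerate cases are explicit:
constant planes (zero std/entropy, zero GLCM features, quantization to
level 0), empty regions (error naming the region), all-dark RR input
(error), rank-deficient unmixing (error naming the channel), Gaussian-only
sources (unidentifiability flag), non-finite training loss (error with the
epoch index). The pipeline is a pure function of (config, image, seed);
every stage is timed and logged.

Problem sizes in the tests and acceptance script — 64×64 phantoms, 32×32
classifier input, 90-image datasets — were chosen as the smallest sizes at
which every class mode, texture scale and split ratio of the full-size
configuration is still faithfully represented.

## Known limitations

* The per-sample TBSA convention (sample = 100%) deliberately differs from
  clinical rule-of-nines TBSA; no body-region mapping or patient-level
  aggregation is attempted.
* The darker-is-deeper cluster→depth mapping is a heuristic (see above).
* The enhancement operator is a principled stand-in, not a validated
  radiometric model of contrast-agent imaging.
* No DICOM, ICC-profile, or chromatic-adaptation handling; no GPU path.
* FCM is not spatially regularized; segmentation of textures with heavy
  intensity overlap degrades accordingly.
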