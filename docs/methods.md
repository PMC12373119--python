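# Methods

## Color pipeline

RGB images (8-bit, sRGB) are converted to CIELAB by the standard chain:
per-channel scaling to [0, 1]; piecewise sRGB inverse gamma (threshold
0.04045, linear divisor 12.92, exponent 2.4); the D65 RGB→XYZ matrix to four
decimals (rows 0.4124 0.3576 0.1805 / 0.2126 0.7152 0.0722 / 0.0193 0.1192
0.9505); normalization by the D65 white (0.95047, 1, 1.08883, 2° observer);
and the CIELAB companding f(t) = t^{1/3} for t > δ³, else αt + β with
δ = 6/29, α = 1/(3δ²), β = 4/29 (the values that make f continuous at δ³).
L\* = 116 f(Y/Yn) − 16, a\* = 500[f(X/Xn) − f(Y/Yn)],
b\* = 200[f(Y/Yn) − f(Z/Zn)].

Chroma is kept unclamped internally — the sRGB gamut peaks near |b\*| ≈ 108,
inside the nominal [−128, 127] storage range — and clipped only at
normalization or 8-bit serialization, so RGB→Lab→RGB round trips are exact
to ±1 count. Training normalization maps L\* → L\*/50 − 1 and
a\*, b\* → clip(·, −128, 127)/128; divisors 50 and 128 were chosen so the
declared channel ranges map onto [−1, 1] with a closed-form inverse.
Inversion (Lab→RGB) is the exact algebraic inverse with out-of-gamut values
clipped at the final 8-bit rounding (half-even).

## Networks

Everything is implemented in numpy/float32: convolutions are lowered to
BLAS matmuls via im2col, the input gradient of a strided convolution is
expressed as a convolution of the zero-dilated output gradient with the
flipped transposed kernel, and Adam (lr 2·10⁻⁴, β = (0.5, 0.999)) performs
the updates. Runs are bitwise-reproducible given a seed. Backpropagation
was verified against central finite differences layer-by-layer and
end-to-end (directional derivatives at smooth operating points).

**Generator.** U-Net on the normalized L\* plane, depth log₂(size) so the
bottleneck is 1×1 (depth 8 at 256 px, auto-reduced to 6 at 64 px); encoder
convs are 4×4 stride 2 with BatchNorm + LeakyReLU(0.2) (no norm on the first
level); channel widths grow as base·min(2ⁱ, 8). The decoder uses
nearest-neighbour ×2 upsampling followed by a 3×3 convolution (chosen over
transposed convolution to avoid checkerboard artifacts and keep the bespoke
backward pass small), BatchNorm + ReLU, with the same-resolution encoder
features concatenated at each level. The head is a 3×3 convolution with
tanh, so predicted chroma lies strictly in (−1, 1). Dropout is omitted:
the determinism contract is worth more here than the mild regularization.

**CBAM.** Channel attention: sigmoid(MLP(avg-pool F) + MLP(max-pool F)),
MLP = bias-free two-layer (reduction ratio 16, configuration error when
C < r); spatial attention: sigmoid of a 7×7 convolution over the
channel-wise [avg; max] planes. Attention is applied to every
skip-connection feature map and the bottleneck, toggleable. Geometry is
always preserved; with both sigmoids at 1 the module is the identity, and
with all parameters zero it scales features by exactly 0.25 (both sigmoids
at 0.5) — a convenient analytic checkpoint used in the tests.

**Discriminator.** PatchGAN: 4×4 convolutions with channel widths
base·(1, 2, 4, 8) at strides 2, 2, 2, 1 and a final stride-1 projection to
one logit per patch; each logit sees a 70×70 px receptive field and a
256×256 input yields a 30×30 score map. The image-level score is the
arithmetic mean of the per-patch probabilities. By default the
discriminator is conditioned on L\* concatenated with (a\*, b\*) — standard
conditional-GAN practice — with a configuration switch (`condition_on_l =
False`) for judging chroma alone, since which input the original
discriminator saw is ambiguous. BatchNorm uses current-batch statistics
with no running averages; at inference batch 1 this is instance
normalization and keeps prediction a pure function of the input image.

## Training

Per batch: one discriminator update (real pair, then generated pair), then
one generator update — two for Model 3, operationalizing "generator
iteration" as two generator updates per discriminator update so the
generator/discriminator balance is uniform across the epoch. Both
cross-entropies are computed in logit form (softplus), so no NaN/Inf arises
for finite logits. The L1 term is the mean over batch, channels and pixels,
making λ (default 100, the customary image-translation weighting)
resolution-independent. Learning rate, optimizer and epoch count are
configuration with logged defaults; fine-tuning keeps the original learning
rate unless overridden.

Fine-tuning continues training on the original pool plus
floor(fraction·|new batch|) images of the new batch (default fraction 1/3,
selected by a seeded permutation); held-out new-batch images never enter
training.

## Metrics

PSNR: 20 log₁₀ 255 − 10 log₁₀ MSE over all pixels/channels; +∞ (reported
as the string "inf", never capped) iff images are identical. SSIM: the
luminance·contrast·structure product with K₁ = 0.01, K₂ = 0.03, dynamic
range 255, 11×11 Gaussian window σ = 1.5, population covariances, averaged
over valid windows and over R, G, B; it agrees with scikit-image's
implementation to ~1e-16 and is asserted against it in the tests.

WPH: both images are partitioned into (size/patch)² square patches (default
32 px, 32 bins per channel over [0, 256)); per patch and channel the
probability histograms are compared and channel scores averaged. The
comparison kernel is normalized histogram intersection (Σ min) — the choice
is open in principle, and intersection is the kernel that is symmetric,
bounded in [0, 1] and exactly 1 for identical patches; a correlation kernel
(affinely mapped to [0, 1]) is available via configuration. The final score
is a weighted mean with patches inside the ROI multiplied by 1.5. The ROI
default is the centered half-width × half-height block of the patch grid
(central 4×4 of an 8×8 grid), configurable as an explicit mask. The grid is
always derived as image_size/patch_size (a 256×256 image with 32-px patches
is an 8×8 grid; statements of a fixed grid count only hold at one specific
resolution). Evaluation always runs in RGB; CIELAB exists only inside
training.

## Quantification

Per channel (R = mOrange-EC, G = GFP-CM), the organoid mask is pixels
strictly above threshold T (default 10 of 255, suppressing camera-noise
counts; T = 0 counts any nonzero pixel). Area, % coverage, total intensity
(summed over the mask, so intensity/area is self-consistent), intensity by
organoid area and by image area follow the printed formulas. Undefined
ratios (zero area, zero ground truth) are NaN sentinels, never 0 or ∞.
difference% = 100·|gen − gt|/gt per measurement, classified "low" at ≤ 25%
(boundary inclusive) and "high" above.

## Synthetic data

The generator emulates ring organoids on a dark background: an annulus
(default radii 0.18–0.45 of the image), a cardiomyocyte domain produced by
thresholding a smoothed noise field at the quantile matching the configured
fill fraction (default 0.85 of the ring), and an endothelial network grown
by branching random walks confined to the ring. Fluorescence: green on the
CM domain, red on the EC network (mean intensities ~185/~205 with smooth
±15–18% spatial variation), background exactly zero. Phase contrast:
bright ring on dark background with cell-type-coded texture — fine grain
(correlation length 0.8 px, contrast 25) and a darker offset on the CM
body, coarser grain (2 px) and a +70 brightness offset on EC branches —
plus σ = 2 background noise. The EC/CM phase-brightness separation is the
learnable signal; because the fluorescence is a deterministic function of
the masks, a sufficiently trained model can approach WPH → 1 on this data
while an untrained generator scores far lower, which is the training
smoke-test signal. The "new batch" domain shift is a +25 global brightness
offset plus a 1.6× texture-scale change.

What the generator does not emulate: optical physics, debris and focus
artifacts, morphological diversity across differentiation batches, or
intensity nonstationarity within a channel. Passing tests on this data
demonstrate that the pipeline wiring, losses and metrics behave as
specified and that the model can learn a texture→color mapping; they say
nothing quantitative about performance on real microscopy.

## Problem sizes and numerical choices

The end-to-end study in the test suite trains Model 2 on 200 synthetic
64×64 pairs for 20 epochs (base width 16) and fine-tunes for 5 epochs with
a third of a 30-image shifted batch — sizes chosen so the whole suite runs
on a single CPU in well under half an hour while leaving a clear
trained-vs-untrained margin on all three metrics. WPH at 64 px uses 16-px
patches (4×4 grid) so the grid keeps a central ROI. Degenerate inputs are
errors, not silent defaults: rings thinner than 2 px, non-power-of-two
network inputs, patch sizes that do not divide the image, double
normalization, empty batches and λ < 0 all raise.

## Known limitations

Real phase-contrast → fluorescence mapping is far harder than the synthetic
analogue; no claim is made about reproducing microscopy-scale accuracy.
BatchNorm batch statistics couple samples within a training batch, so loss
histories depend on batch composition (they remain seed-reproducible).
The numpy engine is single-threaded BLAS-bound; 256×256 training at full
width is possible but slow, and the intended desk scale is 32–128 px.
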