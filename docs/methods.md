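# Methods

`synthrad` implements a two-part pipeline: (1) translation between two
brain-MRI-like contrasts with CycleGAN-style adversarial networks, and
(2) an evaluation schema that scores how distinguishable the synthetic
images are from real ones, using pixel fidelity metrics and a 23-feature
texture-radiomics panel compared with normality-gated statistics.

## Synthetic phantoms

Real paired T2W/FLAIR slices are replaced by seeded phantoms
(`synthrad.phantom`). Each phantom is an elliptical "brain" with nested
elliptical regions — outer tissue, a white-matter-like band, a central
fluid-like region, and an optional lesion blob — whose geometry is
randomized per slice. The two contrasts share the label geometry exactly;
they differ only through a per-class intensity table. The fluid class is
bright in domain A (0.90) and dark in domain B (0.10), mimicking fluid
attenuation, so the cross-contrast mapping is a deterministic, monotone,
anatomy-preserving intensity remap — the property a translation network
must learn. The remaining classes differ by a small offset (0.45/0.50,
0.35/0.40, 0.75/0.85) so the mapping is nontrivial everywhere.

Acquisition noise is additive Gaussian, independent between the two
domains, default sigma 0.02 in [0,1] intensity units (roughly the visual
noise level of a clean clinical slice after unit normalization); images
are clipped to [0,1]. The generator does **not** simulate MRI physics:
no bias fields, partial-volume effects, k-space artifacts, or 3D
structure. Passing tests therefore demonstrate that the algorithms behave
correctly on images with realistic piecewise-smooth structure and noise,
not that the trained toy networks would transfer to clinical data.

`degrade(image, level, seed)` manufactures "synthetic-quality" surrogates
by blending with a Gaussian-smoothed copy (sigma = 1.5·level) and adding
noise (sigma = 0.08·level). It is the controllable dial used to verify
that the evaluation schema responds monotonically to image corruption;
`level=0` is the exact identity.

Default canvas is 64×64 for feature-level work and 32×32 for training
experiments; 256×256 is available and mirrors the reference
configuration.

## Discretization and texture features

Features are computed per 2D slice from a masked image quantized to
B = 20 gray levels (levels 1..B inside the mask, 0 outside). The bin
width is derived per image from the in-mask range:
`w = (max − min)/B`, `level(x) = min(floor((x − min)/w) + 1, B)`; a
constant region maps to level 1. Min/max come from masked pixels only,
matching extraction after whole-brain segmentation. The number of bins
is the fixed quantity; the width adapts per image (the behaviour of a
bin-count setting in common radiomics toolkits).

Three matrices are built per image:

* **GLCM** — pooled, symmetrized co-occurrence counts over the four
  unique 2D directions (0,r), (r,0), (r,r), (r,−r) at radius r = 1
  ("combined" offsets as merged-matrix aggregation, giving one value per
  feature), normalized to probabilities p(i,j).
* **GLRLM** — maximal same-level runs along the same four directions;
  out-of-mask pixels terminate runs; counts are pooled over directions.
* **GLSZM** — connected components of same-level in-mask pixels,
  8-connectivity by default.

From these, 23 features: 8 GLCM (auto-correlation, cluster prominence,
cluster shade, contrast, correlation, energy, entropy, homogeneity),
7 GLRLM and 8 GLSZM emphasis/nonuniformity statistics. Conventions:
levels are 1-indexed so 1/i² terms are finite; entropy is base-2 with
0·log 0 := 0; homogeneity is the inverse-difference form Σ p/(1+|i−j|);
GLCM correlation is the Pearson-style Σ(i−μ)(j−μ)p/σ², defined as 0 for
a constant image (σ = 0). The entire engine is cross-checked to 1e-10
against an independent brute-force enumerator on random images.

## Fidelity metrics

MAE, MSE and PSNR = 10·log₁₀(MAX²/MSE) between aligned image pairs, with
MAX the largest pixel value over *both* evaluated images, which makes all
three metrics symmetric in their arguments. PSNR is +∞ exactly when
MSE = 0; such pairs are excluded from PSNR averages and counted
separately. Summaries report the mean and population SD across pairs.
Metrics run on the whole image by default (the defining sums range over
all voxels); an optional mask restricts them to the brain.

## Statistical comparison

For each feature, the real and synthetic groups are compared unpaired:

1. Both groups are tested for normality with the D'Agostino–Pearson
   omnibus K² (needs n ≥ 8; a constant sample counts as non-normal).
2. If both pass at the same alpha, a Welch (unequal-variance) t-test with
   the exact 95% CI of the mean difference; otherwise a Mann–Whitney U
   test with the Hodges–Lehmann shift estimate and its distribution-free
   order-statistic CI (normal approximation for the rank cutoff).
3. A feature is *significant* exactly when the CI of the difference
   (real − synthetic) excludes zero. On the t path this coincides with
   p < alpha by construction.

No multiple-testing correction is applied across the 23 features — the
report mirrors per-feature significance tables. Both test paths are
calibrated: under the null (both groups from one distribution, 50 per
group) the rejection rate at alpha = 0.05 lands in [0.03, 0.07] over
thousands of replicates. Unpaired testing is deliberate even though the
underlying slices are paired; group-level mean ± SE reporting is the
schema being emulated, and a paired mode is out of scope for v1.
If a feature is constant and identical in both groups the row is marked
"degenerate" and non-significant; constant but unequal groups raise an
error rather than fabricating a test.

## Translation models

Both models share the generator: 7×7 convolution → two stride-2
downsampling convolutions → residual blocks (reference count 9) → two
nearest-neighbour-upsample + convolution stages → 7×7 output convolution,
instance normalization throughout, sigmoid output so [0,1] images map to
[0,1] images. Discriminators are strided-convolution patch classifiers
(4×4 kernels, LeakyReLU 0.2, instance norm after the first block) ending
in a sigmoid score map; the DC2Anet variant is conditional and consumes
the channel-concatenation of the source image and the candidate target.

Losses (natural-log cross-entropy adversarial form by default; a
least-squares switch is provided):

* adversarial: D maximizes log D(real) + log(1 − D(fake)); G minimizes
  −log D(fake); scores averaged over the patch map, probabilities clamped
  to [1e-7, 1−1e-7] so every term is finite;
* cycle consistency: mean L1 of both round trips A→B→A and B→A→B,
  weight λ_cyc = 10 against λ_GAN = 1;
* DC2Anet's supervised objective adds, at unit weights: voxel-wise L1,
  gradient-difference (L1 between finite-difference gradient magnitudes
  along rows and columns), perceptual (L1 between the discriminator's
  intermediate activations for generated vs target input), and structural
  (1 − mean SSIM, 7×7 box window, C1 = 0.01², C2 = 0.03², data range 1,
  zero-padded filtering so the operator is self-adjoint and the analytic
  gradient is exact).

Training follows the reference recipe: Adam (β₁ = 0.5, β₂ = 0.999),
weight init N(0, 0.02), batch size 2, learning rate 2e-4 held constant
then decayed linearly to 0 (reference schedule: 400 epochs, decay from
epoch 200), and three generator update iterations per discriminator
iteration, implemented literally as 3 generator steps on the current
batch followed by 1 discriminator step. DC2Anet alternates one supervised
step (conditional adversarial + cycle + the four auxiliary losses) with
one unsupervised step on successive batches; the alternation ratio is a
design choice (the source description fixes none), and the unsupervised
step optimizes the cycle-consistency objective, since with conditional
discriminators the unpaired adversarial term has no natural input.

The networks are built on `synthrad.nn`, a compact numpy layer library
with hand-written backward passes (im2col convolution, instance norm,
nearest-neighbour upsampling, residual blocks, Adam). Parameters default
to float32 for speed; every backward pass is verified against central
finite differences in the test suite. For stride-1 convolutions the
input gradient is computed as a flipped-kernel correlation of the output
gradient, which is substantially cheaper than scatter-based col2im for
wide kernels.

## Desk-scale configuration and what the tests show

The reference configuration (256×256, 64 base channels, 9 residual
blocks, 400 epochs) is recorded in the defaults of `GANSpec` and
`TrainSchedule` but is not what the test suite runs. Training
experiments use 32×32 phantoms, 8 base channels, 2 residual blocks,
50 training pairs and 30 epochs (decay from epoch 15) — sizes chosen so a
seeded run finishes in about two minutes on one CPU while the learning
signal is still unambiguous. Under those conditions a trained CycleGAN
reduces held-out translation MAE from ≈0.33 (untrained generator) to
≈0.05, and its cycle loss falls by about 3× within 30 epochs; it does not
reach the ≈0.04 MAE of the identity mapping between the two contrasts,
which would require far longer training. Statements about the full-scale
configuration are limited to arithmetic (e.g. the learning-rate schedule)
that needs no training to verify.

## Known limitations

* Phantoms are 2D, piecewise-constant-plus-noise; real-MRI texture,
  scanner effects and misregistration are absent, so the evaluation
  schema's behaviour on clinical data is not demonstrated here.
* The GLCM correlation variant and the GLSZM nonuniformity normalization
  differ between radiomics toolkits; the conventions above are fixed and
  documented, but other tools may print different absolute values.
* The Mann–Whitney CI uses the large-sample rank cutoff; for groups
  smaller than ~10 its coverage is approximate.
* The numpy training stack is single-threaded and desk-scale by design;
  it is not a route to 256×256/400-epoch training.
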