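# Methods

`brainsynth` implements a two-stage generative pipeline for paired brain-MRI
semantic label maps and intensity images, together with the synthetic
phantom data used to train and verify it. This note records the models, the
parameter choices that matter, the numerical decisions, and what the
phantom-scale experiments do and do not demonstrate.

## Overview of the pipeline

1. **Label generator** — a latent diffusion model (LDM): a spatial VAE
   (S-VAE) compresses multi-channel probabilistic label maps into a spatial
   latent grid; a time-conditioned denoising U-Net with cross-attention
   conditioning on lesion proportions is trained in that latent space with
   the epsilon-prediction objective; sampling runs a deterministic DDIM
   trajectory and decodes through the frozen VAE.
2. **Image generator** — a style/content-separated VAE-GAN: a style encoder
   maps an intensity image to a 16-dimensional style code (contrast); a
   decoder driven by spatially-adaptive normalisation renders a semantic
   map in that style; training combines hinge GAN, feature-matching,
   perceptual, style-KLD and contrastive losses under an adversarial
   scheduler.
3. **Phantom and SD simulator** — nested-ellipsoid brain phantoms with
   optional WMH and three-compartment tumours, plus a statistics-derived
   (SD) image model: per-region Gaussian intensities sharpened by a
   contrast factor K and modulated by a random multiplicative bias field.

All neural components run on a small reverse-mode automatic-differentiation
engine written in numpy (`brainsynth.nn`), with convolutions expressed as
blocked GEMMs. Analytic gradients are verified against central finite
differences in the test suite, and the convolution forward pass is
cross-checked against `scipy.ndimage.correlate`.

## Label maps

A `ProbLabelMap` holds per-voxel probabilities for five healthy tissues
(CSF, GM, WM, DGM, brainstem) followed by binary lesion channels (WMH, NE
tumour core, oedema, GD-enhancing tumour). Invariants: all values in
[0, 1]; per-voxel channel sum ≤ 1; lesion channels binary; healthy
probabilities are zero wherever a lesion is present (lesion fusion zeroes
healthy tissue under the mask). Lesion voxel counts always threshold the
channel at > 0.5.

## Phantom generator

Anatomy is a categorical map built from concentric jittered ellipsoids
(outer CSF shell, GM ribbon, WM interior, paired ventricle surrogates,
paired DGM blobs, inferior brainstem stalk), one-hot encoded with an
explicit background class, Gaussian-smoothed channel-wise (default sigma
1.5 voxels in 2D) and renormalised, which leaves genuinely fractional
probabilities on every boundary. Every operation is a pure function of
(config, seed).

Parameter notes:

- `jitter` (default 0.08) perturbs semi-axes and centres by a uniform
  fraction; it controls anatomical variability across subjects.
- `lesion_radius_range` (default 1.5–4.5 voxels) maps the size parameter
  in [0, 1] linearly to a target lesion radius. The lower bound keeps even
  the smallest lesions spatially coherent: a 32×32 slice is compressed 4×
  per axis by the S-VAE, and sub-voxel-scale scattered lesions are not
  representable through that bottleneck in any configuration we consider
  realistic at this resolution. WMH lesions are 1–2 blobs grown inside a
  periventricular white-matter band; tumours are three nested compartments
  (core, GD ring, oedema shell) seeded inside white matter.
- For 3D phantoms a boundary softness of ~1.0 voxel and shapes of at least
  (24, 24, 16) keep all five tissue shells above the 0.5 level after
  smoothing; the 2D default of 1.5 is too aggressive for thin 3D shells.

The simulator's default intensity statistics emulate T1 / FLAIR / T2
contrast orderings (e.g. CSF dark in T1 and bright in T2, WMH bright in
FLAIR) on a 0–100 intensity scale with per-region sigma 5 and K = 1.5,
giving a GM/WM contrast-to-noise ratio ≥ 3. The bias field is the
exponential of a spline-interpolated coarse Gaussian random surface scaled
to a log-amplitude drawn uniformly from [0.05, 0.15], applied with
probability 0.4. The Gaussian draw in the SD model is per voxel by
default (the minimal-assumption reading; `per_region=True` draws one value
per region).

## S-VAE

2D: two stride-2 downsamplings, 3 latent channels (a 32×32×9 map becomes
a 3×8×8 latent — the same per-axis compression as the reference design);
3D: three downsamplings, 8 latent channels. The decoder ends in a
per-channel sigmoid; the channel-sum invariant is restored at sampling
time by renormalising voxels whose healthy sum exceeds 1, and lesion
channels are binarised at the counting threshold.

The five-term loss: KLD against N(0,1); perceptual loss through a
pluggable feature extractor; patch-GAN hinge adversarial loss; focal
reconstruction loss; and a noise-robustness term that decodes z + eps
(eps ~ N(0, 0.05²)) so latents perturbed the way a diffusion sampler will
perturb them still decode cleanly.

Numerical choices in the focal loss: the per-element base penalty is the
binary KL divergence KL(l‖l̂) — cross-entropy minus the target's own
entropy — rather than raw cross-entropy, so that perfect reconstruction of
*fractional* boundary probabilities scores exactly zero. The focal weight
is |l − l̂|^γ with γ = 0.3 (smoothed by 1e-6 at the origin, where the
exact power has an unbounded derivative), and a class-balance factor
2(αl + (1−α)(1−l)) with α = 0.9 compensates the extreme
foreground/background imbalance of small lesions (a few voxels against a
thousand); without it the decoder reconstructs lesions as diffuse
sub-threshold probability mass. α = 0.5 recovers the unweighted loss.

Default loss weights (KLD 1e-4, perceptual 0.3, adversarial 0.05, focal 1,
noise-robustness 1) put all terms within roughly one order of magnitude on
phantom batches early in training. Training uses Adam (lr 2e-3), batch 64,
20 epochs at the standard phantom-study scale of 500 32×32 labels; the
discriminator takes a hinge step every other generator step.

## Latent diffusion model

The forward process is the standard fixed-variance chain, T = 1000 steps,
linear beta from 1e-4 to 0.02 (the endpoints are scaled by 1000/T when a
shorter chain is configured, preserving the terminal cumulative signal
level). Latents are standardised by their global standard deviation before
diffusion (recorded in the checkpoint). The denoiser is a small U-Net with
sinusoidal time embeddings injected additively per channel and single-head
cross-attention at the bottleneck over a short token sequence: one token
per conditioning scalar, token_i = value_i · W_i + b_i, so a token carries
both which lesion it denotes and how much is requested.

Conditioning values are the lesion proportions P_c = M_c / max_j M_c,j
(voxel count normalised by the dataset maximum; all zeros when a lesion is
absent from the dataset, avoiding the 0/0). For 2D slices cut from
volumes, the relative slice position (axial index / 256) is appended as
one extra conditioning dimension. Training samples one uniform timestep
per batch and minimises the L2 between injected and predicted noise.

DDIM sampling is fully deterministic (eta = 0) over an evenly spaced
timestep subset (default 200 of 1000); same seed, same inputs — bit-identical
output. Decoded samples are finalised by binarising lesion channels at
0.5, zeroing healthy tissue under lesions and renormalising healthy sums.

The two-stage contract is enforced: diffusion training refuses a VAE that
is still in training mode.

## Image generator

The style encoder (strided convolutions + global average pool) outputs a
16-dimensional posterior. The decoder starts from a learned projection of
the style code and applies three SPADE blocks: the semantic map, average-
pooled to the feature resolution, predicts per-pixel scale and shift
applied to parameter-free instance-normalised features. Because instance
normalisation erases channel-wise constants, the style code additionally
modulates each block's output through a channel-wise FiLM (scale/shift
from a zero-initialised linear layer — identity at the start of training,
growing only as the style pathway proves useful). Content therefore enters
only through the semantic map, style only through the code.

Training triplets pair a semantic map and its ground-truth image with a
style image drawn from a *different* slice of the same volume and
contrast, forcing the code to carry contrast rather than content; the
contrastive loss 1 − cos(E(i), E(affine(i))) (rotation ≤ 10°, translation
≤ 5%, scale 0.95–1.05) additionally makes codes geometry-invariant. The
sign convention: the encoder should *agree* on augmented pairs, so the
minimised quantity is one minus the cosine similarity. The multi-scale
discriminator (2 scales at this resolution) sees the channel concatenation
[image ‖ label channels ‖ broadcast one-hot modality planes]. A modality/
dataset discrimination loss exists behind a flag but is disabled by
default — with the contrastive loss and unpaired styles in place it did
not improve slice consistency, so the default configuration omits it.

The adversarial scheduler averages discriminator accuracy (fraction of
patches on the correct hinge side of zero, averaged over patches and
scales) across a 20-iteration window: above 0.75 only the generator
trains, below 0.6 only the discriminator, in between both; the thresholds
are strict inequalities, so a window mean exactly at a threshold trains
both. For the first 5 warm-up epochs both networks train unconditionally —
without this, a weak early discriminator (window mean < 0.6) can lock the
generator out indefinitely and training never leaves the gate.

Generator loss weights: GAN 0.1, style-KLD 0.02, perceptual 8 (through an
extractor whose first "layer" is the identity, so the perceptual term
contains a plain L1 alongside texture features), feature matching 0.5,
contrastive 1. Discriminator lr 8e-3 against generator lr 2e-3: the
deliberately faster discriminator keeps its windowed accuracy inside the
scheduler's active band.

## Pipeline

Dataset sampling draws absent lesions at P = 0 and requested lesions
either at an explicit value or uniformly within the training set's
[Q1, Q3] proportion band (quartiles are stored in the label-generator
checkpoint). 3D volumes are assembled by sampling one 3D label and
rendering each axial slice through the 2D image generator with the *same*
style code; per-slice re-encoding is available only as the explicit
inconsistent variant for comparison. One master seed fans out
per-component seeds via SHA-256, so every product is reproducible from its
configuration.

## Evaluation suite

- Tissue-proportion profiles (region mass / brain mass, per slice or per
  volume, mean ± std) as the label-quality surrogate; a coverage statistic
  reports the fraction of bins of a candidate profile inside the reference
  mean ± 3 std band.
- Lesion-size-versus-conditioning curves (median and IQR of thresholded
  voxel counts).
- FP_tum: tumour voxels mislabelled as WMH over tumour size.
- SSIM (7×7 window, K1=0.01, K2=0.03 via scikit-image) and MSE.
- Fréchet distance between Gaussian fits of feature sets, square root via
  eigen-decomposition with 1e-6 jitter on near-singular products; the
  feature extractor is pluggable (no pretrained backbone is bundled).
- Dice-based nearest-neighbour retrieval (channels thresholded at 0.5,
  unweighted mean over channels present in either map) as the
  memorisation check.
- K-means clustering of style codes (random init, 300 iterations, seeded),
  scored by adjusted Rand index; clustering runs in code space by default,
  an embedding hook exists but none is applied (dimensionality-reduction
  hyperparameters belong to figure-making, not the metric).

## What the phantom experiments show — and what they do not

The phantoms reproduce the *structure* of the real task: probabilistic
multi-tissue maps with fractional boundaries, binary lesions of controlled
size fused by the healthy-zeroing rule, multi-modal images with
tissue-dependent contrast, noise and bias fields. They do not reproduce
cortical folding, registration artefacts, scanner-specific noise spectra,
partial-volume anatomy beyond Gaussian boundary blur, or the sample sizes
of the real datasets. Passing the phantom-scale checks therefore
demonstrates that the training objectives, conditioning mechanism,
samplers and metrics are implemented correctly and interact as designed —
not that the models reach publication-grade fidelity on real MRI.

Problem sizes were chosen so the whole verification runs on one CPU:
500 32×32 labels and 20 epochs for the S-VAE; 150 epochs for the latent
diffusion model (width-48 denoiser); 50 samples per conditioning value at
200 DDIM steps; 220 training triplets and 20 epochs for the image
generator.

## Known limitations

- The 3D generative path shares all code with 2D (dimension-agnostic
  convolutions) but is exercised only at smoke-test scale; 3D training to
  quality is out of desk-scale reach.
- Small lesions (under ~10 voxels at 32×32) do not survive the 4× latent
  compression and decode as sub-threshold probability mass; lesion-size
  conditioning is therefore reliable in the mid-to-large size range.
- The default perceptual backbone is an untrained fixed-seed feature
  stack; a weights-file plug-in point exists for pretrained extractors.
- GAN training at this scale is stabilised by the warm-up and the
  scheduler, but per-seed variation in final image sharpness remains.
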