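# Methods

`crackspec` implements a pixel-level crack-segmentation pipeline for
shortwave-infrared (SWIR) hyperspectral images of chicken eggs: raw
push-broom counts are calibrated to relative reflectance, spectra are
denoised and de-scattered, a small set of informative wavelengths is
selected chemometrically, and a 3-D convolutional encoder–decoder with
parameter-free attention segments crack pixels from the reduced cube.
Because no public egg hypercube corpus exists, the package ships a
seeded synthetic scene generator that emulates the relevant spectral
physics; every quantitative claim in the test suite is made on that
synthetic benchmark, with the limitations spelled out below.

## Reflectance calibration

Raw counts `I0` are converted to relative reflectance with white (`W`)
and dark (`D`) reference frames:

    I = (I0 − D) / (W − D)

The denominator is floored at `epsilon` (default 1e-6) so dead or
saturated sensor elements cannot produce infinities, and the output is
clamped to [0, 2] to bound specular outliers. Calibration frames may be
full-frame or per-column (a line-scan sensor calibrates per detector
column); per-column frames broadcast over scan lines. The operation is
invariant to a common positive rescaling of `I0`, `W`, `D`.

## Spectral preprocessing

Savitzky–Golay (SG) smoothing runs along the band axis (default window
11 bands, polynomial order 2 — common chemometric settings; both in
config), followed by Multiplicative Scatter Correction (MSC): each
spectrum is regressed on a reference spectrum, `x ≈ a + b·r`, and
corrected to `(x − a)/b`. The reference defaults to the mean of the
set being corrected; for supervised runs the training-set reference is
frozen and reused on validation/test spectra so no information leaks
across the split.

MSC is applied to the pixel spectra used for wavelength selection but
*not* to the cubes fed to the segmentation networks: per-pixel affine
renormalization would equalize the dark background with the shell and
remove the broadband intensity deficit that distinguishes cracks —
scatter correction helps the chemometric regression, not the spatial
model. A config switch (`msc.enabled`) exposes the choice.

## Wavelength selection

All three selectors score candidate subsets by RMSECV: the
root-mean-square error of PLS regression of the binary crack label on
the subset's bands under Monte-Carlo cross-validation (default 30
draws, 80/20 splits, seeded). The binary label is regressed directly
(PLS-DA style) with 5 latent variables, capped by the data rank.

* **CARS** — at iteration *i*, a Monte-Carlo draw of 80% of the samples
  fits PLS on the bands still in play; bands are ranked by
  `w_j = |β_j| / Σ|β_i|`; the top `r_i·B` survive enforced elimination
  with `r_i = a·e^(−k·i)` fixed so the first iteration keeps all `B`
  bands and the last keeps 2 (`k = ln(B/2)/(N−1)`, `a = e^k`); adaptive
  reweighted sampling (a weighted draw with replacement) thins the
  survivors; the subset with minimal RMSECV over all iterations is
  returned. The printed weight formula is read with an absolute value
  in the numerator, since sampling weights must be non-negative.
  Optional `min_bands`/`max_bands` restrict the argmin to a subset-size
  window; when the decay schedule skips the window entirely, the
  nearest visited sizes are used. Ties in the top-k rank break toward
  the lower band index for determinism.
* **SPA** — forward selection from the largest-norm band column; each
  step adds the band with the largest residual after orthogonal
  projection onto the span of the selected bands (implemented as a
  modified Gram–Schmidt deflation, with a pseudo-inverse fallback for a
  singular Gram matrix); every prefix of the chain is then scored by
  RMSECV and the best prefix returned.
* **Random Frog** — a stochastic subset walk: replace, add or remove
  one band with equal probability (never emptying the set), score the
  candidate by RMSECV (8 Monte-Carlo draws by default, a cheaper proxy
  than the final 30-draw score), accept with probability
  `min(1, exp(−(E′ − E)/T))`, and decay `T` geometrically (default
  0.95 per iteration from 0.05). Per-band selection probabilities are
  the occupancy frequencies over the walk; bands above the 0.2
  threshold are returned. The chain starts from the bands most
  correlated with the label rather than a uniform draw — with several
  hundred iterations, random initialization leaves the occupancy
  estimate dominated by burn-in.

## Segmentation networks

Input is a `1 × D × H × W` reflectance cube (D = selected bands).
The main model (`cracknet3d`) is a U-Net-style encoder–decoder:

* **Encoder** — three units of {3-D residual block → SimAM attention →
  2×2 spatial max-pool}. A residual block is two same-padded 3×3×3
  convolutions, each with batch normalization, plus an identity
  shortcut (a 1×1×1 projection with BN when channel counts change),
  with ReLU after the sum. Channel widths 8→16→32 at desk scale
  (16→32→64 by default config).
* **Pooling** is spatial-only (1×2×2). With ~15 input bands, three
  spectral halvings would annihilate the band axis; the per-unit pool
  factors are configurable.
* **SimAM** assigns each voxel a weight from a closed-form energy
  measuring how much it deviates from its channel's statistics; the
  module has no trainable parameters. Two energy variants are
  implemented: `direct` — the weight is the sigmoid of the squared
  deviation from the channel mean normalized by the channel's mean
  squared deviation plus a stabilizer λ (default 1e-4) — and
  `canonical` — the sigmoid of the inverse of the classic SimAM minimal
  energy `4(σ²+λ)/((x−μ)²+2σ²+2λ)`. Under both, deviant voxels get
  weights near 1. The backward pass treats the attention weights as
  constants with respect to the input (a straight-through
  approximation); the exact gradient through the channel statistics
  adds cost and complexity without observable benefit at these scales.
  The default is the `direct` variant.
* **Decoder** — mirrors the encoder with nearest-neighbour 2×
  upsampling, skip concatenation and the same block type. Nearest
  upsampling (rather than trilinear) keeps the adjoint trivial in the
  handwritten engine and is the standard U-Net variant.
* **Head** — a linear map spanning all channels and the full remaining
  spectral depth at each spatial location (equivalently a valid
  convolution over the whole band axis), followed by a sigmoid,
  produces the 2-D crack-probability map. Binarization is strict
  (`p > threshold`, default 0.5).

Baselines share the training interface: `cnn3d` is the identical
topology with plain double-conv blocks and no attention; `cnn2d` is the
same U-Net on the spectrally averaged single image; `cnn1d` is a
per-pixel convolutional classifier over the band axis (spectral-only —
provably invariant to spatial permutation of pixels).

The engine itself is a compact numpy implementation with explicit
backward passes; convolutions dispatch to JIT-compiled direct kernels
for wide feature maps and to im2col + BLAS for narrow ones. Inputs are
standardized with training-set mean/scale stored in the checkpoint,
spatial dims are reflection-padded to the pooling divisor and cropped
back, and large scenes can be processed in independent non-overlapping
tiles.

## Training

Focal-Dice compound loss: `L = w·(1 − softDice) + (1−w)·focal` with
`w = 0.5`, focal term `−α_t (1−p_t)^γ log p_t` (γ = 2, α = 0.8
favouring the rare crack class; the composition and constants are
design choices — the criterion is named in the protocol but its formula
is not fixed). Optimizer AdamW (lr 1e-4, decoupled weight decay 1e-4),
cosine-annealing warm restarts (period 10 epochs, doubling), early
stopping on validation loss with patience 15 and best-weights
restoration, batch size 32, 100 epochs — all per the study protocol and
all exposed in `TrainConfig`. Training samples random crack-biased
spatial crops (optionally several per image per epoch) with random
flip/transpose augmentation; inference is full-image. Runs are
bit-reproducible under a fixed seed.

Metrics use pixel counts with crack = positive: IoU, precision, recall,
F1 (harmonic mean; identically `2·IoU/(1+IoU)`). When ground truth and
prediction are both empty all metrics are 1 by convention; any other
zero denominator yields 0. Both pooled counts (headline) and per-image
metrics are reported. Run-to-run comparisons use a two-sided paired
t-test over per-run metric values.

## Synthetic scenes

The generator is phenomenological, not radiative-transfer-based: the
study's real corpus is not public, so curve shapes are emulated with
chosen constants and no fidelity to absolute reflectance is claimed.

* **Spectra** — smooth per-color baselines (white 0.78, brown 0.55,
  speckled 0.66 mean reflectance, jittered per scene) carry Gaussian
  absorption valleys at the 1450 and 1940 nm water-overtone bands and a
  broad shallow protein-related feature across 2100–2300 nm. Cracked
  shell multiplies the baseline by 0.78 and deepens the water valleys
  by 1.35× (exposed-membrane moisture), so a crack spectrum lies below
  the intact spectrum at every band under equal illumination.
* **Scenes** — a limb-darkened ellipse over a dark-velvet background
  (level 0.05); cracks drawn as random-walk polylines (linear, widened
  to 2–3 px at high severity), radial stars, or faint hairline traces
  blended at 50% contrast; crack extent scales with severity.
* **Severity** comes from the slider-impact model: release from height
  `h` gives `v = sqrt(2gh)` and `E = mgh` (m = 150 g, g = 9.8 m/s², so
  the 10 cm release reproduces 1.40 m/s exactly), mapped through the
  saturating curve `1 − exp(−E/0.15)`.
* **Confounders** — speckle spots (Poisson-distributed, broadband
  intensity factors 0.70–0.90) perturb intensity without touching
  relative valley depths, so only the spectral dimension separates them
  from cracks; natural shell texture (8% per-pixel multiplicative
  spread) defeats single-pixel intensity thresholds while leaving the
  spatial coherence of cracks intact. Without texture, single-pixel
  spectra were nearly perfectly separable and a spectral-only
  per-pixel classifier beat the spatial models — the opposite of real
  eggshell data, where pixel-level class spectra overlap heavily.
  Gaussian sensor noise (sd 0.02 reflectance) is added last.
* **Standard benchmark** — 100 eggs, 64×64 pixels, 273 bands
  (1000–2500 nm), mixed colors and crack types with ~10% crack-free
  controls, severities sampled from release heights 0.10–0.15 m. Crack
  pixels are well under 10% of shell pixels, reproducing the class
  imbalance that motivates the focal-Dice loss.

What passing tests on these scenes do show: the selectors recover
genuinely informative wavelengths; the network learns joint
spatial-spectral discrimination (rejecting confounders that fool the
spatial-only and spectral-only baselines); the whole pipeline runs end
to end deterministically. What they cannot show: performance on real
eggshells, whose texture statistics, specularities, and crack
morphologies are richer than the generator's.

## Desk-scale experiment settings

The four-model comparison (the ablation/baseline experiment) runs at
reduced size so it completes on one CPU core: 100 eggs of 64×64 pixels,
CARS restricted to a 12–16-band window (the synthetic task is more
separable than real shell spectra, so unconstrained CARS collapses to
2–3 bands; the study protocol feeds ~15 bands to the network), first
network stage 8 channels, 12 epochs of two crack-biased 24×24 crops
per training image (batch 8, flip/transpose augmentation), learning
rate 5e-3 with a single cosine cycle, focal α 0.7, Dice weight 0.75,
and the binarization threshold chosen on the validation split by
pooled F1. Three training seeds; data split fixed. The full-size
defaults from the study protocol remain the package defaults
(`TrainConfig`, `NetworkConfig`).

## Numerical notes and edge cases

* PLS latent variables are capped at `min(N−1, B)`; a constant response
  yields a zero coefficient vector rather than an error.
* `rmsecv` pools squared errors over all Monte-Carlo draws before the
  square root.
* MSC skips (with a warning) spectra whose fitted slope is below 1e-8;
  a constant reference is rejected.
* The Metropolis acceptance returns exactly 1 for any improvement,
  avoiding overflow for large negative energy differences.
* Degenerate masks (no crack pixels in either prediction or ground
  truth) hit the metric sentinel path, not a division error.
* Mask ingestion binarizes any strictly positive pixel to 1; masks are
  8-bit PNGs with {0, 255} on disk.
* ENVI I/O supports BSQ/BIL/BIP interleaves and data types 1 (uint8),
  2 (int16) and 4 (float32); the in-memory layout is always
  rows × cols × bands, band axis last.

## Known limitations

* The generator's confounder model is deliberately minimal (two
  mechanisms: broadband spots, iid texture); real stains have spectral
  signatures of their own.
* The SimAM energy is implemented in two variants because descriptions
  of the method in the applied literature vary between the direct
  deviation energy and the classic closed form; the `direct` variant is
  the default and both satisfy the same qualitative contract (deviant
  voxels upweighted, zero parameters).
* Hairline cracks at desk scale occupy only a handful of pixels, so
  per-image F1 on them is extremely sensitive to single-pixel
  localization; pooled metrics are the stable headline.
* Training-time comparisons between models are hardware-bound and are
  not part of the test surface.
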