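# Methods

This note documents the models implemented in `tagan`, the assumptions they
make, the defaults chosen where the method leaves room, and what the
synthetic-data experiments do and do not establish.

## 1. Simulated nanodomain samples

The simulator's latent state is a **datamap**: a 64×64 grid (20 nm/px) of
fluorophore counts. A mushroom-spine silhouette — an ellipse head with a
rectangular neck, randomly rotated and translated — is rejection-sampled
until its area lies in 0.12–0.48 µm² (300–1,200 px), it is connected, and it
fits entirely inside the grid. N ∈ 1–6 nanodomains (one 20×20 nm pixel of
elevated density each) are placed by rejection sampling on the edge band:
every centre is strictly closer than 140 nm to the nearest non-spine pixel
(Euclidean distance transform) and every pair is ≥40 nm apart. Rejection
sampling is capped at 10,000 retries per constraint and then raises a
`ConstraintError` naming the violated constraint — deterministic failure is
preferred to silent constraint relaxation. A single root seed is split into
per-stage child streams (shape, placement, rendering), so each stage is
independently reproducible and dataset generation is bit-stable.

The "mushroom spine" shape family, and the per-pixel densities (base 5
molecules/px on the spine, +50 on a nanodomain), photon yield (3
photons/molecule) and background (1 photon/px) are this package's own
declarations: the source imaging study used a full STED physics simulator
and did not print these values. The shape provider is a plain function and
can be swapped.

**Forward model.** An acquisition renders
`Poisson( photons_per_molecule · (counts ⊛ Gaussian PSF) + background )`.
The PSF FWHM is the modality's resolution: 250 nm confocal, 50 nm STED,
chosen so that nanodomain pairs below ~100 nm separation are resolvable in
the STED render and not in the confocal one at 20 nm pixels. This replaces
vectorial/depletion-beam physics, detector dead time and scan artifacts —
adequate for resolution/decision logic, not for instrument calibration.
Photobleaching is binomial thinning of the counts with survival
1 − bleach_fraction per acquisition (0.2 % confocal, 5 % STED by default);
inside the closed loop the expected-value factor is applied instead of
per-pixel thinning so that a time-evolving sample state stays well defined.

**Dataset layout** (defaults): 200 train-pool datamaps per N (1,200 total)
split 90/10 into 1,080 training / 120 validation; test set 1 has 15 maps
per N ∈ 2–6 (75); test set 2 has 80 two-domain maps whose centre
separations sample 40–450 nm approximately uniformly (lattice quantization
±15 nm, verified by a KS test).

## 2. Task targets

* **Cubic-root localization map**: per pixel, the cube root of the
  Euclidean distance (in *pixels*; the source text does not state the unit,
  pixels adopted) to the nearest nanodomain centre; exactly 0 at centres.
* **Centroid maps**: a unit impulse at each cluster's intensity-weighted
  centroid (rounded to the nearest pixel, ties toward the lower index;
  zero-intensity clusters fall back to the unweighted centroid), then
  Gaussian σ=2.
* **Wavelet segmentation**: à-trous B3-spline decomposition; a pixel is
  detected when its coefficient exceeds k·MAD of the scale plane at every
  requested scale (product rule over scales {3, 4}); k = 3 by default — the
  upstream tooling leaves this constant implicit, so it is configurable.
  Size filters (min area 5 px, min bounding-box width/height 3 px) are
  applied only on request; training-set construction keeps all clusters.
* **Dividing-cell (HR) annotations**: Sobel gradient magnitude of the
  min-max-normalized SIM image (normalization makes the 20 %-of-max
  threshold intensity-scale invariant), Gaussian σ=1, threshold at 20 % of
  the maximum, minus the analogous border mask of the low-resolution
  whole-cell annotation.
* **Dataset preparation**: sliding-window crops (stride = crop − overlap)
  kept only when the annotated fraction reaches the configured minimum
  (3 % bacterial, 1 % dendritic conventions); corner-crop × dihedral
  augmentation (4 × 8 = 32, or 8 when the image equals the crop size).

## 3. Networks and training

No GPU deep-learning framework is assumed: the three networks are pure
numpy functions differentiated by HIPS `autograd` (im2col + einsum
convolutions). The generator is an encoder–decoder with skip connections,
batch normalization and decoder dropout (rate 0.5) so MC sampling is
possible; the discriminator is a conditional patch classifier; the task
network is a U-Net (default) or ResNet. The published "U-Net-128" geometry
corresponds to `GeneratorSpec(depth=7, base_width=64)`; the desk default
(`depth=3, base_width=8, max_width=32`) trains in minutes on one CPU and is
the scale used by the test suite. Inputs whose size is not a multiple of
the downsampling factor are reflect-padded and un-padded on output.
Batch statistics are always used by normalization (with one sample this is
instance normalization); no running averages are kept.

**Losses.** GEN = MSE(task(fake), annotation); TL = MSE(task(real),
annotation); adversarial terms use sigmoid binary cross-entropy by default
(least-squares by flag — the source names neither). Per-class weights scale
GEN/TL channel-wise (the live model's fibre class ×2.5). λ_GEN = 100,
λ_GAN = 1, λ_CYC = 10 follow the pix2pix/CycleGAN conventions because the
experiment-specific hyperparameter table is not available. The ablation
flag replaces GEN with pixel-wise MSE(fake, real), which is exactly the
conditional-GAN baseline. Each step performs one Adam update (β₁ = 0.5,
β₂ = 0.999, lr 2·10⁻⁴ constant) of the discriminator, then the generator,
then the task network; frozen-task mode (pretrained live task network)
skips the third. No early stopping is applied; validation is left to the
caller. Gradients are clipped at a global-norm cap (100).

The cycle variant computes CYC on both reconstruction cycles, adversarial
terms per domain, and GEN as the frozen fixed-domain task network's
discrepancy between the real fixed image and its end-of-cycle
reconstruction; the live cycle carries no task term. The standard CycleGAN
identity loss is not mentioned by the method and is excluded by default.

## 4. The acquisition decision engine

Geometry defaults: 500×500 px FOV (10×10 µm), 5×5 blocks of 100×100 px
(2×2 µm), central 3×3 blocks = ROI (6×6 µm). Per frame: confocal FOV →
K = 10 dropout syntheses → Horn–Schunck flow between consecutive samples,
magnitudes averaged and block-pooled → the most variable block outside the
ROI (row-major tie-break) is acquired with STED and pasted into the
3-channel conditioning input (confocal, STED subregion, binary position
matrix; all-zero channels 2–3 when no subregion exists yet) → K conditioned
syntheses → ROI segmentation → trigger.

* **DC policy**: mean Dice between the K ensemble segmentations and the
  segmentation of the last real STED; trigger strictly below θ = 0.5.
  A both-empty mask pair scores Dice 1 (no evidence of change).
* **VS policy**: over the K binarized segmentations, a foreground pixel
  (positive count) is low-variability when ≥80 % of samples agree (counts
  {1,2} ∪ {9,10} at K = 10) and high-variability otherwise (3–8); the score
  is high/(high+low) and triggers strictly above 0.5 — the tipping point
  where high-variability pixels outnumber low-variability ones. Note the
  source's Methods text once defines the score as the *low*-variability
  proportion; that reading contradicts the trigger rule and the
  tipping-point rationale, so the high-variability definition is used.
* Equality never triggers, for either policy.

Horn–Schunck defaults α = 1.0, 100 iterations (the source prints none); the
closed loop uses 30 iterations, and identical sample pairs short-circuit to
zero flow. Initial and final reference STED frames are always acquired.
The photon-dose ledger integrates dose-rate × dwell-time × pixels over each
acquisition's overlap with the ROI (rates 1.168·10¹³ photons/s confocal,
1.543·10¹⁸ photons/s STED); the reduction is reported against an
always-STED baseline of the same length, both including and excluding the
reference frames, since the printed percentages do not state which
convention they use.

**Closed-loop experiments** run against a simulated microscope
(`acquire_confocal`/`acquire_sted` driver) with a scripted structural
change: two disjoint spine datamaps swap at a programmed frame. The
generator stub is ground-truth-aware with explicit epistemic uncertainty —
each MC sample renders either the current truth or the structure remembered
from the last real STED (probability 0.5) — so the ensemble is unanimous
until an unobserved change occurs, then disagrees exactly where the
structure changed. A green closed-loop test therefore establishes that the
*decision logic* detects change and saves dose given a well-calibrated
generator; it says nothing about how well a trained generator approximates
one, and nothing about real-microscope latencies or drift.

## 5. Evaluation

Dice/IoU with both-empty = 1; SSIM via the standard 11×11 Gaussian window;
PSNR against a declared data range (+∞ sentinel for identical images);
localization F1 with one-to-one greedy matching under a 3-px tolerance
(ties by distance, then truth index — optimal-assignment agreement is
tested for well-separated truths); dividing-cell rule ≥20 px / 0 px / 1–19
px; tie-aware rank AUROC. The nanodomain counter — difference-of-Gaussians
enhancement, thresholded local maxima, and a saddle test that merges two
maxima when the ridge between them never dips below 85 % of the dimmer peak
— is this package's automatic stand-in for the expert counting used in the
source study; it is tuned for noise-free renders of the simulated geometry
and under-counts pairs near the resolution limit on noisy images.

## 6. Numerical choices and limitations

* Coordinates are 0-based row-major; all rectangles are half-open
  (row0, col0, height, width).
* Rasterized photon counts are stored as 16-bit TIFF; masks 8-bit; float
  maps 32-bit; the pixel size rides in the image description tag.
* Training at the desk scale (64×64, widths ≤32) demonstrates loss
  mechanics and convergence direction, not publication-grade image
  quality; full-scale geometry is configuration, not new code.
* The forward model omits depletion-beam physics; absolute photon numbers
  are nominal, so only relative dose comparisons are meaningful.
* Horn–Schunck is the slowest loop stage (as in the source study); the
  block-ranking interface accepts any disparity measure if flow is too
  costly.
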