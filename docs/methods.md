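# Methods

This note records the models, parameter choices and numerical decisions
behind `carostab`, and what the synthetic validation does and does not show.

## Disturbance model and estimation

A frame `k` is modelled as frame 1's scene carried by a global rigid
transform `T_k = (d_long, d_rad, θ)` (the common-mode disturbance: probe
jitter plus breathing) composed with local wall motion confined to the
vessel band. Tissue bands far above and below the wall see only `T_k`, so
`T_k` is estimated by rigidly registering each band of frame `k` against the
same band of frame 1 and averaging the two estimates. Averaging also cancels
the translation each band picks up from rotation about the image centre
(the bands sit symmetrically about it), so the averaged transform is the
image-centre transform.

Registration maximizes the normalized cross-correlation in two stages:

* **Stage 1** scans rotations on a 0.5° grid (the grid always contains 0°).
  At each angle the de-rotated float band is scored against the reference
  band at every integer shift inside the search bounds with an
  overlap-normalized NCC map: the cross term comes from one FFT
  correlation, the per-window statistics from integral images, so the value
  at each lag is exactly the NCC over the actual overlap. Rotated bands are
  cropped by the rotation's corner intrusion so no invalid pixels enter.
* **Stage 2** refines `(d_col, d_row, θ)` with a bounded Nelder–Mead simplex
  on the overlap-masked NCC, with bilinear interpolation, down to the 0.01
  px / 0.01° scale. The refined optimum is kept only if it does not score
  below the stage-1 point.

The similarity metric, optimizer, rotation pivot and band heights are
design choices of this package (the method family leaves them open): NCC is
deterministic, affine-invariant in intensity, and consistent with the
block-matching criterion used for tracking; rotation pivots at the
(sub)image centre.

## Feature surfaces

The registration surface is a method variant: raw intensity, local phase,
local orientation, or the confidence-combined image `C = sin²φ·θ`, each
optionally after (altered) SRAD.

* SRAD: explicit Jacobi scheme, `I ← I + (Δt/4)·div(c∇I)` with one-sided
  differences, right-neighbour diffusivities on the forward fluxes and
  reflective borders; `Δt = 0.1`, 100 iterations; the speckle scale `q0` is
  re-estimated each iteration from a 20×20 homogeneous region (population
  variance) that is propagated across frames (known offsets when ground
  truth exists, otherwise centroid/principal-axis moments of the thresholded
  frame). The diffusivity is clamped to `[0, 1]` because the closed form
  exceeds 1 for `q < q0`; the clamp keeps the explicit scheme stable at
  `Δt = 0.1`. The altered variant doubles the longitudinal one-sided
  differences (so their squares enter the edge detector with weight 4) and
  uses the 2,2,1,1 Laplacian with −6 centre; the longitudinal axis maps to
  image columns (vessel axis) and is configurable.
* Monogenic features: the DoG bandpass uses unit-mass discrete Gaussians
  (difference has zero DC gain, hence brightness invariance), `σ₂ = √2·σ₁`.
  The module default is `σ₁ = 10 px`, appropriate for clinical-scale
  images; the pipeline shrinks it for desk-scale subimage bands
  (`σ₁ = clip(band_rows/12, 2.5, 4)` px) because a 6σ₂ kernel must fit well
  inside the band and because disturbance-recovery error on synthetic bands
  grows steeply for σ₁ ≳ 6 (measured on a registration fixture with known
  transforms). Degenerate pixels with amplitude below `1e-9·max A` get
  `φ = π/2`, `θ = 0`, confidence 0.
* Orientation is axial (θ ≡ θ+π), so pointwise estimates are regularized by
  Gaussian smoothing (σ = 3 px) of the confidence-weighted double-angle
  field `(w·cos2θ, w·sin2θ)` before folding back — the standard estimator
  for axial data; plain smoothing of θ would average across the 0/π wrap.

## Wall tracking

NCC block matching of a fixed frame-1 ROI straddling the deep blood/wall
interface, exhaustive over integer displacements, ties broken by smallest
displacement magnitude then row-major order; optional 1D parabolic subpixel
refinement (off by default). Tracking runs on the aligned intensity frames
by default; a flag tracks on combined-feature images instead. The reference
block is never updated, so errors do not accumulate.

## Synthetic data: what it emulates

The simulator is a 2D convolutional speckle model, not an acoustic solver.
A persistent population of uniformly distributed scatterers (≈300 per mm²
of slab) carries echo amplitudes sampled from a tissue template times
vessel-layer multipliers; frames are rendered by bilinear splatting, a
complex PSF (Gaussian envelope σ_ax = 0.15 mm, σ_lat = 0.30 mm, axial
carrier λ = 0.308 mm ≙ 5 MHz), envelope detection and 50 dB log compression
to 8 bits at 0.05 mm/px. Over a homogeneous region the envelope is Rayleigh
(point SNR ≈ 1.91), i.e. fully developed speckle.

Scene content, chosen to reflect what the method needs from real neck
tissue:

* far tissue: smooth echogenicity blobs plus fascia-like sheets that are
  *nearly uniform in brightness along the vessel* but geometrically tilted
  and undulating, plus a few compact bright reflectors. Longitudinal
  registration information therefore lives mostly in geometry, not in
  brightness gradients — longitudinal homogeneity is the stated difficulty
  of this direction;
* vessel: a two-interface wall (intima/media/adventitia bands: 0.10/0.25/
  0.40 mm at multipliers 1.5/0.5/1.7, near-anechoic lumen) whose axis
  undulates gently (0.12 mm amplitude) and whose layer echogenicity is
  modulated along the vessel (50 % relative, 0.8 mm correlation length):
  real walls are longitudinally heterogeneous, and without such
  macro-texture no block matcher can recover longitudinal motion;
* motion: radial distension is a sin⁴ pulse train (four cardiac cycles per
  3.2 s respiratory cycle; 0.35 mm amplitude), longitudinal motion a
  zero-mean excursion per cycle (0.25 mm); wall-band scatterers move with
  the wall, mirrored across the lumen axis, tapering linearly to zero over
  0.5 mm beyond the adventitia (a continuum shear zone, not a step);
* disturbance: smooth one-cycle respiratory drift (defaults 0.8 mm
  longitudinal, 0.35 mm radial, 1.2°) plus Poisson-count Gaussian glitches
  (rate 2.5 s⁻¹, widths 15–40 ms) emulating probe jitter; applied rigidly
  to *all* scatterers about the image centre;
* speckle decorrelation: a fresh per-frame elevational jitter
  (σ = 0.25 mm against a 0.5 mm elevational beam) decorrelates the fine
  speckle between frames while preserving the macro structure. This
  emulates the strong frame-to-frame speckle turnover of phantom
  populations regenerated independently at every time step; with near-zero
  jitter the speckle would be ~99.6 % correlated between frames and
  intensity registration would be unrealistically easy.

What passing tests therefore show: the pipeline recovers known rigid
disturbances to sub-pixel accuracy and restores wall-motion tracking in the
presence of realistic speckle turnover, on scenes with realistic macro
structure. What they do not show: performance on clinical images (true
beamforming, depth-dependent PSF, shadowing, out-of-plane motion), or the
relative ranking of the feature surfaces on clinical data, which depends on
scene texture and on the registration optimizer.

## Study profiles and problem sizes

* `default`: 200 frames, 3.2 s, 280×256 px (14×12.8 mm), registration bands
  30 % of the height (84 rows), ROI 24×64 px at the deep interface. Used
  for the headline agreement number.
* `fast`: 64 frames, 224×192 px — the variant-comparison study.
* `tiny`: 8 frames, 100×80 px — smoke-test scale only; its bands are too
  small for meaningful rotation estimation.

Analysis geometry (band fractions, search bounds, ROI and search-region
size) is derived from each profile's wall geometry and disturbance
amplitudes (`pipeline.analysis_config`), so bands always clear the moving
tissue and bounds cover drift plus two coincident glitches.

## Known limitations

* Rotation sensitivity on desk-scale bands is limited by the short lever
  arm; orientation-only registration (SWOM) has rotation noise of the same
  order as the disturbance itself at the `fast` scale.
* With an exhaustive overlap-normalized NCC search, raw-intensity
  registration is a very strong baseline on synthetic scenes: it uses all
  image information and NCC averages decorrelated speckle away. Smoothing
  (SRAD) and feature surfaces mainly help optimizers that need smooth
  similarity landscapes; their advantage over intensity observed on
  clinical data should not be expected to reproduce verbatim here.
* The simulator's elevational-jitter decorrelation is stationary; it does
  not model motion-dependent decorrelation (faster decorrelation during
  rapid wall motion) or out-of-plane vessel curvature.
* Tracking is integer-resolution by default (one pixel = 0.05 mm), so
  motion-error comparisons between well-performing variants sit near the
  quantization floor. In particular, aligning with the exact ground-truth
  disturbance is not strictly optimal for subsequent tracking: the exact
  fractional warp maximizes interpolation blur, and an estimate differing
  by sub-pixel amounts can track marginally better.
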