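# Methods

This note records the models, the parameter choices that matter, the
numerical decisions, and the known limitations of the package.  Everything
quantitative stated here is computed by the test suite or the examples; no
number is asserted that the code does not reproduce.

## Motion models and their simulation

Chromatin-domain motion is modeled per focus as a stationary-increment
process in 3-D physical coordinates (µm):

* **Brownian** (α = 1): i.i.d. Gaussian increments per axis with variance
  2·D·Δt, giving the 3-D MSD 6·D·t.
* **Sub-/super-diffusive** (α ≠ 1): fractional Brownian motion per axis with
  Hurst exponent H = α/2, scaled so the ensemble 3-D MSD is exactly
  6·Γ·t^α with Γ = D at t = 1 s.  fBm is chosen because it is the standard
  stationary-increment Gaussian process with precisely the power-law MSD
  that the anomalous model fits; the generator uses a Cholesky factorization
  of the exact fractional-Gaussian-noise covariance, which is exact for any
  H and cheap at the trajectory lengths involved (≤ a few hundred steps).

Observed positions add isotropic per-axis Gaussian localization error σ;
this is the textbook origin of the MSD bias term b ≈ 6σ².  The nucleus
boundary reflects trajectories radially in the ellipsoid's normalized
coordinates — reflection preserves uniform occupancy, where absorbing or
sticky boundaries would thin the rim.  `simulate_trajectories` also accepts
`nucleus=None` for unbounded motion, used when the quantity under test has a
closed form only in free space.

### Defaults

The generator's defaults mirror the target acquisition: voxels
(0.17, 0.048, 0.048) µm, 5 z-slices, Δt = 5 s, two channels, 100–200
frames; D defaults to 14.99×10⁻⁵ µm²/s (the most mobile condition studied)
and σ to 30 nm.  Focus intrinsic size is a free parameter
(`focus_sigma`, default 0.10 µm, scalar or range) because no physical size
distribution is established for labeled chromatin domains; the rendered
spot sigma combines it with the PSF sigma in quadrature.

### Rendering

Channel 0 transports the nucleus DNA texture through the global motion;
channel 1 sums anisotropic Gaussian spots (σ = FWHM/2.3548 per axis) at the
true positions, with amplitude decaying as exp(−bleach_rate·t), plus a
constant background.  Poisson noise is applied first, then Gaussian read
noise.  Global motion is a per-frame small in-plane rotation and a smooth
translation (linear drift + low-frequency sinusoid), optionally plus a
low-frequency sinusoidal displacement field — deliberately restricted to
the transform class the registration module estimates, so recovery is
well-posed.  The true camera→cell transform series is recorded with the
ground truth.

### What the generator does not emulate

No camera-specific noise calibration, no spectral cross-talk, no
out-of-focus haze or depth-dependent PSF, no replication biology, no
blinking.  Passing recovery tests therefore demonstrates correctness of the
computation chain under the stated forward model, not robustness to every
artifact of real acquisitions.

## Registration

`Transform3D` stores the forward point map moving→fixed,
f(x) = A·x + t + u(A·x + t), with u a dense residual field on the fixed
grid.  Points are mapped through f exactly; volumes are resampled through
f⁻¹ (affine inverted in closed form, the displacement by fixed-point
iteration, which converges for the small smooth deformations targeted).
Estimation is per frame against frame 0 on the DNA channel:

1. subpixel translation by phase correlation (default precision 1/20
   voxel), seeded by the previous frame's translation so slow drift cannot
   alias;
2. optionally, a Powell search over in-plane rotation + translation
   maximizing normalized cross-correlation (rotation about the optical axis
   only: with ~5 z-slices, out-of-plane rotations are unidentifiable);
3. optionally, a dense displacement from iterative Lucas–Kanade optical
   flow, Gaussian-regularized with σ_reg = 4 voxels by default — smooth
   cell deformation is the target; fine chromatin texture must not be
   matched point to point.

Each stage is kept only if it improves NCC; otherwise the best transform so
far (ultimately the identity) is returned with a warning.  Transforms are
estimated on the DNA channel only and applied to foci **detections** (point
mapping), never by resampling the foci channel — avoiding a second
interpolation of the signal being quantified.

## Detection

The spot-enhancing filter is a negated Laplacian-of-Gaussian with per-axis
scale σ/voxel_size (anisotropic voxels respected), multiplied by the
geometric-mean squared voxel scale (scale normalization).  The discrete LoG
kernel's small DC gain is removed so constant offsets map exactly to zero;
together with the mean + k·std threshold this makes detection counts
invariant under affine intensity changes.  Threshold statistics are pooled
over the whole sequence (not per frame) so counts are comparable across
time.  The default k = 4 was set by the pure-noise false-positive property
(zero detections in ≥ 95% of pure-noise volumes at k = 8; k = 4 keeps full
recall at SNR ≥ 5 on well-separated foci).

Subvoxel refinement interpolates a parabola through the 3 response samples
per axis.  A weighted 3³-centroid was evaluated first and rejected: its
truncation bias left ~0.19 voxel lateral RMSE even without noise, while the
parabola achieves ~0.01 voxel noiseless and ~0.03 at SNR ≈ 10.  Focus size
is the geometric mean of the **lateral** moment sigmas after background
subtraction (2-D images use both axes): with only 5 z-slices the axial
moment is truncation-dominated and would corrupt the small/large split.

### Axial localization with 5-slice stacks

With 5 z-slices spanning 0.85 µm, *any* single-peak axial estimator is
biased: measured on rendered data, quadratic refinement has a z gain of
~1.4 (overshoot) and a full-column centroid ~0.6 (compression).  A gain
g ≠ 1 on one axis scales the fitted 3-D D by (2 + g²)/3, i.e. tens of
percent.  At ≥ 9 slices the gain is ~1.0 and the full imaging chain
recovers D within ~10%, so the quantitative image-chain tests use 9-slice
stacks; trajectory-level analyses are unaffected.  For real 5-slice data, z
positions should be treated as low-precision and condition comparisons read
as relative, not absolute.

## Tracking

A constant-position (random-walk) Kalman filter per track — matching
constrained chromatin motion, which has no persistent velocity — predicts
positions; a cost matrix of squared Euclidean distances, gated at
`gate_radius` (default 0.5 µm), is solved globally per frame with the
Hungarian algorithm.  Unmatched tracks survive `max_gap` frames (default 1)
and gaps are never interpolated; the MSD uses actual frame differences.
This is the Kalman/global-assignment core of the probabilistic trackers
used for such data; a particle-filter measurement-fusion layer is a
possible extension but is not needed at the spot densities involved —
tracking-induced bias on fitted D is under 10% (tested), and track/identity
overlap with ground truth exceeds 0.9 (Jaccard) at 200 foci per field.

Trajectory duration is counted in spanned time steps (last frame − first
frame), inclusive at the threshold.  Two presets exist because both appear
in practice: 10 steps (≈ 50 s) for MSD model fits, 100 steps (500 s) for
the radius-of-gyration analysis.  The small/large split assigns each
trajectory the median of its detections' sizes and cuts at the median of
those medians (even split; with an odd count the middle trajectory goes to
"small"; ties break by id).

## MSD and model fits

Per-trajectory MSD is time-averaged over all pairs at each lag with gaps
excluded pairwise; the ensemble curve is the unweighted mean over
trajectories covering the lag (each trajectory counts once, regardless of
length).  The diffusion model 6·D·t + b is fitted by non-negative least
squares to lags ≤ 50 s inclusive (10 lags at Δt = 5 s); a negative
unconstrained solution is clipped and flagged.  The anomalous model
6·Γ·t^α is fitted to the whole curve by nonlinear least squares in linear
space, initialized from the log-log regression; pure log-space fitting was
rejected because it overweights long lags, where the ensemble curve is
noisiest.  α is bounded to (0, 2]; α < 0.9 (strict) labels sub-diffusion.
The radius of gyration uses only points within 500 s (default) of each
trajectory's start, so tracks of different lengths are compared over the
same observation window.  Uncertainty on fitted parameters, when needed, is
obtained by bootstrap over trajectories (the per-track curves can be
retained for this); it is labeled as such since it captures sampling
variability across tracks, not acquisition-level replication.

## Compaction classification

*2-class (live-cell):* a two-component GMM on inside-mask DNA intensities
(k-means init, fixed seed), hard assignment, classes ordered by mean
(1 = euchromatin-like).  If the components collapse (mean separation below
the larger component sd) the split falls back to Otsu and is flagged.
Classification is per frame by default; trajectories vote with each point's
own frame, a plurality wins, exact ties and all-outside tracks are
"unassigned".

*7-class (fixed-cell):* Gaussian class parameters are fitted by
quantile-initialized hard EM, then frozen; labels are refined by ICM with a
Potts prior (default β = 0.5) on the 6-neighborhood.  The update is
checkerboard (two-phase): the 6-neighborhood graph is bipartite, so
alternating parities with neighbors held fixed decreases the energy
monotonically, where a fully synchronous update can oscillate forever.
Freezing the class parameters during ICM makes β = 0 *exactly* the
per-voxel maximum-likelihood assignment, which is the oracle the tests
check against.  Class 1 is interchromatin (lowest intensity), classes 2–3
low-compaction perichromatin, 4–7 the compact inactive compartment; means
strictly increase with index by relabeling.

*Nucleus segmentation* uses the lowest threshold of a 3-class Otsu on the
lightly smoothed volume: the DNA stain is itself bimodal inside the
nucleus, so 2-class Otsu tends to cut between the chromatin modes rather
than at the nuclear border.  Largest connected component, holes filled;
deterministic and intensity-scale invariant.

*Signal fractions* segment the mapped channel by Otsu inside the mask and
weight by intensity, so bright spots dominate; fractions sum to 1.  A
constant positive signal is treated as fully segmented (fractions equal the
class volume shares); an empty or all-nonpositive signal returns zeros with
a flag.

*Morphometry:* volume is voxel count × voxel volume; the shape factor is
3-D sphericity π^{1/3}(6V)^{2/3}/A with A from a marching-cubes mesh.  The
binary mask is lightly smoothed before meshing because the raw voxel
staircase overestimates surface area by ~8%, biasing sphericity low (a
digital ball then measures ≥ 0.97 instead of ~0.92).

## Resolution gain

Profiles are taken along the horizontal axis only, by design — the
measurement emulates a line-profile protocol and is axis-specific;
averaging over ≥ 50 matched foci suppresses noise and sub-pixel placement
jitter.  Profile length is fixed at 1 µm (round(1 µm/pixel)+1 samples,
linear interpolation at the detection's sub-pixel row); detections closer
than half the profile length to the lateral border are skipped and counted.
Half-maximum crossings are linearly interpolated between samples, making
the FWHM sub-pixel and invariant to affine intensity transforms.  The
matching gate defaults to 0.3 µm (one confocal FWHM).  The recovered FWHM
slightly exceeds the PSF truth (≈ +1%) because detection jitter convolves
into the averaged profile; this is well inside the stochastic tolerance.

## Problem sizes

Test and acceptance runs use: 500 trajectories × 100 steps per diffusion
condition (statistical error ≲ 2% on D̂); 2000 × 100 for exponent recovery
(±0.02 typical); 64 emitters per resolution image; movies of 5–9 z-slices ×
96–256 px laterally × 30–100 frames with 12–200 foci.  These sizes keep
every statistical check an order of magnitude inside its tolerance while
running the whole suite in a few minutes on one CPU.

## Known limitations

* 5-slice axial geometry biases absolute 3-D D estimates (see above).
* The tracker has no merge/split handling and no intensity re-identification;
  extremely dense fields or heavy blinking will fragment tracks.
* The 7-class Potts/ICM classifier is a documented surrogate for HMRF-EM
  estimation: β is fixed, not estimated from the data.
* Replication-timing (early/late) labels are accepted as per-cell metadata,
  never inferred from images.
* Registration assumes deformation far smoother than chromatin texture; a
  deformation at texture scale would be partially absorbed and subtract
  real motion.
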