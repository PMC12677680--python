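# chromotion

Quantitative chromatin-mobility analysis for 3D live-cell fluorescence
microscopy, with a matched synthetic-movie generator that makes every stage
verifiable by parameter recovery.

## The problem

Chromatin domains in living nuclei undergo constrained diffusive motion, and
how mobile they are changes with cell state (e.g. stem cells vs
differentiated neurons).  Measuring that motion from a two-channel 3-D
time-lapse (DNA stain + labeled chromatin foci) requires a chain of image
computations, each of which can silently bias the result:

1. **Registration** (`chromotion.registration`) — every frame of the DNA
   channel is registered onto frame 1 (affine stage + regularized dense
   displacement) and the transform is transferred to the foci channel, so
   cell movement and deformation do not masquerade as chromatin motion.
2. **Detection** (`chromotion.detection`) — the spot-enhancing filter: a
   scale-normalized Laplacian-of-Gaussian, an automatic threshold at
   `mean + k·std` of the responses pooled over the sequence, local maxima
   with subvoxel refinement, and moment-based focus-size estimates.
3. **Tracking** (`chromotion.tracking`) — a constant-position Kalman filter
   predicts each track, and a gated global (Hungarian) assignment links
   detections frame to frame; trajectories shorter than a duration preset
   (10 steps ≈ 50 s for model fits, 100 steps = 500 s for the radius of
   gyration) are excluded.
4. **Mobility statistics** (`chromotion.mobility`) — per-trajectory
   time-averaged mean square displacement, ensemble-averaged with equal
   weight per trajectory, then two model fits:

   * short-range diffusion  MSD(t) = 6·D·t + b  on the first 50 s of the
     curve (b absorbs localization error, ≈ 6σ² for isotropic error σ);
   * anomalous diffusion  MSD(t) = 6·Γ·t^α  on the whole curve, with
     α < 0.9 classifying sub-diffusive (constrained) motion;

   plus the radius of gyration R_g = √⟨|r_i − r̄|²⟩ over a fixed 500 s
   observation window.
5. **Chromatin-state stratification** (`chromotion.nucleus`) — nucleus
   segmentation, a 2-class GMM compaction split (euchromatin /
   heterochromatin) for live movies, a 7-class Gaussian+Potts (ICM) map for
   fixed-cell stacks, trajectory-to-class majority voting,
   intensity-weighted signal fractions per class, and volume/sphericity
   morphometry.
6. **Resolution gain** (`chromotion.resolution`) — foci detected in matched
   images of two modalities (e.g. STED vs confocal) are paired by Hungarian
   matching; the FWHM of the normalized averaged 1 µm intensity profile per
   modality quantifies effective resolution.

The synthetic generator (`chromotion.simulate`) emulates the acquisition the
pipeline targets — 48 nm lateral / 170 nm axial voxels, Δt = 5 s, 5 z-slices,
two channels — with Brownian or fractional-Brownian foci motion of known
(D, α), a perturbed-ellipsoid nucleus with a two-class DNA texture,
Gaussian-PSF rendering, Poisson + read noise, photobleaching, and recorded
global affine + non-rigid cell motion.

## Worked example

`examples/diffusion_recovery.py` simulates 500 trajectories per condition at
the condition's diffusion coefficient (Δt = 5 s, 100 steps, 30 nm
localization noise) and fits the short-range model:

```
condition        D_true        D_fit  rel.err      b_fit
iPSC          1.499e-04    1.521e-04   +1.5%    0.00527
NSC           8.380e-05    8.231e-05   -1.8%    0.00546
neuron        1.047e-04    1.069e-04   +2.1%    0.00526
```

The fitted D lands within ~2% of the simulated value and the bias term b
recovers the localization-noise floor 6·(0.03)² = 0.0054 µm².  The other
examples cover the anomalous-exponent fit (`anomalous_diffusion.py`, α
recovered within ±0.01 at n = 2000), the compaction classifiers
(`compaction_mapping.py`), the FWHM resolution chain (`resolution_gain.py`,
0.1417 µm vs 0.14 truth and 0.3007 µm vs 0.30 truth, a 2.1× gain), and the
full movie pipeline with two conditions (`full_pipeline.py`).

## Conventions

All positions, sizes and displacement fields are physical micrometres in
z-y-x axis order; voxel indices are 0-based and refer to voxel centres;
time is in seconds.  Movies are TCZYX OME-TIFF (`chromotion.movie`), tables
are CSV, fits and transforms JSON — every output carries the configuration
hash and seed, and identical config + seed reproduces identical bytes.
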