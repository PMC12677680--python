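"""Synthetic ground-truth generator for chromatin-mobility movies.

Every downstream stage of the pipeline (registration, detection, tracking,
MSD fitting, compaction classification, resolution analysis) is validated by
parameter recovery on data from this module, which emulates the statistical
structure of 3D live-cell two-channel acquisitions: a nucleus-shaped
DNA-intensity texture with low/high-compaction subregions, point-like
chromatin foci moving by Brownian or fractional Brownian motion with known
D and alpha, anisotropic Gaussian-PSF blur, Poisson + Gaussian read noise,
exponential photobleaching, and slow global affine + smooth non-rigid cell
motion recorded as the true transform series.

Motion models
-------------
For ``alpha = 1`` each axis takes i.i.d. Gaussian increments of variance
``2 D dt`` (3-D MSD ``6 D t``).  For ``alpha != 1`` each axis is fractional
Brownian motion with Hurst exponent ``H = alpha / 2``, scaled so the
ensemble 3-D MSD equals ``6 Gamma t^alpha`` with ``Gamma = D`` at t = 1 s —
the standard stationary-increment process with exactly the power-law MSD the
anomalous-diffusion model fits.  Reported (observed) positions add isotropic
Gaussian localization error of ``loc_noise_sigma`` per axis, the textbook
origin of the MSD bias term ``b ~ 6 sigma^2``.

Units: all positions and sizes in µm, time in seconds; arrays are z-y-x
ordered, voxel indices 0-based, coordinates refer to voxel centres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import ndimage

from .movie import Movie5D
from .nucleus import NucleusMask
from .registration import Transform3D, TransformSeries

__all__ = [
    "SimulationConfig",
    "TextureParams",
    "GroundTruth",
    "NucleusSample",
    "simulate_trajectories",
    "simulate_nucleus",
    "render_movie",
    "render_psf_pair",
    "fbm_increments",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 1/2.3548


@dataclass
class SimulationConfig:
    """All knobs of the forward model.

    Defaults reproduce the study's acquisition geometry: 48 nm lateral /
    170 nm axial voxels, 5 z-slices, Δt = 5 s, two channels; the default D
    is the pluripotent-state diffusion coefficient (14.99e-5 µm²/s) and the
    localization error 30 nm per axis.
    """

    n_foci: int = 50
    n_frames: int = 100
    dt: float = 5.0
    voxel_size: tuple[float, float, float] = (0.17, 0.048, 0.048)
    image_shape: tuple[int, int, int] = (5, 64, 64)
    D: float = 14.99e-5
    alpha: float = 1.0
    loc_noise_sigma: float = 0.03
    psf_fwhm: tuple[float, float, float] = (0.40, 0.16, 0.16)
    focus_sigma: float | tuple[float, float] = 0.10
    photon_scale: float = 200.0
    background: float = 10.0
    read_noise: float = 2.0
    noise: bool = True
    bleach_rate: float = 0.0
    motion_amplitude: float = 0.0
    motion_rotation_deg: float = 0.0
    nonrigid_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.D < 0:
            raise ValueError("D must be non-negative")
        if not (0.0 < self.alpha <= 2.0):
            raise ValueError(f"alpha must lie in (0, 2], got {self.alpha}")
        if self.n_foci < 0 or self.n_frames < 2:
            raise ValueError("need n_foci >= 0 and n_frames >= 2")
        if any(v <= 0 for v in self.voxel_size) or any(s <= 0 for s in self.image_shape):
            raise ValueError("voxel sizes and image shape must be positive")
        if self.loc_noise_sigma < 0 or self.photon_scale <= 0 or self.background < 0:
            raise ValueError("invalid intensity/noise parameters")
        if self.bleach_rate < 0:
            raise ValueError("bleach_rate must be non-negative")

    @property
    def extent_um(self) -> np.ndarray:
        return np.asarray(self.image_shape, float) * np.asarray(self.voxel_size, float)


@dataclass
class TextureParams:
    """Two-component chromatin texture: low mean = euchromatin-like blobs,
    high mean = heterochromatin-like blobs, arranged as smooth spatial
    patches of characteristic size ``blob_sigma_um``."""

    means: tuple[float, float] = (100.0, 300.0)
    sds: tuple[float, float] = (20.0, 20.0)
    weights: tuple[float, float] = (0.5, 0.5)
    blob_sigma_um: float = 0.4
    semi_axes_um: tuple[float, float, float] | None = None
    boundary_perturb: float = 0.0

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("texture weights must sum to 1")


class NucleusSample(NamedTuple):
    """A simulated nucleus: binary mask, DNA-intensity volume, true labels."""

    mask: NucleusMask
    dna: np.ndarray
    labels: np.ndarray  # 0 outside, 1 = euchromatin-like, 2 = heterochromatin-like


@dataclass
class GroundTruth:
    """True quantities behind a rendered movie, for parameter-recovery tests."""

    true_positions: np.ndarray  # (n_foci, n_frames, 3) µm, cell frame
    observed_positions: np.ndarray  # true + localization noise
    focus_sizes: np.ndarray  # (n_foci,) intrinsic Gaussian sigma, µm
    config: SimulationConfig
    transforms: TransformSeries | None = None  # camera frame -> cell frame
    compaction_labels: np.ndarray | None = None

    @property
    def n_foci(self) -> int:
        return self.true_positions.shape[0]

    @property
    def n_frames(self) -> int:
        return self.true_positions.shape[1]


def fbm_increments(
    rng: np.random.Generator, n_steps: int, n_series: int, hurst: float,
    step_scale: float,
) -> np.ndarray:
    """Sample fractional-Gaussian-noise increment series, shape (n_series, n_steps).

    Uses a Cholesky factorization of the exact fGn autocovariance
    ``gamma(k) = s^2/2 (|k+1|^{2H} + |k-1|^{2H} - 2|k|^{2H})`` with per-step
    variance ``s^2 = step_scale``; exact for any H, O(n^3) setup which is
    negligible at the trajectory lengths used here (<= a few hundred steps).
    """
    h2 = 2.0 * hurst
    k = np.arange(n_steps, dtype=float)
    gamma = 0.5 * step_scale * (
        np.abs(k + 1) ** h2 + np.abs(k - 1) ** h2 - 2.0 * np.abs(k) ** h2
    )
    cov = gamma[np.abs(k[:, None] - k[None, :]).astype(int)]
    cov[np.diag_indices(n_steps)] += 1e-12 * step_scale
    chol = np.linalg.cholesky(cov)
    z = rng.standard_normal((n_steps, n_series))
    return (chol @ z).T


def _reflect_in_ellipsoid(pos: np.ndarray, center: np.ndarray, semi: np.ndarray) -> np.ndarray:
    """Mirror points that left the ellipsoid back across its surface (radially)."""
    u = (pos - center) / semi
    r = np.linalg.norm(u, axis=-1)
    out = r > 1.0
    if np.any(out):
        ro = r[out]
        # mirror the radial coordinate about the unit sphere; cap deep excursions
        rnew = np.clip(2.0 - ro, 0.0, 1.0)
        u[out] *= (rnew / ro)[:, None]
        pos = center + u * semi
    return pos


def simulate_trajectories(
    config: SimulationConfig, nucleus: NucleusMask | None = None
) -> GroundTruth:
    """Simulate ground-truth foci trajectories (Brownian or fBm) in 3-D.

    With a nucleus, starting points are drawn uniformly inside the mask and
    positions are reflected at the (ellipsoidal) boundary; with
    ``nucleus=None`` motion is unbounded and starts uniformly inside the
    field of view.  Observed positions add isotropic localization noise.
    """
    rng = np.random.default_rng(config.seed)
    n, t = config.n_foci, config.n_frames
    n_steps = t - 1

    # starting positions
    if nucleus is not None:
        idx = np.argwhere(nucleus.mask)
        if len(idx) < max(config.n_foci, 1):
            raise ValueError(
                f"nucleus too small to hold {config.n_foci} foci ({len(idx)} voxels)"
            )
        pick = rng.choice(len(idx), size=n, replace=False)
        vs = np.asarray(nucleus.voxel_size, float)
        start = (idx[pick] + rng.uniform(-0.5, 0.5, size=(n, 3))) * vs
    else:
        start = rng.uniform(0.0, 1.0, size=(n, 3)) * config.extent_um

    # increments per axis
    if config.D == 0 or n_steps == 0:
        inc = np.zeros((n, n_steps, 3))
    elif config.alpha == 1.0:
        inc = rng.normal(0.0, np.sqrt(2.0 * config.D * config.dt), size=(n, n_steps, 3))
    else:
        step_var = 2.0 * config.D * config.dt ** config.alpha
        flat = fbm_increments(rng, n_steps, n * 3, hurst=config.alpha / 2.0,
                              step_scale=step_var)
        inc = flat.reshape(n, 3, n_steps).transpose(0, 2, 1)

    true = np.empty((n, t, 3))
    true[:, 0] = start
    if nucleus is not None and nucleus.semi_axes_um is not None:
        center = np.asarray(nucleus.center_um, float)
        semi = np.asarray(nucleus.semi_axes_um, float)
        pos = start.copy()
        for k in range(n_steps):
            pos = _reflect_in_ellipsoid(pos + inc[:, k], center, semi)
            true[:, k + 1] = pos
    else:
        true[:, 1:] = start[:, None, :] + np.cumsum(inc, axis=1)

    observed = true + rng.normal(0.0, config.loc_noise_sigma, size=true.shape)

    fs = config.focus_sigma
    if np.isscalar(fs):
        sizes = np.full(n, float(fs))
    else:
        lo, hi = fs
        sizes = rng.uniform(lo, hi, size=n)

    return GroundTruth(
        true_positions=true,
        observed_positions=observed,
        focus_sizes=sizes,
        config=config,
    )


def simulate_nucleus(
    shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
    texture_params: TextureParams | None = None,
    seed: int = 0,
) -> NucleusSample:
    """Simulate a perturbed-ellipsoid nucleus and its two-class DNA texture.

    The inside-mask intensities are drawn from a two-component Gaussian
    mixture (low mean ~ euchromatin, high mean ~ heterochromatin) arranged in
    smooth spatial blobs; the true per-voxel class labels are returned.
    """
    tp = texture_params or TextureParams()
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < 3 for s in shape):
        raise ValueError(f"degenerate nucleus shape {shape}")
    vs = np.asarray(voxel_size, float)
    extent = np.asarray(shape, float) * vs
    center = (np.asarray(shape, float) - 1.0) / 2.0 * vs
    semi = (
        np.asarray(tp.semi_axes_um, float)
        if tp.semi_axes_um is not None
        else 0.42 * extent
    )
    if np.any(semi <= 0) or np.any(semi > extent / 2.0 + 1e-9):
        raise ValueError(f"ellipsoid semi-axes {tuple(semi)} do not fit inside {tuple(extent)}")

    rng = np.random.default_rng(seed)
    grid = np.indices(shape).astype(float)
    u = [(grid[a] * vs[a] - center[a]) / semi[a] for a in range(3)]
    r = np.sqrt(u[0] ** 2 + u[1] ** 2 + u[2] ** 2)
    radius = 1.0
    if tp.boundary_perturb > 0:
        pert = rng.standard_normal(shape)
        pert = ndimage.gaussian_filter(pert, sigma=np.maximum(tp.blob_sigma_um / vs, 1.0))
        sd = pert.std()
        if sd > 0:
            pert /= sd
        radius = 1.0 + tp.boundary_perturb * pert
    mask = r <= radius

    # smooth random field -> spatially coherent two-class labels at the
    # configured volume weights (threshold at the inside-mask quantile)
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=np.maximum(tp.blob_sigma_um / vs, 0.5))
    inside_vals = f[mask]
    thr = np.quantile(inside_vals, tp.weights[0])
    labels = np.zeros(shape, dtype=np.uint8)
    labels[mask] = np.where(f[mask] <= thr, 1, 2)

    dna = np.zeros(shape)
    for k, (mu, sd) in enumerate(zip(tp.means, tp.sds), start=1):
        sel = labels == k
        dna[sel] = rng.normal(mu, sd, size=int(sel.sum()))
    dna = np.clip(dna, 0.0, None)

    nm = NucleusMask(
        mask=mask, voxel_size=tuple(vs),
        center_um=tuple(center), semi_axes_um=tuple(semi),
    )
    return NucleusSample(mask=nm, dna=dna, labels=labels)


def _true_transform_series(config: SimulationConfig, rng: np.random.Generator) -> TransformSeries:
    """Global cell motion as camera->cell transforms (frame 0 = identity).

    Per-frame small-angle in-plane rotation and translation (linear drift
    plus a low-frequency sinusoid) and, optionally, a smooth sinusoidal
    displacement field — exactly the transform class the registration module
    recovers, so parameter recovery is well-posed.
    """
    t_n = config.n_frames
    shape = np.asarray(config.image_shape, float)
    vs = np.asarray(config.voxel_size, float)
    center = (shape - 1.0) / 2.0 * vs
    direction = rng.normal(size=3)
    direction[0] *= 0.25  # axial drift smaller than lateral
    direction /= max(np.linalg.norm(direction), 1e-12)

    transforms = [Transform3D.identity()]
    for t in range(1, t_n):
        frac = t / max(t_n - 1, 1)
        shift = config.motion_amplitude * (
            0.8 * frac * direction + 0.2 * np.sin(2.0 * np.pi * frac) * direction
        )
        theta = np.deg2rad(config.motion_rotation_deg) * frac
        c, s = np.cos(theta), np.sin(theta)
        rot = np.array([[1, 0, 0], [0, c, -s], [0, s, c]], float)
        # forward cell->camera: x_cam = R(x-c)+c+shift; store camera->cell
        ainv = rot.T
        trans = center - ainv @ (center + shift)
        disp = None
        if config.nonrigid_amplitude > 0:
            gz, gy, gx = np.indices(config.image_shape).astype(float)
            ly, lx = shape[1] * vs[1], shape[2] * vs[2]
            amp = config.nonrigid_amplitude * np.sin(np.pi * frac)
            uy = amp * np.sin(2 * np.pi * gx * vs[2] / lx)
            ux = amp * np.sin(2 * np.pi * gy * vs[1] / ly)
            disp = np.stack([np.zeros_like(uy), uy, ux])
        transforms.append(
            Transform3D(
                affine=ainv, translation=trans,
                displacement=disp,
                grid_voxel_size=tuple(vs) if disp is not None else None,
            )
        )
    return TransformSeries(transforms=transforms)


def _render_spots(
    shape, vs, positions_um, amplitudes, sigmas_um
) -> np.ndarray:
    """Sum of anisotropic Gaussians evaluated on the voxel grid (local windows)."""
    vol = np.zeros(shape)
    shape_arr = np.asarray(shape)
    for pos, amp, sig in zip(positions_um, amplitudes, sigmas_um):
        sig_vox = np.maximum(sig / vs, 1e-6)
        c_vox = pos / vs
        lo = np.maximum(np.floor(c_vox - 4 * sig_vox).astype(int), 0)
        hi = np.minimum(np.ceil(c_vox + 4 * sig_vox).astype(int) + 1, shape_arr)
        if np.any(lo >= hi):
            continue
        ax = [np.arange(lo[a], hi[a]) for a in range(3)]
        d2 = sum(
            ((ax[a].reshape([-1 if i == a else 1 for i in range(3)]) - c_vox[a])
             / sig_vox[a]) ** 2
            for a in range(3)
        )
        vol[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += amp * np.exp(-0.5 * d2)
    return vol


def render_movie(
    truth: GroundTruth,
    config: SimulationConfig | None = None,
    dna_volume: np.ndarray | None = None,
) -> Movie5D:
    """Render a two-channel TCZYX movie from ground truth.

    Channel 0 is the DNA texture transported by the global cell motion;
    channel 1 is the sum of anisotropic Gaussian foci (per-axis sigma
    combining the PSF sigma ``psf_fwhm/2.3548`` with the focus's intrinsic
    size) at the true positions, with amplitude decaying as
    ``exp(-bleach_rate * t)``, plus background.  Poisson noise is applied
    first, then Gaussian read noise.  The true camera->cell transform series
    is recorded on ``truth.transforms``.
    """
    config = config or truth.config
    rng = np.random.default_rng(config.seed + 1_000_003)
    shape = tuple(config.image_shape)
    vs = np.asarray(config.voxel_size, float)
    tser = _true_transform_series(config, rng)
    truth.transforms = tser

    psf_sigma = np.asarray(config.psf_fwhm, float) * FWHM_TO_SIGMA
    sig_um = np.sqrt(psf_sigma[None, :] ** 2 + truth.focus_sizes[:, None] ** 2)

    if dna_volume is None:
        dna_volume = np.zeros(shape)

    n_frames = config.n_frames
    data = np.empty((n_frames, 2) + shape, dtype=np.float64)
    for t in range(n_frames):
        tr = tser[t]
        # channel 0: dna_t(x_cam) = dna_0(T(x_cam)); direct forward evaluation
        if tr.is_identity(tol=1e-15):
            ch0 = dna_volume.astype(float).copy()
        else:
            grid = np.indices(shape).reshape(3, -1).T * vs
            src = tr.apply_points(grid)
            coords = (src / vs).T.reshape((3,) + shape)
            ch0 = ndimage.map_coordinates(dna_volume.astype(float), coords,
                                          order=1, mode="constant")
        # channel 1: foci at camera positions
        cam_pos = tr.invert_points(truth.true_positions[:, t, :]) if truth.n_foci else \
            np.zeros((0, 3))
        amp = config.photon_scale * np.exp(-config.bleach_rate * t * config.dt)
        ch1 = _render_spots(shape, vs, cam_pos, np.full(truth.n_foci, amp), sig_um)
        ch1 += config.background
        data[t, 0] = ch0
        data[t, 1] = ch1

    if config.noise:
        data = rng.poisson(np.clip(data, 0.0, None)).astype(np.float64)
        if config.read_noise > 0:
            data += rng.normal(0.0, config.read_noise, size=data.shape)

    return Movie5D(
        data=data, voxel_size=tuple(vs), dt=config.dt,
        channel_names=("dna", "foci"),
    )


def render_psf_pair(
    points: np.ndarray,
    fwhm_a: float,
    fwhm_b: float,
    pixel: float,
    noise: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int] | None = None,
    photon_scale: float = 1000.0,
    background: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Render the same 2-D emitters with two PSF widths (STED/confocal-like).

    ``points`` is (N, 2) in µm (y, x).  With ``noise > 0`` Poisson noise is
    applied and Gaussian read noise of that standard deviation added (seeded,
    independent per image).  Emitters closer than twice the larger FWHM
    trigger a warning because their profiles would overlap.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    if pts.shape[0] >= 2:
        from scipy.spatial.distance import pdist

        if pdist(pts).min() < 2.0 * max(fwhm_a, fwhm_b):
            warnings.warn("emitters closer than 2x max FWHM: profiles will mix",
                          stacklevel=2)
    if shape is None:
        margin = 0.7  # µm, > half the 1 µm profile line
        hi = pts.max(axis=0) + margin
        shape = tuple(int(np.ceil(h / pixel)) + 1 for h in hi)

    rng = np.random.default_rng(seed)
    images = []
    for fwhm in (fwhm_a, fwhm_b):
        sigma = fwhm * FWHM_TO_SIGMA
        img = np.zeros(shape)
        sig_px = sigma / pixel
        for y, x in pts:
            cy, cx = y / pixel, x / pixel
            lo = np.maximum(np.floor([cy - 5 * sig_px, cx - 5 * sig_px]).astype(int), 0)
            hi_ = np.minimum(np.ceil([cy + 5 * sig_px, cx + 5 * sig_px]).astype(int) + 1,
                             shape)
            yy = np.arange(lo[0], hi_[0])[:, None]
            xx = np.arange(lo[1], hi_[1])[None, :]
            img[lo[0]:hi_[0], lo[1]:hi_[1]] += photon_scale * np.exp(
                -0.5 * (((yy - cy) / sig_px) ** 2 + ((xx - cx) / sig_px) ** 2)
            )
        img += background
        if noise > 0:
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
            img += rng.normal(0.0, noise, size=img.shape)
        images.append(img)
    return images[0], images[1]
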