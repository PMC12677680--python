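"""Joint affine + non-rigid 3D registration of live-cell movies.

Cell movement and deformation are removed by registering every frame of the
DNA channel onto the first frame and transferring the recovered transform to
the chromatin-foci channel.  The affine stage is estimated by subpixel phase
correlation (translation) optionally refined by a direct normalized
cross-correlation (NCC) search over in-plane rotation and translation; the
non-rigid stage is a Gaussian-regularized dense displacement estimated by
iterative Lucas-Kanade optical flow.  All geometry is handled in physical
micrometres so anisotropic voxels (e.g. 170 nm axial vs 48 nm lateral) are
respected.

Transform semantics
-------------------
``Transform3D`` stores the forward point map from the moving frame onto the
fixed (reference) frame:

    f(x) = A @ x + t + u(A @ x + t)

with ``x`` in µm (z, y, x order) and the dense residual field ``u`` sampled
on the fixed grid.  Applying a transform to points uses ``f`` directly (no
interpolation of image data); resampling a volume pulls intensities through
``f``:sup:`-1` (the affine part is inverted exactly, the displacement by
fixed-point iteration, valid for the small smooth deformations targeted
here).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from skimage.registration import optical_flow_ilk, phase_cross_correlation

from .movie import Movie5D

__all__ = [
    "Transform3D",
    "TransformSeries",
    "RegistrationParams",
    "register_frame",
    "register_sequence",
    "apply_transform",
    "ncc",
]


def ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized cross-correlation between two equally shaped arrays."""
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float(np.dot(a, b) / denom)


@dataclass
class Transform3D:
    """Affine + dense-displacement transform, moving frame -> fixed frame.

    ``affine`` is the 3x3 linear part, ``translation`` the 3-vector offset
    (µm, z-y-x).  ``displacement`` is an optional (3, Z, Y, X) field in µm
    sampled on the fixed voxel grid (``grid_voxel_size``); ``None`` means a
    purely affine transform.
    """

    affine: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    displacement: np.ndarray | None = None
    grid_voxel_size: tuple[float, float, float] | None = None
    warning: str | None = None

    def __post_init__(self) -> None:
        self.affine = np.asarray(self.affine, float).reshape(3, 3)
        self.translation = np.asarray(self.translation, float).reshape(3)
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine linear part is singular")
        if self.displacement is not None:
            self.displacement = np.asarray(self.displacement, float)
            if self.displacement.ndim != 4 or self.displacement.shape[0] != 3:
                raise ValueError("displacement must have shape (3, Z, Y, X)")
            if not np.all(np.isfinite(self.displacement)):
                raise ValueError("displacement field contains non-finite values")
            if self.grid_voxel_size is None:
                raise ValueError("displacement field requires grid_voxel_size")

    @classmethod
    def identity(cls) -> "Transform3D":
        return cls()

    @classmethod
    def from_translation(cls, t) -> "Transform3D":
        return cls(translation=np.asarray(t, float))

    def is_identity(self, tol: float = 1e-12) -> bool:
        return (
            self.displacement is None
            and np.allclose(self.affine, np.eye(3), atol=tol)
            and np.allclose(self.translation, 0.0, atol=tol)
        )

    # -- displacement sampling -------------------------------------------------
    def _sample_u(self, pts_um: np.ndarray) -> np.ndarray:
        """Interpolate the displacement field at physical points (N, 3) µm."""
        if self.displacement is None:
            return np.zeros_like(pts_um)
        vs = np.asarray(self.grid_voxel_size, float)
        coords = (pts_um / vs).T  # (3, N) voxel coordinates on the fixed grid
        out = np.empty_like(pts_um)
        for ax in range(3):
            out[:, ax] = ndimage.map_coordinates(
                self.displacement[ax], coords, order=1, mode="nearest"
            )
        return out

    # -- point maps ------------------------------------------------------------
    def apply_points(self, points: np.ndarray) -> np.ndarray:
        """Forward map: moving-frame points (N, 3) µm -> fixed-frame points."""
        pts = np.atleast_2d(np.asarray(points, float))
        y = pts @ self.affine.T + self.translation
        if self.displacement is not None:
            y = y + self._sample_u(y)
        return y if np.asarray(points).ndim == 2 else y[0]

    def invert_points(self, points: np.ndarray, n_iter: int = 8) -> np.ndarray:
        """Inverse map: fixed-frame points -> moving-frame points.

        The affine part is inverted exactly; the displacement contribution by
        fixed-point iteration (converges for small smooth fields).
        """
        pts = np.atleast_2d(np.asarray(points, float))
        ainv = np.linalg.inv(self.affine)
        if self.displacement is None:
            x = (pts - self.translation) @ ainv.T
        else:
            # solve y + u(y) = g for y, then x = A^-1 (y - t)
            y = pts.copy()
            for _ in range(n_iter):
                y = pts - self._sample_u(y)
            x = (y - self.translation) @ ainv.T
        return x if np.asarray(points).ndim == 2 else x[0]

    # -- volume resampling -----------------------------------------------------
    def warp_volume(self, volume: np.ndarray, voxel_size) -> np.ndarray:
        """Resample the moving-frame volume onto the fixed grid (linear interp)."""
        volume = np.asarray(volume, float)
        vs = np.asarray(voxel_size, float)
        grid = np.indices(volume.shape).reshape(3, -1).T * vs  # fixed-grid µm
        src = self.invert_points(grid)  # moving-frame µm
        coords = (src / vs).T.reshape((3,) + volume.shape)
        return ndimage.map_coordinates(volume, coords, order=1, mode="nearest")


@dataclass
class TransformSeries:
    """One transform per movie frame; frame 0 is the identity reference."""

    transforms: list[Transform3D]
    similarity_before: np.ndarray | None = None
    similarity_after: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.transforms:
            raise ValueError("empty transform series")
        if not self.transforms[0].is_identity(tol=1e-9):
            raise ValueError("transforms[0] must be the identity")

    def __len__(self) -> int:
        return len(self.transforms)

    def __getitem__(self, i: int) -> Transform3D:
        return self.transforms[i]


@dataclass
class RegistrationParams:
    """Knobs for frame-to-frame registration.

    upsample_factor: subpixel precision of phase correlation (1/upsample voxel).
    refine_affine: run the NCC rotation+translation refinement after phase
        correlation (needed when the cell rotates, not just drifts).
    nonrigid: estimate the dense displacement refinement.
    reg_sigma_vox: Gaussian regularization of the displacement field, voxels.
    smooth_sigma_vox: pre-smoothing applied before estimation, lateral voxels.
    """

    upsample_factor: int = 20
    refine_affine: bool = True
    nonrigid: bool = True
    reg_sigma_vox: float = 4.0
    smooth_sigma_vox: float = 1.0
    max_rotation_deg: float = 5.0
    flow_radius: int = 7


def _presmooth(vol: np.ndarray, voxel_size, sigma_vox: float) -> np.ndarray:
    if sigma_vox <= 0:
        return np.asarray(vol, float)
    vs = np.asarray(voxel_size, float)
    # sigma specified in lateral voxels; scale per axis to be isotropic in µm
    sig_um = sigma_vox * vs[2]
    sig = np.minimum(sig_um / vs, 2.0)  # cap axial smoothing for thin stacks
    return ndimage.gaussian_filter(np.asarray(vol, float), sigma=sig)


def _rotz(theta: float) -> np.ndarray:
    """Rotation about the optical (z) axis in z-y-x coordinates."""
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _affine_warp(volume, voxel_size, A, t_um, center_um):
    """Warp moving volume by forward map x_f = A (x - c) + c + t (about center)."""
    vs = np.asarray(voxel_size, float)
    ainv = np.linalg.inv(A)
    # inverse map in voxel coordinates for affine_transform: x_m = A^-1 (x_f - c - t) + c
    m = np.diag(1.0 / vs) @ ainv @ np.diag(vs)
    offset = (ainv @ (-np.asarray(center_um) - t_um) + center_um) / vs
    return ndimage.affine_transform(
        np.asarray(volume, float), m, offset=offset, order=1, mode="nearest"
    )


def register_frame(
    fixed: np.ndarray,
    moving: np.ndarray,
    voxel_size,
    params: RegistrationParams | None = None,
    _init_translation_um: np.ndarray | None = None,
) -> Transform3D:
    """Register ``moving`` onto ``fixed`` (both (Z, Y, X) volumes).

    Returns a :class:`Transform3D` whose application to ``moving`` does not
    decrease NCC relative to identity: the affine stage (phase correlation,
    optional rotation refinement) is estimated first on smoothed volumes,
    then the regularized dense displacement refinement.  If a stage worsens
    the similarity it is rolled back and the best transform so far is kept.
    """
    params = params or RegistrationParams()
    fixed = np.asarray(fixed, float)
    moving = np.asarray(moving, float)
    if fixed.shape != moving.shape:
        raise ValueError("fixed and moving must share a shape")
    if fixed.std() == 0 or moving.std() == 0:
        raise ValueError("constant image: registration is degenerate")
    vs = np.asarray(voxel_size, float)
    fs = _presmooth(fixed, vs, params.smooth_sigma_vox)
    ms = _presmooth(moving, vs, params.smooth_sigma_vox)

    ncc0 = ncc(fs, ms)
    best = Transform3D.identity()
    best_ncc = ncc0

    # --- translation by subpixel phase correlation ---------------------------
    shift_vox, _, _ = phase_cross_correlation(
        fs, ms, upsample_factor=params.upsample_factor, normalization=None
    )
    t_um = np.asarray(shift_vox, float) * vs
    if _init_translation_um is not None:
        # choose whichever init explains the data better
        cand = _affine_warp(ms, vs, np.eye(3), _init_translation_um, np.zeros(3))
        if ncc(fs, cand) > ncc(fs, _affine_warp(ms, vs, np.eye(3), t_um, np.zeros(3))):
            t_um = np.asarray(_init_translation_um, float)
    warped = _affine_warp(ms, vs, np.eye(3), t_um, np.zeros(3))
    ncc_t = ncc(fs, warped)
    if ncc_t > best_ncc:
        best = Transform3D.from_translation(t_um)
        best_ncc = ncc_t

    center = (np.asarray(fixed.shape, float) - 1.0) / 2.0 * vs

    # --- in-plane rotation + translation refinement (NCC, Powell) ------------
    if params.refine_affine:
        max_rot = np.deg2rad(params.max_rotation_deg)

        def negncc(p):
            theta = np.clip(p[0], -max_rot, max_rot)
            w = _affine_warp(ms, vs, _rotz(theta), p[1:4], center)
            return -ncc(fs, w)

        x0 = np.concatenate([[0.0], t_um])
        res = optimize.minimize(
            negncc, x0, method="Powell",
            options={"xtol": 1e-3, "ftol": 1e-6, "maxfev": 400},
        )
        theta = float(np.clip(res.x[0], -max_rot, max_rot))
        a_ref = _rotz(theta)
        t_ref = np.asarray(res.x[1:4], float)
        if -res.fun > best_ncc:
            # convert center-relative rotation to plain affine + translation
            best = Transform3D(affine=a_ref, translation=t_ref + center - a_ref @ center)
            best_ncc = -res.fun

    # --- non-rigid refinement -------------------------------------------------
    warning = None
    if params.nonrigid:
        warped = best.warp_volume(ms, vs)
        # flow maps fixed-grid voxels to source offsets: warped(g + flow) ~ fixed(g)
        flow = optical_flow_ilk(
            fs, warped, radius=params.flow_radius, gaussian=True, prefilter=True
        )
        flow = np.asarray(flow, float)
        for ax in range(3):
            flow[ax] = ndimage.gaussian_filter(flow[ax], sigma=params.reg_sigma_vox)
            flow[ax] *= vs[ax]  # voxels -> µm
        cand = Transform3D(
            affine=best.affine.copy(),
            translation=best.translation.copy(),
            displacement=-flow,  # forward residual u = -pullback flow
            grid_voxel_size=tuple(vs),
        )
        ncc_nr = ncc(fs, cand.warp_volume(ms, vs))
        if ncc_nr > best_ncc:
            best, best_ncc = cand, ncc_nr

    if best_ncc < ncc0:
        warning = "registration did not improve similarity; returning identity"
        warnings.warn(warning, stacklevel=2)
        best = Transform3D.identity()
    best.warning = warning
    return best


def register_sequence(
    movie: Movie5D,
    reference_channel: int = 0,
    params: RegistrationParams | None = None,
) -> TransformSeries:
    """Register every frame of ``reference_channel`` onto frame 0.

    Each frame's transform maps that frame's coordinates onto frame 0; the
    translation of the previous frame seeds the next (drift is slow and
    smooth) so the phase-correlation stage cannot lock onto a wrong period.
    """
    if not (0 <= reference_channel < movie.n_channels):
        raise ValueError(f"reference channel {reference_channel} does not exist")
    params = params or RegistrationParams()
    fixed = movie.frame(0, reference_channel)
    vs = movie.voxel_size

    transforms: list[Transform3D] = [Transform3D.identity()]
    before = [1.0]
    after = [1.0]
    prev_t = None
    for t in range(1, movie.n_frames):
        mov = movie.frame(t, reference_channel)
        try:
            tr = register_frame(fixed, mov, vs, params, _init_translation_um=prev_t)
        except ValueError as err:
            raise ValueError(f"frame {t}: {err}") from err
        transforms.append(tr)
        prev_t = tr.translation.copy()
        before.append(ncc(fixed, mov))
        after.append(ncc(fixed, tr.warp_volume(mov, vs)))
    return TransformSeries(
        transforms=transforms,
        similarity_before=np.asarray(before),
        similarity_after=np.asarray(after),
    )


def apply_transform(volume_or_points, t: Transform3D, voxel_size=None):
    """Apply a transform to a volume (resampling) or an (N, 3) µm point set.

    Volumes are pulled onto the fixed grid with linear interpolation and
    require ``voxel_size``; point sets are mapped exactly through the forward
    map with no image interpolation.
    """
    arr = np.asarray(volume_or_points)
    if arr.ndim == 3 and not (arr.shape[-1] == 3 and arr.ndim == 2):
        if voxel_size is None:
            raise ValueError("voxel_size required to transform a volume")
        return t.warp_volume(arr, voxel_size)
    if arr.ndim in (1, 2) and arr.shape[-1] == 3:
        return t.apply_points(arr)
    raise ValueError(f"cannot interpret input of shape {arr.shape}")
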