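"""MSD analysis, diffusion-model fitting, and trajectory confinement measures.

The mean square displacement over lag time is computed per trajectory
(time-averaged over all pairs at each lag, gaps excluded pairwise) and then
averaged across trajectories with equal weight per trajectory.  Two models
are fitted to the ensemble curve:

* short-range diffusion, ``MSD = 6 D t + b``, fitted to the initial linear
  part of the curve (default window: first 50 s, i.e. 10 lags at Δt = 5 s)
  with both parameters constrained non-negative.  The bias ``b`` absorbs
  localization error (``b ≈ 6 σ²`` for isotropic per-axis error σ);
* anomalous diffusion, ``MSD = 6 Γ t^α``, fitted to the whole curve by
  nonlinear least squares initialized from the log-log regression.  α < 0.9
  is the sub-diffusion criterion; lower α means more constrained motion.

The radius of gyration — RMS distance of a trajectory's points from their
centroid over a fixed observation window (default 500 s) — measures the
nuclear volume a locus explores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .tracking import Trajectory

__all__ = [
    "MSDCurve",
    "DiffusionFit",
    "AnomalousFit",
    "GyrationResult",
    "compute_msd",
    "fit_diffusion",
    "fit_anomalous",
    "classify_motion",
    "radius_of_gyration",
    "radii_of_gyration",
]

SUBDIFFUSION_ALPHA = 0.9


@dataclass
class MSDCurve:
    """Ensemble-averaged MSD: lag times (s), MSD (µm²), and the total
    number of displacement pairs contributing at each lag.  ``per_track``
    optionally retains the per-trajectory curves (lag-index -> MSD dict)."""

    lags: np.ndarray
    msd: np.ndarray
    n_pairs: np.ndarray
    dt: float
    n_tracks: np.ndarray | None = None
    per_track: list[dict[int, float]] | None = None

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, float)
        self.msd = np.asarray(self.msd, float)
        self.n_pairs = np.asarray(self.n_pairs, int)
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(self.msd < 0):
            raise ValueError("msd must be non-negative")


@dataclass
class DiffusionFit:
    D: float
    b: float
    fit_window: float
    residual_rms: float
    clipped: bool = False


@dataclass
class AnomalousFit:
    Gamma: float
    alpha: float
    residual_rms: float


@dataclass
class GyrationResult:
    track_id: int
    rg: float
    duration_used: float
    n_points: int


def _densify(traj: Trajectory) -> np.ndarray:
    """Positions on a dense frame grid spanning the track, NaN where absent."""
    span = traj.n_steps
    dense = np.full((span + 1, traj.positions.shape[1]), np.nan)
    dense[traj.frames - traj.frames[0]] = traj.positions
    return dense


def compute_msd(
    trajectories: list[Trajectory],
    dt: float,
    max_lag: float | None = None,
    keep_per_track: bool = False,
) -> MSDCurve:
    """Ensemble MSD curve: per-trajectory time-averaged MSD, then an
    unweighted mean across trajectories at each lag (only trajectories
    covering that lag contribute).  Gaps are excluded pairwise; lags with no
    coverage are omitted.

    Tracks are densified onto their frame span (NaN at gaps) and grouped by
    span so each lag is one vectorized pass."""
    if not trajectories:
        raise ValueError("no trajectories")
    if dt <= 0:
        raise ValueError("dt must be positive")
    max_span = max(tr.n_steps for tr in trajectories)
    max_k = max_span if max_lag is None else min(int(np.floor(max_lag / dt)), max_span)
    if max_k < 1:
        raise ValueError("max_lag shorter than one frame interval")

    groups: dict[int, list[int]] = {}
    for i, tr in enumerate(trajectories):
        groups.setdefault(tr.n_steps, []).append(i)

    n = len(trajectories)
    track_msd = np.full((n, max_k), np.nan)  # per-track time-averaged MSD
    pair_count = np.zeros(max_k, dtype=int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN lag slices
        for span, idxs in groups.items():
            dense = np.stack([_densify(trajectories[i]) for i in idxs])  # (m, span+1, 3)
            for k in range(1, min(max_k, span) + 1):
                d2 = np.sum((dense[:, k:] - dense[:, :-k]) ** 2, axis=-1)  # (m, span+1-k)
                track_msd[idxs, k - 1] = np.nanmean(d2, axis=1)
                pair_count[k - 1] += int(np.sum(~np.isnan(d2)))

    covered = ~np.isnan(track_msd)
    has_lag = covered.any(axis=0)
    ks = np.flatnonzero(has_lag)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ens = np.nanmean(track_msd[:, ks], axis=0)
    per_track = None
    if keep_per_track:
        per_track = [
            {k + 1: float(track_msd[i, k]) for k in range(max_k) if covered[i, k]}
            for i in range(n)
        ]
    return MSDCurve(
        lags=(ks + 1) * dt, msd=ens, n_pairs=pair_count[ks],
        dt=dt, n_tracks=covered[:, ks].sum(axis=0),
        per_track=per_track,
    )


def fit_diffusion(curve: MSDCurve, fit_window: float = 50.0) -> DiffusionFit:
    """Least-squares fit of ``MSD = 6 D t + b`` over lags <= fit_window
    (inclusive), constrained to D >= 0, b >= 0.

    If the unconstrained solution is negative in either parameter the
    non-negative solution is reported with ``clipped=True``."""
    sel = curve.lags <= fit_window + 1e-9
    t = curve.lags[sel]
    y = curve.msd[sel]
    if len(t) < 3:
        raise ValueError(f"need >= 3 lags within the {fit_window} s window, got {len(t)}")
    a = np.column_stack([6.0 * t, np.ones_like(t)])
    unconstrained, *_ = np.linalg.lstsq(a, y, rcond=None)
    sol, _ = optimize.nnls(a, y)
    clipped = bool(np.any(unconstrained < -1e-15))
    resid = y - a @ sol
    return DiffusionFit(
        D=float(sol[0]), b=float(sol[1]), fit_window=float(fit_window),
        residual_rms=float(np.sqrt(np.mean(resid ** 2))), clipped=clipped,
    )


def fit_anomalous(curve: MSDCurve) -> AnomalousFit:
    """Nonlinear least-squares fit of ``MSD = 6 Γ t^α`` to the whole curve.

    Initialized from the log-log linear regression; α bounded to (0, 2].
    The fit runs in linear space so the (noisier) long lags are not
    overweighted the way a pure log-space fit would."""
    ok = curve.msd > 0
    if not np.all(ok):
        warnings.warn(f"dropping {int((~ok).sum())} non-positive MSD values",
                      stacklevel=2)
    t = curve.lags[ok]
    y = curve.msd[ok]
    if len(t) < 5:
        raise ValueError(f"need >= 5 positive lags, got {len(t)}")
    slope, intercept = np.polyfit(np.log(t), np.log(y), 1)
    alpha0 = float(np.clip(slope, 0.05, 2.0))
    gamma0 = float(np.exp(intercept) / 6.0)

    def model(tt, gamma, alpha):
        return 6.0 * gamma * tt ** alpha

    popt, _ = optimize.curve_fit(
        model, t, y, p0=[gamma0, alpha0],
        bounds=([1e-300, 1e-6], [np.inf, 2.0]), maxfev=10000,
    )
    resid = y - model(t, *popt)
    return AnomalousFit(
        Gamma=float(popt[0]), alpha=float(popt[1]),
        residual_rms=float(np.sqrt(np.mean(resid ** 2))),
    )


def classify_motion(fit: AnomalousFit) -> str:
    """``"subdiffusive"`` when α < 0.9 (strict), else ``"normal-or-super"``."""
    return "subdiffusive" if fit.alpha < SUBDIFFUSION_ALPHA else "normal-or-super"


def radius_of_gyration(
    trajectory: Trajectory, dt: float, duration: float = 500.0
) -> GyrationResult:
    """RMS distance from the centroid over the first ``duration`` seconds.

    Only points within ``duration`` of the trajectory's first frame are
    used; fewer than two such points raises."""
    rel_t = (trajectory.frames - trajectory.frames[0]) * dt
    sel = rel_t <= duration + 1e-9
    pts = trajectory.positions[sel]
    if len(pts) < 2:
        raise ValueError(
            f"track {trajectory.id}: {len(pts)} point(s) within {duration} s"
        )
    centroid = pts.mean(axis=0)
    rg = float(np.sqrt(np.mean(np.sum((pts - centroid) ** 2, axis=1))))
    return GyrationResult(
        track_id=trajectory.id, rg=rg,
        duration_used=float(rel_t[sel][-1]), n_points=int(len(pts)),
    )


def radii_of_gyration(
    trajectories: list[Trajectory], dt: float, duration: float = 500.0
) -> tuple[list[GyrationResult], list[tuple[int, str]]]:
    """Radius of gyration for every eligible trajectory; ineligible tracks
    are excluded and returned with the reason."""
    results, excluded = [], []
    for tr in trajectories:
        try:
            results.append(radius_of_gyration(tr, dt, duration))
        except ValueError as err:
            excluded.append((tr.id, str(err)))
    return results, excluded
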