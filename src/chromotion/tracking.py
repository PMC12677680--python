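"""Linking per-frame detections into trajectories.

A constant-position (near-random-walk) Kalman filter predicts each live
track, a gated cost matrix of squared Euclidean distances couples
predictions to the frame's detections, and the assignment is solved globally
(Hungarian method).  Matched tracks are updated, unmatched tracks survive up
to ``max_gap`` frames, and unmatched detections seed new tracks.  The
zero-velocity motion model matches chromatin's constrained diffusive motion;
gaps are never interpolated (MSD analysis uses actual frame differences).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .detection import Detection

__all__ = [
    "TrackerParams",
    "Trajectory",
    "track",
    "filter_by_duration",
    "split_by_size",
]

_BIG = 1e12


@dataclass
class TrackerParams:
    """gate_radius: max link distance, µm; max_gap: frames a track survives
    unassigned; process_noise: random-walk intensity, µm²/s; measurement_noise:
    localization variance, µm²; min_steps: duration-filter preset."""

    gate_radius: float = 0.5
    max_gap: int = 1
    process_noise: float = 2e-4
    measurement_noise: float = 1e-3
    min_steps: int = 10

    def __post_init__(self) -> None:
        if self.gate_radius <= 0 or self.max_gap < 0 or self.min_steps < 2:
            raise ValueError("gate_radius > 0, max_gap >= 0, min_steps >= 2 required")
        if self.process_noise < 0 or self.measurement_noise < 0:
            raise ValueError("noise intensities must be non-negative")


@dataclass
class Trajectory:
    """A time-ordered chain of detections (gaps allowed).

    positions are in registered physical µm coordinates; ``labels`` carries
    stratification results (compaction class, replication timing, size
    class).  Duration in steps = last frame - first frame."""

    id: int
    frames: np.ndarray
    positions: np.ndarray
    sizes: np.ndarray
    responses: np.ndarray | None = None
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, int)
        self.positions = np.atleast_2d(np.asarray(self.positions, float))
        self.sizes = np.asarray(self.sizes, float)
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")

    @property
    def n_points(self) -> int:
        return len(self.frames)

    @property
    def n_steps(self) -> int:
        """Time steps spanned: last frame minus first frame."""
        return int(self.frames[-1] - self.frames[0])

    def duration(self, dt: float) -> float:
        return self.n_steps * dt

    @property
    def median_size(self) -> float:
        return float(np.median(self.sizes))


class _Track:
    __slots__ = ("state", "var", "frames", "positions", "sizes", "responses", "misses")

    def __init__(self, det: Detection):
        self.state = det.position.astype(float).copy()
        self.var = 0.0
        self.frames = [det.frame]
        self.positions = [det.position.copy()]
        self.sizes = [det.size]
        self.responses = [det.peak_response]
        self.misses = 0

    def predict(self, q_per_frame: float) -> None:
        self.var += q_per_frame

    def update(self, det: Detection, r: float) -> None:
        gain = self.var / (self.var + r) if (self.var + r) > 0 else 0.0
        self.state = self.state + gain * (det.position - self.state)
        self.var *= 1.0 - gain
        self.frames.append(det.frame)
        self.positions.append(det.position.copy())
        self.sizes.append(det.size)
        self.responses.append(det.peak_response)
        self.misses = 0


def track(
    detections_per_frame: list[list[Detection]],
    params: TrackerParams | None = None,
    dt: float = 5.0,
) -> list[Trajectory]:
    """Link detections into trajectories frame by frame.

    Every detection is used at most once per frame; no link exceeds
    ``gate_radius``.  Ties (identical costs) resolve deterministically by
    detection order via the Hungarian solver."""
    params = params or TrackerParams()
    q = params.process_noise * dt
    r = params.measurement_noise

    live: list[_Track] = []
    done: list[_Track] = []
    for frame_dets in detections_per_frame:
        dets = list(frame_dets)
        for tr in live:
            tr.predict(q)

        if live and dets:
            pred = np.stack([tr.state for tr in live])
            meas = np.stack([d.position for d in dets])
            dist = np.linalg.norm(pred[:, None, :] - meas[None, :, :], axis=-1)
            cost = np.where(dist <= params.gate_radius, dist ** 2, _BIG)
            rows, cols = linear_sum_assignment(cost)
            matched_tracks = set()
            matched_dets = set()
            for i, j in zip(rows, cols):
                if cost[i, j] >= _BIG:
                    continue
                live[i].update(dets[j], r)
                matched_tracks.add(i)
                matched_dets.add(j)
        else:
            matched_tracks, matched_dets = set(), set()

        still_live = []
        for i, tr in enumerate(live):
            if i in matched_tracks:
                still_live.append(tr)
            else:
                tr.misses += 1
                if tr.misses > params.max_gap:
                    done.append(tr)
                else:
                    still_live.append(tr)
        live = still_live

        for j, det in enumerate(dets):
            if j not in matched_dets:
                live.append(_Track(det))

    done.extend(live)
    done.sort(key=lambda tr: (tr.frames[0], tr.positions[0].tolist()))
    return [
        Trajectory(
            id=i,
            frames=np.asarray(tr.frames),
            positions=np.stack(tr.positions),
            sizes=np.asarray(tr.sizes),
            responses=np.asarray(tr.responses),
        )
        for i, tr in enumerate(done)
    ]


def filter_by_duration(trajectories: list[Trajectory], min_steps: int) -> list[Trajectory]:
    """Keep trajectories spanning at least ``min_steps`` time steps
    (inclusive; a 10-step track survives a 10-step filter).  Order preserved."""
    if min_steps < 2:
        raise ValueError("min_steps must be >= 2")
    return [tr for tr in trajectories if tr.n_steps >= min_steps]


def split_by_size(trajectories: list[Trajectory]):
    """Even split of trajectories into (small, large) by median focus size.

    Per-trajectory size is the median of its detections' size estimates; the
    split point is the median of those medians, so the two groups differ by
    at most one trajectory.  The trajectory sitting exactly at the split
    goes to the small group; ties break by trajectory id."""
    import warnings

    if len(trajectories) < 2:
        raise ValueError("need at least two trajectories to split by size")
    sizes = np.array([tr.median_size for tr in trajectories])
    if np.allclose(sizes, sizes[0]):
        warnings.warn("all trajectory sizes identical; split is arbitrary but "
                      "deterministic (by id)", stacklevel=2)
    order = sorted(range(len(sizes)), key=lambda i: (sizes[i], trajectories[i].id))
    n_small = (len(order) + 1) // 2  # odd count: median goes to small
    small_idx = set(order[:n_small])
    small, large = [], []
    for i, tr in enumerate(trajectories):
        (small if i in small_idx else large).append(tr)
        tr.labels["size_class"] = "small" if i in small_idx else "large"
    return small, large
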