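"""5-D movie container and TIFF/OME-TIFF input/output.

The universal pipeline input is a ``Movie5D``: an intensity array ordered
time x channel x z x y x x (TCZYX) together with the physical voxel sizes
(z, y, x, in micrometres) and the frame interval in seconds.  All physical
quantities downstream (positions, MSD, radii) are expressed in micrometres
and seconds; voxel indices are 0-based and refer to voxel centres, in
z-y-x axis order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = ["Movie5D", "read_movie", "write_movie"]


@dataclass
class Movie5D:
    """A time x channel x z x y x x intensity array with physical metadata.

    Parameters
    ----------
    data:
        5-D array (T, C, Z, Y, X).
    voxel_size:
        Physical voxel size ``(z, y, x)`` in micrometres.
    dt:
        Frame interval in seconds.
    channel_names:
        One label per channel.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    dt: float
    channel_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise ValueError(f"expected 5-D TCZYX data, got ndim={self.data.ndim}")
        if self.data.shape[0] < 1 or self.data.shape[1] < 1:
            raise ValueError("movie needs at least one frame and one channel")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive values, got {self.voxel_size}")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not self.channel_names:
            self.channel_names = tuple(f"ch{i}" for i in range(self.data.shape[1]))
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names length must match channel count")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def volume_shape(self) -> tuple[int, int, int]:
        return self.data.shape[2:]

    def frame(self, t: int, channel: int) -> np.ndarray:
        """Return the (Z, Y, X) volume of frame ``t``, channel ``channel``."""
        return self.data[t, channel]


def write_movie(movie: Movie5D, path) -> None:
    """Write a Movie5D as OME-TIFF with TCZYX axes and physical sizes."""
    meta = {
        "axes": "TCZYX",
        "PhysicalSizeZ": movie.voxel_size[0],
        "PhysicalSizeY": movie.voxel_size[1],
        "PhysicalSizeX": movie.voxel_size[2],
        "PhysicalSizeZUnit": "µm",
        "PhysicalSizeYUnit": "µm",
        "PhysicalSizeXUnit": "µm",
        "TimeIncrement": movie.dt,
        "TimeIncrementUnit": "s",
        "Channel": {"Name": list(movie.channel_names)},
    }
    tifffile.imwrite(str(path), movie.data, ome=True, metadata=meta)


def _normalize_axes(data: np.ndarray, axes: str) -> np.ndarray:
    """Permute/expand ``data`` with axis string ``axes`` to TCZYX order."""
    axes = axes.upper().replace("S", "C").replace("Q", "T")
    target = "TCZYX"
    for ax in axes:
        if ax not in target:
            raise ValueError(f"unsupported axis {ax!r} in axes {axes!r}")
    # insert missing axes as singletons
    for ax in target:
        if ax not in axes:
            data = data[np.newaxis]
            axes = ax + axes
    order = [axes.index(ax) for ax in target]
    return np.transpose(data, order)


def read_movie(
    path,
    axes: str | None = None,
    voxel_size: tuple[float, float, float] | None = None,
    dt: float | None = None,
    channel_names: tuple[str, ...] | None = None,
) -> Movie5D:
    """Read a TIFF/OME-TIFF into a Movie5D, normalizing axes to TCZYX.

    Axis order and physical sizes are taken from OME metadata when present;
    for plain TIFF stacks they must be supplied explicitly — missing
    metadata raises rather than silently defaulting.
    """
    with tifffile.TiffFile(str(path)) as tf:
        series = tf.series[0]
        data = series.asarray()
        file_axes = series.axes
        ome = tf.ome_metadata

    use_axes = axes or file_axes
    if use_axes is None:
        raise ValueError("axis order not in metadata; pass axes= explicitly")
    data = _normalize_axes(data, use_axes)

    if voxel_size is None:
        if ome is None:
            raise ValueError("voxel sizes not in metadata; pass voxel_size= explicitly")
        import re

        sizes = {}
        for ax in "ZYX":
            m = re.search(rf'PhysicalSize{ax}="([0-9.eE+-]+)"', ome)
            if not m:
                raise ValueError(f"PhysicalSize{ax} missing from OME metadata; pass voxel_size=")
            sizes[ax] = float(m.group(1))
        voxel_size = (sizes["Z"], sizes["Y"], sizes["X"])
    if dt is None:
        if ome is None:
            raise ValueError("frame interval not in metadata; pass dt= explicitly")
        import re

        m = re.search(r'TimeIncrement="([0-9.eE+-]+)"', ome)
        if not m:
            raise ValueError("TimeIncrement missing from OME metadata; pass dt= explicitly")
        dt = float(m.group(1))

    kwargs = {}
    if channel_names is not None:
        kwargs["channel_names"] = tuple(channel_names)
    return Movie5D(data=data, voxel_size=voxel_size, dt=dt, **kwargs)
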