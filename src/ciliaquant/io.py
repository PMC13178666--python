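"""Reading and writing image stacks and tables.

All stacks are multi-page TIFF.  In-memory axis order is always
``T(Z)(C)YX`` with y increasing downward and 0-based pixel indices; files
that do not carry unambiguous axis metadata need the axis order supplied
explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile


@dataclass
class VideoStack:
    """A T x Y x X intensity time series with acquisition metadata.

    Parameters
    ----------
    data:
        Array of shape (n_frames, height, width).
    fps:
        Acquisition frame rate in frames per second.
    pixel_size:
        Lateral pixel size in micrometres per pixel.
    """

    data: np.ndarray
    fps: float
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"video data must be T x Y x X, got shape {self.data.shape}")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("video contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_frames / self.fps


def write_stack(path, data: np.ndarray, *, dtype=np.uint16, scale: bool = False) -> None:
    """Write an array as a multi-page TIFF.

    Integer label masks should be passed with ``dtype=None`` to preserve
    their dtype; float maps with ``dtype=np.float32``.  With ``scale=True``
    the data are min-max scaled into the full range of the target integer
    dtype before casting.
    """
    arr = np.asarray(data)
    if dtype is not None:
        if scale and np.issubdtype(np.dtype(dtype), np.integer):
            lo, hi = float(arr.min()), float(arr.max())
            span = hi - lo if hi > lo else 1.0
            info = np.iinfo(dtype)
            arr = (arr - lo) / span * info.max
        if np.issubdtype(np.dtype(dtype), np.integer):
            arr = np.clip(np.round(arr), np.iinfo(dtype).min, np.iinfo(dtype).max)
        arr = arr.astype(dtype)
    tifffile.imwrite(str(path), arr)


def read_stack(path, *, axes: str | None = None) -> np.ndarray:
    """Read a multi-page TIFF and normalize axes to T(Z)(C)YX order.

    The TIFF's own axis annotation is used when present; otherwise the
    array is returned as stored for <=3 dimensions, and ``axes`` (e.g.
    ``"CZYX"``) is required for higher-dimensional files.
    """
    with tifffile.TiffFile(str(path)) as tf:
        series = tf.series[0]
        arr = series.asarray()
        file_axes = series.axes
    if axes is None:
        axes = file_axes
    axes = axes.upper()
    if len(axes) != arr.ndim:
        raise ValueError(
            f"axis order {axes!r} does not match array with {arr.ndim} dimensions; "
            f"candidates include 'TYX', 'ZYX', 'CYX', 'CZYX', 'TCYX'"
        )
    # canonical order: any of T, Z, C (in that precedence) before Y, X
    order = "TZCYX"
    unknown = [a for a in axes if a not in order + "SQI"]
    if unknown:
        raise ValueError(f"unrecognized axes {unknown} in {axes!r}; pass axes= explicitly")
    axes = axes.replace("S", "C").replace("Q", "T").replace("I", "T")
    perm = sorted(range(arr.ndim), key=lambda i: order.index(axes[i]))
    return np.transpose(arr, perm)


def read_video(path, fps: float, pixel_size: float = 1.0, *, axes: str | None = None) -> VideoStack:
    """Read a TIFF video into a :class:`VideoStack`."""
    arr = read_stack(path, axes=axes)
    if arr.ndim != 3:
        raise ValueError(f"expected a T x Y x X video, got shape {arr.shape}")
    return VideoStack(arr.astype(np.float64), fps=fps, pixel_size=pixel_size)


def read_labels(path) -> np.ndarray:
    """Read an integer label mask (0 = background)."""
    arr = tifffile.imread(str(path))
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"label mask must be integer-typed, got {arr.dtype}")
    return arr
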