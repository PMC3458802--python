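"""Shared in-memory containers for well images.

A well is imaged as a short z-stack of grayscale brightfield slices
(:class:`WellImageStack`); the analysis collapses it to a single 2-D frame
(:class:`Image2D`) by minimum-intensity projection before segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError

__all__ = ["Image2D", "WellImageStack"]


@dataclass
class Image2D:
    """A single 2-D intensity image with pixel-size metadata.

    Parameters
    ----------
    data : ndarray, shape (rows, cols)
        Intensity values; must be finite.
    pixel_size_um : float
        Physical edge length of one pixel in micrometres (NaN if unknown).
    name : str, optional
        Label used in error messages (typically the well id).
    """

    data: np.ndarray
    pixel_size_um: float = float("nan")
    name: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2 or self.data.size == 0:
            raise FormatError(f"Image2D requires a non-empty 2-D array, got shape {self.data.shape}")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(np.isfinite(self.data)):
            raise FormatError("Image2D intensities must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class WellImageStack:
    """Ordered z-slices of one well at one time point.

    ``data`` is a (z, rows, cols) array; slice 0 is the first focal plane.
    """

    well_id: str
    day: float
    data: np.ndarray
    pixel_size_um: float = float("nan")

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim == 2:
            arr = arr[np.newaxis]
        if arr.ndim != 3 or arr.shape[0] < 1 or arr.shape[1] * arr.shape[2] == 0:
            raise FormatError(
                f"stack for well {self.well_id!r} must hold >=1 equally shaped 2-D slices, got shape {arr.shape}"
            )
        self.data = arr

    @property
    def n_slices(self) -> int:
        return int(self.data.shape[0])

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    def __iter__(self):
        return iter(self.data)
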