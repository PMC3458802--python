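"""Minimum-intensity projection and particle segmentation.

The measurement chain per well and time point is: collapse the z-stack with
a per-pixel minimum (dark, in-focus cells from every focal plane survive the
projection), threshold the projection inside the circular well footprint
(cells are *darker* than the agar background, so foreground is at or below
the threshold), extract 8-connected components, drop debris below a minimum
area, and record per-particle area, centroid and - when a fluorescence frame
is supplied - mean fluorescence over the particle's pixels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage import measure, morphology
from skimage.filters import threshold_otsu

from .errors import DegenerateImageError, FormatError
from .types import Image2D, WellImageStack

__all__ = [
    "PARTICLE_COLUMNS",
    "min_projection",
    "circular_footprint",
    "otsu_threshold",
    "make_mask",
    "extract_particles",
    "segment_stack",
]

#: column order of every particle table emitted by this module
PARTICLE_COLUMNS = [
    "well_id",
    "day",
    "particle_id",
    "area_px2",
    "centroid_row",
    "centroid_col",
    "mean_fluor",
]


def min_projection(stack: WellImageStack) -> Image2D:
    """Per-pixel minimum across the z-slices of ``stack``.

    Raises :class:`FormatError` for an empty stack (enforced by
    :class:`WellImageStack` itself on construction).
    """
    if not isinstance(stack, WellImageStack):
        stack = WellImageStack("?", float("nan"), np.asarray(stack))
    proj = np.min(stack.data, axis=0)
    return Image2D(proj, pixel_size_um=stack.pixel_size_um, name=stack.well_id)


def circular_footprint(
    shape: tuple[int, int],
    center: tuple[float, float] | None = None,
    radius: float | None = None,
) -> np.ndarray:
    """Boolean mask of the circular well area inside a rectangular frame.

    Defaults to a circle centred in the frame whose diameter is the smaller
    frame edge.
    """
    rows, cols = shape
    if center is None:
        center = ((rows - 1) / 2.0, (cols - 1) / 2.0)
    if radius is None:
        radius = min(rows, cols) / 2.0
    rr, cc = np.ogrid[:rows, :cols]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def otsu_threshold(values: np.ndarray) -> float:
    """Otsu threshold of a sample of intensities.

    For integer-typed input the histogram uses one bin per integer level so
    the result is exactly the between-class-variance maximiser over integer
    thresholds (foreground = values <= threshold).
    """
    values = np.asarray(values).ravel()
    if np.issubdtype(values.dtype, np.integer):
        lo, hi = int(values.min()), int(values.max())
        counts = np.bincount((values - lo).astype(np.intp), minlength=hi - lo + 1)
        centers = np.arange(lo, hi + 1)
        return float(threshold_otsu(hist=(counts, centers)))
    return float(threshold_otsu(values))


def make_mask(
    img: Image2D | np.ndarray,
    method: str = "otsu",
    footprint: np.ndarray | None = None,
    threshold: float | None = None,
    min_contrast_sigmas: float = 3.0,
) -> np.ndarray:
    """Binary foreground mask of dark objects inside the well footprint.

    Parameters
    ----------
    img : Image2D or ndarray
        Minimum-intensity projection of a well.
    method : {"otsu", "fixed"}
        ``otsu`` computes the threshold from within-footprint intensities;
        ``fixed`` uses ``threshold`` as given.
    footprint : bool ndarray, optional
        Restriction to the circular well area (rim artifacts excluded). When
        omitted the whole frame is used.
    threshold : float, optional
        Fixed threshold (required for ``method='fixed'``).
    min_contrast_sigmas : float
        Otsu sanity guard: the split is accepted only when the background and
        foreground class means are separated by more than this many pooled
        within-class standard deviations. A featureless noise image fails the
        guard (a normal sample split anywhere separates its halves by ~1.6
        sigma) and yields an empty mask instead of spurious foreground.

    Raises
    ------
    DegenerateImageError
        If the image is constant inside the footprint.
    """
    if not isinstance(img, Image2D):
        img = Image2D(np.asarray(img))
    data = img.data
    if footprint is None:
        footprint = np.ones(data.shape, dtype=bool)
    elif footprint.shape != data.shape:
        raise FormatError(
            f"footprint shape {footprint.shape} does not match image shape {data.shape}"
        )
    vals = data[footprint]
    if vals.size == 0 or vals.min() == vals.max():
        where = f" for well {img.name}" if img.name else ""
        raise DegenerateImageError(f"degenerate image{where}: constant intensity inside the well footprint")

    if method == "fixed":
        if threshold is None:
            raise ValueError("method='fixed' requires a threshold value")
        thr = float(threshold)
    elif method == "otsu":
        thr = otsu_threshold(vals)
        fg = vals[vals <= thr]
        bg = vals[vals > thr]
        if fg.size == 0 or bg.size == 0:
            return np.zeros(data.shape, dtype=bool)
        pooled_sd = float(
            np.sqrt((fg.size * fg.var() + bg.size * bg.var()) / vals.size)
        )
        if pooled_sd > 0 and (bg.mean() - fg.mean()) <= min_contrast_sigmas * pooled_sd:
            # weakly bimodal: treat as background-only rather than hallucinate cells
            return np.zeros(data.shape, dtype=bool)
    else:
        raise ValueError(f"unknown threshold method {method!r}")

    return (data <= thr) & footprint


def extract_particles(
    mask: np.ndarray,
    fluor_img: np.ndarray | None = None,
    min_particle_area: int = 4,
    well_id: str = "",
    day: float = float("nan"),
) -> pd.DataFrame:
    """Measure 8-connected components of ``mask`` as a particle table.

    Components smaller than ``min_particle_area`` pixels are dropped as
    debris. Centroids are 0-based (row, col) pixel coordinates. When
    ``fluor_img`` is given, ``mean_fluor`` is the mean fluorescence over each
    particle's pixels; otherwise it is NaN.
    """
    mask = np.asarray(mask, dtype=bool)
    if fluor_img is not None and np.asarray(fluor_img).shape != mask.shape:
        raise FormatError(
            f"fluorescence shape {np.asarray(fluor_img).shape} does not match mask shape {mask.shape}"
        )
    # keep components with area >= min_particle_area (max_size removes <=)
    cleaned = morphology.remove_small_objects(mask, max_size=min_particle_area - 1, connectivity=2)
    labels = measure.label(cleaned, connectivity=2)
    n = int(labels.max())
    if n == 0:
        return pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
            PARTICLE_COLUMNS, [str, float, int, float, float, float, float])})
    props = measure.regionprops_table(labels, properties=("label", "area", "centroid"))
    table = pd.DataFrame(
        {
            "well_id": well_id,
            "day": float(day),
            "particle_id": props["label"].astype(int),
            "area_px2": props["area"].astype(float),
            "centroid_row": props["centroid-0"],
            "centroid_col": props["centroid-1"],
        }
    )
    if fluor_img is not None:
        fprops = measure.regionprops_table(
            labels, intensity_image=np.asarray(fluor_img, dtype=float),
            properties=("label", "intensity_mean"),
        )
        table["mean_fluor"] = fprops["intensity_mean"]
    else:
        table["mean_fluor"] = np.nan
    return table[PARTICLE_COLUMNS]


def segment_stack(
    stack: WellImageStack,
    well_diameter_px: float | None = None,
    fluor_img: np.ndarray | None = None,
    method: str = "otsu",
    threshold: float | None = None,
    min_particle_area: int = 4,
) -> pd.DataFrame:
    """Full per-stack measurement: projection -> mask -> particle table."""
    proj = min_projection(stack)
    footprint = None
    if well_diameter_px is not None:
        footprint = circular_footprint(proj.shape, radius=well_diameter_px / 2.0)
    mask = make_mask(proj, method=method, footprint=footprint, threshold=threshold)
    return extract_particles(
        mask,
        fluor_img=fluor_img,
        min_particle_area=min_particle_area,
        well_id=stack.well_id,
        day=stack.day,
    )
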