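"""Quantification of two-channel colony micrographs.

A colony is imaged in two registered channels: an all-cells nuclear stain
("nuclei", e.g. Hoechst) and a marker expressed only by drug-sensitive
cells ("marker", e.g. Citrine).  This module stitches tile grids into
mosaics, segments the colony by intensity thresholding, converts mask area
to an equivalent-circle diameter (2 * sqrt(area / pi), treating the colony
as a perfect disc), computes the resistant area fraction
(nuclei_area - marker_area) / nuclei_area, and normalises radius time
series to their starting value.

Segmentation is automated thresholding rather than manual outline tracing:
optionally a binary closing (``close_radius``) merges sub-confluent nuclei
into a contiguous colony mask before small-object cleanup and
largest-component selection.  The resistant area fraction always uses the
raw threshold masks of both channels, with the same threshold applied to
both.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import convex_hull_image

__all__ = [
    "ColonyImagePair",
    "ColonyMeasurement",
    "SegmentationResult",
    "IncompleteGridError",
    "stitch_tiles",
    "segment_colony",
    "diameter_from_area",
    "resistant_fraction",
    "normalize_radius",
    "measure_pair",
]


class IncompleteGridError(ValueError):
    """A tile position of the stitching grid is missing."""


@dataclass
class ColonyImagePair:
    """Two registered channels of one colony plus the pixel size.

    ``nuclei`` images every cell; ``marker`` images sensitive cells only.
    """

    nuclei: np.ndarray
    marker: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.nuclei = np.asarray(self.nuclei)
        self.marker = np.asarray(self.marker)
        if self.nuclei.ndim != 2 or self.nuclei.shape != self.marker.shape:
            raise ValueError("channels must be 2D arrays of identical shape")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")

    @classmethod
    def from_files(cls, nuclei_path, marker_path, pixel_size_um: float):
        """Load a pair from TIFF/PNG files (8/16-bit grayscale)."""
        import imageio.v3 as iio

        return cls(
            nuclei=np.asarray(iio.imread(nuclei_path)),
            marker=np.asarray(iio.imread(marker_path)),
            pixel_size_um=pixel_size_um,
        )


@dataclass
class ColonyMeasurement:
    """Measured size and composition of one colony image (one timepoint)."""

    area_mm2: float
    equivalent_diameter_um: float
    resistant_area_fraction: Optional[float] = None
    threshold_used: Optional[float] = None
    timepoint_h: Optional[float] = None


@dataclass
class SegmentationResult:
    mask: np.ndarray
    area_mm2: float
    threshold_used: float
    warnings: list = field(default_factory=list)


def stitch_tiles(tiles, overlap: int = 0) -> np.ndarray:
    """Assemble a row/column grid of equal-shape tiles into one mosaic.

    ``tiles`` is either a mapping ``{(row, col): 2D array}`` or a nested
    sequence ``tiles[row][col]``.  Adjacent tiles share ``overlap`` pixels,
    cropped symmetrically from the two internal edges (no registration or
    blending).  A missing grid position raises
    :class:`IncompleteGridError`.
    """
    if isinstance(tiles, dict):
        grid = dict(tiles)
    else:
        grid = {
            (r, c): t
            for r, row in enumerate(tiles)
            for c, t in enumerate(row)
            if t is not None
        }
    if not grid:
        raise IncompleteGridError("no tiles supplied")
    n_rows = max(r for r, _ in grid) + 1
    n_cols = max(c for _, c in grid) + 1
    missing = [
        (r, c) for r in range(n_rows) for c in range(n_cols) if (r, c) not in grid
    ]
    if missing:
        raise IncompleteGridError(f"missing tiles at {missing}")
    shape = np.asarray(next(iter(grid.values()))).shape
    if any(np.asarray(t).shape != shape for t in grid.values()):
        raise ValueError("all tiles must share one shape")
    if overlap < 0 or overlap >= min(shape):
        raise ValueError("overlap must be >= 0 and smaller than a tile")
    a, b = overlap // 2, overlap - overlap // 2

    rows = []
    for r in range(n_rows):
        strips = []
        for c in range(n_cols):
            t = np.asarray(grid[(r, c)])
            r0 = a if r > 0 else 0
            r1 = t.shape[0] - (b if r < n_rows - 1 else 0)
            c0 = a if c > 0 else 0
            c1 = t.shape[1] - (b if c < n_cols - 1 else 0)
            strips.append(t[r0:r1, c0:c1])
        rows.append(np.hstack(strips))
    return np.vstack(rows)


def _disc_structure(radius: int) -> np.ndarray:
    yy, xx = np.ogrid[-radius : radius + 1, -radius : radius + 1]
    return (yy * yy + xx * xx) <= radius * radius


def _drop_small(mask: np.ndarray, min_size: int) -> np.ndarray:
    labels, n = ndimage.label(mask)
    if n == 0:
        return mask
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    keep = 1 + np.flatnonzero(sizes >= min_size)
    return np.isin(labels, keep)


def segment_colony(
    image: np.ndarray,
    pixel_size_um: float,
    threshold: Union[float, str] = "auto",
    close_radius: int = 0,
    min_size: int = 50,
    largest_only: bool = True,
    convex_hull: bool = False,
) -> SegmentationResult:
    """Threshold an image into a colony mask and measure its area.

    ``threshold="auto"`` uses Otsu's method; an explicit threshold, once
    chosen, should be reused across a whole imaging batch.  The raw mask is
    ``image > threshold``; ``close_radius > 0`` then applies binary closing
    with a disc of that radius plus hole filling — needed to merge
    sub-confluent nuclei into one contiguous colony footprint before
    small-object cleanup (< ``min_size`` px) and largest-connected-component
    selection.  ``convex_hull`` replaces the final mask by its convex hull:
    appropriate for footprint-size measurement, where the colony is treated
    as a perfect disc and the scalloped rim between boundary nuclei would
    otherwise bias the area low.  Area is the final mask pixel count times
    pixel_size^2.

    An empty mask yields area 0 with a warning record rather than an error.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be > 0")
    if threshold == "auto":
        thr = float(threshold_otsu(image))
    else:
        thr = float(threshold)
    mask = image > thr
    notes: list = []
    if not mask.any():
        notes.append("empty mask: no pixel above threshold")
        return SegmentationResult(mask, 0.0, thr, notes)
    if close_radius > 0:
        mask = ndimage.binary_closing(mask, structure=_disc_structure(int(close_radius)))
        mask = ndimage.binary_fill_holes(mask)
    if min_size > 0:
        mask = _drop_small(mask, int(min_size))
    if largest_only and mask.any():
        labels, n = ndimage.label(mask)
        if n > 1:
            sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
            mask = labels == (1 + int(np.argmax(sizes)))
    if not mask.any():
        notes.append("mask vanished after cleanup")
        return SegmentationResult(mask, 0.0, thr, notes)
    if convex_hull:
        mask = convex_hull_image(mask)
    area_mm2 = float(mask.sum()) * (pixel_size_um / 1000.0) ** 2
    return SegmentationResult(mask, area_mm2, thr, notes)


def diameter_from_area(area_mm2: float) -> float:
    """Equivalent-circle diameter (um) of a colony of given area (mm^2)."""
    if area_mm2 < 0:
        raise ValueError("area must be >= 0")
    return 2.0 * np.sqrt(area_mm2 / np.pi) * 1000.0


def resistant_fraction(pair: ColonyImagePair, threshold: float) -> float:
    """Resistant area fraction (nuclei - marker) / nuclei of a channel pair.

    Both channels are thresholded at the same value with no morphological
    cleanup; the result is clipped to [0, 1].  Raises when no nuclei pixel
    exceeds the threshold.
    """
    thr = float(threshold)
    area_nuclei = int(np.count_nonzero(pair.nuclei > thr))
    area_marker = int(np.count_nonzero(pair.marker > thr))
    if area_nuclei == 0:
        raise ValueError("zero nuclei area: resistant fraction undefined")
    return float(np.clip((area_nuclei - area_marker) / area_nuclei, 0.0, 1.0))


def normalize_radius(series) -> np.ndarray:
    """Divide a time-ordered radius series by its first value.

    Accepts plain radii or :class:`ColonyMeasurement` objects (using their
    equivalent diameters, whose normalisation is identical to the radius
    one).  The first value must be positive; the normalised series starts
    exactly at 1.
    """
    values = [
        m.equivalent_diameter_um if isinstance(m, ColonyMeasurement) else float(m)
        for m in series
    ]
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("empty series")
    if arr[0] <= 0:
        raise ValueError("initial radius must be > 0")
    return arr / arr[0]


def measure_pair(
    pair: ColonyImagePair,
    threshold: Union[float, str] = "auto",
    close_radius: int = 0,
    convex_hull: bool = False,
    timepoint_h: Optional[float] = None,
) -> ColonyMeasurement:
    """Full single-image measurement: area, diameter, resistant fraction."""
    seg = segment_colony(
        pair.nuclei,
        pair.pixel_size_um,
        threshold,
        close_radius=close_radius,
        convex_hull=convex_hull,
    )
    for note in seg.warnings:
        warnings.warn(note, stacklevel=2)
    frac = None
    if np.count_nonzero(pair.nuclei > seg.threshold_used):
        frac = resistant_fraction(pair, seg.threshold_used)
    return ColonyMeasurement(
        area_mm2=seg.area_mm2,
        equivalent_diameter_um=diameter_from_area(seg.area_mm2),
        resistant_area_fraction=frac,
        threshold_used=seg.threshold_used,
        timepoint_h=timepoint_h,
    )
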