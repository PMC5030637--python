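"""Patch segmentation from grayscale rasters.

Implements the image-processing chain used to extract tussock-like
structures from aerial imagery: luminance conversion, median filtering,
percentile contrast stretching, dark-object binarization, border and
minimum-size filtering, 8-connected labelling, and per-patch properties
in physical units (metres) from the metres-per-pixel scale.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import color, filters, measure, util

__all__ = ["PatchSet", "preprocess", "binarize", "label_patches"]

_EIGHT = np.ones((3, 3), dtype=bool)

#: smallest structure considered real, as an equivalent diameter (m)
DEFAULT_MIN_DIAMETER_M = 0.3


@dataclasses.dataclass
class PatchSet:
    """Labelled patches extracted from a raster.

    ``table`` has one row per retained patch with columns ``label``,
    ``row``, ``col`` (sub-pixel centroid), ``area_px``, ``area_m2``,
    ``r_eq_m`` (radius of the circle with the same area) and
    ``border_touching`` (always False for retained patches).
    ``label_image`` maps pixels to patch labels (0 = background).
    """

    table: pd.DataFrame
    label_image: np.ndarray
    pixel_size: float
    shape: tuple[int, int]

    def __len__(self) -> int:
        return len(self.table)

    def mask(self, label: int) -> np.ndarray:
        return self.label_image == label

    def boundary_pixels(self, label: int) -> np.ndarray:
        """(n, 2) array of (row, col) boundary pixels of one patch."""
        m = self.mask(label)
        inner = ndimage.binary_erosion(m, structure=_EIGHT, border_value=0)
        return np.argwhere(m & ~inner)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def preprocess(image: np.ndarray, median_size: int = 3) -> np.ndarray:
    """Luminance conversion, median filter and contrast stretch.

    RGB input is converted with the ITU luminance weights; a
    ``median_size`` x ``median_size`` median filter removes speckle;
    intensities are rescaled so the 1st/99th percentiles map to 0/1
    (values outside are clipped).  A constant image is returned as-is
    (no contrast to stretch).
    """
    image = np.asarray(image)
    if image.ndim == 3 and image.shape[2] == 3:
        image = color.rgb2gray(image)
    if image.ndim != 2 or min(image.shape) < 3:
        raise ValueError("expected a 2-D grayscale or RGB raster, >= 3 px per side")
    image = util.img_as_float(image)
    image = ndimage.median_filter(image, size=median_size, mode="nearest")
    lo, hi = np.percentile(image, [1.0, 99.0])
    if hi <= lo:
        return image.copy()
    return np.clip((image - lo) / (hi - lo), 0.0, 1.0)


def binarize(
    image: np.ndarray,
    method: str = "otsu",
    threshold: Optional[float] = None,
    polarity: str = "dark",
) -> np.ndarray:
    """Foreground mask of dark (or bright) objects.

    ``method='otsu'`` picks the threshold from the histogram;
    ``method='fixed'`` uses ``threshold``.  With ``polarity='dark'``
    (tussocks appear as dark spots) foreground pixels are those strictly
    below the threshold; ``polarity='bright'`` selects above it, so
    inverting the image and flipping polarity yields the same mask.
    """
    image = np.asarray(image, dtype=float)
    if polarity not in ("dark", "bright"):
        raise ValueError("polarity must be 'dark' or 'bright'")
    if method == "fixed":
        if threshold is None:
            raise ValueError("method='fixed' requires a threshold")
        t = float(threshold)
    elif method == "otsu":
        if np.ptp(image) == 0:  # constant image: nothing to separate
            return np.zeros(image.shape, dtype=bool)
        t = float(filters.threshold_otsu(image))
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    return image < t if polarity == "dark" else image > t


def label_patches(
    mask: np.ndarray,
    pixel_size: float,
    min_diameter_m: float = DEFAULT_MIN_DIAMETER_M,
) -> PatchSet:
    """Label 8-connected components and filter to credible patches.

    Components touching any image border are removed (the structure may
    continue off-image); components with an equivalent diameter below
    ``min_diameter_m`` are removed (below the resolution at which a
    structure is credible).  Properties: ``area_m2 = n_px *
    pixel_size**2`` and ``r_eq_m = sqrt(area_m2 / pi)``.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    mask = np.asarray(mask, dtype=bool)
    labels = measure.label(mask, connectivity=2)
    rows = []
    keep = np.zeros(labels.max() + 1, dtype=bool)
    h, w = mask.shape
    for region in measure.regionprops(labels):
        r0, c0, r1, c1 = region.bbox
        border = r0 == 0 or c0 == 0 or r1 == h or c1 == w
        area_m2 = region.area * pixel_size**2
        r_eq_m = float(np.sqrt(area_m2 / np.pi))
        if border or 2.0 * r_eq_m < min_diameter_m:
            continue
        keep[region.label] = True
        cy, cx = region.centroid
        rows.append(
            {
                "label": region.label,
                "row": cy,
                "col": cx,
                "area_px": int(region.area),
                "area_m2": area_m2,
                "r_eq_m": r_eq_m,
                "border_touching": False,
            }
        )
    label_image = np.where(keep[labels], labels, 0)
    table = pd.DataFrame(
        rows,
        columns=["label", "row", "col", "area_px", "area_m2", "r_eq_m", "border_touching"],
    )
    return PatchSet(table=table, label_image=label_image, pixel_size=pixel_size, shape=(h, w))
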