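"""Background correction, cell masking and ratio-image computation.

Pipeline: threshold the acceptor channel into a binary cell mask, subtract
the background median from donor and FRET channels, then divide FRET by
donor per pixel inside the mask.  The per-cell summary is the arithmetic
mean of the pixelwise ratios (mean-of-ratios); a ratio-of-means variant is
available via ``method="ratio_of_means"``.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, morphology

from ..img_io import Mask, Raster
from .types import FretImageSet, RatioImage


class EmptyMaskError(ValueError):
    """No connected component satisfied the minimum-area requirement."""


def estimate_background_mask(cell_mask: Mask, dilation_px: int = 5) -> Mask:
    """Background = complement of the dilated cell mask."""
    grown = ndi.binary_dilation(cell_mask.as_bool(), structure=morphology.disk(dilation_px))
    bg = ~grown
    if not bg.any():
        raise ValueError("no background pixels left after dilation")
    return Mask(bg.astype(np.uint8))


def correct_background(raster: Raster, background_region: Mask) -> Raster:
    """Subtract the median intensity of the background region, clipping at 0."""
    if raster.shape != background_region.shape:
        raise ValueError("background region shape mismatch")
    bg = background_region.as_bool()
    if not bg.any():
        raise ValueError("background region is empty")
    level = float(np.median(raster.pixels[bg]))
    return Raster(
        np.clip(raster.pixels - level, 0.0, None),
        raster.pixel_size_um,
        raster.bit_depth,
    )


def make_cell_mask(
    acceptor: Raster,
    method: str = "otsu",
    min_area_px: int = 100,
) -> Mask:
    """Threshold the acceptor channel into a single-cell binary mask.

    Holes are filled and only the largest connected component is kept.
    Raises :class:`EmptyMaskError` for uniform images or when no component
    reaches ``min_area_px``.
    """
    px = acceptor.pixels
    if np.ptp(px) == 0:
        raise EmptyMaskError("acceptor raster is uniform; cannot threshold")
    if method == "otsu":
        thresh = filters.threshold_otsu(px)
    elif method == "mean":
        thresh = px.mean()
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    binary = px > thresh
    binary = ndi.binary_fill_holes(binary)
    labels, n = ndi.label(binary)
    if n == 0:
        raise EmptyMaskError("thresholding produced no foreground")
    sizes = ndi.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    biggest = int(np.argmax(sizes)) + 1
    if sizes[biggest - 1] < min_area_px:
        raise EmptyMaskError(
            f"largest component has {int(sizes[biggest - 1])} px < {min_area_px}"
        )
    return Mask((labels == biggest).astype(np.uint8))


def ratio_image(
    image_set: FretImageSet,
    mask: Mask,
    donor_floor: float = 0.0,
    method: str = "mean_of_ratios",
) -> RatioImage:
    """Per-pixel FRET/donor ratio inside the mask.

    Pixels whose (background-corrected) donor intensity is at or below
    ``donor_floor`` are removed from the mask before dividing — division at
    dim donor pixels is numerically explosive.  ``mean_ratio`` is the
    arithmetic mean of defined pixels, or sum(fret)/sum(donor) when
    ``method="ratio_of_means"``.
    """
    if image_set.donor.shape != mask.shape:
        raise ValueError("mask shape mismatch")
    valid = mask.as_bool() & (image_set.donor.pixels > donor_floor)
    if not valid.any():
        raise ValueError("all pixels fail the donor floor; nothing to ratio")
    donor = image_set.donor.pixels[valid]
    fret = image_set.fret.pixels[valid]
    ratios = np.full(mask.shape, np.nan)
    ratios[valid] = fret / donor
    if method == "mean_of_ratios":
        mean_ratio = float(np.mean(fret / donor))
    elif method == "ratio_of_means":
        mean_ratio = float(fret.sum() / donor.sum())
    else:
        raise ValueError(f"unknown method {method!r}")
    return RatioImage(ratios, Mask(valid.astype(np.uint8)), mean_ratio)


def fret_fold_change(
    sample_mean_ratios: list[float], control_mean_ratios: list[float]
) -> float:
    """Fold change of per-cell mean ratios, sample over control."""
    if not sample_mean_ratios or not control_mean_ratios:
        raise ValueError("both ratio lists must be non-empty")
    control = float(np.mean(control_mean_ratios))
    if control <= 0:
        raise ValueError("control mean ratio must be positive")
    return float(np.mean(sample_mean_ratios)) / control
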