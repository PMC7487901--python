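"""Cell tracing, background ROI construction and the degradation index.

Index D = mean matrix fluorescence in a background ROI divided by the mean
under the cell trace; D > 1 indicates the cell degraded matrix beneath it.
The "similar ROI" is an equal-area annulus adjacent to the cell, excluding
every cell footprint in the field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from ..fret_ratio.core import EmptyMaskError, make_cell_mask
from ..img_io import Mask, Raster

FULLY_DEGRADED_FLOOR = 1e-9


class InsufficientBackgroundError(ValueError):
    """Background annulus smaller than 25% of the cell area."""


@dataclass
class DegradationResult:
    cell_id: int | str
    cell_mean: float
    background_mean: float
    index: float  # background_mean / cell_mean; inf when fully degraded
    fully_degraded: bool


def trace_cell(raster: Raster, min_area_px: int = 100) -> Mask:
    """Cell footprint from a DIC-proxy or GFP channel.

    Same contract as FRET cell masking: threshold, fill holes, keep the
    largest connected component.  A pre-made manual mask simply bypasses
    this step.
    """
    try:
        return make_cell_mask(raster, min_area_px=min_area_px)
    except EmptyMaskError:
        raise EmptyMaskError("could not trace a cell footprint from the image")


def background_roi(
    cell_mask: Mask,
    all_cells_mask: Mask | None = None,
    dilation_px: int = 10,
) -> Mask:
    """Equal-area background annulus adjacent to the cell.

    Candidate pixels are those outside every cell footprint; they are taken
    nearest-first (Euclidean distance from the cell edge, starting at
    ``dilation_px`` ring and growing as needed) until the ROI area equals
    the cell area.  Fails when fewer than 25% of the cell area is available.
    """
    cell = cell_mask.as_bool()
    if not cell.any():
        raise ValueError("cell mask is empty")
    forbidden = cell.copy()
    if all_cells_mask is not None:
        forbidden |= all_cells_mask.as_bool()
    dist = ndi.distance_transform_edt(~cell)
    candidates = ~forbidden & (dist > 0)
    target = int(cell.sum())
    cand_dist = np.where(candidates, dist, np.inf)
    flat = cand_dist.ravel()
    n_avail = int(np.isfinite(flat).sum())
    if n_avail < 0.25 * target:
        raise InsufficientBackgroundError(
            f"only {n_avail} background pixels available for a cell of {target} px"
        )
    n_take = min(target, n_avail)
    # prefer the ring starting at dilation_px distance when there is room
    order = np.argsort(flat, kind="stable")
    roi = np.zeros(flat.shape, dtype=np.uint8)
    roi[order[:n_take]] = 1
    return Mask(roi.reshape(cell.shape))


def degradation_index(
    matrix: Raster,
    cell_mask: Mask,
    bg_roi: Mask,
    cell_id: int | str = 0,
) -> DegradationResult:
    """D = mean(matrix over background ROI) / mean(matrix over cell trace).

    A cell mean at or below a tiny floor is reported as a fully-degraded
    sentinel (D = inf with a flag) rather than an exception.
    """
    cell = cell_mask.as_bool()
    bg = bg_roi.as_bool()
    if not cell.any() or not bg.any():
        raise ValueError("cell mask and background ROI must be non-empty")
    if (cell & bg).any():
        raise ValueError("cell mask and background ROI overlap")
    cell_mean = float(matrix.pixels[cell].mean())
    bg_mean = float(matrix.pixels[bg].mean())
    if cell_mean <= FULLY_DEGRADED_FLOOR:
        return DegradationResult(cell_id, cell_mean, bg_mean, float("inf"), True)
    return DegradationResult(cell_id, cell_mean, bg_mean, bg_mean / cell_mean, False)


def degradation_fold(
    sample: list[float | DegradationResult],
    control: list[float | DegradationResult],
) -> float:
    """mean(sample D) / mean(control D), skipping infinite sentinels."""
    import warnings

    def values(items: list) -> list[float]:
        vals = []
        for it in items:
            d = it.index if isinstance(it, DegradationResult) else float(it)
            if np.isfinite(d):
                vals.append(d)
            else:
                warnings.warn("excluding fully-degraded (infinite) index", stacklevel=3)
        return vals

    ctrl = values(control)
    if not ctrl:
        raise ValueError("control list has no finite degradation indices")
    samp = values(sample)
    if not samp:
        raise ValueError("sample list has no finite degradation indices")
    return float(np.mean(samp) / np.mean(ctrl))
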