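"""Containers for ratiometric FRET analysis."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..img_io import Mask, Raster


@dataclass
class FretImageSet:
    """Paired donor / FRET / acceptor channels of one biosensor acquisition.

    donor    : CFP excitation, CFP emission
    fret     : CFP excitation, YFP emission
    acceptor : YFP excitation, YFP emission (used for cell masking)
    """

    donor: Raster
    fret: Raster
    acceptor: Raster

    def __post_init__(self) -> None:
        shapes = {self.donor.shape, self.fret.shape, self.acceptor.shape}
        if len(shapes) != 1:
            raise ValueError("donor/fret/acceptor rasters must share one shape")
        sizes = {
            self.donor.pixel_size_um,
            self.fret.pixel_size_um,
            self.acceptor.pixel_size_um,
        }
        if len(sizes) != 1:
            raise ValueError("donor/fret/acceptor rasters must share one pixel size")

    def rescaled(self, factor: float) -> "FretImageSet":
        """Joint exposure change on all three channels."""
        return FretImageSet(
            self.donor.rescaled(factor),
            self.fret.rescaled(factor),
            self.acceptor.rescaled(factor),
        )


@dataclass
class RatioImage:
    """Per-pixel FRET/donor ratio defined where mask = 1."""

    pixels: np.ndarray  # NaN outside the mask
    mask: Mask
    mean_ratio: float

    def __post_init__(self) -> None:
        inside = self.mask.as_bool()
        vals = self.pixels[inside]
        if vals.size == 0:
            raise ValueError("ratio image has no defined pixels")
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0):
            raise ValueError("defined ratios must be finite and positive")
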