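"""Shared data containers for the analysis pipelines.

Conventions
-----------
* Raster indexing is (row, col), 0-based.  Physical coordinates are
  ``x = col * pixel_size_um`` and ``y = row * pixel_size_um``.
* All intensities are handled as floating point internally; the source
  integer dtype is remembered only through ``bit_depth`` for writing.
* Masks are binary uint8 grids with 1 = inside the object, 0 = background.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_PIXEL_SIZE_UM = 1.0


@dataclass
class Raster:
    """A 2-D grayscale intensity image with physical pixel size.

    Parameters
    ----------
    pixels : ndarray
        2-D array of finite, non-negative intensities.  Stored as float64.
    pixel_size_um : float
        Physical size of one pixel in micrometres.  Must be > 0.
    bit_depth : int
        Bit depth of the source data (8, 12, 16 for integers, 32 for float).
    """

    pixels: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    bit_depth: int = 32

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError("raster must be 2-D with at least one row and column")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("raster intensities must be finite")
        if np.any(self.pixels < 0):
            raise ValueError("raster intensities must be non-negative")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def rescaled(self, factor: float) -> "Raster":
        """Return a copy with all intensities multiplied by `factor`."""
        return Raster(self.pixels * factor, self.pixel_size_um, self.bit_depth)


@dataclass
class Mask:
    """Binary grid aligned to a Raster: 1 = inside, 0 = background."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValueError("mask must be 2-D")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be 0 or 1")
        self.pixels = arr.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())

    def as_bool(self) -> np.ndarray:
        return self.pixels.astype(bool)


TRACK_COLUMNS = ["track_id", "frame", "x", "y"]


@dataclass
class TrackTable:
    """Time-ordered cell positions, one row per (track, frame).

    ``frame`` is an integer frame index; ``x``/``y`` are micrometres.
    ``frame_interval_min`` converts frame indices to minutes.
    """

    data: pd.DataFrame
    frame_interval_min: float

    def __post_init__(self) -> None:
        if not self.frame_interval_min > 0:
            raise ValueError("frame_interval_min must be positive")
        df = pd.DataFrame(self.data, columns=TRACK_COLUMNS).copy()
        df["track_id"] = df["track_id"].astype(int)
        df["frame"] = df["frame"].astype(int)
        df = df.sort_values(["track_id", "frame"], kind="stable").reset_index(drop=True)
        if df.duplicated(["track_id", "frame"]).any():
            raise ValueError("duplicate (track_id, frame) rows")
        self.data = df

    @property
    def track_ids(self) -> list[int]:
        return sorted(self.data["track_id"].unique().tolist())

    @property
    def n_tracks(self) -> int:
        return self.data["track_id"].nunique()

    def track(self, track_id: int) -> pd.DataFrame:
        sel = self.data[self.data["track_id"] == track_id]
        if sel.empty:
            raise KeyError(f"no track with id {track_id}")
        return sel.reset_index(drop=True)


def resolve_pixel_size(pixel_size_um: float | None) -> float:
    """Return a pixel size, defaulting to 1.0 μm/px with a logged warning."""
    if pixel_size_um is None:
        logger.warning(
            "pixel_size_um not supplied; defaulting to %.1f um/px", DEFAULT_PIXEL_SIZE_UM
        )
        warnings.warn(
            "pixel_size_um not supplied; assuming 1.0 um/px", stacklevel=3
        )
        return DEFAULT_PIXEL_SIZE_UM
    if not pixel_size_um > 0:
        raise ValueError("pixel_size_um must be positive")
    return float(pixel_size_um)
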