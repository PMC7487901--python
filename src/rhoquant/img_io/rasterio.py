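"""TIFF raster reading/writing.

Intensities are never rescaled or gamma-corrected on read; integer data
round-trips bit exactly.  Pixel size is carried in a small JSON sidecar
(``<image>.tif.meta.json``) because plain TIFF has no reliable μm/px slot.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .types import Mask, Raster, resolve_pixel_size

_SIDECAR_SUFFIX = ".meta.json"


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + _SIDECAR_SUFFIX)


def _infer_bit_depth(dtype: np.dtype) -> int:
    if np.issubdtype(dtype, np.floating):
        return 32
    return dtype.itemsize * 8


def read_raster(
    path: str | Path,
    pixel_size_um: float | None = None,
    page: int = 0,
) -> Raster:
    """Read one page of a TIFF file as a :class:`Raster`.

    Parameters
    ----------
    path : path to a single- or multi-page TIFF.
    pixel_size_um : μm per pixel.  When ``None``, the sidecar written by
        :func:`write_raster` is consulted; failing that, 1.0 with a warning.
    page : page index for multi-page stacks (default 0).

    Raises
    ------
    IOError / FileNotFoundError for unreadable files, IndexError for an
    out-of-range page.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        n_pages = len(tif.pages)
        if not 0 <= page < n_pages:
            raise IndexError(f"page {page} out of range for {n_pages}-page file")
        arr = tif.pages[page].asarray()
    bit_depth = _infer_bit_depth(arr.dtype)

    if pixel_size_um is None:
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            pixel_size_um = float(meta["pixel_size_um"])
            bit_depth = int(meta.get("bit_depth", bit_depth))
    return Raster(arr, resolve_pixel_size(pixel_size_um), bit_depth)


def write_raster(raster: Raster, path: str | Path) -> Path:
    """Write a raster as TIFF plus a pixel-size sidecar.

    Integer bit depths (8/12/16) are written as the matching unsigned
    integer type for a lossless round trip; anything else goes out as
    32-bit float.
    """
    path = Path(path)
    if raster.bit_depth <= 8:
        out = raster.pixels.astype(np.uint8)
    elif raster.bit_depth <= 16:
        out = raster.pixels.astype(np.uint16)
    else:
        out = raster.pixels.astype(np.float32)
    tifffile.imwrite(path, out)
    _sidecar_path(path).write_text(
        json.dumps(
            {"pixel_size_um": raster.pixel_size_um, "bit_depth": raster.bit_depth}
        )
    )
    return path


def write_stack(pages: list[np.ndarray], path: str | Path) -> Path:
    """Write a list of 2-D arrays as one multi-page TIFF."""
    path = Path(path)
    tifffile.imwrite(
        path, np.stack([np.asarray(p) for p in pages]), photometric="minisblack"
    )
    return path


def read_mask(path: str | Path, page: int = 0) -> Mask:
    """Read a binary mask TIFF (any nonzero pixel counts as inside)."""
    r = read_raster(path, pixel_size_um=1.0, page=page)
    return Mask((r.pixels > 0).astype(np.uint8))


def write_mask(mask: Mask, path: str | Path) -> Path:
    tifffile.imwrite(Path(path), mask.pixels)
    return Path(path)
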