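"""Auxiliary quantifications.

DNA-content gating follows the ploidy rule: G0/G1 at 2n, S strictly
between 2n and 4n, G2/M at 4n.  The 2n peak is located from the PI
histogram; the 4n position is fixed at twice the 2n mode (PI linearity
assumed).  Gate half-width is k times the measured CV of the 2n peak
(k = 2.5 by default — the original gate widths are unpublished), with
half-open [low, high) intervals.  Sub-G1 and >4n events are excluded from
the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from ..img_io import Raster

MIN_PEAK_CV = 0.01


@dataclass
class CellCycleFractions:
    g0g1: float
    s: float
    g2m: float
    n_events: int  # events inside the gated denominator
    peak_2n: float
    peak_4n: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.g0g1, self.s, self.g2m)


@dataclass
class ApoptosisFractions:
    live: float
    early_apoptotic: float
    necrotic: float
    other: float  # annexin-negative / PI-positive

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.live, self.early_apoptotic, self.necrotic, self.other)


@dataclass
class GelBand:
    lane: str
    band: float
    loading: float

    def __post_init__(self) -> None:
        if self.band <= 0 or self.loading <= 0:
            raise ValueError("band and loading intensities must be positive")

    @property
    def normalized(self) -> float:
        return self.band / self.loading


def _find_2n_mode(values: np.ndarray) -> float:
    """Locate the 2n peak as the lowest-position prominent histogram mode."""
    hi = np.quantile(values, 0.995)
    counts, edges = np.histogram(values, bins=256, range=(0.0, float(hi)))
    # pad so spikes at the range edges still register as peaks
    padded = np.concatenate([[0], counts, [0]])
    peaks, props = find_peaks(padded, height=1)
    if len(peaks) == 0:
        raise ValueError("no detectable 2n mode in the PI histogram")
    heights = props["peak_heights"]
    keep = heights >= 0.25 * heights.max()
    candidates = peaks[keep] - 1
    first = int(candidates.min())
    centers = 0.5 * (edges[:-1] + edges[1:])
    coarse = float(centers[first])
    # refine with the median of events near the coarse mode (robust to the
    # histogram bin width and to lognormal peak asymmetry)
    near = values[(values > 0.9 * coarse) & (values < 1.1 * coarse)]
    return float(np.median(near)) if near.size else coarse


def gate_cell_cycle(
    pi_values: np.ndarray, cv_window_k: float = 2.5
) -> CellCycleFractions:
    """Gate PI DNA-content events into G0/G1, S and G2/M fractions.

    Requires at least 100 events.  Fractions are taken over the gated
    denominator (sub-G1 and >4n excluded) and always sum to 1.
    """
    values = np.asarray(pi_values, dtype=float)
    values = values[np.isfinite(values) & (values > 0)]
    if len(values) < 100:
        raise ValueError("need at least 100 positive events")
    mode_2n = _find_2n_mode(values)
    mode_4n = 2.0 * mode_2n

    near = values[(values > 0.85 * mode_2n) & (values < 1.15 * mode_2n)]
    med = np.median(near)
    cv = max(float(1.4826 * np.median(np.abs(near - med)) / med), MIN_PEAK_CV)

    half = cv_window_k * cv
    g1_lo, g1_hi = mode_2n * (1 - half), mode_2n * (1 + half)
    g2_lo, g2_hi = mode_4n * (1 - half), mode_4n * (1 + half)
    if g1_hi >= g2_lo:
        raise ValueError("G0/G1 and G2/M gates overlap; CV too large for k")

    g1 = (values >= g1_lo) & (values < g1_hi)
    s = (values >= g1_hi) & (values < g2_lo)
    g2 = (values >= g2_lo) & (values < g2_hi)
    n = int(g1.sum() + s.sum() + g2.sum())
    if n == 0:
        raise ValueError("no events inside the cell-cycle gates")
    return CellCycleFractions(
        g0g1=float(g1.sum()) / n,
        s=float(s.sum()) / n,
        g2m=float(g2.sum()) / n,
        n_events=n,
        peak_2n=mode_2n,
        peak_4n=mode_4n,
    )


def classify_annexin_pi(
    events: np.ndarray,
    thresholds: tuple[float, float] | None = None,
) -> ApoptosisFractions:
    """Quadrant classification of (annexin, PI) event pairs.

    Both below threshold: live; annexin-only: early apoptotic; both:
    necrotic; PI-only: other.  Missing thresholds are derived per channel
    by Otsu on log10 intensities.
    """
    ev = np.asarray(events, dtype=float).reshape(-1, 2)
    if thresholds is None:
        from skimage.filters import threshold_otsu

        thresholds = tuple(
            10.0 ** threshold_otsu(np.log10(np.clip(ev[:, i], 1e-12, None)))
            for i in range(2)
        )
    t_ann, t_pi = thresholds
    ann_pos = ev[:, 0] >= t_ann
    pi_pos = ev[:, 1] >= t_pi
    n = len(ev)
    if n == 0:
        raise ValueError("no events")
    return ApoptosisFractions(
        live=float((~ann_pos & ~pi_pos).sum()) / n,
        early_apoptotic=float((ann_pos & ~pi_pos).sum()) / n,
        necrotic=float((ann_pos & pi_pos).sum()) / n,
        other=float((~ann_pos & pi_pos).sum()) / n,
    )


def densitometry_fold(bands: list[GelBand], control_lane: str) -> dict[str, float]:
    """Loading-normalized fold change of each lane versus the control lane."""
    by_lane = {b.lane: b for b in bands}
    if control_lane not in by_lane:
        raise ValueError(f"control lane {control_lane!r} not present")
    ctrl = by_lane[control_lane].normalized
    return {b.lane: b.normalized / ctrl for b in bands}


def sphere_metrics(
    diameter_um: float | None = None,
    mask: np.ndarray | None = None,
    pixel_size_um: float = 1.0,
) -> dict[str, float]:
    """Projected area and spherical volume from a diameter or a 2-D mask.

    area = pi d^2 / 4, volume = pi d^3 / 6 (sphericity assumed).  With a
    mask, the diameter is the equivalent-circle diameter of its area.
    """
    if diameter_um is None:
        if mask is None or not np.any(mask):
            raise ValueError("need a positive diameter or a non-empty mask")
        area_um2 = float(np.count_nonzero(mask)) * pixel_size_um**2
        diameter_um = 2.0 * np.sqrt(area_um2 / np.pi)
    if diameter_um <= 0:
        raise ValueError("diameter must be positive")
    return {
        "diameter_um": float(diameter_um),
        "area_um2": float(np.pi * diameter_um**2 / 4.0),
        "volume_um3": float(np.pi * diameter_um**3 / 6.0),
    }


def tissue_mean_intensity(rasters: list[Raster]) -> list[float]:
    """Mean intensity per pixel of each fixed-area frame."""
    if not rasters:
        raise ValueError("need at least one frame")
    shape = rasters[0].shape
    for r in rasters:
        if r.shape != shape:
            raise ValueError("all frames must share one shape")
    return [float(r.pixels.mean()) for r in rasters]


def intensity_group_fold(group_a: list[Raster], group_b: list[Raster]) -> float:
    """mean per-pixel intensity of group A over group B."""
    a = tissue_mean_intensity(group_a)
    b = tissue_mean_intensity(group_b)
    denom = float(np.mean(b))
    if denom <= 0:
        raise ValueError("group B mean intensity must be positive")
    return float(np.mean(a)) / denom
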