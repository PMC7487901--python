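"""Ground-truth records returned alongside every generated scene."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class FretGroundTruth:
    ratio_map: np.ndarray  # per-pixel true FRET/donor ratio
    mask: np.ndarray  # bool, true cell footprint
    mean_ratio: float  # area-weighted mean of ratio_map over mask
    donor_level: float
    background_level: float
    seed: int


@dataclass
class MatrixGroundTruth:
    degradation_map: np.ndarray  # per-pixel depth in [0, 1]
    footprint: np.ndarray  # bool
    degraded_fraction: float  # fraction of footprint pixels with depth > 0
    spots: list[tuple[float, float, float, float]]  # (row, col, radius, depth)
    matrix_level: float
    cell_mean: float  # noiseless mean matrix signal under the footprint
    background_mean: float  # noiseless background signal (= matrix_level)
    degradation_index: float  # background_mean / cell_mean
    seed: int


@dataclass
class PunctaGroundTruth:
    centers: np.ndarray  # (n, 2) float (row, col)
    radii: np.ndarray  # (n,) px
    areas_px: np.ndarray  # (n,) true area pi * r^2
    peak_intensity: float
    background_level: float
    seed: int

    @property
    def n_puncta(self) -> int:
        return len(self.radii)


@dataclass
class TrackGroundTruth:
    """Per-track noiseless path statistics (μm / minutes)."""

    per_track: pd.DataFrame  # track_id, total_path_um, net_um, speed_um_min
    step_len_um: float
    persistence: float
    frame_interval_min: float
    seed: int

    @property
    def mean_speed_um_min(self) -> float:
        return float(self.per_track["speed_um_min"].mean())


@dataclass
class WoundGroundTruth:
    frame_times_hr: tuple[float, ...]
    nominal_width_um: list[float]  # max(0, w0 - rate*t)
    rasterized_mean_width_um: list[float]  # mean width of the drawn masks
    closure_rate_um_hr: float
    seed: int


@dataclass
class CytometryGroundTruth:
    labels: np.ndarray  # int class per event
    class_names: tuple[str, ...]
    fractions: tuple[float, ...]  # requested mixture
    empirical_fractions: tuple[float, ...]  # realized label frequencies
    peak_2n: float | None
    seed: int


@dataclass
class GelGroundTruth:
    lanes: list[str]
    band_true: np.ndarray
    loading_true: np.ndarray
    normalized_true: np.ndarray  # band/loading
    fold_vs_first: np.ndarray
    seed: int
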