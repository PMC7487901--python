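"""Validated parameter blocks for the scene generators.

Default noise levels are arbitrary: the source assays report no SNR or
camera characteristics, so any realistic-looking default is a convention,
not a measurement.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class FretSceneParams:
    """Elliptical cell with a spatially varying FRET/donor ratio.

    The true ratio map is ``ratio_baseline`` everywhere inside the cell,
    optionally multiplied by ``hotspot_factor`` over the ``hotspot_fraction``
    of cell pixels at one end of the major axis (a "tail" activation zone).
    """

    shape: tuple[int, int] = (256, 256)
    center: tuple[float, float] = (128.0, 128.0)  # (row, col), px
    axes: tuple[float, float] = (80.0, 45.0)  # semi-axes (row, col), px
    orientation_rad: float = 0.0
    donor_level: float = 1000.0
    ratio_baseline: float = 1.0
    hotspot_fraction: float = 0.0  # fraction of cell pixels in the hotspot
    hotspot_factor: float = 1.0
    background_level: float = 100.0
    noise_model: str = "gaussian"  # gaussian | poisson | poisson+gaussian | none
    gaussian_sigma: float = 0.0
    pixel_size_um: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.donor_level > self.background_level >= 0:
            raise ValueError("need donor_level > background_level >= 0")
        if self.ratio_baseline <= 0 or self.hotspot_factor <= 0:
            raise ValueError("true ratios must be positive")
        if not 0.0 <= self.hotspot_fraction <= 1.0:
            raise ValueError("hotspot_fraction must lie in [0, 1]")
        if self.noise_model not in ("gaussian", "poisson", "poisson+gaussian", "none"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")


@dataclass
class MatrixSceneParams:
    """Fluorescent gelatin with dark degradation spots under a cell footprint.

    Either pass explicit ``spots`` as (row, col, radius_px, depth) tuples, or
    request a target ``degraded_fraction`` of the footprint area; in the
    latter case circular spots of radius in ``spot_radius_px`` are placed at
    random until the requested within-footprint pixel fraction is hit exactly
    (the final spot is trimmed pixelwise).
    """

    shape: tuple[int, int] = (256, 256)
    matrix_level: float = 1000.0
    center: tuple[float, float] = (128.0, 128.0)
    axes: tuple[float, float] = (70.0, 50.0)
    orientation_rad: float = 0.0
    spots: list[tuple[float, float, float, float]] | None = None
    degraded_fraction: float | None = None
    depth: float = 1.0
    spot_radius_px: tuple[float, float] = (4.0, 8.0)
    noise_sigma: float = 0.0
    pixel_size_um: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.matrix_level <= 0:
            raise ValueError("matrix_level must be positive")
        if not 0.0 <= self.depth <= 1.0:
            raise ValueError("depth must lie in [0, 1]")
        if self.spots is not None:
            for r, c, rad, dep in self.spots:
                if not 0.0 <= dep <= 1.0:
                    raise ValueError("spot depth must lie in [0, 1]")
                if not (0 <= r < self.shape[0] and 0 <= c < self.shape[1]):
                    raise ValueError("spot centers must lie inside the image")
        if self.degraded_fraction is not None and not 0.0 <= self.degraded_fraction <= 1.0:
            raise ValueError("degraded_fraction must lie in [0, 1]")


@dataclass
class PunctaSceneParams:
    """Gaussian-profile puncta on an optionally graded background.

    A punctum of radius r has intensity ``peak * exp(-d^2 / (2 s^2))`` with
    ``s = r / sqrt(2)``, i.e. the profile falls to peak/e at distance r.
    """

    shape: tuple[int, int] = (256, 256)
    center: tuple[float, float] = (128.0, 128.0)
    axes: tuple[float, float] = (110.0, 110.0)
    orientation_rad: float = 0.0
    n_puncta: int = 12
    radius_px: tuple[float, float] = (3.0, 3.0)  # (min, max)
    peak_intensity: float = 500.0
    background_level: float = 100.0
    gradient_amplitude: float = 0.0
    min_separation_px: float = 18.0
    allow_overlap: bool = False
    noise_sigma: float = 0.0
    pixel_size_um: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_puncta < 0:
            raise ValueError("n_puncta must be >= 0")
        if self.radius_px[0] < 1.0:
            raise ValueError("spot radii must be >= 1 px")
        if self.radius_px[1] < self.radius_px[0]:
            raise ValueError("radius_px must be (min, max) with min <= max")


@dataclass
class MotilitySceneParams:
    """Persistent-random-walk track generation (default cadence: 60-s
    frames for 2 h)."""

    n_cells: int = 15
    n_frames: int = 121
    frame_interval_min: float = 1.0
    step_len_um: float = 0.3  # per-frame step length, fixed within a track
    persistence: float = 0.5  # E[cos(turn)] of the heading process
    noise_sigma_um: float = 0.0  # localization noise on reported positions
    field_um: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.persistence <= 1.0:
            raise ValueError("persistence must lie in [0, 1]")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be positive")
        if self.step_len_um < 0 or self.noise_sigma_um < 0:
            raise ValueError("lengths must be non-negative")


@dataclass
class WoundSceneParams:
    """A vertical wound band closing at a constant rate with rough edges."""

    shape: tuple[int, int] = (400, 600)
    pixel_size_um: float = 2.0
    initial_width_um: float = 500.0
    closure_rate_um_hr: float = 5.0
    roughness_um: float = 0.0  # std of the per-row edge offsets
    frame_times_hr: tuple[float, ...] = (0.0, 48.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.initial_width_um < 0 or self.roughness_um < 0:
            raise ValueError("widths must be non-negative")
        if len(self.frame_times_hr) < 1:
            raise ValueError("need at least one frame time")


@dataclass
class CytometrySimParams:
    """DNA-content (PI) and Annexin/PI event simulation.

    Cell-cycle mode: PI signals are lognormal peaks at the 2n and 4n
    positions with coefficient of variation ``cv`` and a uniform S-phase
    bridge between them; ``s_margin_k`` keeps the bridge ``k * cv`` away
    from both peaks so that ploidy gating is identifiable.
    """

    n_events: int = 10_000
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)  # g0g1, s, g2m
    cv: float = 0.05
    peak_2n: float = 100.0
    s_margin_k: float = 2.5
    apoptosis_fractions: tuple[float, float, float] = (0.7, 0.2, 0.1)  # live, early, necrotic
    separation_decades: float = 1.5
    log_spread_decades: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        for fr in (self.fractions, self.apoptosis_fractions):
            if any(f < 0 for f in fr) or abs(sum(fr) - 1.0) > 1e-9:
                raise ValueError("fractions must be >= 0 and sum to 1")
        if self.cv <= 0:
            raise ValueError("cv must be positive")
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")
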