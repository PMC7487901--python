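"""Scene generators.

Noiseless limits are exact closed-form constructions; noise is layered on
top via named substreams so geometry is independent of the noise draw.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..fret_ratio.types import FretImageSet
from ..img_io import Mask, Raster, TrackTable
from .params import (
    CytometrySimParams,
    FretSceneParams,
    MatrixSceneParams,
    MotilitySceneParams,
    PunctaSceneParams,
    WoundSceneParams,
)
from .streams import substream
from .truth import (
    CytometryGroundTruth,
    FretGroundTruth,
    GelGroundTruth,
    MatrixGroundTruth,
    PunctaGroundTruth,
    TrackGroundTruth,
    WoundGroundTruth,
)


class PlacementError(RuntimeError):
    """Raised when non-overlapping spot placement fails after bounded retries."""


# ---------------------------------------------------------------- helpers


def _ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    axes: tuple[float, float],
    orientation_rad: float,
) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    co, si = np.cos(orientation_rad), np.sin(orientation_rad)
    u = co * dr + si * dc
    v = -si * dr + co * dc
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def _check_ellipse_inside(
    shape: tuple[int, int], center: tuple[float, float], axes: tuple[float, float]
) -> None:
    rad = max(axes)
    if (
        center[0] - rad < 0
        or center[1] - rad < 0
        or center[0] + rad > shape[0] - 1
        or center[1] + rad > shape[1] - 1
    ):
        raise ValueError("ellipse exceeds the image bounds")


def _apply_noise(
    expected: np.ndarray, model: str, gaussian_sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Poisson shot noise on expected counts, then Gaussian read noise."""
    out = expected.astype(np.float64)
    if model in ("poisson", "poisson+gaussian"):
        out = rng.poisson(out).astype(np.float64)
    if model in ("gaussian", "poisson+gaussian") and gaussian_sigma > 0:
        out = out + rng.normal(0.0, gaussian_sigma, size=out.shape)
    return np.clip(out, 0.0, None)


# ---------------------------------------------------------------- FRET


def make_fret_scene(
    params: FretSceneParams,
) -> tuple[FretImageSet, Mask, FretGroundTruth]:
    """Donor/FRET/acceptor triplet over an elliptical cell.

    Inside the cell the expected donor signal is ``donor_level`` and the
    expected FRET signal is ``donor_level * true_ratio``; both sit on
    ``background_level``.  The acceptor channel mirrors the donor and is
    meant for mask derivation only.
    """
    _check_ellipse_inside(params.shape, params.center, params.axes)
    cell = _ellipse_mask(params.shape, params.center, params.axes, params.orientation_rad)

    ratio_map = np.full(params.shape, params.ratio_baseline, dtype=np.float64)
    if params.hotspot_fraction > 0 and params.hotspot_factor != 1.0:
        # "tail" hotspot: the requested fraction of cell pixels at the far
        # end of the major axis, selected exactly by projection rank.
        rr, cc = np.nonzero(cell)
        co, si = np.cos(params.orientation_rad), np.sin(params.orientation_rad)
        major_is_row = params.axes[0] >= params.axes[1]
        if major_is_row:
            proj = co * (rr - params.center[0]) + si * (cc - params.center[1])
        else:
            proj = -si * (rr - params.center[0]) + co * (cc - params.center[1])
        n_hot = int(round(params.hotspot_fraction * len(rr)))
        if n_hot > 0:
            order = np.argsort(proj)[::-1][:n_hot]
            ratio_map[rr[order], cc[order]] = (
                params.ratio_baseline * params.hotspot_factor
            )

    donor_exp = np.where(cell, params.donor_level, 0.0) + params.background_level
    fret_exp = np.where(cell, params.donor_level * ratio_map, 0.0) + params.background_level
    acceptor_exp = donor_exp.copy()

    noisy = {}
    for name, exp in (("donor", donor_exp), ("fret", fret_exp), ("acceptor", acceptor_exp)):
        rng = substream(params.seed, "noise", name)
        noisy[name] = _apply_noise(exp, params.noise_model, params.gaussian_sigma, rng)

    def raster(arr: np.ndarray) -> Raster:
        return Raster(arr, pixel_size_um=params.pixel_size_um, bit_depth=32)

    image_set = FretImageSet(raster(noisy["donor"]), raster(noisy["fret"]), raster(noisy["acceptor"]))
    mask = Mask(cell.astype(np.uint8))
    truth = FretGroundTruth(
        ratio_map=ratio_map,
        mask=cell,
        mean_ratio=float(ratio_map[cell].mean()),
        donor_level=params.donor_level,
        background_level=params.background_level,
        seed=params.seed,
    )
    return image_set, mask, truth


# ---------------------------------------------------------------- matrix


def _disk_pixels(
    shape: tuple[int, int], center: tuple[float, float], radius: float
) -> tuple[np.ndarray, np.ndarray]:
    r0 = max(int(np.floor(center[0] - radius)), 0)
    r1 = min(int(np.ceil(center[0] + radius)) + 1, shape[0])
    c0 = max(int(np.floor(center[1] - radius)), 0)
    c1 = min(int(np.ceil(center[1] + radius)) + 1, shape[1])
    rr, cc = np.mgrid[r0:r1, c0:c1]
    keep = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    return rr[keep], cc[keep]


def make_matrix_scene(
    params: MatrixSceneParams,
) -> tuple[Raster, Mask, MatrixGroundTruth]:
    """Gelatin raster with dark degradation spots under an elliptical footprint.

    Overlapping spots combine by max depth per pixel (degraded matrix cannot
    be re-degraded back up).  In ``degraded_fraction`` mode the within-
    footprint degraded pixel count matches the request exactly: the last
    spot is trimmed pixel by pixel, farthest from its center first.
    """
    footprint = _ellipse_mask(
        params.shape, params.center, params.axes, params.orientation_rad
    )
    depth_map = np.zeros(params.shape, dtype=np.float64)
    spots: list[tuple[float, float, float, float]] = []

    if params.spots is not None:
        for r, c, rad, dep in params.spots:
            rr, cc = _disk_pixels(params.shape, (r, c), rad)
            np.maximum.at(depth_map, (rr, cc), dep)
            spots.append((float(r), float(c), float(rad), float(dep)))
    elif params.degraded_fraction is not None and params.degraded_fraction > 0:
        rng = substream(params.seed, "placement")
        target = int(round(params.degraded_fraction * footprint.sum()))
        degraded = np.zeros(params.shape, dtype=bool)
        frows, fcols = np.nonzero(footprint)
        guard = 0
        while int((degraded & footprint).sum()) < target:
            guard += 1
            if guard > 10_000:
                raise PlacementError("could not reach requested degraded_fraction")
            i = rng.integers(len(frows))
            center = (float(frows[i]), float(fcols[i]))
            rad = float(rng.uniform(*params.spot_radius_px))
            rr, cc = _disk_pixels(params.shape, center, rad)
            # confine generated spots to the footprint so the background
            # reference stays intact (keeps the truth index closed-form)
            inside = footprint[rr, cc]
            rr, cc = rr[inside], cc[inside]
            new = ~degraded[rr, cc]
            deficit = target - int((degraded & footprint).sum())
            if int(new.sum()) > deficit:
                # trim the final spot: drop its outermost new pixels
                d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
                cand = np.nonzero(new)[0]
                keep = cand[np.argsort(d2[cand])[:deficit]]
                sel = np.zeros(len(rr), dtype=bool)
                sel[keep] = True
                sel |= ~new  # previously degraded pixels stay degraded
                rr, cc = rr[sel], cc[sel]
            degraded[rr, cc] = True
            depth_map[rr, cc] = np.maximum(depth_map[rr, cc], params.depth)
            spots.append((center[0], center[1], rad, params.depth))

    expected = params.matrix_level * (1.0 - depth_map)
    if params.noise_sigma > 0:
        rng_noise = substream(params.seed, "noise")
        expected = np.clip(
            expected + rng_noise.normal(0.0, params.noise_sigma, size=expected.shape),
            0.0,
            None,
        )

    cell_mean = float((params.matrix_level * (1.0 - depth_map))[footprint].mean())
    truth = MatrixGroundTruth(
        degradation_map=depth_map,
        footprint=footprint,
        degraded_fraction=float((depth_map[footprint] > 0).mean()),
        spots=spots,
        matrix_level=params.matrix_level,
        cell_mean=cell_mean,
        background_mean=params.matrix_level,
        degradation_index=params.matrix_level / cell_mean if cell_mean > 0 else np.inf,
        seed=params.seed,
    )
    raster = Raster(expected, pixel_size_um=params.pixel_size_um, bit_depth=32)
    return raster, Mask(footprint.astype(np.uint8)), truth


# ---------------------------------------------------------------- puncta


def make_puncta_scene(
    params: PunctaSceneParams,
) -> tuple[Raster, Mask, PunctaGroundTruth]:
    """Gaussian-profile puncta inside an elliptical cell region.

    A punctum of radius r contributes ``peak * exp(-d^2/(2 s^2))`` with
    ``s = r/sqrt(2)`` so its scale-normalized LoG response peaks at
    sigma = r/sqrt(2).  Placement rejects candidates closer than
    ``min_separation_px`` to an accepted punctum unless overlap is allowed.
    """
    cell = _ellipse_mask(params.shape, params.center, params.axes, params.orientation_rad)
    rng_place = substream(params.seed, "placement")

    margin = params.radius_px[1] * 3.0
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    rows, cols = np.nonzero(cell)
    attempts = 0
    max_attempts = 500 * max(params.n_puncta, 1)
    while len(centers) < params.n_puncta:
        attempts += 1
        if attempts > max_attempts:
            raise PlacementError(
                f"placed only {len(centers)}/{params.n_puncta} puncta "
                f"after {max_attempts} attempts"
            )
        i = rng_place.integers(len(rows))
        cand = (
            rows[i] + rng_place.uniform(-0.5, 0.5),
            cols[i] + rng_place.uniform(-0.5, 0.5),
        )
        if not (
            margin <= cand[0] <= params.shape[0] - 1 - margin
            and margin <= cand[1] <= params.shape[1] - 1 - margin
        ):
            continue
        if not params.allow_overlap and any(
            (cand[0] - r0) ** 2 + (cand[1] - c0) ** 2 < params.min_separation_px**2
            for r0, c0 in centers
        ):
            continue
        centers.append(cand)
        radii.append(float(rng_place.uniform(*params.radius_px)))

    rr, cc = np.mgrid[0 : params.shape[0], 0 : params.shape[1]]
    img = np.full(params.shape, params.background_level, dtype=np.float64)
    if params.gradient_amplitude > 0:
        img += params.gradient_amplitude * (cc / max(params.shape[1] - 1, 1))
    for (r0, c0), rad in zip(centers, radii):
        s2 = (rad / np.sqrt(2.0)) ** 2
        img += params.peak_intensity * np.exp(
            -((rr - r0) ** 2 + (cc - c0) ** 2) / (2.0 * s2)
        )
    if params.noise_sigma > 0:
        rng_noise = substream(params.seed, "noise")
        img = np.clip(
            img + rng_noise.normal(0.0, params.noise_sigma, size=img.shape), 0.0, None
        )

    radii_arr = np.asarray(radii, dtype=np.float64)
    truth = PunctaGroundTruth(
        centers=np.asarray(centers, dtype=np.float64).reshape(-1, 2),
        radii=radii_arr,
        areas_px=np.pi * radii_arr**2,
        peak_intensity=params.peak_intensity,
        background_level=params.background_level,
        seed=params.seed,
    )
    raster = Raster(img, pixel_size_um=params.pixel_size_um, bit_depth=32)
    return raster, Mask(cell.astype(np.uint8)), truth


# ---------------------------------------------------------------- tracks


def make_track_set(params: MotilitySceneParams) -> tuple[TrackTable, TrackGroundTruth]:
    """Persistent random walks sampled at the frame interval.

    The heading evolves by wrapped-Gaussian turns with standard deviation
    chosen so E[cos(turn)] equals ``persistence``; the step length is fixed
    within a track.  Ground truth records the noiseless total path, net
    displacement and speed (total / elapsed time) per track.
    """
    p = params
    sigma_turn = 0.0 if p.persistence >= 1.0 else (
        np.inf if p.persistence <= 0.0 else np.sqrt(-2.0 * np.log(p.persistence))
    )
    rows = []
    truth_rows = []
    duration_min = (p.n_frames - 1) * p.frame_interval_min
    for tid in range(p.n_cells):
        rng = substream(p.seed, "walk", str(tid))
        pos = rng.uniform(0.0, p.field_um, size=2)
        heading = rng.uniform(0.0, 2.0 * np.pi)
        path = [pos.copy()]
        for _ in range(p.n_frames - 1):
            if np.isinf(sigma_turn):
                heading = rng.uniform(0.0, 2.0 * np.pi)
            elif sigma_turn > 0:
                heading += rng.normal(0.0, sigma_turn)
            pos = pos + p.step_len_um * np.array([np.cos(heading), np.sin(heading)])
            path.append(pos.copy())
        path = np.asarray(path)
        steps = np.linalg.norm(np.diff(path, axis=0), axis=1)
        total = float(steps.sum())
        net = float(np.linalg.norm(path[-1] - path[0]))
        truth_rows.append(
            {
                "track_id": tid,
                "total_path_um": total,
                "net_um": net,
                "speed_um_min": total / duration_min,
            }
        )
        observed = path
        if p.noise_sigma_um > 0:
            rng_noise = substream(p.seed, "locnoise", str(tid))
            observed = path + rng_noise.normal(0.0, p.noise_sigma_um, size=path.shape)
        for f, (x, y) in enumerate(observed):
            rows.append({"track_id": tid, "frame": f, "x": x, "y": y})

    table = TrackTable(pd.DataFrame(rows), frame_interval_min=p.frame_interval_min)
    truth = TrackGroundTruth(
        per_track=pd.DataFrame(truth_rows),
        step_len_um=p.step_len_um,
        persistence=p.persistence,
        frame_interval_min=p.frame_interval_min,
        seed=p.seed,
    )
    return table, truth


# ---------------------------------------------------------------- wound


def make_wound_series(params: WoundSceneParams) -> tuple[list[Mask], WoundGroundTruth]:
    """Monolayer masks (1 = cells) with a vertical cell-free wound band.

    The wound width follows ``w(t) = max(0, w0 - rate * t)``.  Edge
    roughness is a smoothed per-row offset pattern, fixed across frames so
    both edges recede uniformly as the wound closes.
    """
    p = params
    n_rows, n_cols = p.shape
    rng = substream(p.seed, "edges")
    if p.roughness_um > 0:
        from scipy.ndimage import gaussian_filter1d

        def rough_edge() -> np.ndarray:
            raw = rng.normal(0.0, 1.0, size=n_rows)
            sm = gaussian_filter1d(raw, sigma=5.0, mode="wrap")
            sm = sm / sm.std() * (p.roughness_um / p.pixel_size_um)
            return sm - sm.mean()  # zero-mean so the mean width stays nominal

        off_left, off_right = rough_edge(), rough_edge()
    else:
        off_left = off_right = np.zeros(n_rows)

    center_col = n_cols / 2.0
    masks: list[Mask] = []
    nominal: list[float] = []
    raster_means: list[float] = []
    cols = np.arange(n_cols)
    for t in p.frame_times_hr:
        w_um = max(0.0, p.initial_width_um - p.closure_rate_um_hr * t)
        half_px = w_um / p.pixel_size_um / 2.0
        left = center_col - half_px + off_left
        right = center_col + half_px + off_right
        # a fully closed wound has no 0 pixels at all
        wound = (cols[None, :] >= left[:, None]) & (cols[None, :] < right[:, None])
        if w_um <= 0:
            wound[:] = False
        mask = np.ones(p.shape, dtype=np.uint8)
        mask[wound] = 0
        masks.append(Mask(mask))
        nominal.append(w_um)
        raster_means.append(float(wound.sum(axis=1).mean()) * p.pixel_size_um)

    truth = WoundGroundTruth(
        frame_times_hr=tuple(p.frame_times_hr),
        nominal_width_um=nominal,
        rasterized_mean_width_um=raster_means,
        closure_rate_um_hr=p.closure_rate_um_hr,
        seed=p.seed,
    )
    return masks, truth


# ---------------------------------------------------------------- cytometry


def make_cytometry_events(
    params: CytometrySimParams, mode: str = "cellcycle"
) -> tuple[pd.DataFrame, CytometryGroundTruth]:
    """Simulate flow-cytometry event tables.

    mode="cellcycle": one ``pi`` column; G0/G1 and G2/M are lognormal peaks
    at the 2n and 4n positions with the stated CV, S is a uniform bridge
    between the peak gate margins.

    mode="annexin": ``annexin``/``pi`` columns; live, early-apoptotic and
    necrotic clusters are bivariate lognormal, separated by
    ``separation_decades`` in the positive channel(s).
    """
    p = params
    rng = substream(p.seed, "sampling", mode)
    if mode == "cellcycle":
        names = ("g0g1", "s", "g2m")
        labels = rng.choice(3, size=p.n_events, p=list(p.fractions))
        sigma_ln = np.sqrt(np.log1p(p.cv**2))
        pos2n, pos4n = p.peak_2n, 2.0 * p.peak_2n
        values = np.empty(p.n_events)
        n0 = int((labels == 0).sum())
        n2 = int((labels == 2).sum())
        values[labels == 0] = pos2n * rng.lognormal(-0.5 * sigma_ln**2, sigma_ln, n0)
        values[labels == 2] = pos4n * rng.lognormal(-0.5 * sigma_ln**2, sigma_ln, n2)
        lo = pos2n * (1.0 + p.s_margin_k * p.cv)
        hi = pos4n * (1.0 - p.s_margin_k * p.cv)
        values[labels == 1] = rng.uniform(lo, hi, int((labels == 1).sum()))
        events = pd.DataFrame({"pi": values})
        fractions = p.fractions
        peak = p.peak_2n
    elif mode == "annexin":
        names = ("live", "early_apoptotic", "necrotic")
        labels = rng.choice(3, size=p.n_events, p=list(p.apoptosis_fractions))
        lo_dec, hi_dec = 0.0, p.separation_decades
        centers = {0: (lo_dec, lo_dec), 1: (hi_dec, lo_dec), 2: (hi_dec, hi_dec)}
        ann = np.empty(p.n_events)
        pi = np.empty(p.n_events)
        for k, (ca, cp) in centers.items():
            n = int((labels == k).sum())
            ann[labels == k] = 10.0 ** rng.normal(ca, p.log_spread_decades, n)
            pi[labels == k] = 10.0 ** rng.normal(cp, p.log_spread_decades, n)
        events = pd.DataFrame({"annexin": ann, "pi": pi})
        fractions = p.apoptosis_fractions
        peak = None
    else:
        raise ValueError(f"unknown cytometry mode {mode!r}")

    emp = tuple(float((labels == k).mean()) for k in range(3))
    truth = CytometryGroundTruth(
        labels=labels,
        class_names=names,
        fractions=fractions,
        empirical_fractions=emp,
        peak_2n=peak,
        seed=p.seed,
    )
    return events, truth


# ---------------------------------------------------------------- gels


def make_gel_lanes(
    band_intensities: list[float],
    loading_intensities: list[float],
    noise_cv: float = 0.0,
    seed: int = 0,
    lane_labels: list[str] | None = None,
) -> tuple[pd.DataFrame, GelGroundTruth]:
    """Densitometry table: lane -> (band, loading) with multiplicative noise.

    Truth records the noiseless band/loading values and their loading-
    normalized fold change relative to the first lane.
    """
    band = np.asarray(band_intensities, dtype=np.float64)
    load = np.asarray(loading_intensities, dtype=np.float64)
    if band.shape != load.shape or band.ndim != 1:
        raise ValueError("band and loading lists must have equal length")
    if np.any(band <= 0) or np.any(load <= 0):
        raise ValueError("intensities must be positive")
    labels = lane_labels or [f"lane{i}" for i in range(len(band))]
    if len(labels) != len(band):
        raise ValueError("lane_labels length mismatch")

    rng = substream(seed, "gelnoise")
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        band_obs = band * rng.lognormal(-0.5 * sigma**2, sigma, band.shape)
        load_obs = load * rng.lognormal(-0.5 * sigma**2, sigma, load.shape)
    else:
        band_obs, load_obs = band.copy(), load.copy()

    table = pd.DataFrame({"lane": labels, "band": band_obs, "loading": load_obs})
    normalized = band / load
    truth = GelGroundTruth(
        lanes=list(labels),
        band_true=band,
        loading_true=load,
        normalized_true=normalized,
        fold_vs_first=normalized / normalized[0],
        seed=seed,
    )
    return table, truth
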