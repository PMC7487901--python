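"""Wound-width measurement and single-cell track statistics.

Wound widths are read at 11 evenly spaced rows by convention (the protocol
says "11 different points" without placement); closure rate uses only the
first and last frames.  Track speed is total path length divided by the
elapsed time between first and last frames, unsmoothed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..img_io import Mask, TrackTable


@dataclass
class WoundMeasurement:
    widths_um: list[float]
    flags_no_wound: list[bool]

    @property
    def mean_width_um(self) -> float:
        return float(np.mean(self.widths_um))


@dataclass
class TrackStats:
    track_id: int
    total_path_um: float
    net_um: float
    duration_min: float
    speed_um_min: float


def wound_widths(
    wound_mask: Mask,
    n_lines: int = 11,
    pixel_size_um: float = 1.0,
    horizontal: bool = False,
) -> WoundMeasurement:
    """Widths of the cell-free (0) band at ``n_lines`` evenly spaced lines.

    The wound is assumed to span the image vertically (set ``horizontal``
    to transpose).  On each sampled row the width is the longest contiguous
    run of 0 pixels; a row with no wound pixels yields width 0 and a flag.
    """
    px = wound_mask.pixels
    if horizontal:
        px = px.T
    n_rows = px.shape[0]
    rows = np.unique(np.round(np.linspace(0, n_rows - 1, n_lines)).astype(int))
    widths: list[float] = []
    flags: list[bool] = []
    for r in rows:
        line = px[r] == 0
        if not line.any():
            widths.append(0.0)
            flags.append(True)
            continue
        # longest contiguous zero-run
        edges = np.diff(np.concatenate([[0], line.view(np.int8), [0]]))
        starts = np.nonzero(edges == 1)[0]
        ends = np.nonzero(edges == -1)[0]
        widths.append(float((ends - starts).max()) * pixel_size_um)
        flags.append(False)
    return WoundMeasurement(widths, flags)


def closure_rate(
    widths_t0: WoundMeasurement | list[float],
    widths_t1: WoundMeasurement | list[float],
    elapsed_hr: float,
) -> float:
    """(mean width at t0 − mean width at t1) / elapsed hours; may be negative."""
    if elapsed_hr <= 0:
        raise ValueError("elapsed_hr must be positive")
    w0 = widths_t0.widths_um if isinstance(widths_t0, WoundMeasurement) else widths_t0
    w1 = widths_t1.widths_um if isinstance(widths_t1, WoundMeasurement) else widths_t1
    return float((np.mean(w0) - np.mean(w1)) / elapsed_hr)


def track_stats(
    track: pd.DataFrame, frame_interval_min: float, subsample_k: int = 1
) -> TrackStats:
    """Path statistics of one track (columns frame, x, y; positions in μm).

    total = sum of consecutive Euclidean steps, net = first-to-last
    distance, speed = total / elapsed minutes.  ``subsample_k`` keeps every
    k-th frame before measuring, which reduces the upward speed bias caused
    by localization noise.
    """
    if len(track) < 2:
        raise ValueError("track needs at least 2 points")
    if subsample_k < 1:
        raise ValueError("subsample_k must be >= 1")
    t = track.sort_values("frame")
    if subsample_k > 1:
        keep = np.zeros(len(t), dtype=bool)
        keep[::subsample_k] = True
        keep[-1] = True  # always retain the endpoint
        t = t[keep]
    xy = t[["x", "y"]].to_numpy(dtype=float)
    steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    total = float(steps.sum())
    net = float(np.linalg.norm(xy[-1] - xy[0]))
    frames = t["frame"].to_numpy()
    duration = float((frames[-1] - frames[0]) * frame_interval_min)
    tid = int(track["track_id"].iloc[0]) if "track_id" in track.columns else -1
    return TrackStats(tid, total, net, duration, total / duration)


def cohort_speed(
    tracks: TrackTable, subsample_k: int = 1
) -> tuple[float, pd.DataFrame]:
    """Arithmetic mean of per-track speeds plus the per-track table."""
    if tracks.n_tracks < 1:
        raise ValueError("need at least one track")
    rows = []
    for tid in tracks.track_ids:
        st = track_stats(tracks.track(tid), tracks.frame_interval_min, subsample_k)
        rows.append(
            {
                "track_id": tid,
                "total_path_um": st.total_path_um,
                "net_um": st.net_um,
                "duration_min": st.duration_min,
                "speed_um_min": st.speed_um_min,
            }
        )
    table = pd.DataFrame(rows)
    return float(table["speed_um_min"].mean()), table


def link_detections(
    frames: list[np.ndarray],
    max_step_um: float,
    frame_interval_min: float = 1.0,
) -> TrackTable:
    """Greedy nearest-neighbour linking of per-frame centroid lists.

    ``frames[i]`` is an (n_i, 2) array of (x, y) positions in μm.  Each
    active track claims its nearest detection within ``max_step_um``
    (closest pairs first); unclaimed detections start new tracks.
    """
    if max_step_um <= 0:
        raise ValueError("max_step_um must be positive")
    rows: list[dict] = []
    active: dict[int, np.ndarray] = {}
    next_id = 0
    for f, dets in enumerate(frames):
        dets = np.asarray(dets, dtype=float).reshape(-1, 2)
        claimed = np.zeros(len(dets), dtype=bool)
        new_active: dict[int, np.ndarray] = {}
        if active and len(dets):
            tids = list(active)
            prev = np.array([active[t] for t in tids])
            d = np.linalg.norm(prev[:, None, :] - dets[None, :, :], axis=2)
            pairs = sorted(
                ((d[i, j], i, j) for i in range(len(tids)) for j in range(len(dets))),
            )
            used_tracks: set[int] = set()
            for dist, i, j in pairs:
                if dist > max_step_um:
                    break
                if i in used_tracks or claimed[j]:
                    continue
                used_tracks.add(i)
                claimed[j] = True
                new_active[tids[i]] = dets[j]
                rows.append(
                    {"track_id": tids[i], "frame": f, "x": dets[j, 0], "y": dets[j, 1]}
                )
        for j in np.nonzero(~claimed)[0]:
            new_active[next_id] = dets[j]
            rows.append({"track_id": next_id, "frame": f, "x": dets[j, 0], "y": dets[j, 1]})
            next_id += 1
        active = new_active
    df = pd.DataFrame(rows, columns=["track_id", "frame", "x", "y"])
    return TrackTable(df, frame_interval_min)
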