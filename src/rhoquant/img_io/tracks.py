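"""CSV track-table I/O (columns: track_id, frame, x, y; units μm)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .types import TRACK_COLUMNS, TrackTable


def read_tracks(path: str | Path, frame_interval_min: float) -> TrackTable:
    """Read a track CSV, validating uniqueness and frame monotonicity.

    Frames within a track must be strictly increasing after sorting; a
    duplicate (track_id, frame) pair raises ``ValueError``.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"track CSV missing columns {missing}")
    return TrackTable(df[TRACK_COLUMNS], frame_interval_min)


def write_tracks(table: TrackTable, path: str | Path) -> Path:
    path = Path(path)
    table.data.to_csv(path, index=False)
    return path
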