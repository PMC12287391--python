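"""Fixed-length time-window segmentation of actigraphy recordings.

Recordings are cut into windows of 180 / 60 / 20 minutes (3 h, 1 h,
20 min) by default; combining several window sizes augments the dataset.
Windows are tiled from the recording's first epoch (optionally aligned to
midnight), with stride equal to the window by default (non-overlapping).
Gap epochs inside a kept window are filled with zero ("no movement");
windows whose gap fraction exceeds ``max_gap_fraction`` are dropped and
counted.  Every segment inherits its participant's diagnosis label.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ActigraphyRecording, CohortManifest, Group

logger = logging.getLogger("acti2img")

DEFAULT_WINDOWS = (180, 60, 20)


@dataclass
class Segment:
    """A contiguous fixed-length sub-series with provenance."""

    participant_id: str
    group: Group
    start_index: int  # 0-based epoch index on the recording's minute grid
    window_minutes: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.window_minutes < 2:
            raise ValueError("window_minutes must be >= 2")
        if self.values.size != self.window_minutes:
            raise ValueError(
                f"segment has {self.values.size} values, "
                f"expected {self.window_minutes}"
            )
        if np.any(self.values < 0):
            raise ValueError("segment values must be non-negative")

    @property
    def label(self) -> int:
        """Binary label: condition = 1, control = 0."""
        return int(self.group is Group.CONDITION)


def _minute_grid(
    rec: ActigraphyRecording, align: str
) -> tuple[np.ndarray, np.ndarray]:
    """Counts on a complete minute grid; missing epochs flagged as gaps."""
    start = pd.Timestamp(rec.timestamps[0])
    if align == "midnight":
        start = start.normalize()
    elif align != "start":
        raise ValueError(f"unknown alignment {align!r}")
    end = pd.Timestamp(rec.timestamps[-1])
    grid = pd.date_range(start, end, freq="min")
    series = pd.Series(rec.counts, index=pd.DatetimeIndex(rec.timestamps))
    on_grid = series.reindex(grid)
    missing = on_grid.isna().to_numpy()
    values = on_grid.fillna(0).to_numpy().astype(np.int64)
    return values, missing


def segment_recording(
    rec: ActigraphyRecording,
    window_minutes: int,
    stride_minutes: int | None = None,
    max_gap_fraction: float = 0.1,
    align: str = "start",
) -> list[Segment]:
    """Cut one recording into fixed-length windows.

    A window longer than the recording yields an empty list with a warning.
    Trailing epochs that do not fill a whole window are dropped.  Windows
    with too many gap epochs are dropped (count logged); gaps inside kept
    windows are zero-filled.
    """
    if window_minutes < 2:
        raise ValueError("window_minutes must be >= 2")
    stride = window_minutes if stride_minutes is None else int(stride_minutes)
    if stride < 1:
        raise ValueError("stride_minutes must be >= 1")
    values, missing = _minute_grid(rec, align)
    n = values.size
    if window_minutes > n:
        warnings.warn(
            f"recording {rec.participant_id!r} ({n} epochs) shorter than "
            f"window {window_minutes}; no segments produced",
            stacklevel=2,
        )
        return []
    segments: list[Segment] = []
    dropped = 0
    for start in range(0, n - window_minutes + 1, stride):
        stop = start + window_minutes
        gap_fraction = float(missing[start:stop].mean())
        if gap_fraction > max_gap_fraction:
            dropped += 1
            continue
        segments.append(
            Segment(
                participant_id=rec.participant_id,
                group=rec.group,
                start_index=start,
                window_minutes=window_minutes,
                values=values[start:stop],
            )
        )
    if dropped:
        logger.info(
            "recording %s: dropped %d window(s) of %d min exceeding gap "
            "fraction %.2f",
            rec.participant_id,
            dropped,
            window_minutes,
            max_gap_fraction,
        )
    return segments


def build_multiwindow_dataset(
    cohort: CohortManifest,
    windows: list[int] | tuple[int, ...] = DEFAULT_WINDOWS,
    stride_minutes: int | None = None,
    max_gap_fraction: float = 0.1,
    align: str = "start",
) -> list[Segment]:
    """Segment every recording at every window size and concatenate.

    Per-segment provenance (participant, window size, start index) is
    retained, so the augmented dataset can be audited per window size.
    """
    if not windows:
        raise ValueError("windows must be non-empty")
    out: list[Segment] = []
    for rec in cohort.recordings:
        for window in windows:
            out.extend(
                segment_recording(
                    rec,
                    window,
                    stride_minutes=stride_minutes,
                    max_gap_fraction=max_gap_fraction,
                    align=align,
                )
            )
    return out


def segments_to_frame(segments: list[Segment]) -> pd.DataFrame:
    """Columnar view of segments (values serialized as JSON-ready lists)."""
    return pd.DataFrame(
        {
            "participant_id": [s.participant_id for s in segments],
            "group": [s.group.value for s in segments],
            "start_index": [s.start_index for s in segments],
            "window_minutes": [s.window_minutes for s in segments],
            "values": [s.values.tolist() for s in segments],
        }
    )
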