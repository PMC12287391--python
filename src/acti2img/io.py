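"""Reading, validating and writing minute-epoch actigraphy recordings.

The on-disk dialect follows the public Depresjon and Psykose repositories:
one CSV per participant with a header row containing at least ``timestamp``
and ``activity`` columns (``date`` optional), comma-separated, timestamps as
``YYYY-MM-DD HH:MM[:SS]`` in timezone-naive local time.  Activity is a
non-negative integer count per one-minute epoch.  Gaps in the minute grid
are allowed; they are detected and logged, never imputed, so that I/O stays
lossless and segmentation can decide how to treat them.
"""

from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("acti2img")

EPOCH_SECONDS = 60


class ActigraphyError(Exception):
    """Base class for actigraphy I/O errors."""


class FormatError(ActigraphyError):
    """A file violates the expected CSV dialect or value constraints."""


class EmptyInputError(ActigraphyError):
    """A file or cohort contains no usable rows."""


class ManifestError(ActigraphyError):
    """A cohort manifest is inconsistent (duplicate ids, missing files...)."""


class Group(str, enum.Enum):
    """Diagnostic group of a participant."""

    CONDITION = "condition"
    CONTROL = "control"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @classmethod
    def coerce(cls, value: "Group | str") -> "Group":
        if isinstance(value, Group):
            return value
        try:
            return cls(str(value).strip().lower())
        except ValueError as exc:
            raise ValueError(
                f"group must be 'condition' or 'control', got {value!r}"
            ) from exc


@dataclass
class ActigraphyRecording:
    """One participant's minute-epoch activity-count series.

    Attributes
    ----------
    participant_id:
        Unique identifier of the participant.
    group:
        Diagnostic group (:class:`Group`).
    timestamps:
        Strictly increasing minute-resolution ``datetime64[s]`` array.
    counts:
        Non-negative integer activity counts, one per timestamp.
    gap_indices:
        Positions ``i`` where ``timestamps[i+1] - timestamps[i]`` exceeds the
        nominal 60 s epoch (a gap follows row ``i``).
    """

    participant_id: str
    group: Group
    timestamps: np.ndarray
    counts: np.ndarray
    gap_indices: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.group = Group.coerce(self.group)
        self.timestamps = np.asarray(self.timestamps, dtype="datetime64[s]")
        counts = np.asarray(self.counts)
        if counts.size == 0 or self.timestamps.size == 0:
            raise EmptyInputError(
                f"recording {self.participant_id!r} has no samples"
            )
        if counts.shape != self.timestamps.shape:
            raise FormatError(
                f"recording {self.participant_id!r}: {counts.size} counts "
                f"but {self.timestamps.size} timestamps"
            )
        as_float = counts.astype(np.float64)
        if not np.all(np.isfinite(as_float)):
            raise FormatError(
                f"recording {self.participant_id!r}: non-finite activity value"
            )
        if np.any(as_float < 0):
            raise FormatError(
                f"recording {self.participant_id!r}: negative activity value"
            )
        if np.any(as_float != np.floor(as_float)):
            raise FormatError(
                f"recording {self.participant_id!r}: non-integer activity value"
            )
        self.counts = as_float.astype(np.int64)
        deltas = np.diff(self.timestamps).astype("timedelta64[s]").astype(np.int64)
        if np.any(deltas <= 0):
            bad = int(np.argmax(deltas <= 0))
            raise FormatError(
                f"recording {self.participant_id!r}: timestamps not strictly "
                f"increasing at row {bad + 1}"
            )
        self.gap_indices = np.flatnonzero(deltas > EPOCH_SECONDS)
        if self.gap_indices.size:
            logger.info(
                "recording %s: %d gap(s) in the minute grid at rows %s",
                self.participant_id,
                self.gap_indices.size,
                self.gap_indices.tolist(),
            )

    def __len__(self) -> int:
        return int(self.counts.size)

    @property
    def n_gaps(self) -> int:
        return int(self.gap_indices.size)


@dataclass
class CohortManifest:
    """A validated collection of recordings with unique participant ids."""

    recordings: list[ActigraphyRecording]

    def __post_init__(self) -> None:
        if not self.recordings:
            raise ManifestError("cohort is empty")
        ids = [r.participant_id for r in self.recordings]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ManifestError(f"duplicate participant ids: {sorted(dupes)}")

    @property
    def label_map(self) -> dict[str, Group]:
        return {r.participant_id: r.group for r in self.recordings}

    def group_counts(self) -> dict[str, int]:
        out = {Group.CONDITION.value: 0, Group.CONTROL.value: 0}
        for r in self.recordings:
            out[r.group.value] += 1
        return out

    def __len__(self) -> int:
        return len(self.recordings)

    def __iter__(self) -> Iterable[ActigraphyRecording]:
        return iter(self.recordings)


def _parse_timestamps(raw: pd.Series, path: Path) -> np.ndarray:
    parsed = pd.to_datetime(raw, format="mixed", errors="coerce")
    bad = parsed.isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise FormatError(
            f"{path}: unparseable timestamp {raw.iloc[row]!r} at data row {row + 1}"
        )
    return parsed.to_numpy().astype("datetime64[s]")


def read_recording(
    path: str | Path,
    participant_id: str | None = None,
    group: Group | str = Group.CONTROL,
) -> ActigraphyRecording:
    """Read one participant CSV into a validated :class:`ActigraphyRecording`.

    ``participant_id`` defaults to the file stem.  Raises
    :class:`FormatError` on missing columns, unparseable timestamps or
    negative/non-integer activity values, and :class:`EmptyInputError` on a
    file with no data rows.  Gap positions are recorded on the returned
    object and logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path}: empty file") from exc
    frame.columns = [str(c).strip().lower() for c in frame.columns]
    missing = {"timestamp", "activity"} - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    if len(frame) == 0:
        raise EmptyInputError(f"{path}: no data rows")
    activity = pd.to_numeric(frame["activity"], errors="coerce")
    if activity.isna().any():
        row = int(np.flatnonzero(activity.isna().to_numpy())[0])
        raise FormatError(
            f"{path}: non-numeric activity {frame['activity'].iloc[row]!r} "
            f"at data row {row + 1}"
        )
    timestamps = _parse_timestamps(frame["timestamp"], path)
    return ActigraphyRecording(
        participant_id=participant_id or path.stem,
        group=Group.coerce(group),
        timestamps=timestamps,
        counts=activity.to_numpy(),
    )


def write_recording(rec: ActigraphyRecording, path: str | Path) -> Path:
    """Write a recording back to the CSV dialect (lossless round-trip)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    stamps = pd.DatetimeIndex(rec.timestamps)
    frame = pd.DataFrame(
        {
            "timestamp": stamps.strftime("%Y-%m-%d %H:%M:%S"),
            "date": stamps.strftime("%Y-%m-%d"),
            "activity": rec.counts,
        }
    )
    frame.to_csv(path, index=False)
    return path


_LAYOUT_SUBDIRS = {
    # subdirectory name -> group, per public dataset layout
    "depresjon_like": {"condition": Group.CONDITION, "control": Group.CONTROL},
    "psykose_like": {"patient": Group.CONDITION, "control": Group.CONTROL},
}


def load_cohort(
    root: str | Path, layout: str = "depresjon_like"
) -> CohortManifest:
    """Load a cohort from a directory tree or an explicit manifest file.

    ``layout`` is one of ``depresjon_like`` (``condition/`` + ``control/``
    subdirectories), ``psykose_like`` (``patient/`` + ``control/``) or
    ``manifest_file`` (``root`` is a YAML/JSON file listing
    ``{participant_id, path, group}`` entries; relative paths resolve
    against the manifest's directory).
    """
    root = Path(root)
    recordings: list[ActigraphyRecording] = []
    if layout == "manifest_file":
        if not root.is_file():
            raise ManifestError(f"manifest file not found: {root}")
        text = root.read_text()
        entries = (
            json.loads(text) if root.suffix == ".json" else yaml.safe_load(text)
        )
        if not entries:
            raise ManifestError(f"{root}: empty manifest")
        for entry in entries:
            csv_path = Path(entry["path"])
            if not csv_path.is_absolute():
                csv_path = root.parent / csv_path
            if not csv_path.exists():
                raise ManifestError(f"{root}: listed file does not exist: {csv_path}")
            recordings.append(
                read_recording(
                    csv_path,
                    participant_id=entry.get("participant_id"),
                    group=entry["group"],
                )
            )
    elif layout in _LAYOUT_SUBDIRS:
        for subdir, grp in _LAYOUT_SUBDIRS[layout].items():
            folder = root / subdir
            if not folder.is_dir():
                continue
            for csv_path in sorted(folder.glob("*.csv")):
                recordings.append(read_recording(csv_path, group=grp))
    else:
        raise ValueError(f"unknown cohort layout {layout!r}")
    return CohortManifest(recordings)


def write_cohort(
    manifest: CohortManifest,
    root: str | Path,
    layout: str = "depresjon_like",
) -> Path:
    """Write every recording as CSV under ``root`` plus a YAML manifest.

    Returns the path of the written manifest file.
    """
    root = Path(root)
    subdir_of = {g: name for name, g in _LAYOUT_SUBDIRS[layout].items()}
    entries = []
    for rec in manifest.recordings:
        rel = Path(subdir_of[rec.group]) / f"{rec.participant_id}.csv"
        write_recording(rec, root / rel)
        entries.append(
            {
                "participant_id": rec.participant_id,
                "path": str(rel),
                "group": rec.group.value,
            }
        )
    manifest_path = root / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(entries, sort_keys=False))
    return manifest_path
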