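"""Readers/writers for trajectory tables, intensity traces and result records.

Trajectory CSV dialect
----------------------
Comma-separated UTF-8 with header ``track_id,frame,x_um,y_um``; frame indices
are 0-based integers and coordinates are in micrometers.  Metadata travels in
``# key = value`` comment lines before the header (``frame_interval_s``,
optionally ``pixel_size_um``).  Files exported in pixel units can be converted
on read by passing ``pixel_size`` (the multiplier to micrometers).

Gaps (missing frames inside a track) are permitted on input and recorded in
the log; downstream residence analysis treats a gap as breaking a static
interval.  Native tracker formats (MTrackJ ``.mdf``, u-track ``.mat``,
TrackMate XML) are not parsed — export/convert to this CSV dialect first.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError, InsufficientDataError

logger = logging.getLogger(__name__)

__all__ = [
    "Trajectory",
    "TrackSet",
    "FrapTrace",
    "OscillationTrace",
    "read_tracks_csv",
    "write_tracks_csv",
    "read_frap_csv",
    "write_frap_csv",
    "read_oscillation_csv",
    "write_oscillation_csv",
    "write_results_json",
]


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Time-ordered 2D localizations of one molecule.

    Parameters
    ----------
    track_id : str
        Unique identifier within a :class:`TrackSet`.
    frames : ndarray of int
        0-based frame indices, strictly increasing.  Consecutive indices may
        skip values (a gap); gap-aware consumers must check ``frames``.
    x, y : ndarray of float
        Coordinates in micrometers.
    frame_interval : float
        Seconds between consecutive frame indices.
    """

    track_id: str
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    frame_interval: float

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.frames) == len(self.x) == len(self.y)):
            raise FormatError(f"track {self.track_id}: column lengths differ")
        if len(self.frames) < 2:
            raise FormatError(f"track {self.track_id}: needs >= 2 points")
        if np.any(np.diff(self.frames) <= 0):
            raise FormatError(f"track {self.track_id}: frames not strictly increasing")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise FormatError(f"track {self.track_id}: non-finite coordinate")
        if self.frame_interval <= 0:
            raise FormatError("frame_interval must be > 0")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def has_gaps(self) -> bool:
        return bool(np.any(np.diff(self.frames) > 1))


@dataclass
class TrackSet:
    """A collection of trajectories acquired at one fixed frame interval."""

    trajectories: list[Trajectory]
    frame_interval: float
    pixel_size: float | None = None  # metadata only, micrometers

    def __post_init__(self):
        ids = [t.track_id for t in self.trajectories]
        if len(set(ids)) != len(ids):
            raise FormatError("track_ids are not unique")
        for t in self.trajectories:
            if not np.isclose(t.frame_interval, self.frame_interval):
                raise FormatError(
                    f"track {t.track_id}: frame_interval differs from set"
                )

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)

    def __getitem__(self, key):
        if isinstance(key, str):
            for t in self.trajectories:
                if t.track_id == key:
                    return t
            raise KeyError(key)
        return self.trajectories[key]


@dataclass
class FrapTrace:
    """A bleach-recovery intensity series with its reference channels.

    ``bleach_index`` is the index of the first post-bleach frame: frames
    ``[0, bleach_index)`` are pre-bleach, frames ``[bleach_index, n)`` carry
    the recovery.
    """

    times: np.ndarray          # seconds
    roi: np.ndarray            # bleached-region intensity
    background: np.ndarray
    control_cell: np.ndarray   # unbleached neighbor cell
    whole_cell: np.ndarray     # whole bleached cell
    bleach_index: int

    def __post_init__(self):
        for name in ("times", "roi", "background", "control_cell", "whole_cell"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.times)
        for name in ("roi", "background", "control_cell", "whole_cell"):
            if len(getattr(self, name)) != n:
                raise FormatError(f"FRAP trace: column {name!r} length mismatch")
        if np.any(np.diff(self.times) <= 0):
            raise FormatError("FRAP trace: times not strictly increasing")
        if not (1 <= self.bleach_index <= n - 3):
            raise InsufficientDataError(
                "FRAP trace needs >= 1 pre-bleach and >= 3 post-bleach points "
                f"(bleach_index={self.bleach_index}, n={n})"
            )

    def __len__(self) -> int:
        return len(self.times)

    @property
    def n_pre(self) -> int:
        return int(self.bleach_index)

    @property
    def n_post(self) -> int:
        return len(self.times) - int(self.bleach_index)


@dataclass
class OscillationTrace:
    """Paired region intensities plus the whole-cell channel."""

    times: np.ndarray
    area1: np.ndarray
    area2: np.ndarray
    whole_cell: np.ndarray

    def __post_init__(self):
        for name in ("times", "area1", "area2", "whole_cell"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.times)
        for name in ("area1", "area2", "whole_cell"):
            if len(getattr(self, name)) != n:
                raise FormatError(f"oscillation trace: column {name!r} length mismatch")
        if np.any(np.diff(self.times) <= 0):
            raise FormatError("oscillation trace: times not strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def _read_metadata(path: Path) -> dict[str, float]:
    """Parse ``# key = value`` comment lines preceding the header."""
    meta: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                try:
                    meta[key.strip()] = float(value.strip())
                except ValueError:
                    pass
    return meta


def _numeric(df: pd.DataFrame, columns: list[str], path) -> pd.DataFrame:
    """Coerce columns to float, naming the first offending cell on failure."""
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise FormatError(
                f"{path}: malformed numeric value {df[col][row]!r} "
                f"in column {col!r}, data row {row}"
            )
        if coerced.isna().any():
            row = int(coerced.isna().idxmax())
            raise FormatError(f"{path}: missing value in column {col!r}, data row {row}")
        df[col] = coerced
    return df


# ---------------------------------------------------------------------------
# Trajectory I/O
# ---------------------------------------------------------------------------

def read_tracks_csv(
    path,
    frame_interval: float | None = None,
    pixel_size: float | None = None,
) -> TrackSet:
    """Read a trajectory CSV into a :class:`TrackSet`.

    Parameters
    ----------
    path : path-like
        CSV file with header ``track_id,frame,x_um,y_um``.
    frame_interval : float, optional
        Seconds per frame; overrides (and is required in the absence of) the
        ``frame_interval_s`` metadata line.
    pixel_size : float, optional
        If the coordinate columns are in pixels, multiply them by this factor
        (micrometers per pixel).  Overrides the ``pixel_size_um`` metadata.

    Raises
    ------
    FormatError
        On duplicate ``(track, frame)`` pairs or frames out of order within a
        track (reported with the offending data row number).
    """
    path = Path(path)
    meta = _read_metadata(path)
    dt = frame_interval if frame_interval is not None else meta.get("frame_interval_s")
    if dt is None:
        raise FormatError(
            f"{path}: no frame interval; add a '# frame_interval_s = ...' "
            "metadata line or pass frame_interval"
        )
    px = pixel_size if pixel_size is not None else meta.get("pixel_size_um")

    df = pd.read_csv(path, comment="#", dtype={"track_id": str},
                     float_precision="round_trip")
    required = ["track_id", "frame", "x_um", "y_um"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    df = _numeric(df, ["frame", "x_um", "y_um"], path)

    scale = px if pixel_size is not None else 1.0
    trajectories = []
    n_rows = 0
    for tid, sub in df.groupby("track_id", sort=False):
        frames = sub["frame"].to_numpy(dtype=int)
        diffs = np.diff(frames)
        if np.any(diffs == 0):
            row = int(sub.index[int(np.argmax(diffs == 0)) + 1])
            raise FormatError(
                f"{path}: duplicate (track, frame) pair for track {tid!r} "
                f"at data row {row}"
            )
        if np.any(diffs < 0):
            row = int(sub.index[int(np.argmax(diffs < 0)) + 1])
            raise FormatError(
                f"{path}: non-monotone frames for track {tid!r} at data row {row}"
            )
        trajectories.append(
            Trajectory(
                track_id=str(tid),
                frames=frames,
                x=sub["x_um"].to_numpy() * scale,
                y=sub["y_um"].to_numpy() * scale,
                frame_interval=dt,
            )
        )
        n_rows += len(sub)
    logger.info("%s: read %d rows into %d tracks", path, n_rows, len(trajectories))
    return TrackSet(trajectories=trajectories, frame_interval=dt, pixel_size=px)


def write_tracks_csv(tracks: TrackSet, path) -> None:
    """Write a :class:`TrackSet` in the package dialect (inverse of read)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# frame_interval_s = {float(tracks.frame_interval)!r}\n")
        if tracks.pixel_size is not None:
            fh.write(f"# pixel_size_um = {float(tracks.pixel_size)!r}\n")
        fh.write("track_id,frame,x_um,y_um\n")
        for t in tracks:
            for f, xi, yi in zip(t.frames, t.x, t.y):
                fh.write(f"{t.track_id},{int(f)},{float(xi)!r},{float(yi)!r}\n")


# ---------------------------------------------------------------------------
# Intensity-trace I/O
# ---------------------------------------------------------------------------

def read_frap_csv(path, bleach_index: int | None = None) -> FrapTrace:
    """Read a FRAP trace CSV (columns ``time_s, roi, background, control_cell,
    whole_cell``).

    Missing optional columns are filled with a flagged default: background
    with zeros, control_cell and whole_cell with ones.  ``bleach_index`` is
    taken from the argument, else from a ``# bleach_index = n`` metadata
    line, else detected as the largest single-frame fractional drop in the
    ROI channel.
    """
    path = Path(path)
    meta = _read_metadata(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if "time_s" not in df.columns or "roi" not in df.columns:
        raise FormatError(f"{path}: required columns 'time_s' and 'roi' not found")
    n = len(df)
    for col, fill in (("background", 0.0), ("control_cell", 1.0), ("whole_cell", 1.0)):
        if col not in df.columns:
            logger.warning("%s: column %r missing, filled with %s", path, col, fill)
            df[col] = fill
    df = _numeric(df, ["time_s", "roi", "background", "control_cell", "whole_cell"], path)

    if bleach_index is None:
        if "bleach_index" in meta:
            bleach_index = int(meta["bleach_index"])
        else:
            roi = df["roi"].to_numpy()
            drops = (roi[:-1] - roi[1:]) / np.maximum(np.abs(roi[:-1]), 1e-30)
            bleach_index = int(np.argmax(drops)) + 1
            logger.info("%s: detected bleach at frame %d", path, bleach_index)
    if n - bleach_index < 4:
        raise InsufficientDataError(
            f"{path}: fewer than 4 post-bleach rows (n={n}, bleach_index={bleach_index})"
        )
    return FrapTrace(
        times=df["time_s"].to_numpy(),
        roi=df["roi"].to_numpy(),
        background=df["background"].to_numpy(),
        control_cell=df["control_cell"].to_numpy(),
        whole_cell=df["whole_cell"].to_numpy(),
        bleach_index=bleach_index,
    )


def write_frap_csv(trace: FrapTrace, path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# bleach_index = {trace.bleach_index}\n")
        fh.write("time_s,roi,background,control_cell,whole_cell\n")
        for row in zip(trace.times, trace.roi, trace.background,
                       trace.control_cell, trace.whole_cell):
            fh.write(",".join(repr(float(v)) for v in row) + "\n")


def read_oscillation_csv(path) -> OscillationTrace:
    """Read a two-area oscillation trace CSV (columns ``time_s, area1, area2,
    whole_cell``)."""
    path = Path(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    required = ["time_s", "area1", "area2", "whole_cell"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    df = _numeric(df, required, path)
    return OscillationTrace(
        times=df["time_s"].to_numpy(),
        area1=df["area1"].to_numpy(),
        area2=df["area2"].to_numpy(),
        whole_cell=df["whole_cell"].to_numpy(),
    )


def write_oscillation_csv(trace: OscillationTrace, path) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("time_s,area1,area2,whole_cell\n")
        for row in zip(trace.times, trace.area1, trace.area2, trace.whole_cell):
            fh.write(",".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# Result records
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_results_json(results, path) -> None:
    """Serialize fit/result dataclasses to JSON with deterministic key order."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_jsonable(results), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_results_json(path):
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
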