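"""Trajectory data model, I/O, blink-gap reindexing and length filtering.

A :class:`Trajectory` is the atom of every computation in this package: one
particle's time-ordered 2D positions (micrometres) with integer frame
indices.  Quantum-dot blinking leaves gaps in the frame sequence; before MSD
analysis trajectories are reindexed onto a continuous frame grid (gaps of at
most :data:`MAX_BLINK_GAP` frames are collapsed, longer gaps mean the track
should have been split upstream by the linker).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Longest blink gap (in frames) across which a track is considered continuous.
MAX_BLINK_GAP = 10

#: Default camera pixel size in micrometres, for pixel-unit inputs.
DEFAULT_PIXEL_SIZE = 0.22

#: Minimum track length (frames) retained for analysis.
MIN_TRACK_LENGTH = 50

CSV_COLUMNS = ["track_id", "frame", "t", "x", "y"]


class TrackDataError(ValueError):
    """Malformed trajectory data (missing columns, non-monotone frames, ...)."""


@dataclass(frozen=True)
class Trajectory:
    """One particle's 2D positions on an integer frame grid.

    Parameters
    ----------
    track_id : str or int
        Identifier, unique within a :class:`TrackSet`.
    frames : ndarray of int
        Strictly increasing 0-based frame indices.
    x, y : ndarray of float
        Coordinates in micrometres.
    dt : float
        Nominal frame interval in seconds.
    t : ndarray of float, optional
        Acquisition times in seconds; rebuilt as ``frames * dt`` when absent.
    gap_frames : tuple of int
        Original frame indices removed by blinking, retained as metadata by
        :func:`reindex_blink_gaps`.
    """

    track_id: object
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    dt: float = 0.1
    t: np.ndarray | None = None
    gap_frames: tuple = field(default_factory=tuple)

    def __post_init__(self):
        frames = np.asarray(self.frames, dtype=np.int64)
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if not (len(frames) == len(x) == len(y)):
            raise TrackDataError(
                f"track {self.track_id}: frames/x/y lengths differ "
                f"({len(frames)}/{len(x)}/{len(y)})"
            )
        if len(frames) < 2:
            raise TrackDataError(f"track {self.track_id}: fewer than 2 points")
        if np.any(np.diff(frames) <= 0):
            raise TrackDataError(
                f"track {self.track_id}: frame indices not strictly increasing"
            )
        if self.dt <= 0:
            raise TrackDataError(f"track {self.track_id}: dt must be positive")
        t = self.t
        t = frames * self.dt if t is None else np.asarray(t, dtype=float)
        for name, arr in (("frames", frames), ("x", x), ("y", y), ("t", t)):
            object.__setattr__(self, name, arr)

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def xy(self) -> np.ndarray:
        """Positions as an (N, 2) array in micrometres."""
        return np.column_stack([self.x, self.y])

    @property
    def is_contiguous(self) -> bool:
        """True when the frame grid has no gaps."""
        return bool(np.all(np.diff(self.frames) == 1))

    def translated(self, dx: float, dy: float) -> "Trajectory":
        return replace(self, x=self.x + dx, y=self.y + dy)

    def rotated(self, angle_rad: float) -> "Trajectory":
        c, s = np.cos(angle_rad), np.sin(angle_rad)
        return replace(self, x=c * self.x - s * self.y, y=s * self.x + c * self.y)


@dataclass
class TrackSet:
    """An ordered collection of trajectories with shared acquisition metadata."""

    tracks: list
    dt: float = 0.1
    loc_sigma: float = 0.025
    source: str = ""

    def __post_init__(self):
        ids = [tr.track_id for tr in self.tracks]
        if len(set(ids)) != len(ids):
            raise TrackDataError("duplicate track_ids in TrackSet")

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)

    def __getitem__(self, i):
        return self.tracks[i]

    def to_dataframe(self) -> pd.DataFrame:
        parts = [
            pd.DataFrame(
                {
                    "track_id": tr.track_id,
                    "frame": tr.frames,
                    "t": tr.t,
                    "x": tr.x,
                    "y": tr.y,
                }
            )
            for tr in self.tracks
        ]
        if not parts:
            return pd.DataFrame(columns=CSV_COLUMNS)
        return pd.concat(parts, ignore_index=True)


def read_tracks(path, units: str = "um", pixel_size: float = DEFAULT_PIXEL_SIZE,
                dt: float = 0.1) -> TrackSet:
    """Read a trajectory table (CSV/TSV) into a :class:`TrackSet`.

    The file must have columns ``track_id, frame, x, y`` (``t`` optional).
    ``units='pixel'`` multiplies coordinates by ``pixel_size`` (default
    0.22 um/px) to obtain micrometres.
    """
    if units not in ("um", "pixel"):
        raise ValueError(f"units must be 'um' or 'pixel', got {units!r}")
    df = pd.read_csv(path, sep=None, engine="python")
    if df.empty and df.columns.size == 0:
        warnings.warn(f"{path}: empty track file", stacklevel=2)
        return TrackSet([], dt=dt, source=str(path))
    missing = [c for c in ("track_id", "frame", "x", "y") if c not in df.columns]
    if missing:
        raise TrackDataError(f"{path}: missing column(s) {', '.join(missing)}")
    return tracks_from_dataframe(df, units=units, pixel_size=pixel_size,
                                 dt=dt, source=str(path))


def tracks_from_dataframe(df: pd.DataFrame, units: str = "um",
                          pixel_size: float = DEFAULT_PIXEL_SIZE,
                          dt: float = 0.1, source: str = "") -> TrackSet:
    """Build a :class:`TrackSet` from a long-format DataFrame."""
    scale = pixel_size if units == "pixel" else 1.0
    tracks = []
    for tid, grp in df.groupby("track_id", sort=False):
        grp = grp.sort_values("frame")
        dup = grp["frame"].duplicated()
        if dup.any():
            logger.warning("track %s: %d duplicate frame(s) dropped", tid, dup.sum())
            grp = grp[~dup]
        frames = grp["frame"].to_numpy(dtype=np.int64)
        if np.any(np.diff(frames) <= 0):
            raise TrackDataError(f"track {tid}: non-monotone frame indices")
        if len(grp) < 2:
            logger.warning("track %s: fewer than 2 points, dropped", tid)
            continue
        t = grp["t"].to_numpy(dtype=float) if "t" in grp.columns else None
        if t is not None and np.any(pd.isna(t)):
            t = None
        tracks.append(
            Trajectory(
                track_id=tid,
                frames=frames,
                x=grp["x"].to_numpy(dtype=float) * scale,
                y=grp["y"].to_numpy(dtype=float) * scale,
                dt=dt,
                t=t,
            )
        )
    if not tracks:
        warnings.warn("no usable tracks found", stacklevel=2)
    return TrackSet(tracks, dt=dt, source=source)


def write_tracks(trackset: TrackSet, path) -> None:
    """Write a TrackSet to CSV with the canonical header."""
    trackset.to_dataframe().to_csv(path, index=False)


def reindex_blink_gaps(traj: Trajectory, max_gap: int = MAX_BLINK_GAP) -> Trajectory:
    """Collapse blink gaps by remapping frames onto a continuous 0..n-1 grid.

    Positions are untouched; ``t`` is rebuilt as ``frame * dt`` on the new
    grid.  The original gap frame indices are kept in ``gap_frames`` so the
    gap structure remains auditable.  A gap longer than ``max_gap`` frames
    raises: such detections should have been split into separate tracks.
    """
    frames = traj.frames
    gaps = np.diff(frames) - 1
    too_long = np.nonzero(gaps > max_gap)[0]
    if too_long.size:
        i = too_long[0]
        raise TrackDataError(
            f"track {traj.track_id}: gap of {gaps[i]} frames between frames "
            f"{frames[i]} and {frames[i + 1]} exceeds the {max_gap}-frame "
            "continuity window; split the track first"
        )
    if traj.is_contiguous and frames[0] == 0:
        return traj
    missing = tuple(
        int(f)
        for f in np.setdiff1d(np.arange(frames[0], frames[-1] + 1), frames)
    )
    new_frames = np.arange(len(frames), dtype=np.int64)
    return replace(
        traj,
        frames=new_frames,
        t=None,  # rebuilt from frames * dt
        gap_frames=traj.gap_frames + missing,
    )


def filter_min_length(trackset: TrackSet, min_frames: int = MIN_TRACK_LENGTH) -> TrackSet:
    """Keep only trajectories with at least ``min_frames`` points."""
    kept = [tr for tr in trackset.tracks if len(tr) >= min_frames]
    removed = len(trackset.tracks) - len(kept)
    if removed:
        logger.info("filter_min_length: removed %d track(s) shorter than %d frames",
                    removed, min_frames)
    return TrackSet(kept, dt=trackset.dt, loc_sigma=trackset.loc_sigma,
                    source=trackset.source)
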