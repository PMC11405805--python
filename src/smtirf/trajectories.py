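"""Trajectory containers and TrackMate-dialect CSV input/output.

A :class:`Trajectory` is the ordered sequence of detections of one molecule
on the membrane; a :class:`TrajectorySet` is the collection produced by one
movie (or one simulation), carrying the frame interval and, when known, the
movie geometry needed by the edge and movie-boundary filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spot",
    "Trajectory",
    "TrajectorySet",
    "read_trackmate_csv",
    "write_trackmate_csv",
]

#: Column names of the TrackMate export dialect we read and write.
TRACKMATE_COLUMNS = ("TRACK_ID", "POSITION_X", "POSITION_Y", "FRAME")


@dataclass(frozen=True)
class Spot:
    """A single detection: frame index (0-based) and position in micrometres."""

    frame: int
    x: float
    y: float
    intensity: float = 0.0
    quality: float = 0.0


@dataclass
class Trajectory:
    """Detections of one molecule in consecutive frames, no gaps."""

    id: int
    frames: np.ndarray  # int, strictly consecutive
    x: np.ndarray  # μm
    y: np.ndarray  # μm
    frame_interval: float  # s

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.frames) == 0:
            raise ValueError("trajectory must contain at least one detection")
        if not (len(self.frames) == len(self.x) == len(self.y)):
            raise ValueError("frames, x, y must have equal length")
        if len(self.frames) > 1 and not np.all(np.diff(self.frames) == 1):
            raise ValueError("trajectory frames must be strictly consecutive")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def start_frame(self) -> int:
        return int(self.frames[0])

    @property
    def end_frame(self) -> int:
        return int(self.frames[-1])

    @property
    def duration(self) -> float:
        """Track duration in seconds: (detections - 1) x frame interval."""
        return (len(self.frames) - 1) * self.frame_interval

    def displacements_from_start(self) -> np.ndarray:
        """Euclidean distance of every detection from the first one (μm)."""
        return np.hypot(self.x - self.x[0], self.y - self.y[0])

    def max_displacement(self) -> float:
        """Maximum excursion from the starting position (μm)."""
        return float(self.displacements_from_start().max())

    def steps(self, lag: int = 1) -> np.ndarray:
        """Euclidean displacements between detections ``lag`` frames apart (μm)."""
        if len(self.frames) <= lag:
            return np.empty(0)
        return np.hypot(self.x[lag:] - self.x[:-lag], self.y[lag:] - self.y[:-lag])


@dataclass
class TrajectorySet:
    """Trajectories from one movie plus the geometry the filters need.

    ``n_movie_frames`` (total frames in the movie) and ``field_width`` /
    ``field_height`` (μm) may be ``None`` when unknown, in which case the
    movie-end and edge filters cannot be applied.
    """

    trajectories: list[Trajectory] = field(default_factory=list)
    frame_interval: float = 1.0
    n_movie_frames: Optional[int] = None
    field_width: Optional[float] = None
    field_height: Optional[float] = None

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self) -> Iterator[Trajectory]:
        return iter(self.trajectories)

    def __getitem__(self, i: int) -> Trajectory:
        return self.trajectories[i]

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table in the TrackMate export dialect."""
        if not self.trajectories:
            return pd.DataFrame(columns=list(TRACKMATE_COLUMNS))
        parts = [
            pd.DataFrame(
                {
                    "TRACK_ID": t.id,
                    "POSITION_X": t.x,
                    "POSITION_Y": t.y,
                    "FRAME": t.frames,
                }
            )
            for t in self.trajectories
        ]
        return pd.concat(parts, ignore_index=True)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        frame_interval: float,
        n_movie_frames: Optional[int] = None,
        field_width: Optional[float] = None,
        field_height: Optional[float] = None,
    ) -> "TrajectorySet":
        missing = [c for c in TRACKMATE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing TrackMate columns: {missing}")
        trajectories = []
        for tid, grp in df.groupby("TRACK_ID", sort=True):
            grp = grp.sort_values("FRAME")
            trajectories.append(
                Trajectory(
                    id=int(tid),
                    frames=grp["FRAME"].to_numpy(dtype=int),
                    x=grp["POSITION_X"].to_numpy(dtype=float),
                    y=grp["POSITION_Y"].to_numpy(dtype=float),
                    frame_interval=frame_interval,
                )
            )
        return cls(
            trajectories,
            frame_interval=frame_interval,
            n_movie_frames=n_movie_frames,
            field_width=field_width,
            field_height=field_height,
        )


def write_trackmate_csv(tset: TrajectorySet, path) -> None:
    """Write trajectories as TrackMate-dialect CSV (positions in μm)."""
    tset.to_dataframe().to_csv(path, index=False)


def read_trackmate_csv(
    path,
    frame_interval: float,
    n_movie_frames: Optional[int] = None,
    field_width: Optional[float] = None,
    field_height: Optional[float] = None,
) -> TrajectorySet:
    """Read a TrackMate-dialect CSV (TRACK_ID, POSITION_X, POSITION_Y, FRAME).

    The frame interval is not stored in the CSV and must be supplied.
    """
    df = pd.read_csv(path)
    return TrajectorySet.from_dataframe(
        df,
        frame_interval=frame_interval,
        n_movie_frames=n_movie_frames,
        field_width=field_width,
        field_height=field_height,
    )
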