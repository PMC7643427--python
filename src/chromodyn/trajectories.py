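"""Locus-trajectory data model and I/O.

A :class:`Track` is one tracked chromatin locus: an ordered sequence of
2D or 3D positions (micrometres) sampled at a fixed interval ``dt``
(seconds).  A :class:`TrackSet` is a homogeneous collection of tracks
sharing ``dt`` and dimensionality, typically one imaging condition.

Trajectories come from spot-tracking software as delimited text with
columns ``track_id, frame, x, y[, z]`` (CSV or TSV, autodetected from
the extension).  Missing frames split a track into separate tracks:
interpolating across gaps would bias displacement statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Default sampling interval (s): single-plane acquisition at 20 ms.
DEFAULT_DT = 0.02

#: Relative tolerance on frame-spacing uniformity when a time column is given.
TIME_RTOL = 1e-3


@dataclass(frozen=True)
class Track:
    """One locus trajectory.

    Parameters
    ----------
    id : str
        Track identifier (unique within a :class:`TrackSet`).
    dt : float
        Sampling interval in seconds (> 0).
    positions : ndarray, shape (n_frames, d)
        Positions in micrometres, d in {2, 3}; frame 0 is t = 0.
    """

    id: str
    dt: float
    positions: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] not in (2, 3):
            raise ValueError(f"track {self.id!r}: positions must be (n, 2) or (n, 3)")
        if pos.shape[0] < 2:
            raise ValueError(f"track {self.id!r}: need at least 2 frames")
        if not self.dt > 0:
            raise ValueError(f"track {self.id!r}: dt must be positive")
        object.__setattr__(self, "positions", pos)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def ndim(self) -> int:
        return self.positions.shape[1]

    @property
    def duration(self) -> float:
        """Track duration T = (n_frames - 1) * dt, seconds."""
        return (self.n_frames - 1) * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt


@dataclass
class TrackSet:
    """A non-empty collection of tracks sharing dt and dimension."""

    tracks: list[Track]
    condition: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.tracks:
            raise ValueError("TrackSet must contain at least one track")
        dt0, d0 = self.tracks[0].dt, self.tracks[0].ndim
        for t in self.tracks:
            if not np.isclose(t.dt, dt0, rtol=1e-9):
                raise ValueError(f"track {t.id!r} has dt {t.dt}, expected {dt0}")
            if t.ndim != d0:
                raise ValueError(f"track {t.id!r} has dimension {t.ndim}, expected {d0}")

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)

    @property
    def dt(self) -> float:
        return self.tracks[0].dt

    @property
    def ndim(self) -> int:
        return self.tracks[0].ndim

    def filter_min_frames(self, min_frames: int = 26) -> "TrackSet":
        """Drop tracks shorter than ``min_frames``.

        The default keeps every track that supports at least one
        displacement at a 0.5 s delay when dt = 0.02 s.
        """
        kept = [t for t in self.tracks if t.n_frames >= min_frames]
        if not kept:
            raise ValueError("no tracks pass the minimum-length filter")
        return TrackSet(kept, condition=self.condition, metadata=dict(self.metadata))


def displacement_count(track: Track, delay: float) -> int:
    """Number of displacement pairs N_i(tau) at delay tau = k*dt.

    All overlapping pairs are counted: N_i = n_frames - k, the exact
    count approximated by (T_i - tau)/dt.  Overlapping displacements are
    statistically dependent; the downstream weighted estimators are
    defined over this count regardless.
    """
    k = delay_to_lag(track.dt, delay)
    if k < 1:
        raise ValueError("delay must be at least one frame interval")
    if k >= track.n_frames:
        raise ValueError(f"delay {delay} exceeds track duration {track.duration}")
    return track.n_frames - k


def delay_to_lag(dt: float, delay: float) -> int:
    """Convert a delay in seconds to an integer frame lag, validating it."""
    k = delay / dt
    k_int = int(round(k))
    if abs(k - k_int) > 1e-6 * max(1.0, abs(k)):
        raise ValueError(f"delay {delay} is not an integer multiple of dt={dt}")
    return k_int


def _sep_for(path: str) -> str:
    return "\t" if str(path).lower().endswith((".tsv", ".tab")) else ","


def read_tracks(
    path,
    dt: float | None = None,
    condition: str = "",
    split_gaps: bool = True,
) -> TrackSet:
    """Read a delimited trajectory file into a :class:`TrackSet`.

    The file must have columns ``track_id`` and either ``frame`` (integer
    frame index) or ``time`` (seconds), plus coordinate columns ``x, y``
    and optionally ``z`` in micrometres.  Tracks with missing frames are
    split at each gap into independent tracks (suffixes ``.0``, ``.1``,
    ...), because interpolation would bias the MSD.

    Parameters
    ----------
    dt : float, optional
        Seconds per frame.  Defaults to 0.02 s when the file has a
        ``frame`` column; inferred (and checked for uniformity) when the
        file has a ``time`` column.
    """
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    df.columns = [str(c).strip().lower() for c in df.columns]
    if df.empty:
        raise ValueError("no tracks: trajectory file is empty")
    if "track_id" not in df.columns:
        raise ValueError("trajectory file lacks a 'track_id' column")
    coord_cols = [c for c in ("x", "y", "z") if c in df.columns]
    if len(coord_cols) < 2:
        raise ValueError("trajectory file needs at least x and y columns")

    tracks: list[Track] = []
    for tid, grp in df.groupby("track_id", sort=True):
        if "frame" in grp.columns:
            if dt is None:
                dt = DEFAULT_DT
            grp = grp.sort_values("frame")
            frames = grp["frame"].to_numpy(dtype=int)
        elif "time" in grp.columns:
            grp = grp.sort_values("time")
            times = grp["time"].to_numpy(dtype=float)
            steps = np.diff(times)
            if len(steps) == 0:
                continue
            step = np.median(steps)
            if dt is None:
                dt = float(step)
            ratio = steps / dt
            if np.any(np.abs(ratio - np.round(ratio)) > TIME_RTOL * np.maximum(1.0, ratio)):
                raise ValueError(f"track {tid!r}: non-uniform sampling beyond tolerance")
            frames = np.round(times / dt).astype(int)
        else:
            raise ValueError("trajectory file needs a 'frame' or 'time' column")
        if np.any(np.diff(frames) == 0):
            raise ValueError(f"track {tid!r}: duplicate frames")
        pos = grp[coord_cols].to_numpy(dtype=float)
        for piece_idx, (f_seg, p_seg) in enumerate(_split_at_gaps(frames, pos, split_gaps)):
            if len(f_seg) < 2:
                continue
            name = str(tid) if piece_idx == 0 and len(f_seg) == len(frames) else f"{tid}.{piece_idx}"
            tracks.append(Track(id=name, dt=float(dt), positions=p_seg))
    if not tracks:
        raise ValueError("no tracks with at least 2 frames")
    return TrackSet(tracks, condition=condition)


def _split_at_gaps(frames, pos, split_gaps):
    if not split_gaps:
        yield frames, pos
        return
    breaks = np.nonzero(np.diff(frames) != 1)[0] + 1
    for seg_f, seg_p in zip(np.split(frames, breaks), np.split(pos, breaks)):
        yield seg_f, seg_p


def write_tracks(trackset: TrackSet, path) -> None:
    """Write a TrackSet in the same schema ``track_id,frame,x,y[,z]``.

    Coordinates round-trip bit-exactly through :func:`read_tracks`.
    """
    cols = ["x", "y", "z"][: trackset.ndim]
    rows = []
    for t in trackset:
        df = pd.DataFrame(t.positions, columns=cols)
        df.insert(0, "frame", np.arange(t.n_frames))
        df.insert(0, "track_id", t.id)
        rows.append(df)
    out = pd.concat(rows, ignore_index=True)
    # 17 significant digits: float64 round-trips bit-exactly
    out.to_csv(path, sep=_sep_for(path), index=False, float_format="%.17g")
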