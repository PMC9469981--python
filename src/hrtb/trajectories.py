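"""Data model and plain-text I/O for timestamped 3D cell tracks.

A :class:`Track` is a sequence of cell-centroid positions (microns) observed
at discrete times (minutes); an :class:`Ensemble` is a collection of tracks
sharing a nominal frame interval (3 minutes for the intravital recordings
this pipeline targets).  Times need not start at zero: every downstream
statistic uses time differences only.

Tracks are exchanged as plain UTF-8 CSV with the header
``track_id,t_min,x_um,y_um,z_um``, matching typical tracking-software
exports.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Required columns of the track-table CSV dialect.
TRACK_COLUMNS = ("track_id", "t_min", "x_um", "y_um", "z_um")


class TrackFormatError(ValueError):
    """A track table does not conform to the expected CSV dialect."""


class TrackValidationError(ValueError):
    """Track data violate a structural invariant (ordering, finiteness)."""


@dataclass(frozen=True)
class Track:
    """One cell trajectory: strictly increasing times and 3D positions.

    Parameters
    ----------
    track_id
        Identifier, unique within an ensemble.
    times
        Observation times in minutes, strictly increasing, length >= 2.
    positions
        Array of shape ``(n_frames, 3)`` with x/y/z in microns.
    """

    track_id: str
    times: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        positions = np.asarray(self.positions, dtype=float)
        if positions.ndim != 2 or positions.shape[1] != 3:
            raise TrackValidationError(
                f"track {self.track_id!r}: positions must have shape (n, 3), "
                f"got {positions.shape}"
            )
        if times.ndim != 1 or times.shape[0] != positions.shape[0]:
            raise TrackValidationError(
                f"track {self.track_id!r}: times and positions lengths differ"
            )
        if times.shape[0] < 2:
            raise TrackValidationError(
                f"track {self.track_id!r}: needs at least 2 frames"
            )
        if not (np.all(np.isfinite(times)) and np.all(np.isfinite(positions))):
            raise TrackValidationError(
                f"track {self.track_id!r}: non-finite time or coordinate"
            )
        if np.any(np.diff(times) <= 0):
            raise TrackValidationError(
                f"track {self.track_id!r}: times are not strictly increasing"
            )
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "positions", positions)

    @property
    def n_frames(self) -> int:
        return int(self.times.shape[0])

    @property
    def duration(self) -> float:
        """Track length in minutes (last time minus first time)."""
        return float(self.times[-1] - self.times[0])

    def frame_dt(self, rtol: float = 1e-6) -> float:
        """Return the uniform frame interval, or raise if sampling is uneven."""
        dts = np.diff(self.times)
        dt = float(dts[0])
        if not np.allclose(dts, dt, rtol=rtol, atol=rtol * max(dt, 1.0)):
            raise TrackValidationError(
                f"track {self.track_id!r}: non-uniform frame interval"
            )
        return dt


@dataclass(frozen=True)
class Ensemble:
    """A collection of tracks with unique ids and a nominal frame interval."""

    tracks: tuple[Track, ...]
    nominal_dt: float = 3.0

    def __post_init__(self) -> None:
        tracks = tuple(self.tracks)
        ids = [t.track_id for t in tracks]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise TrackValidationError(f"duplicate track ids: {dupes}")
        if self.nominal_dt <= 0:
            raise TrackValidationError("nominal_dt must be positive")
        object.__setattr__(self, "tracks", tracks)

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self) -> Iterator[Track]:
        return iter(self.tracks)

    def __getitem__(self, i: int) -> Track:
        return self.tracks[i]

    @property
    def track_ids(self) -> list[str]:
        return [t.track_id for t in self.tracks]

    def get(self, track_id: str) -> Track:
        for t in self.tracks:
            if t.track_id == track_id:
                return t
        raise KeyError(track_id)


def read_tracks(path: str | Path, nominal_dt: float = 3.0) -> Ensemble:
    """Read an ensemble from a track-table CSV.

    One :class:`Track` is built per distinct ``track_id``, frames taken in
    file order; a track whose times are not strictly increasing raises
    :class:`TrackValidationError` naming the offender.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"track_id": str}, float_precision="round_trip")
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise TrackFormatError(f"{path}: missing columns {missing}")
    tracks = []
    for tid in df["track_id"].unique():
        sub = df[df["track_id"] == tid]
        tracks.append(
            Track(
                track_id=str(tid),
                times=sub["t_min"].to_numpy(dtype=float),
                positions=sub[["x_um", "y_um", "z_um"]].to_numpy(dtype=float),
            )
        )
    return Ensemble(tracks=tuple(tracks), nominal_dt=nominal_dt)


def write_tracks(ensemble: Ensemble, path: str | Path) -> Path:
    """Write an ensemble as track-table CSV; re-readable losslessly.

    Coordinates are written at full repr precision so the round trip is exact.
    An empty ensemble yields a header-only file.
    """
    path = Path(path)
    frames = []
    for t in ensemble:
        frames.append(
            pd.DataFrame(
                {
                    "track_id": t.track_id,
                    "t_min": t.times,
                    "x_um": t.positions[:, 0],
                    "y_um": t.positions[:, 1],
                    "z_um": t.positions[:, 2],
                }
            )
        )
    if frames:
        df = pd.concat(frames, ignore_index=True)
    else:
        df = pd.DataFrame(columns=list(TRACK_COLUMNS))
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def filter_tracks(ensemble: Ensemble, min_duration: float) -> Ensemble:
    """Retain tracks whose duration is at least ``min_duration`` minutes.

    The boundary is inclusive ("three hours or more" keeps exactly-180-minute
    tracks).  Order is preserved and the operation is idempotent.
    """
    if min_duration < 0:
        raise ValueError("min_duration must be >= 0")
    kept = tuple(t for t in ensemble if t.duration >= min_duration)
    if not kept and len(ensemble) > 0:
        logger.warning(
            "filter_tracks: no track reaches min_duration=%g min", min_duration
        )
    return Ensemble(tracks=kept, nominal_dt=ensemble.nominal_dt)
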