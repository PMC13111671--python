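"""Reading, validation and rescaling of particle-track tables.

Tracker exports arrive as CSV (one row per bead per retained frame).  This
module converts them into :class:`TrackSet` objects whose positions are in
micrometres and whose time base is seconds, accounting for frame thinning:
the ``frame`` column indexes *retained* frames, so the elapsed time between
consecutive retained frames is ``subsample_factor / fps`` seconds per unit
frame difference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Column map of the package's own CSV dialect.
DEFAULT_DIALECT: Mapping[str, str] = {
    "track_id": "track_id",
    "frame": "frame",
    "x": "x_um",
    "y": "y_um",
    "species": "species",
    "specimen": "specimen",
}

#: Example column map for a commercial-tracker export
#: (positions in the tracker's native units; rescale afterwards).
IMARIS_DIALECT: Mapping[str, str] = {
    "track_id": "TrackID",
    "frame": "Time",
    "x": "Position X",
    "y": "Position Y",
    "species": "species",
    "specimen": "specimen",
}

_REQUIRED = ("track_id", "frame", "x", "y")


class SchemaError(ValueError):
    """A required column is missing from a tracker export."""


class TrackValidationError(ValueError):
    """Track rows violate the (track_id, frame) monotonicity contract."""


@dataclass
class Track:
    """One bead's time-ordered 2-D positions.

    Parameters
    ----------
    track_id : str
        Unique identifier within a :class:`TrackSet`.
    frames : ndarray of int
        Strictly increasing retained-frame indices.
    xy : ndarray, shape (n, 2)
        Positions in micrometres.
    species, specimen : str, optional
        Metadata labels carried through the pipeline.
    """

    track_id: str
    frames: np.ndarray
    xy: np.ndarray
    species: str | None = None
    specimen: str | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.xy = np.asarray(self.xy, dtype=np.float64)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValueError(f"track {self.track_id}: xy must be (n, 2)")
        if len(self.frames) != len(self.xy):
            raise ValueError(f"track {self.track_id}: frames/xy length mismatch")

    @property
    def n_points(self) -> int:
        return len(self.frames)

    def step_lengths(self) -> np.ndarray:
        """Euclidean length of each consecutive step, in µm."""
        return np.linalg.norm(np.diff(self.xy, axis=0), axis=1)


@dataclass
class TrackSet:
    """A collection of tracks sharing one recording's time base.

    ``fps`` is the native camera frame rate; ``subsample_factor`` is the
    frame-thinning factor applied before export (every k-th frame retained),
    so one unit of the ``frame`` column corresponds to
    ``subsample_factor / fps`` seconds.  ``um_per_px`` records the spatial
    calibration already applied (1.0 once positions are in µm).
    """

    tracks: list[Track]
    fps: float = 24.0
    subsample_factor: int = 1
    um_per_px: float = 1.0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.subsample_factor < 1:
            raise ValueError("subsample_factor must be a positive integer")
        ids = [t.track_id for t in self.tracks]
        if len(set(ids)) != len(ids):
            raise TrackValidationError("duplicate track_ids in TrackSet")

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self):
        return iter(self.tracks)

    @property
    def frame_dt(self) -> float:
        """Elapsed seconds per unit retained-frame difference."""
        return self.subsample_factor / self.fps

    def bounding_box(self, pad_frac: float = 0.0) -> tuple[float, float, float, float]:
        """(x_min, x_max, y_min, y_max) over all points, optionally padded."""
        if not self.tracks:
            raise ValueError("empty TrackSet has no bounding box")
        allxy = np.vstack([t.xy for t in self.tracks])
        x0, y0 = allxy.min(axis=0)
        x1, y1 = allxy.max(axis=0)
        px = pad_frac * max(x1 - x0, 1e-12)
        py = pad_frac * max(y1 - y0, 1e-12)
        return (x0 - px, x1 + px, y0 - py, y1 + py)


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_tracks`; purely informational."""

    n_tracks: int
    point_counts: dict[str, int]
    issues: list[dict] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues


def read_tracker_csv(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    fps: float = 24.0,
    subsample_factor: int = 1,
    um_per_px: float = 1.0,
    min_points: int = 2,
) -> TrackSet:
    """Read a tracker-export CSV into a :class:`TrackSet`.

    Rows are grouped by track id and sorted by frame; tracks with fewer than
    ``min_points`` points are dropped (the count is logged).  Metadata
    columns (species, specimen) are carried through when present.

    Raises
    ------
    SchemaError
        If a required column is absent under the chosen dialect.
    TrackValidationError
        If a (track_id, frame) pair is duplicated.
    """
    dialect = dict(DEFAULT_DIALECT if dialect is None else dialect)
    df = pd.read_csv(path)
    missing = [dialect[k] for k in _REQUIRED if dialect[k] not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing} in {path}")

    tid_col, fr_col = dialect["track_id"], dialect["frame"]
    x_col, y_col = dialect["x"], dialect["y"]
    sp_col = dialect.get("species")
    spec_col = dialect.get("specimen")

    dup = df.duplicated(subset=[tid_col, fr_col], keep=False)
    if dup.any():
        offenders = df.loc[dup, [tid_col, fr_col]].drop_duplicates()
        raise TrackValidationError(
            f"duplicated (track_id, frame) pairs: {offenders.to_dict('records')}"
        )

    tracks: list[Track] = []
    n_dropped = 0
    for tid, g in df.groupby(tid_col, sort=True):
        g = g.sort_values(fr_col)
        if len(g) < min_points:
            n_dropped += 1
            continue
        species = str(g[sp_col].iloc[0]) if sp_col in g.columns and g[sp_col].notna().any() else None
        specimen = str(g[spec_col].iloc[0]) if spec_col in g.columns and g[spec_col].notna().any() else None
        tracks.append(
            Track(
                track_id=str(tid),
                frames=g[fr_col].to_numpy(dtype=np.int64),
                xy=g[[x_col, y_col]].to_numpy(dtype=np.float64),
                species=species,
                specimen=specimen,
            )
        )
    if n_dropped:
        logger.info("read_tracker_csv: dropped %d track(s) with < %d points", n_dropped, min_points)
    return TrackSet(tracks, fps=fps, subsample_factor=subsample_factor, um_per_px=um_per_px)


def write_tracker_csv(
    tracks: TrackSet,
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    float_format: str = "%.6f",
) -> Path:
    """Write a :class:`TrackSet` as a tracker-export CSV.

    The fixed float format makes the output byte-stable and round-trips
    positions to within 1e-6 µm.
    """
    dialect = dict(DEFAULT_DIALECT if dialect is None else dialect)
    rows = []
    for t in tracks:
        for k in range(t.n_points):
            rows.append(
                {
                    dialect["track_id"]: t.track_id,
                    dialect["frame"]: int(t.frames[k]),
                    dialect["x"]: t.xy[k, 0],
                    dialect["y"]: t.xy[k, 1],
                    dialect["species"]: t.species if t.species is not None else "",
                    dialect["specimen"]: t.specimen if t.specimen is not None else "",
                }
            )
    cols = [dialect[k] for k in ("track_id", "frame", "x", "y", "species", "specimen")]
    df = pd.DataFrame(rows, columns=cols)
    path = Path(path)
    df.to_csv(path, index=False, float_format=float_format, lineterminator="\n")
    return path


def rescale_tracks(
    tracks: TrackSet,
    um_per_px: float,
    fps: float | None = None,
    subsample_factor: int | None = None,
) -> TrackSet:
    """Convert pixel positions to µm and (re)declare the time base.

    Positions are multiplied by ``um_per_px``; the geometry of each track is
    unchanged up to uniform scaling.  ``fps``/``subsample_factor`` default to
    the input set's values.
    """
    if um_per_px <= 0:
        raise ValueError("um_per_px must be positive")
    fps = tracks.fps if fps is None else fps
    subsample_factor = tracks.subsample_factor if subsample_factor is None else subsample_factor
    if fps <= 0 or subsample_factor < 1:
        raise ValueError("fps must be > 0 and subsample_factor >= 1")
    new = [
        replace(t, xy=t.xy * um_per_px, frames=t.frames.copy())
        for t in tracks
    ]
    return TrackSet(
        new,
        fps=fps,
        subsample_factor=subsample_factor,
        um_per_px=tracks.um_per_px * um_per_px,
    )


def validate_tracks(tracks: TrackSet) -> ValidationReport:
    """Report per-track point counts and structural problems.

    Checks: duplicate ids, non-finite coordinates, non-monotone frame
    indices, tracks shorter than 2 points.  The TrackSet is not modified.
    """
    issues: list[dict] = []
    counts: dict[str, int] = {}
    seen: set[str] = set()
    for t in tracks.tracks:
        counts[t.track_id] = t.n_points
        if t.track_id in seen:
            issues.append({"track_id": t.track_id, "issue": "duplicate_id"})
        seen.add(t.track_id)
        if t.n_points < 2:
            issues.append({"track_id": t.track_id, "issue": "too_few_points"})
        bad = ~np.isfinite(t.xy).all(axis=1)
        for row in np.flatnonzero(bad):
            issues.append({"track_id": t.track_id, "issue": "non_finite", "row": int(row)})
        if np.any(np.diff(t.frames) <= 0):
            issues.append({"track_id": t.track_id, "issue": "non_monotone_frames"})
    return ValidationReport(n_tracks=len(tracks.tracks), point_counts=counts, issues=issues)
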