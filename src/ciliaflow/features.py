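"""Per-track movement statistics and their normalizations.

Eight statistics summarize each bead track: number of turns, sinuosity,
mean/max/variance of speed, number of self-intersections, total track
length and net displacement length.  Sinuosity is the ratio of path length
to straight-line start-to-end distance (1 for a straight path).  Turns are
counted as maximal runs of points whose sliding-window sinuosity (20-point
window, per-point maximum over overlapping windows) exceeds 1.2.

Speeds honour frame thinning: the elapsed time per unit frame difference is
``subsample_factor / fps`` seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Iterable

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import Track, TrackSet

FEATURE_COLUMNS = [
    "n_turns",
    "sinuosity",
    "mean_speed",
    "max_speed",
    "speed_variance",
    "n_intersections",
    "track_length",
    "displacement_length",
]

META_COLUMNS = ["track_id", "species", "specimen"]


@dataclass(frozen=True)
class FeatureParams:
    """Tunables of the per-track statistics.

    ``window_points``: sliding-window length in points (not µm) for local
    sinuosity.  ``sinuosity_turn_threshold``: windowed-sinuosity level above
    which a run of points counts as one turn.  ``displacement_epsilon``:
    guard (µm) that keeps the sinuosity of closed tracks finite.
    """

    window_points: int = 20
    sinuosity_turn_threshold: float = 1.2
    displacement_epsilon: float = 1e-9

    def __post_init__(self) -> None:
        if self.window_points < 3:
            raise ValueError("window_points must be >= 3")
        if self.sinuosity_turn_threshold <= 1:
            raise ValueError("sinuosity_turn_threshold must be > 1")
        if self.displacement_epsilon <= 0:
            raise ValueError("displacement_epsilon must be > 0")


@dataclass
class FeatureTable:
    """Feature rows plus the normalization state.

    ``df`` has one row per track (metadata + the 8 feature columns);
    ``normalization`` is one of raw / zscore / minmax.  ``column_stats``
    retains the per-column statistics used, enabling inverse mapping;
    ``flags`` records degeneracies (constant columns, zero-displacement
    tracks, excluded tracks).
    """

    df: pd.DataFrame
    normalization: str = "raw"
    column_stats: dict = dc_field(default_factory=dict)
    flags: dict = dc_field(default_factory=dict)

    def feature_matrix(self) -> np.ndarray:
        return self.df[FEATURE_COLUMNS].to_numpy(dtype=np.float64)

    def __len__(self) -> int:
        return len(self.df)


def _check_min_points(track: Track, n: int) -> None:
    if track.n_points < n:
        raise ValueError(f"track {track.track_id}: needs >= {n} points")


def track_length(track: Track) -> float:
    """Total path length: sum of Euclidean step lengths, µm."""
    _check_min_points(track, 2)
    return float(track.step_lengths().sum())


def displacement_length(track: Track) -> float:
    """Net displacement: Euclidean distance from first to last point, µm."""
    _check_min_points(track, 2)
    return float(np.linalg.norm(track.xy[-1] - track.xy[0]))


def global_sinuosity(track: Track, params: FeatureParams = FeatureParams()) -> float:
    """Whole-track sinuosity: path length over net displacement (>= 1).

    Zero-displacement (closed) tracks divide by ``displacement_epsilon``
    instead, yielding a large finite value; callers can detect this via the
    per-track flag in :func:`feature_table`.
    """
    L = track_length(track)
    d = displacement_length(track)
    return L / max(d, params.displacement_epsilon)


def _segment_sinuosity(xy: np.ndarray, cum: np.ndarray, i: int, j: int, eps: float) -> float:
    L = cum[j] - cum[i]
    d = float(np.linalg.norm(xy[j] - xy[i]))
    return L / max(d, eps)


def windowed_sinuosity(track: Track, params: FeatureParams = FeatureParams()) -> np.ndarray:
    """Per-point local sinuosity by a sliding window.

    A ``window_points``-long window moves one point at a time; each point is
    assigned the maximum sinuosity over all complete windows containing it.
    Tracks shorter than the window use a single whole-track window, so every
    point receives the global sinuosity.
    """
    _check_min_points(track, 2)
    xy = track.xy
    n = len(xy)
    W = min(params.window_points, n)
    eps = params.displacement_epsilon
    cum = np.concatenate([[0.0], np.cumsum(track.step_lengths())])
    vals = np.full(n, -np.inf)
    for s in range(n - W + 1):
        sw = _segment_sinuosity(xy, cum, s, s + W - 1, eps)
        seg = vals[s : s + W]
        np.maximum(seg, sw, out=seg)
    return vals


def count_turns(track: Track, params: FeatureParams = FeatureParams()) -> int:
    """Number of turns: maximal runs of windowed sinuosity strictly above
    the threshold, each run counting once."""
    vals = windowed_sinuosity(track, params)
    above = vals > params.sinuosity_turn_threshold
    if not above.any():
        return 0
    # count run starts
    return int(above[0]) + int(np.sum(above[1:] & ~above[:-1]))


def count_self_intersections(track: Track, collinear_tol: float = 1e-12) -> int:
    """Number of unordered pairs of non-adjacent polyline segments that
    cross or touch.

    Consecutive segments (which share a vertex by construction) are
    excluded; a collinear overlap counts once per pair.  Orientation tests
    use cross products with a relative collinearity tolerance.
    """
    _check_min_points(track, 3)
    P = track.xy
    m = len(P) - 1  # number of segments
    if m < 3:
        return 0
    A, B = P[:-1], P[1:]
    i, j = np.triu_indices(m, k=2)  # non-adjacent pairs only
    a, b = A[i], B[i]
    c, d = A[j], B[j]

    scale = np.maximum.reduce(
        [
            np.abs(a).max(axis=1),
            np.abs(b).max(axis=1),
            np.abs(c).max(axis=1),
            np.abs(d).max(axis=1),
            np.ones(len(i)),
        ]
    )
    eps = collinear_tol * scale**2

    def cross(o, p, q):
        return (p[:, 0] - o[:, 0]) * (q[:, 1] - o[:, 1]) - (p[:, 1] - o[:, 1]) * (
            q[:, 0] - o[:, 0]
        )

    d1 = cross(c, d, a)
    d2 = cross(c, d, b)
    d3 = cross(a, b, c)
    d4 = cross(a, b, d)

    proper = (
        (((d1 > eps) & (d2 < -eps)) | ((d1 < -eps) & (d2 > eps)))
        & (((d3 > eps) & (d4 < -eps)) | ((d3 < -eps) & (d4 > eps)))
    )

    def on_segment(o, q, p, e):
        # p collinear with segment (o, q): inside its bounding box?
        lo = np.minimum(o, q)
        hi = np.maximum(o, q)
        tol = np.sqrt(e)[:, None]
        return np.all((p >= lo - tol) & (p <= hi + tol), axis=1)

    touch = (
        ((np.abs(d1) <= eps) & on_segment(c, d, a, eps))
        | ((np.abs(d2) <= eps) & on_segment(c, d, b, eps))
        | ((np.abs(d3) <= eps) & on_segment(a, b, c, eps))
        | ((np.abs(d4) <= eps) & on_segment(a, b, d, eps))
    )
    return int(np.count_nonzero(proper | touch))


def speed_stats(
    track: Track, fps: float, subsample_factor: int = 1
) -> tuple[float, float, float]:
    """Per-step speeds and their (mean, max, sample variance).

    Step speed = step length / (Δframe · subsample_factor / fps).  Variance
    uses the n−1 denominator; a single-step track has variance 0.
    """
    _check_min_points(track, 2)
    dframes = np.diff(track.frames)
    if np.any(dframes <= 0):
        raise ValueError(f"track {track.track_id}: non-positive frame steps")
    dt = dframes * (subsample_factor / fps)
    speeds = track.step_lengths() / dt
    var = float(np.var(speeds, ddof=1)) if len(speeds) > 1 else 0.0
    return float(speeds.mean()), float(speeds.max()), var


def feature_table(
    tracks: TrackSet,
    params: FeatureParams = FeatureParams(),
    include_windowed_max: bool = False,
) -> FeatureTable:
    """Compute the 8-feature row for every track in a TrackSet.

    Tracks on which a feature fails are excluded and reported in
    ``flags['excluded']``; closed (zero-displacement) tracks are listed in
    ``flags['zero_displacement']``.
    """
    rows = []
    excluded: list[dict] = []
    zero_disp: list[str] = []
    for t in tracks:
        try:
            L = track_length(t)
            D = displacement_length(t)
            if D < params.displacement_epsilon:
                zero_disp.append(t.track_id)
            mean_s, max_s, var_s = speed_stats(t, tracks.fps, tracks.subsample_factor)
            row = {
                "track_id": t.track_id,
                "species": t.species,
                "specimen": t.specimen,
                "n_turns": count_turns(t, params),
                "sinuosity": global_sinuosity(t, params),
                "mean_speed": mean_s,
                "max_speed": max_s,
                "speed_variance": var_s,
                "n_intersections": count_self_intersections(t) if t.n_points >= 3 else 0,
                "track_length": L,
                "displacement_length": D,
            }
            if include_windowed_max:
                row["windowed_sinuosity_max"] = float(windowed_sinuosity(t, params).max())
        except ValueError as exc:  # pragma: no cover - defensive
            excluded.append({"track_id": t.track_id, "error": str(exc)})
            continue
        rows.append(row)
    cols = META_COLUMNS + FEATURE_COLUMNS + (
        ["windowed_sinuosity_max"] if include_windowed_max else []
    )
    df = pd.DataFrame(rows, columns=cols)
    flags = {"excluded": excluded, "zero_displacement": zero_disp}
    return FeatureTable(df=df, normalization="raw", flags=flags)


def _normalize(table: FeatureTable, kind: str) -> FeatureTable:
    if table.normalization != "raw":
        raise ValueError(f"table already normalized ({table.normalization})")
    if len(table) < 2:
        raise ValueError("normalization needs at least 2 rows")
    df = table.df.copy()
    stats: dict = {}
    constant: list[str] = []
    for col in FEATURE_COLUMNS:
        x = df[col].to_numpy(dtype=np.float64)
        if kind == "zscore":
            mu, sd = float(x.mean()), float(x.std(ddof=1))
            stats[col] = {"mean": mu, "sd": sd}
            if sd < 1e-15:
                df[col] = 0.0
                constant.append(col)
            else:
                df[col] = (x - mu) / sd
        else:
            lo, hi = float(x.min()), float(x.max())
            stats[col] = {"min": lo, "max": hi}
            if hi - lo < 1e-15:
                df[col] = 0.0
                constant.append(col)
            else:
                df[col] = (x - lo) / (hi - lo)
    flags = dict(table.flags)
    flags["constant_columns"] = constant
    return FeatureTable(df=df, normalization=kind, column_stats=stats, flags=flags)


def zscore_features(table: FeatureTable) -> FeatureTable:
    """Z-score every feature column ((x − mean)/sample s.d.); constant
    columns become zeros and are flagged."""
    return _normalize(table, "zscore")


def minmax_features(table: FeatureTable) -> FeatureTable:
    """Min–max scale every feature column to [0, 1]; constant columns
    become zeros and are flagged."""
    return _normalize(table, "minmax")


class TrackFeaturizer(TransformerMixin, BaseEstimator):
    """Transformer turning a :class:`TrackSet` into the 8-feature table.

    scikit-learn-compatible: stateless ``fit``, ``transform(trackset)``
    returns a :class:`FeatureTable` (use ``.feature_matrix()`` for the raw
    ndarray).  ``normalization`` applies z-scoring or min–max scaling after
    extraction.

    Parameters
    ----------
    window_points : int, default 20
        Sliding-window length (points) for local sinuosity.
    turn_threshold : float, default 1.2
        Windowed-sinuosity level defining a turn.
    normalization : {"raw", "zscore", "minmax"}, default "raw"
    include_windowed_max : bool, default False
        Append the per-track maximum windowed sinuosity as an extra column.
    """

    def __init__(
        self,
        window_points: int = 20,
        turn_threshold: float = 1.2,
        displacement_epsilon: float = 1e-9,
        normalization: str = "raw",
        include_windowed_max: bool = False,
    ):
        self.window_points = window_points
        self.turn_threshold = turn_threshold
        self.displacement_epsilon = displacement_epsilon
        self.normalization = normalization
        self.include_windowed_max = include_windowed_max

    def _params(self) -> FeatureParams:
        return FeatureParams(
            window_points=self.window_points,
            sinuosity_turn_threshold=self.turn_threshold,
            displacement_epsilon=self.displacement_epsilon,
        )

    def fit(self, X: TrackSet, y=None) -> "TrackFeaturizer":
        if self.normalization not in ("raw", "zscore", "minmax"):
            raise ValueError("normalization must be raw, zscore or minmax")
        return self

    def transform(self, X: TrackSet) -> FeatureTable:
        table = feature_table(X, self._params(), self.include_windowed_max)
        if self.normalization == "zscore":
            table = zscore_features(table)
        elif self.normalization == "minmax":
            table = minmax_features(table)
        return table
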