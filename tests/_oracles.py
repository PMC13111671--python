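"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (explicit Python loops, shapely for
segment intersection, closed-form Welch formula) kept separate from the
package code paths they check.
"""

from __future__ import annotations

import math

import numpy as np
from shapely.geometry import LineString


def brute_track_length(xy: np.ndarray) -> float:
    total = 0.0
    for k in range(1, len(xy)):
        total += math.dist(xy[k - 1], xy[k])
    return total


def brute_global_sinuosity(xy: np.ndarray, eps: float = 1e-9) -> float:
    disp = math.dist(xy[0], xy[-1])
    return brute_track_length(xy) / max(disp, eps)


def brute_windowed_sinuosity(xy: np.ndarray, window: int, eps: float = 1e-9) -> np.ndarray:
    """Per-point max over exhaustive enumeration of all complete windows."""
    n = len(xy)
    W = min(window, n)
    vals = [-math.inf] * n
    for s in range(n - W + 1):
        seg = xy[s : s + W]
        sw = brute_global_sinuosity(seg, eps)
        for i in range(s, s + W):
            vals[i] = max(vals[i], sw)
    return np.array(vals)


def brute_count_turns(xy: np.ndarray, window: int, threshold: float, eps: float = 1e-9) -> int:
    vals = brute_windowed_sinuosity(xy, window, eps)
    count = 0
    in_run = False
    for v in vals:
        if v > threshold and not in_run:
            count += 1
            in_run = True
        elif v <= threshold:
            in_run = False
    return count


def brute_self_intersections(xy: np.ndarray) -> int:
    """O(n^2) pairwise check of non-adjacent segments via shapely."""
    segs = [LineString([xy[k], xy[k + 1]]) for k in range(len(xy) - 1)]
    count = 0
    for i in range(len(segs)):
        for j in range(i + 2, len(segs)):
            if segs[i].intersects(segs[j]):
                count += 1
    return count


def brute_speed_stats(xy: np.ndarray, frames: np.ndarray, fps: float, subsample: int):
    speeds = []
    for k in range(1, len(xy)):
        dt = (frames[k] - frames[k - 1]) * subsample / fps
        speeds.append(math.dist(xy[k - 1], xy[k]) / dt)
    mean = sum(speeds) / len(speeds)
    if len(speeds) > 1:
        var = sum((s - mean) ** 2 for s in speeds) / (len(speeds) - 1)
    else:
        var = 0.0
    return mean, max(speeds), var


def welch_t(a: np.ndarray, b: np.ndarray) -> float:
    """Closed-form Welch t statistic."""
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    return (ma - mb) / math.sqrt(va / len(a) + vb / len(b))


def brute_bilinear(x, y, xn, yn, grid):
    """Direct bilinear formula at a single point on a uniform grid."""
    ix = min(int((x - xn[0]) / (xn[1] - xn[0])), len(xn) - 2)
    iy = min(int((y - yn[0]) / (yn[1] - yn[0])), len(yn) - 2)
    tx = (x - xn[ix]) / (xn[1] - xn[0])
    ty = (y - yn[iy]) / (yn[1] - yn[0])
    return (
        grid[iy, ix] * (1 - tx) * (1 - ty)
        + grid[iy, ix + 1] * tx * (1 - ty)
        + grid[iy + 1, ix] * (1 - tx) * ty
        + grid[iy + 1, ix + 1] * tx * ty
    )


def random_track_xy(rng: np.random.Generator, n: int, step: float = 1.0) -> np.ndarray:
    """Correlated random walk: persistent heading with random turning."""
    heading = rng.uniform(0, 2 * math.pi)
    pts = [np.zeros(2)]
    for _ in range(n - 1):
        heading += rng.normal(0, 0.7)
        length = step * rng.uniform(0.2, 1.8)
        pts.append(pts[-1] + length * np.array([math.cos(heading), math.sin(heading)]))
    return np.array(pts)
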