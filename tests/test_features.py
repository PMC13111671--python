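import math

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from ciliaflow.features import (
    FeatureParams,
    TrackFeaturizer,
    count_self_intersections,
    count_turns,
    displacement_length,
    feature_table,
    global_sinuosity,
    minmax_features,
    speed_stats,
    track_length,
    windowed_sinuosity,
    zscore_features,
    FEATURE_COLUMNS,
)
from ciliaflow.io import Track, TrackSet

from _oracles import (
    brute_count_turns,
    brute_global_sinuosity,
    brute_self_intersections,
    brute_speed_stats,
    brute_track_length,
    brute_windowed_sinuosity,
    random_track_xy,
)


def mk(xy, frames=None, tid="t"):
    xy = np.asarray(xy, float)
    if frames is None:
        frames = np.arange(len(xy))
    return Track(tid, frames, xy)


class TestLengths:
    @pytest.mark.parametrize(
        "xy,expected",
        [
            ([(0, 0), (1, 0), (2, 0)], 2.0),
            ([(0, 0), (1, 1)], math.sqrt(2)),
        ],
    )
    def test_track_length_analytic(self, xy, expected):
        assert track_length(mk(xy)) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "xy,expected",
        [
            ([(0, 0), (1, 0), (2, 0)], 2.0),
            ([(0, 0), (1, 0), (1, 1), (0, 1), (0, 0)], 0.0),
        ],
    )
    def test_displacement_analytic(self, xy, expected):
        assert displacement_length(mk(xy)) == pytest.approx(expected)


class TestSinuosity:
    def test_straight_track_is_one(self):
        assert global_sinuosity(mk([(0, 0), (1, 0), (2, 0)])) == 1.0

    def test_triangle_is_sqrt2(self):
        assert global_sinuosity(mk([(0, 0), (1, 1), (2, 0)])) == pytest.approx(math.sqrt(2))

    def test_semicircle_tends_to_half_pi(self):
        th = np.linspace(0, math.pi, 1000)
        t = mk(np.column_stack([np.cos(th), np.sin(th)]))
        assert global_sinuosity(t) == pytest.approx(math.pi / 2, abs=1e-4)

    def test_zero_displacement_is_large_finite(self):
        loop = mk([(0, 0), (1, 0), (1, 1), (0, 1), (0, 0)])
        s = global_sinuosity(loop)
        assert np.isfinite(s) and s > 1e6


class TestWindowedSinuosity:
    def test_straight_track_all_one(self):
        xy = np.column_stack([np.arange(30.0), np.zeros(30)])
        assert np.allclose(windowed_sinuosity(mk(xy)), 1.0)

    def test_short_track_uses_whole_track_window(self):
        xy = random_track_xy(np.random.default_rng(0), 10)
        t = mk(xy)
        vals = windowed_sinuosity(t)
        assert np.allclose(vals, global_sinuosity(t))

    def test_matches_exhaustive_window_oracle(self, rng):
        xy = random_track_xy(rng, 50)
        got = windowed_sinuosity(mk(xy))
        want = brute_windowed_sinuosity(xy, 20)
        assert np.abs(got - want).max() <= 1e-9 * np.abs(want).max()


def hairpin(n_out=15, offset=0.1):
    out = np.column_stack([np.arange(n_out, dtype=float), np.zeros(n_out)])
    back = np.column_stack([np.arange(n_out - 1, -1, -1, dtype=float),
                            np.full(n_out, offset)])
    return np.vstack([out, back])


class TestTurns:
    def test_straight_track_has_none(self):
        xy = np.column_stack([np.arange(40.0), np.zeros(40)])
        assert count_turns(mk(xy)) == 0

    def test_single_hairpin_is_one_turn(self):
        xy = hairpin()
        assert count_turns(mk(xy)) == brute_count_turns(xy, 20, 1.2) == 1

    def test_three_separated_hairpins(self):
        """Hairpins joined by >= 25-point straight runs count separately."""
        parts = []
        x0 = 0.0
        for k in range(3):
            hp = hairpin() + [x0, 3.0 * k]
            straight = np.column_stack(
                [np.linspace(hp[-1, 0], hp[-1, 0] + 26, 26), np.full(26, hp[-1, 1])]
            )
            parts.extend([hp, straight[1:]])
            x0 = straight[-1, 0]
        xy = np.vstack(parts)
        got = count_turns(mk(xy))
        assert got == brute_count_turns(xy, 20, 1.2) == 3


class TestSelfIntersections:
    def test_convex_arc_has_none(self):
        th = np.linspace(0, math.pi / 2, 50)
        xy = np.column_stack([np.cos(th), np.sin(th)])
        assert count_self_intersections(mk(xy)) == 0

    def test_constructed_crossing(self):
        xy = [(0, 0), (2, 2), (2, 0), (0, 2)]
        assert count_self_intersections(mk(xy)) == 1

    def test_matches_bruteforce_oracle(self, rng):
        xy = random_track_xy(rng, 200, step=0.8)
        assert count_self_intersections(mk(xy)) == brute_self_intersections(xy)


class TestSpeedStats:
    def test_uniform_steps_with_thinned_time_base(self):
        """5 µm steps every 2/24 s give 60 µm/s, zero variance."""
        xy = np.column_stack([5.0 * np.arange(6), np.zeros(6)])
        mean, mx, var = speed_stats(mk(xy), fps=24.0, subsample_factor=2)
        assert mean == pytest.approx(60.0)
        assert mx == pytest.approx(60.0)
        assert var == pytest.approx(0.0, abs=1e-18)

    def test_two_step_arithmetic(self):
        xy = [(0, 0), (1, 0), (4, 0)]
        mean, mx, var = speed_stats(mk(xy), fps=1.0, subsample_factor=1)
        assert (mean, mx, var) == (2.0, 3.0, 2.0)

    def test_matches_direct_oracle(self, random_tracks):
        for t in random_tracks.tracks[:20]:
            got = speed_stats(t, random_tracks.fps, random_tracks.subsample_factor)
            want = brute_speed_stats(t.xy, t.frames, random_tracks.fps,
                                     random_tracks.subsample_factor)
            assert np.allclose(got, want, rtol=1e-9)


class TestInvariants:
    def _features(self, ts):
        return feature_table(ts).df[FEATURE_COLUMNS].to_numpy()

    def test_rigid_motion_invariance(self, random_tracks):
        th = 0.7
        R = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        shift = np.array([13.0, -4.0])
        moved = TrackSet(
            [Track(t.track_id, t.frames, t.xy @ R.T + shift) for t in random_tracks],
            fps=random_tracks.fps, subsample_factor=random_tracks.subsample_factor,
        )
        a, b = self._features(random_tracks), self._features(moved)
        assert np.abs(a - b).max() <= 1e-9 * max(1.0, np.abs(a).max())

    def test_uniform_scaling(self, random_tracks):
        s = 3.5
        scaled = TrackSet(
            [Track(t.track_id, t.frames, t.xy * s) for t in random_tracks],
            fps=random_tracks.fps, subsample_factor=random_tracks.subsample_factor,
        )
        a = feature_table(random_tracks).df
        b = feature_table(scaled).df
        for col in ("n_turns", "sinuosity", "n_intersections"):
            assert np.allclose(a[col], b[col], rtol=1e-9)
        for col in ("mean_speed", "max_speed", "track_length", "displacement_length"):
            assert np.allclose(s * a[col], b[col], rtol=1e-9)
        assert np.allclose(s**2 * a["speed_variance"], b["speed_variance"], rtol=1e-8)

    def test_time_reversal(self, random_tracks):
        for t in random_tracks.tracks[:20]:
            rev = Track(t.track_id, np.cumsum(np.r_[0, np.diff(t.frames)[::-1]]),
                        t.xy[::-1].copy())
            assert track_length(rev) == pytest.approx(track_length(t))
            assert displacement_length(rev) == pytest.approx(displacement_length(t))
            assert global_sinuosity(rev) == pytest.approx(global_sinuosity(t))
            assert count_self_intersections(rev) == count_self_intersections(t)
            fps, sub = random_tracks.fps, random_tracks.subsample_factor
            assert speed_stats(rev, fps, sub)[0] == pytest.approx(speed_stats(t, fps, sub)[0])

    def test_detour_monotonicity(self, rng):
        xy = random_track_xy(rng, 60)
        base = mk(xy)
        loop = xy[-1] + 2.0 * np.column_stack(
            [np.cos(np.linspace(0, 2 * math.pi, 20)), np.sin(np.linspace(0, 2 * math.pi, 20))]
        )
        extended = mk(np.vstack([xy, loop]))
        assert track_length(extended) >= track_length(base)
        assert count_self_intersections(extended) >= count_self_intersections(base)


class TestFeatureTable:
    def test_row_and_column_counts(self, uniform_trackset):
        table = feature_table(uniform_trackset)
        assert len(table) == len(uniform_trackset)
        assert all(c in table.df.columns for c in FEATURE_COLUMNS)

    def test_empty_set_keeps_schema(self):
        table = feature_table(TrackSet([], fps=24, subsample_factor=2))
        assert len(table) == 0
        assert list(table.df.columns[-8:]) == FEATURE_COLUMNS[-8:]

    def test_straight_line_limits(self, uniform_trackset):
        df = feature_table(uniform_trackset).df
        assert (df["n_turns"] == 0).all()
        assert np.allclose(df["sinuosity"], 1.0, atol=1e-9)
        assert (df["n_intersections"] == 0).all()


class TestNormalization:
    def test_zscore_column(self):
        t = feature_table(_tiny_set())
        z = zscore_features(t)
        X = z.df[FEATURE_COLUMNS].to_numpy()
        assert np.abs(X.mean(axis=0)).max() < 1e-9
        sd = X.std(axis=0, ddof=1)
        nonconst = [c not in z.flags["constant_columns"] for c in FEATURE_COLUMNS]
        assert np.allclose(sd[nonconst], 1.0, atol=1e-9)

    def test_minmax_bounds_and_idempotent_columns(self):
        t = feature_table(_tiny_set())
        m = minmax_features(t)
        X = m.df[FEATURE_COLUMNS].to_numpy()
        nonconst = [c not in m.flags["constant_columns"] for c in FEATURE_COLUMNS]
        assert np.allclose(X[:, nonconst].min(axis=0), 0.0, atol=1e-12)
        assert np.allclose(X[:, nonconst].max(axis=0), 1.0, atol=1e-12)

    def test_constant_column_flagged(self):
        z = zscore_features(feature_table(_tiny_set()))
        # noiseless straight tracks: turns and intersections are constant 0
        assert "n_turns" in z.flags["constant_columns"]
        assert np.all(z.df["n_turns"] == 0.0)

    def test_single_row_rejected(self):
        t = feature_table(_tiny_set())
        t.df = t.df.iloc[:1]
        with pytest.raises(ValueError):
            zscore_features(t)

    def test_double_normalization_rejected(self):
        z = zscore_features(feature_table(_tiny_set()))
        with pytest.raises(ValueError):
            minmax_features(z)


def _tiny_set():
    tracks = []
    for i, speed in enumerate([1.0, 2.0, 3.0]):
        xy = np.column_stack([speed * np.arange(30.0), np.full(30, float(i))])
        tracks.append(Track(f"s{i}", np.arange(30), xy))
    return TrackSet(tracks, fps=1.0, subsample_factor=1)


class TestTrackFeaturizer:
    def test_sklearn_interface(self, uniform_trackset):
        est = TrackFeaturizer(normalization="zscore")
        assert est.get_params()["window_points"] == 20
        table = est.fit(uniform_trackset).transform(uniform_trackset)
        assert table.normalization == "zscore"
        est2 = TrackFeaturizer().set_params(turn_threshold=1.5)
        assert est2.turn_threshold == 1.5

    def test_invalid_normalization_rejected(self, uniform_trackset):
        with pytest.raises(ValueError):
            TrackFeaturizer(normalization="bogus").fit(uniform_trackset)


coord = st.floats(-100, 100, allow_nan=False, width=32)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.lists(st.tuples(coord, coord), min_size=3, max_size=40, unique=True))
def test_sinuosity_properties_hold_for_arbitrary_tracks(pts):
    """Path length dominates displacement, so sinuosity >= 1 and is
    invariant under uniform scaling, for any finite polyline."""
    t = mk(np.array(pts, dtype=float))
    assume(displacement_length(t) > 1e-6)
    s = global_sinuosity(t)
    assert s >= 1 - 1e-12
    scaled = mk(t.xy * 7.25)
    assert global_sinuosity(scaled) == pytest.approx(s, rel=1e-9)


def test_feature_oracle_suite(random_tracks):
    """All five statistics agree with brute-force oracles on 100 seeded tracks."""
    params = FeatureParams()
    for t in random_tracks:
        assert track_length(t) == pytest.approx(brute_track_length(t.xy), rel=1e-9)
        assert global_sinuosity(t) == pytest.approx(
            brute_global_sinuosity(t.xy), rel=1e-9
        )
        got_w = windowed_sinuosity(t, params)
        want_w = brute_windowed_sinuosity(t.xy, params.window_points)
        assert np.abs(got_w - want_w).max() <= 1e-9 * np.abs(want_w).max()
        assert count_turns(t, params) == brute_count_turns(
            t.xy, params.window_points, params.sinuosity_turn_threshold
        )
        if t.n_points >= 3:
            assert count_self_intersections(t) == brute_self_intersections(t.xy)
        got_s = speed_stats(t, random_tracks.fps, random_tracks.subsample_factor)
        want_s = brute_speed_stats(
            t.xy, t.frames, random_tracks.fps, random_tracks.subsample_factor
        )
        assert np.allclose(got_s, want_s, rtol=1e-9)
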