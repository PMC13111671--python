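import numpy as np
import pytest

from ciliaflow.io import Track, TrackSet
from ciliaflow.simulate import SimulationParams, make_flow_field, simulate_tracks

from _oracles import random_track_xy


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_tracks(rng):
    """100 seeded correlated-random-walk tracks with occasional frame gaps."""
    tracks = []
    for i in range(100):
        n = int(rng.integers(5, 120))
        xy = random_track_xy(rng, n)
        frames = np.cumsum(rng.choice([1, 1, 1, 2], size=n))
        tracks.append(Track(f"r{i:03d}", frames, xy))
    return TrackSet(tracks, fps=24.0, subsample_factor=2)


@pytest.fixture
def uniform_trackset():
    """Noiseless straight tracks advected by a uniform 10 µm/s flow."""
    field = make_flow_field("uniform", (0, 500, 0, 500), 10.0, direction=(1, 0))
    params = SimulationParams(
        n_tracks=40,
        duration_s=5,
        diffusion=0.0,
        measurement_noise_sd=0.0,
        seed=7,
    )
    return simulate_tracks(field, params)


@pytest.fixture
def two_species_trackset():
    """Advective + Brownian tracks labelled as two species."""
    dom = (0, 500, 0, 500)
    adv = simulate_tracks(
        make_flow_field("uniform", dom, 10.0, direction=(1, 0)),
        SimulationParams(n_tracks=60, duration_s=5, diffusion=0.5, measurement_noise_sd=0.2, seed=11),
        species="advective",
        id_prefix="a",
    )
    brown = simulate_tracks(
        make_flow_field("none", dom),
        SimulationParams(n_tracks=60, duration_s=5, diffusion=5.0, measurement_noise_sd=0.2, seed=12),
        species="brownian",
        id_prefix="b",
    )
    return TrackSet(adv.tracks + brown.tracks, fps=24.0, subsample_factor=2)
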