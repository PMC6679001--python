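"""Shared fixtures: one synthetic beating-sperm movie traced once per session."""

import numpy as np
import pytest

from flagbeat.kinematics import build_field
from flagbeat.synthetic import WaveformParams, generate_waveform, render_movie
from flagbeat.trace import trace_movie


@pytest.fixture(scope="session")
def beat_params():
    """20 Hz beat, 40 frames (4 full cycles at 200 fps), 10 % ridge noise."""
    return WaveformParams(beat_freq_hz=20.0, n_frames=40, noise_sd=1000.0, seed=1)


@pytest.fixture(scope="session")
def beat_truth(beat_params):
    return generate_waveform(beat_params)


@pytest.fixture(scope="session")
def beat_movie(beat_truth):
    return render_movie(beat_truth)


@pytest.fixture(scope="session")
def beat_trace(beat_movie):
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return trace_movie(beat_movie)


@pytest.fixture(scope="session")
def beat_field(beat_trace):
    return build_field(beat_trace)


def gt_to_movie_px(truth, movie, frame):
    """Ground-truth midline of one frame in the movie's pixel coordinates."""
    origin = np.array(movie.meta["origin_px"])
    return truth.xy_um[frame] / truth.params.pixel_size_um - origin
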